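import numpy as np
import networkx as nx
import pandas as pd
import pytest
from Bio.Align import substitution_matrices

from t2tkit.famscan import (AlignParams, classify_fbh, detect_gene_clusters,
                            extract_srs6, filter_family_candidates, global_align,
                            percent_identity, read_domtbl,
                            tissue_expression_summary)
from t2tkit.models import Alignment, FamilyMember, GeneModel, SeqRecord, SRS6Window
from t2tkit.simulate import simulate_family

AA4 = "ACGT"  # Ala/Cys/Gly/Thr: a 4-letter amino-acid alphabet


def _member(gene_id, seq="ACDEFGHIKL"):
    return FamilyMember(gene_id=gene_id, protein=SeqRecord(gene_id, seq))


def _genes_with_ranks(chrom_ranks):
    """Build a dense annotation where our ids occupy the given ranks."""
    genes = []
    for chrom, ranks in chrom_ranks.items():
        n = max(ranks) + 3
        for r in range(n):
            gid = f"{chrom}_fam{r}" if r in ranks else f"{chrom}_bg{r}"
            genes.append(GeneModel(gid, chrom, r * 1000, r * 1000 + 500, "+", r))
    return genes


class TestFilter:
    def test_inclusive_boundaries(self):
        lengths = {"p399": 399, "p400": 400, "p600": 600, "p601": 601}
        prots = [SeqRecord(n, "A" * L) for n, L in lengths.items()]
        hits = [{"target": n, "evalue": 1e-50, "score": 100.0} for n in lengths]
        members, dropped = filter_family_candidates(hits, prots)
        assert {m.gene_id for m in members} == {"p400", "p600"}
        assert {g for g, _ in dropped} == {"p399", "p601"}

    def test_empty_hits(self):
        assert filter_family_candidates([], []) == ([], [])

    def test_unknown_hit_id_rejected(self):
        with pytest.raises(KeyError, match="ghost"):
            filter_family_candidates([{"target": "ghost", "evalue": 1, "score": 1}],
                                     [])

    def test_synthetic_family_filter_matches_manifest(self, family_cfg):
        fam = simulate_family(family_cfg, 13)
        members, dropped = filter_family_candidates(fam.hits, fam.proteins)
        expect_kept = {m for m, t in fam.truth["members"].items()
                       if not t["filter_excluded"]}
        assert {m.gene_id for m in members} == expect_kept
        assert {g for g, _ in dropped} == set(fam.truth["members"]) - expect_kept

    def test_domtbl_round_trip(self, family_cfg, tmp_path):
        fam = simulate_family(family_cfg, 13)
        paths = fam.write(tmp_path)
        hits = read_domtbl(paths["hits"])
        assert [h["target"] for h in hits] == [h["target"] for h in fam.hits]
        assert hits[0]["score"] == pytest.approx(fam.hits[0]["score"], abs=0.1)


class TestClusters:
    @pytest.mark.parametrize("ranks,n_clusters", [((10, 18), 1), ((10, 19), 0)])
    def test_rank_distance_rule(self, ranks, n_clusters):
        genes = _genes_with_ranks({"Chr1": set(ranks)})
        members = [_member(f"Chr1_fam{r}") for r in ranks]
        assert len(detect_gene_clusters(members, genes)) == n_clusters

    def test_transitive_chaining_and_tandem_pairs(self):
        genes = _genes_with_ranks({"Chr1": {10, 11, 18, 26}})
        members = [_member(f"Chr1_fam{r}") for r in (10, 11, 18, 26)]
        clusters = detect_gene_clusters(members, genes)
        assert len(clusters) == 1
        assert [m.gene_id for m in clusters[0].members] == [
            "Chr1_fam10", "Chr1_fam11", "Chr1_fam18", "Chr1_fam26"]
        assert clusters[0].tandem_pairs == [("Chr1_fam10", "Chr1_fam11")]

    def test_missing_locus_rejected(self):
        with pytest.raises(KeyError, match="lost"):
            detect_gene_clusters([_member("lost")], _genes_with_ranks({"c": {1}}))

    def test_matches_connected_components_oracle(self, rng):
        for _ in range(30):
            n_genes = int(rng.integers(5, 50))
            ranks = sorted(rng.choice(n_genes, size=min(n_genes, 8), replace=False))
            chrom = "Chr" + str(rng.integers(1, 3))
            genes = _genes_with_ranks({chrom: set(int(r) for r in ranks)})
            members = [_member(f"{chrom}_fam{r}") for r in ranks]
            got = {frozenset(m.gene_id for m in c.members)
                   for c in detect_gene_clusters(members, genes)}
            g = nx.Graph()
            g.add_nodes_from(int(r) for r in ranks)
            g.add_edges_from((int(a), int(b)) for a in ranks for b in ranks
                             if a < b and b - a <= 8)
            want = {frozenset(f"{chrom}_fam{r}" for r in comp)
                    for comp in nx.connected_components(g) if len(comp) >= 2}
            assert got == want

    def test_invariant_to_member_order_and_renaming(self):
        genes = _genes_with_ranks({"Chr1": {3, 9, 30, 35}})
        members = [_member(f"Chr1_fam{r}") for r in (3, 9, 30, 35)]
        a = detect_gene_clusters(members, genes)
        b = detect_gene_clusters(members[::-1], genes)
        assert [{m.gene_id for m in c.members} for c in a] == \
               [{m.gene_id for m in c.members} for c in b]


def _brute_force_best_score(a, b, params):
    """Exhaustive enumeration of global alignment paths (affine gaps)."""
    matrix = substitution_matrices.load(params.matrix)

    def gap(state_same):
        return params.gap_extend if state_same else params.gap_open

    best = [-np.inf]

    def walk(i, j, state, score):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            walk(i + 1, j + 1, "M", score + matrix[a[i], b[j]])
        if i < len(a):
            walk(i + 1, j, "D", score + gap(state == "D"))
        if j < len(b):
            walk(i, j + 1, "I", score + gap(state == "I"))

    walk(0, 0, "M", 0.0)
    return best[0]


class TestAlignment:
    def test_identical_sequences(self):
        aln = global_align("MKVLITAAGHQWERTYIPASDFGHKLCVNM",
                           "MKVLITAAGHQWERTYIPASDFGHKLCVNM")
        assert "-" not in aln.aligned_a
        assert percent_identity(aln) == 100.00

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "MKV")

    def test_non_amino_acid_rejected(self):
        with pytest.raises(ValueError):
            global_align("MKV1", "MKV")

    def test_score_matches_exhaustive_oracle_on_small_pairs(self, rng):
        params = AlignParams()
        for _ in range(25):
            la, lb = int(rng.integers(1, 7)), int(rng.integers(1, 7))
            a = "".join(np.array(list(AA4))[rng.integers(0, 4, la)])
            b = "".join(np.array(list(AA4))[rng.integers(0, 4, lb)])
            got = global_align(a, b, params).score
            assert got == pytest.approx(_brute_force_best_score(a, b, params))


class TestPercentIdentity:
    def test_nine_of_ten_columns(self):
        aln = Alignment("ACDEFGHIKL", "ACDEFGHIKV", 0.0)
        assert percent_identity(aln) == 90.00

    def test_gap_columns_count_in_denominator(self):
        aln = Alignment("ACDEF-----", "ACDEFGHIKL", 0.0)
        assert percent_identity(aln) == 50.00

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            Alignment("AC", "ACD", 0.0)

    def test_target_identity_pair_from_generator(self):
        from t2tkit.simulate import FamilyConfig, FamilyMemberSpec
        cfg = FamilyConfig(members=[
            FamilyMemberSpec("p1", identity=0.95),
            FamilyMemberSpec("p2", identity=0.91, derive_from="p1")])
        fam = simulate_family(cfg, 15)
        aln = global_align(fam.proteins[0].seq, fam.proteins[1].seq)
        assert percent_identity(aln) == pytest.approx(91.0, abs=2.0)


class TestSRS6:
    def _anchor(self, rng):
        seq = "".join(np.array(list("ACDEFGHIKLMNPQRSTVWY"))[rng.integers(0, 20, 200)])
        return SeqRecord("anchor", seq)

    def test_anchor_projects_onto_itself(self, rng):
        anchor = self._anchor(rng)
        win = extract_srs6(anchor, anchor, 100, 112)
        assert win.window == anchor.seq[100:112]
        assert win.diagnostic_residue == anchor.seq[107]

    def test_insertion_upstream_does_not_shift_window(self, rng):
        anchor = self._anchor(rng)
        candidate = SeqRecord("cand", anchor.seq[:50] + "WWWWW" + anchor.seq[50:])
        win = extract_srs6(candidate, anchor, 100, 112)
        assert win.window == anchor.seq[100:112]

    def test_planted_residues_recovered(self, family_cfg):
        fam = simulate_family(family_cfg, 16)
        for prot in fam.proteins:
            truth = fam.truth["members"][prot.id]
            if truth["filter_excluded"]:
                continue
            win = extract_srs6(prot, fam.anchor, fam.truth["srs6_start"],
                               fam.truth["srs6_end"])
            assert win.diagnostic_residue == truth["residue"]

    def test_bad_coords_rejected(self, rng):
        anchor = self._anchor(rng)
        with pytest.raises(ValueError):
            extract_srs6(anchor, anchor, 195, 210)


class TestClassify:
    @pytest.mark.parametrize("residue,label", [
        ("T", "F3pH_like"), ("S", "F3pH_like"), ("A", "F3p5pH_like"),
        ("G", "unclassified"), ("-", "unclassified")])
    def test_rule_table(self, residue, label):
        win = SRS6Window("m", "XXXXXXX" + residue, residue)
        assert classify_fbh(win).label == label

    def test_order_invariance_on_synthetic_family(self, family_cfg):
        fam = simulate_family(family_cfg, 17)
        def labels(prots):
            out = {}
            for p in prots:
                win = extract_srs6(p, fam.anchor, fam.truth["srs6_start"],
                                   fam.truth["srs6_end"])
                out[p.id] = classify_fbh(win).label
            return out
        assert labels(fam.proteins) == labels(fam.proteins[::-1])


class TestExpression:
    def _fpkm(self):
        cols = ["FB1", "FB2", "FB3", "L1", "L2", "L3"]
        return pd.DataFrame(
            [[221.6, 221.6, 221.6, 5.0, 5.0, 5.0],
             [10.0, 10.0, 10.0, 5.0, 5.0, 5.0]],
            index=["g1", "g2"], columns=cols)

    def test_equal_means_give_unit_ratio(self):
        out = tissue_expression_summary(self._fpkm(), ["g1", "g2"])
        assert out["fold_ratios"]["g1/g2:L"] == 1.00

    def test_planted_fold_ratio(self):
        out = tissue_expression_summary(self._fpkm(), ["g1", "g2"])
        assert out["fold_ratios"]["g1/g2:FB"] == 22.16

    def test_log10_with_pseudocount(self):
        fpkm = pd.DataFrame([[0.0, 9.0]], index=["g"], columns=["T1", "T2"])
        out = tissue_expression_summary(fpkm, ["g"])
        assert out["log10"].loc["g", "T1"] == 0.0
        assert out["log10"].loc["g", "T2"] == 1.0

    def test_missing_gene_rejected(self):
        with pytest.raises(KeyError, match="ghost"):
            tissue_expression_summary(self._fpkm(), ["ghost"])
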