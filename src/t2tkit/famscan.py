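"""Gene-family mining: HMM-hit filtering, genomic clusters, pairwise
identity, SRS6 extraction and flavonoid B-ring hydroxylase classification.

The profile-HMM search itself (e.g. against the p450 domain model) is
consumed as a domain-table TSV, not re-implemented; this module owns the
downstream rules: the 400-600 aa full-length filter, the eight-ORF
gene-cluster rule, global protein alignment and percent identity, and
the SRS6 position-8 diagnostic (Thr/Ser = F3'H-like CYP75B, Ala =
F3'5'H-like CYP75A).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .models import (Alignment, FamilyMember, FBHClassification, GeneCluster,
                     GeneModel, Interval, SeqRecord, SRS6Window)

AA20 = set("ACDEFGHIKLMNPQRSTVWY")


# ---------------------------------------------------------------------------
# candidate filtering

def read_domtbl(path: str, target_col: int = 0, evalue_col: int = 6,
                score_col: int = 7) -> list[dict]:
    """Parse a domtblout-style whitespace table into hit dicts.

    Column indices are configurable because domain-table layouts differ
    between tools; defaults match the common per-domain table (target
    name first, full-sequence E-value and score in columns 7-8).
    """
    hits: list[dict] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split()
            hits.append({
                "target": cols[target_col],
                "evalue": float(cols[evalue_col]),
                "score": float(cols[score_col]),
            })
    return hits


def filter_family_candidates(hits: list[dict], proteins: list[SeqRecord],
                             min_aa: int = 400, max_aa: int = 600,
                             ) -> tuple[list[FamilyMember], list[tuple[str, str]]]:
    """Keep hits whose protein length is within [min_aa, max_aa] (inclusive).

    Returns (members, dropped) where ``dropped`` pairs each excluded id
    with the reason. A hit with no protein in the FASTA is an error.
    """
    by_id = {p.id: p for p in proteins}
    members: list[FamilyMember] = []
    dropped: list[tuple[str, str]] = []
    seen: set[str] = set()
    for hit in hits:
        pid = hit["target"]
        if pid in seen:
            continue
        seen.add(pid)
        if pid not in by_id:
            raise KeyError(f"hit id {pid!r} absent from protein FASTA")
        prot = by_id[pid]
        if len(prot.seq) < min_aa:
            dropped.append((pid, f"length {len(prot.seq)} < {min_aa} aa"))
        elif len(prot.seq) > max_aa:
            dropped.append((pid, f"length {len(prot.seq)} > {max_aa} aa"))
        else:
            members.append(FamilyMember(gene_id=pid, protein=prot, hmm_hit=hit))
    return members, dropped


# ---------------------------------------------------------------------------
# gene clusters

def detect_gene_clusters(members: list[FamilyMember], all_genes: list[GeneModel],
                         max_gap: int = 8) -> list[GeneCluster]:
    """Group family genes into clusters by the ORF-distance rule.

    Two members are linked iff they sit on the same chromosome within
    ``max_gap`` gene ranks of each other; clusters are the connected
    components of that relation (so chains link transitively), and
    singletons are not reported. Members at adjacent ranks are recorded
    as tandem pairs.
    """
    by_id = {g.gene_id: g for g in all_genes}
    located: list[tuple[FamilyMember, GeneModel]] = []
    for m in members:
        if m.gene_id not in by_id:
            raise KeyError(f"member {m.gene_id!r} missing from gene annotation")
        located.append((m, by_id[m.gene_id]))
        m.locus = by_id[m.gene_id]

    by_chrom: dict[str, list[tuple[FamilyMember, GeneModel]]] = {}
    for m, g in located:
        by_chrom.setdefault(g.chrom, []).append((m, g))

    clusters: list[GeneCluster] = []
    n = 0
    for chrom in sorted(by_chrom):
        entries = sorted(by_chrom[chrom], key=lambda t: t[1].rank)
        # on sorted ranks, transitive chaining == splitting at gaps > max_gap
        current: list[tuple[FamilyMember, GeneModel]] = []
        for entry in entries:
            if current and entry[1].rank - current[-1][1].rank > max_gap:
                clusters.extend(_close_cluster(current, chrom, n))
                n += 1 if len(current) >= 2 else 0
                current = []
            current.append(entry)
        clusters.extend(_close_cluster(current, chrom, n))
        n += 1 if len(current) >= 2 else 0
    return clusters


def _close_cluster(entries: list[tuple[FamilyMember, GeneModel]], chrom: str,
                   idx: int) -> list[GeneCluster]:
    if len(entries) < 2:
        return []
    genes = [g for _, g in entries]
    tandem = [(a.gene_id, b.gene_id)
              for a, b in zip(genes, genes[1:]) if b.rank - a.rank == 1]
    return [GeneCluster(
        cluster_id=f"cluster_{idx + 1:03d}",
        chrom=chrom,
        members=[m for m, _ in entries],
        span=Interval(chrom, min(g.start for g in genes), max(g.end for g in genes)),
        tandem_pairs=tandem,
    )]


# ---------------------------------------------------------------------------
# alignment and identity

@dataclass
class AlignParams:
    matrix: str = "BLOSUM62"
    gap_open: float = -10.0
    gap_extend: float = -0.5


def _aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def global_align(a: str, b: str, params: AlignParams | None = None) -> Alignment:
    """Optimal global protein alignment with affine gap penalties."""
    params = params or AlignParams()
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    for s in (a, b):
        bad = set(s.upper()) - AA20 - {"X"}
        if bad:
            raise ValueError(f"non-amino-acid symbols in input: {sorted(bad)}")
    aln = _aligner(params).align(a.upper(), b.upper())[0]
    return Alignment(aligned_a=str(aln[0]), aligned_b=str(aln[1]),
                     score=float(aln.score))


def percent_identity(alignment: Alignment) -> float:
    """Identical columns over all alignment columns (gaps in the
    denominator), as a percentage rounded to 2 decimals."""
    cols = len(alignment.aligned_a)
    if cols == 0:
        raise ValueError("empty alignment")
    same = sum(1 for x, y in zip(alignment.aligned_a, alignment.aligned_b)
               if x == y and x != "-")
    return round(100.0 * same / cols, 2)


def identity_matrix(members: list[FamilyMember],
                    params: AlignParams | None = None) -> pd.DataFrame:
    ids = [m.gene_id for m in members]
    mat = pd.DataFrame(100.0, index=ids, columns=ids)
    for i, a in enumerate(members):
        for b in members[i + 1:]:
            pid = percent_identity(global_align(a.protein.seq, b.protein.seq, params))
            mat.loc[a.gene_id, b.gene_id] = pid
            mat.loc[b.gene_id, a.gene_id] = pid
    return mat


# ---------------------------------------------------------------------------
# SRS6 extraction and classification

def extract_srs6(candidate: SeqRecord, anchor: SeqRecord, srs6_start: int,
                 srs6_end: int, diagnostic_position: int = 8,
                 params: AlignParams | None = None) -> SRS6Window:
    """Project the anchor's SRS6 columns onto a candidate protein.

    The candidate is globally aligned to the anchor; the candidate
    residues in the alignment columns spanned by the anchor's SRS6
    interval form the window (gaps preserved), and the residue in the
    column of anchor SRS6 position ``diagnostic_position`` (1-based
    within SRS6) is the diagnostic.
    """
    if not (0 <= srs6_start < srs6_end <= len(anchor.seq)):
        raise ValueError("SRS6 coordinates outside anchor protein")
    aln = global_align(candidate.seq, anchor.seq, params)
    window_chars: list[str] = []
    diagnostic = "-"
    anchor_i = 0
    diag_anchor_index = srs6_start + diagnostic_position - 1
    for cand_c, anch_c in zip(aln.aligned_a, aln.aligned_b):
        if anch_c != "-":
            if srs6_start <= anchor_i < srs6_end:
                window_chars.append(cand_c)
                if anchor_i == diag_anchor_index:
                    diagnostic = cand_c
            anchor_i += 1
    return SRS6Window(member_id=candidate.id, window="".join(window_chars),
                      diagnostic_residue=diagnostic,
                      diagnostic_position=diagnostic_position)


def classify_fbh(window: SRS6Window) -> FBHClassification:
    """Call F3'H-like (Thr/Ser), F3'5'H-like (Ala) or unclassified."""
    r = window.diagnostic_residue
    if r in ("T", "S"):
        label = "F3pH_like"
    elif r == "A":
        label = "F3p5pH_like"
    else:
        label = "unclassified"
    return FBHClassification(member_id=window.member_id, label=label, evidence=r)


# ---------------------------------------------------------------------------
# expression summaries

def tissue_expression_summary(fpkm: pd.DataFrame, genes: list[str],
                              tissue_of_sample: dict[str, str] | None = None,
                              pseudo: float = 1.0) -> dict:
    """log10-normalized expression plus per-tissue means and fold ratios.

    ``fpkm`` is genes x samples. Samples map to tissues either via
    ``tissue_of_sample`` or by stripping a trailing replicate number
    from the sample name (``FB1`` -> ``FB``). Heatmap values are
    log10(FPKM + pseudo); fold ratios between genes are computed on raw
    tissue means, reported to 2 decimals.
    """
    missing = [g for g in genes if g not in fpkm.index]
    if missing:
        raise KeyError(f"gene ids missing from FPKM matrix: {missing}")
    sub = fpkm.loc[genes].astype(float)
    if (sub.values < 0).any():
        raise ValueError("FPKM values must be non-negative")
    if tissue_of_sample is None:
        tissue_of_sample = {c: c.rstrip("0123456789") for c in sub.columns}
    tissues = pd.Series({c: tissue_of_sample[c] for c in sub.columns})
    means = sub.T.groupby(tissues).mean().T  # genes x tissues
    log10 = np.log10(sub + pseudo)
    ratios: dict[str, float] = {}
    for ga in genes:
        for gb in genes:
            if ga == gb:
                continue
            for tissue in means.columns:
                denom = means.loc[gb, tissue]
                if denom > 0:
                    ratios[f"{ga}/{gb}:{tissue}"] = round(
                        float(means.loc[ga, tissue] / denom), 2)
    return {"log10": log10, "tissue_means": means, "fold_ratios": ratios}
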