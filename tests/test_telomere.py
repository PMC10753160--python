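import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from t2tkit.models import SeqRecord, TerminalAlignment
from t2tkit.simulate import (ChromosomeSpec, GenomeConfig, simulate_genome,
                             simulate_terminal_reads)
from t2tkit.telomere import (MOTIF_3PRIME, MOTIF_5PRIME, TelomereParams,
                             call_telomeres, collect_terminal_reads,
                             count_motif_repeats, patch_terminus, revcomp,
                             select_reference_read, telomere_count,
                             terminal_repeat_counts)


def _sliding_scan_oracle(seq: str, motif: str) -> int:
    """Regex-free left-to-right greedy non-overlapping count."""
    n, i = 0, 0
    while i + len(motif) <= len(seq):
        if seq[i:i + len(motif)] == motif:
            n += 1
            i += len(motif)
        else:
            i += 1
    return n


class TestCountMotifRepeats:
    def test_empty_sequence(self):
        assert count_motif_repeats("", MOTIF_5PRIME) == 0

    def test_five_copies_in_random_flanks(self, rng):
        flank = "".join(rng.choice(list("AG"), size=50))  # cannot form the motif
        seq = flank + MOTIF_5PRIME * 5 + flank
        assert count_motif_repeats(seq, MOTIF_5PRIME) == 5

    def test_strand_specific(self):
        arr = MOTIF_5PRIME * 5
        assert count_motif_repeats(revcomp(arr), MOTIF_5PRIME) == 0

    def test_empty_motif_rejected(self):
        with pytest.raises(ValueError):
            count_motif_repeats("ACGT", "")

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=0, max_size=2000),
           st.text(alphabet="ACGT", min_size=1, max_size=8))
    def test_matches_sliding_scan_oracle(self, seq, motif):
        assert count_motif_repeats(seq, motif) == _sliding_scan_oracle(seq, motif)

    def test_matches_oracle_on_long_repeat_rich_string(self, rng):
        pieces = [MOTIF_3PRIME, "TTTAGG", "A", "TTAGGG"]
        seq = "".join(pieces[i] for i in rng.integers(0, 4, size=2500))
        assert len(seq) > 10_000
        assert count_motif_repeats(seq, MOTIF_3PRIME) == \
            _sliding_scan_oracle(seq, MOTIF_3PRIME)


class TestTerminalCounts:
    def test_planted_counts_recovered(self, small_bundle):
        rec = small_bundle.record("Chr2")
        assert terminal_repeat_counts(rec) == (50, 300)

    def test_record_shorter_than_window_is_clipped(self):
        rec = SeqRecord("t", MOTIF_5PRIME * 3 + "A" * 10)
        c5, c3 = terminal_repeat_counts(rec, terminal_window=10 ** 6)
        assert (c5, c3) == (3, 0)


class TestCallTelomeres:
    def test_two_repeats_is_not_a_telomere(self):
        seq = MOTIF_5PRIME * 2 + "A" * 2000
        calls = call_telomeres([SeqRecord("c", seq)],
                               TelomereParams(min_repeats=100, terminal_window=2000))
        call5 = next(c for c in calls if c.end == "5prime")
        assert call5.repeat_count == 2 and not call5.is_telomere

    def test_bare_genome_has_zero_telomeres(self, rng):
        seq = "".join(rng.choice(list("AG"), size=5000))
        calls = call_telomeres([SeqRecord("c", seq)])
        assert telomere_count(calls) == 0

    def test_planted_ends_all_called(self, small_bundle):
        calls = call_telomeres(small_bundle.genome)
        # Chr1 has 120/200 copies, Chr2 has 50/300: the 50-copy end fails
        assert telomere_count(calls) == 3
        for c in calls:
            key = "tel5" if c.end == "5prime" else "tel3"
            assert c.repeat_count == small_bundle.manifest["chromosomes"][c.chrom][key]


class TestCollectTerminalReads:
    def test_window_boundaries(self):
        L = 100_000
        near = TerminalAlignment("near", 5000, "Chr1", L - 5010, L - 10, "+")
        far = TerminalAlignment("far", 5000, "Chr1", L - 5100, L - 100, "+")
        head = TerminalAlignment("head", 5000, "Chr1", 30, 5030, "+")
        got = collect_terminal_reads([near, far, head], {"Chr1": L}, screen_window=50)
        assert got[("Chr1", "3prime")] == {"near"}
        assert got[("Chr1", "5prime")] == {"head"}

    def test_empty_alignments(self):
        assert collect_terminal_reads([], {"Chr1": 100}) == {}

    def test_unknown_chromosome_rejected(self):
        aln = TerminalAlignment("r", 100, "ChrX", 0, 100, "+")
        with pytest.raises(ValueError, match="ChrX"):
            collect_terminal_reads([aln], {"Chr1": 1000})


class TestSelectReferenceRead:
    def test_ties_break_by_length_then_id(self):
        reads = [SeqRecord("r1", MOTIF_3PRIME * 5 + "A" * 10),
                 SeqRecord("r2", MOTIF_3PRIME * 9 + "A" * 30),
                 SeqRecord("r3", MOTIF_3PRIME * 9 + "A" * 10)]
        sel = select_reference_read(reads, MOTIF_3PRIME)
        assert sel.reference_read == "r2"
        assert sel.query_reads == ["r1", "r3"]
        assert sel.reference_repeat_count == 9

    def test_single_read(self):
        sel = select_reference_read([SeqRecord("only", "ACGT" * 10)], MOTIF_3PRIME)
        assert sel.reference_read == "only" and sel.query_reads == []

    def test_all_zero_counts_still_selects(self):
        reads = [SeqRecord("a", "AAAA"), SeqRecord("b", "CCCC")]
        sel = select_reference_read(reads, MOTIF_3PRIME)
        assert sel.reference_read in ("a", "b")
        assert sel.reference_repeat_count == 0

    def test_empty_read_set_rejected(self):
        with pytest.raises(ValueError):
            select_reference_read([], MOTIF_3PRIME)


def _truncated_bundle(seed=5):
    cfg = GenomeConfig(chromosomes=[
        ChromosomeSpec("Chr1", 300_000, tel5=150, tel3=20)])
    return simulate_genome(cfg, seed)


class TestPatch:
    def test_truncated_end_patched_to_reference_depth(self):
        bundle = _truncated_bundle()
        reads, alns = simulate_terminal_reads(bundle, "Chr1", "3prime", n_reads=5,
                                              extension=130 * 7, error_rate=0.0,
                                              seed=6)
        sel = select_reference_read(reads, MOTIF_3PRIME, "Chr1", "3prime",
                                    strands={a.read_id: a.strand for a in alns})
        truth = bundle.manifest["terminal_reads"]["Chr1:3prime"]
        assert sel.reference_repeat_count == max(truth.values()) == 150
        anchor = next(a for a in alns if a.read_id == sel.reference_read)
        read = next(r for r in reads if r.id == sel.reference_read)
        patched, report = patch_terminus(bundle.record("Chr1"), sel, anchor, read)
        assert report.status == "patched"
        assert report.pre_count == 20
        assert report.post_count == 150 == truth[sel.reference_read]
        assert terminal_repeat_counts(patched)[1] == 150

    def test_monotonic_over_both_strand_orientations(self):
        # patching must work regardless of which strand the donor aligned on
        bundle = _truncated_bundle(seed=9)
        reads, alns = simulate_terminal_reads(bundle, "Chr1", "3prime", n_reads=8,
                                              extension=400, error_rate=0.0, seed=10)
        assert {a.strand for a in alns} == {"+", "-"}
        for aln in alns:
            read = next(r for r in reads if r.id == aln.read_id)
            sel = select_reference_read([read], MOTIF_3PRIME, "Chr1", "3prime",
                                        strands={aln.read_id: aln.strand})
            patched, rep = patch_terminus(bundle.record("Chr1"), sel, aln, read)
            assert rep.post_count >= rep.pre_count

    def test_five_prime_patch(self):
        cfg = GenomeConfig(chromosomes=[ChromosomeSpec("Chr1", 300_000,
                                                       tel5=15, tel3=150)])
        bundle = simulate_genome(cfg, 8)
        reads, alns = simulate_terminal_reads(bundle, "Chr1", "5prime", n_reads=4,
                                              extension=100 * 7, error_rate=0.0,
                                              seed=9)
        sel = select_reference_read(reads, MOTIF_5PRIME, "Chr1", "5prime",
                                    strands={a.read_id: a.strand for a in alns})
        anchor = next(a for a in alns if a.read_id == sel.reference_read)
        read = next(r for r in reads if r.id == sel.reference_read)
        patched, rep = patch_terminus(bundle.record("Chr1"), sel, anchor, read)
        assert rep.status == "patched"
        assert terminal_repeat_counts(patched)[0] == 115

    def test_complete_end_left_untouched(self):
        bundle = _truncated_bundle()
        rec = bundle.record("Chr1")
        reads, alns = simulate_terminal_reads(bundle, "Chr1", "3prime", n_reads=1,
                                              extension=0, error_rate=0.0, seed=6)
        sel = select_reference_read(reads, MOTIF_3PRIME, "Chr1", "3prime")
        patched, rep = patch_terminus(rec, sel, alns[0], reads[0])
        assert rep.status == "already_complete"
        assert patched.seq == rec.seq

    def test_chromosome_mismatch_rejected(self):
        bundle = _truncated_bundle()
        reads, alns = simulate_terminal_reads(bundle, "Chr1", "3prime", n_reads=1,
                                              extension=70, error_rate=0.0, seed=6)
        sel = select_reference_read(reads, MOTIF_3PRIME, "Chr1", "3prime")
        other = SeqRecord("Chr9", "A" * 1000)
        with pytest.raises(ValueError, match="Chr9"):
            patch_terminus(other, sel, alns[0], reads[0])
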