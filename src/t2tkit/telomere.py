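"""Telomere motif scanning, end classification, and terminal patching.

The workflow mirrors how gap-free plant assemblies are finished: count
telomere repeat motifs (CCCATTT at the 5' end, TTTAGGG at the 3' end) in
a terminal window of each pseudochromosome, classify ends as telomeric
when the count clears a threshold, and for incomplete ends splice in the
terminal ultra-long read that carries the deepest repeat array.
"""

from __future__ import annotations

from dataclasses import dataclass

from .models import PatchReport, ReadSelection, SeqRecord, TelomereCall, TerminalAlignment

MOTIF_5PRIME = "CCCATTT"
MOTIF_3PRIME = "TTTAGGG"

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class TelomereParams:
    """Scan parameters.

    ``min_repeats`` and ``terminal_window`` are artifact defaults chosen
    so that a 111-repeat end classifies as telomeric while a 2-repeat
    end does not; both are exposed on the CLI.
    """

    motif5: str = MOTIF_5PRIME
    motif3: str = MOTIF_3PRIME
    terminal_window: int = 150_000
    min_repeats: int = 100


def count_motif_repeats(seq: str, motif: str) -> int:
    """Count non-overlapping exact occurrences of ``motif``, left-to-right greedy.

    Strand-specific: the reverse complement of an array scores 0.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    return seq.upper().count(motif.upper())


def terminal_repeat_counts(record: SeqRecord, motif5: str = MOTIF_5PRIME,
                           motif3: str = MOTIF_3PRIME,
                           terminal_window: int = 150_000) -> tuple[int, int]:
    """Count motif5 in the leading window and motif3 in the trailing window.

    Windows are clipped to the sequence length, so short records are
    scanned whole.
    """
    w = min(terminal_window, len(record.seq))
    c5 = count_motif_repeats(record.seq[:w], motif5)
    c3 = count_motif_repeats(record.seq[len(record.seq) - w:], motif3)
    return c5, c3


def call_telomeres(records: list[SeqRecord],
                   params: TelomereParams | None = None) -> list[TelomereCall]:
    """Classify both ends of every record; two calls per record."""
    params = params or TelomereParams()
    calls: list[TelomereCall] = []
    for rec in records:
        c5, c3 = terminal_repeat_counts(rec, params.motif5, params.motif3,
                                        params.terminal_window)
        w = min(params.terminal_window, len(rec.seq))
        calls.append(TelomereCall(rec.id, "5prime", c5, w,
                                  c5 >= params.min_repeats, params.motif5))
        calls.append(TelomereCall(rec.id, "3prime", c3, w,
                                  c3 >= params.min_repeats, params.motif3))
    return calls


def telomere_count(calls: list[TelomereCall]) -> int:
    return sum(1 for c in calls if c.is_telomere)


def collect_terminal_reads(alignments: list[TerminalAlignment],
                           chrom_lengths: dict[str, int],
                           screen_window: int = 50) -> dict[tuple[str, str], set[str]]:
    """Assign reads to chromosome ends using a terminal screening window.

    A read belongs to (chrom, 5prime) iff its target start lies within
    ``screen_window`` bp of position 0, and to (chrom, 3prime) iff its
    target end lies within ``screen_window`` bp of the chromosome end.
    A read may satisfy both on a short chromosome.
    """
    out: dict[tuple[str, str], set[str]] = {}
    for a in alignments:
        if a.chrom not in chrom_lengths:
            raise ValueError(f"alignment references unknown chromosome {a.chrom!r}")
        L = chrom_lengths[a.chrom]
        if a.target_start <= screen_window:
            out.setdefault((a.chrom, "5prime"), set()).add(a.read_id)
        if L - a.target_end <= screen_window:
            out.setdefault((a.chrom, "3prime"), set()).add(a.read_id)
    return out


def select_reference_read(reads: list[SeqRecord], motif: str,
                          chrom: str = "", end: str = "",
                          strands: dict[str, str] | None = None) -> ReadSelection:
    """Pick the read with the most motif repeats as the patch reference.

    Counting is strand-specific, so reads that aligned on the minus
    strand must be counted in target orientation: pass their alignment
    strands via ``strands`` (read id -> "+"/"-") to have minus-strand
    reads reverse-complemented before counting. Ties break to the
    longest read, then the lexicographically smallest id, so selection
    is deterministic.
    """
    if not reads:
        raise ValueError("no terminal reads to select from")
    strands = strands or {}

    def oriented(r: SeqRecord) -> str:
        return revcomp(r.seq) if strands.get(r.id) == "-" else r.seq

    counts = {r.id: count_motif_repeats(oriented(r), motif) for r in reads}
    ref = min(reads, key=lambda r: (-counts[r.id], -len(r.seq), r.id))
    return ReadSelection(
        chrom=chrom, end=end,
        reference_read=ref.id,
        query_reads=sorted(r.id for r in reads if r.id != ref.id),
        reference_repeat_count=counts[ref.id],
    )


def patch_terminus(record: SeqRecord, selection: ReadSelection,
                   anchor: TerminalAlignment, read: SeqRecord,
                   params: TelomereParams | None = None) -> tuple[SeqRecord, PatchReport]:
    """Replace a chromosome terminus with the reference read's sequence.

    The aligned span of the reference read substitutes the terminal span
    it covers on the chromosome; any unaligned read overhang (extra
    telomere repeats the assembly lacks) extends the chromosome. If the
    read does not improve the repeat count the sequence is left
    untouched and the report says ``already_complete``.
    """
    params = params or TelomereParams()
    if anchor.chrom != record.id:
        raise ValueError(
            f"anchor maps to {anchor.chrom!r}, record is {record.id!r}"
        )
    if anchor.read_id != selection.reference_read:
        raise ValueError("anchor does not belong to the selected reference read")

    motif = params.motif5 if selection.end == "5prime" else params.motif3
    c5, c3 = terminal_repeat_counts(record, params.motif5, params.motif3,
                                    params.terminal_window)
    pre = c5 if selection.end == "5prime" else c3
    if selection.reference_repeat_count <= pre:
        return record, PatchReport(record.id, selection.end, pre, pre, 0,
                                   "already_complete")

    # Orient the read to the target strand; PAF query coords are on the
    # forward read strand, so flip them when the read aligned reversed.
    if anchor.strand == "+":
        oriented = read.seq
        q_start, q_end = anchor.query_start, anchor.query_end
    else:
        oriented = revcomp(read.seq)
        q_start = anchor.read_len - anchor.query_end
        q_end = anchor.read_len - anchor.query_start

    if selection.end == "5prime":
        # everything up to the aligned read suffix replaces the chromosome head
        new_seq = oriented[:q_end] + record.seq[anchor.target_end:]
        replaced = anchor.target_end
    else:
        new_seq = record.seq[:anchor.target_start] + oriented[q_start:]
        replaced = len(record.seq) - anchor.target_start

    patched = SeqRecord(id=record.id, seq=new_seq, description=record.description)
    p5, p3 = terminal_repeat_counts(patched, params.motif5, params.motif3,
                                    params.terminal_window)
    post = p5 if selection.end == "5prime" else p3
    if post < pre:
        # donor read would degrade the end (e.g. error-riddled read): keep original
        return record, PatchReport(record.id, selection.end, pre, pre, 0,
                                   "already_complete")
    return patched, PatchReport(record.id, selection.end, pre, post, replaced,
                                "patched")
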