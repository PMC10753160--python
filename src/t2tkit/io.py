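"""Readers/writers for FASTA, GFF3, PAF, BED and TSV inputs.

Coordinate conventions are normalized here and nowhere else: GFF3 is
1-based inclusive on disk and 0-based half-open in memory; PAF and BED
are already 0-based half-open and pass through unchanged.
"""

from __future__ import annotations

import os
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .models import GeneModel, Interval, SeqRecord, TerminalAlignment


def read_fasta(path: str | os.PathLike, kind: str | None = None) -> list[SeqRecord]:
    """Read a FASTA file into uppercase :class:`SeqRecord` objects.

    Parameters
    ----------
    path:
        FASTA file path. An empty file yields an empty list.
    kind:
        Optional alphabet check: ``"dna"`` or ``"protein"``.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for bio in SeqIO.parse(str(path), "fasta"):
        if bio.id in seen:
            raise ValueError(f"duplicate FASTA id: {bio.id!r}")
        seen.add(bio.id)
        seq = str(bio.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence under header {bio.id!r}")
        rec = SeqRecord(id=bio.id, seq=seq, description=bio.description)
        if kind:
            rec.validate_alphabet(kind)
        records.append(rec)
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | os.PathLike, width: int = 60) -> None:
    """Write records as multi-FASTA, wrapping sequence lines at ``width``."""
    bio_records = [
        BioSeqRecord(Seq(r.seq), id=r.id, description="")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio_records)


def read_gff_genes(path: str | os.PathLike) -> list[GeneModel]:
    """Parse gene features from a GFF3 file into 0-based half-open models.

    Genes are sorted by (chrom, start) and given a dense per-chromosome
    ``rank`` in that order.
    """
    raw: list[tuple[str, int, int, str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise ValueError(f"{path}: line {lineno}: expected 9 GFF columns, got {len(cols)}")
            if cols[2] != "gene":
                continue
            chrom, start1, end1, strand, attrs = cols[0], cols[3], cols[4], cols[6], cols[8]
            start1, end1 = int(start1), int(end1)
            if start1 > end1:
                raise ValueError(f"{path}: line {lineno}: start > end ({start1} > {end1})")
            gene_id = _gff_attribute(attrs, "ID")
            if gene_id is None:
                raise ValueError(f"{path}: line {lineno}: gene feature lacks ID attribute")
            raw.append((chrom, start1 - 1, end1, strand, gene_id))
    raw.sort(key=lambda t: (t[0], t[1], t[4]))
    genes: list[GeneModel] = []
    rank = 0
    prev_chrom = None
    for chrom, start, end, strand, gene_id in raw:
        if chrom != prev_chrom:
            rank = 0
            prev_chrom = chrom
        genes.append(GeneModel(gene_id=gene_id, chrom=chrom, start=start, end=end,
                               strand=strand, rank=rank))
        rank += 1
    return genes


def write_gff_genes(genes: Iterable[GeneModel], path: str | os.PathLike,
                    source: str = "t2tkit") -> None:
    """Write gene models as GFF3 (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


def _gff_attribute(attrs: str, key: str) -> str | None:
    for field in attrs.split(";"):
        field = field.strip()
        if field.startswith(key + "="):
            return field[len(key) + 1:]
    return None


def read_paf(path: str | os.PathLike) -> list[TerminalAlignment]:
    """Parse a PAF file (12+ columns) into :class:`TerminalAlignment` records."""
    alns: list[TerminalAlignment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ValueError(
                    f"{path}: line {lineno}: PAF needs >=12 columns, got {len(cols)}"
                )
            alns.append(TerminalAlignment(
                read_id=cols[0],
                read_len=int(cols[1]),
                query_start=int(cols[2]),
                query_end=int(cols[3]),
                strand=cols[4],
                chrom=cols[5],
                target_start=int(cols[7]),
                target_end=int(cols[8]),
                mapq=int(cols[11]),
            ))
    return alns


def write_paf(alns: Iterable[TerminalAlignment], path: str | os.PathLike,
              target_lengths: dict[str, int] | None = None) -> None:
    target_lengths = target_lengths or {}
    with open(path, "w") as fh:
        for a in alns:
            tlen = target_lengths.get(a.chrom, a.target_end)
            span = a.target_end - a.target_start
            fh.write("\t".join(map(str, [
                a.read_id, a.read_len, a.query_start, a.query_end, a.strand,
                a.chrom, tlen, a.target_start, a.target_end, span, span, a.mapq,
            ])) + "\n")


def read_bed(path: str | os.PathLike) -> list[Interval]:
    """Read BED3(+label) intervals; coordinates pass through unchanged."""
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}: line {lineno}: BED needs >=3 columns")
            label = cols[3] if len(cols) > 3 else ""
            out.append(Interval(chrom=cols[0], start=int(cols[1]), end=int(cols[2]),
                                label=label))
    return out


def write_bed(intervals: Iterable[Interval], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")
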