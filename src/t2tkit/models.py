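"""Domain types shared across the toolkit.

All genomic coordinates are 0-based half-open throughout the package;
conversion to/from 1-based inclusive (GFF3) happens only in :mod:`t2tkit.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_DNA_ALPHABET = frozenset("ACGTN")
_AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")


@dataclass
class SeqRecord:
    """A named sequence (DNA or protein), residues uppercase."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record must have a non-empty id")
        self.seq = self.seq.upper()

    def __len__(self) -> int:
        return len(self.seq)

    def validate_alphabet(self, kind: str = "dna") -> None:
        allowed = _DNA_ALPHABET if kind == "dna" else _AA_ALPHABET
        bad = set(self.seq) - allowed
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid {kind} symbols {sorted(bad)}"
            )


@dataclass(frozen=True)
class GeneModel:
    """A located, stranded gene with its rank in chromosome gene order.

    ``rank`` is the dense 0-based index of the gene among all genes on its
    chromosome when sorted by start; it is the unit in which the
    eight-ORF gene-cluster rule measures distance.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    rank: int = -1

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: invalid interval [{self.start},{self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start},{self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TerminalAlignment:
    """A read-to-assembly mapping (PAF line), 0-based half-open.

    Query coordinates are kept (PAF-native, always on the forward read
    strand) because terminal patching must know which part of the donor
    read is anchored to the assembly and which part overhangs it.
    """

    read_id: str
    read_len: int
    chrom: str
    target_start: int
    target_end: int
    strand: str
    mapq: int = 60
    query_start: int = 0
    query_end: int = -1

    def __post_init__(self) -> None:
        if self.read_len <= 0:
            raise ValueError(f"read {self.read_id}: non-positive length")
        if not (0 <= self.target_start < self.target_end):
            raise ValueError(
                f"read {self.read_id}: invalid target interval "
                f"[{self.target_start},{self.target_end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"read {self.read_id}: strand must be + or -")
        if self.query_end < 0:
            object.__setattr__(self, "query_end", self.read_len)


@dataclass(frozen=True)
class TelomereCall:
    """Per-chromosome-end telomere evidence and verdict."""

    chrom: str
    end: str  # "5prime" | "3prime"
    repeat_count: int
    scanned_window: int
    is_telomere: bool
    motif: str


@dataclass
class ReadSelection:
    """Terminal reads chosen for one chromosome end: one reference, rest queries."""

    chrom: str
    end: str
    reference_read: str
    query_reads: list[str]
    reference_repeat_count: int


@dataclass
class PatchReport:
    chrom: str
    end: str
    pre_count: int
    post_count: int
    replaced_span: int
    status: str  # "patched" | "no_reads" | "already_complete"


@dataclass(frozen=True)
class TandemArray:
    """A detected tandem repeat array: [start, end) with repeat unit ``period``."""

    chrom: str
    start: int
    end: int
    period: int
    purity: float

    @property
    def copies(self) -> float:
        return (self.end - self.start) / self.period

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class WindowFeature:
    chrom: str
    start: int
    end: int
    tandem_fraction: float
    gene_count: int
    gypsy_fraction: float
    hic_blank: bool = False


@dataclass
class CentromereCall:
    """Per-chromosome centromere candidates and the selected interval (if any)."""

    chrom: str
    candidates: list[Interval]
    scores: list[float]
    selected: Interval | None
    ambiguous: bool

    @property
    def length(self) -> int:
        return len(self.selected) if self.selected is not None else 0


@dataclass
class KmerSurvey:
    """Assembly-vs-reads k-mer comparison for consensus QV estimation.

    ``assembly_total`` counts assembly k-mer positions (with multiplicity,
    N-containing windows excluded); ``assembly_missing`` counts those whose
    canonical k-mer is unsupported by the read k-mer set.
    """

    k: int
    assembly_total: int
    assembly_missing: int
    read_kmer_min_count: int = 2


@dataclass
class FamilyMember:
    gene_id: str
    protein: SeqRecord
    locus: GeneModel | None = None
    hmm_hit: dict | None = None

    @property
    def length_aa(self) -> int:
        return len(self.protein.seq)


@dataclass
class GeneCluster:
    """Two or more family genes within ``max_gap`` ORF ranks of each other."""

    cluster_id: str
    chrom: str
    members: list[FamilyMember]
    span: Interval
    tandem_pairs: list[tuple[str, str]]


@dataclass
class SRS6Window:
    """Candidate residues projected onto the anchor's SRS6 columns."""

    member_id: str
    window: str
    diagnostic_residue: str
    diagnostic_position: int = 8


@dataclass
class FBHClassification:
    """B-ring hydroxylase call from the SRS6 position-8 residue.

    Thr/Ser at position 8 marks CYP75B-type F3'H enzymes; Ala marks
    CYP75A-type F3'5'H enzymes; anything else is left unclassified.
    """

    member_id: str
    label: str  # "F3pH_like" | "F3p5pH_like" | "unclassified"
    evidence: str


@dataclass
class Alignment:
    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings must have equal length")
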