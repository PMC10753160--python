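"""Deterministic synthetic genomes, reads, families and expression tables.

Every generator draws from a single seeded NumPy generator, so a
(config, seed) pair maps to byte-identical artifacts, and every planted
feature is recorded in a machine-readable truth manifest that fully
determines what each downstream detector should report on error-free
input.

What the generator emulates: pseudochromosomes with terminal telomere
arrays of configured repeat counts; centromeric tandem arrays sitting in
gene-poor, Gypsy-rich windows; ultra-long terminal reads that overhang a
(possibly truncated) chromosome end with extra telomere repeats; a
protein family derived from a shared anchor with planted SRS6
diagnostic residues, target identities and gene-cluster layouts; and
assemblies with a known substitution-error rate for QV ground truth.
Background sequence is i.i.d. uniform ACGT with one deliberate
exception: chance occurrences of the telomere motifs outside the
planted arrays are removed, so that motif counts over terminal windows
equal the manifest exactly.
"""

from __future__ import annotations

import copy
import json
from bisect import bisect_right
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .models import GeneModel, Interval, SeqRecord, TerminalAlignment
from .telomere import MOTIF_3PRIME, MOTIF_5PRIME, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_AA20 = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# configuration

@dataclass
class CentromereSpec:
    """One planted centromeric tandem array."""

    monomer_len: int = 171
    copies: int = 2500
    divergence: float = 0.02
    start: int | None = None  # None -> centered (or evenly spread for twins)

    @property
    def length(self) -> int:
        return self.monomer_len * self.copies


@dataclass
class ChromosomeSpec:
    name: str
    length: int
    tel5: int = 0  # telomere motif copies at the 5' terminus
    tel3: int = 0
    centromeres: list[CentromereSpec] = field(default_factory=list)


@dataclass
class GenomeConfig:
    chromosomes: list[ChromosomeSpec]
    motif5: str = MOTIF_5PRIME
    motif3: str = MOTIF_3PRIME
    gene_spacing: int = 20_000        # mean gene start spacing outside centromeres
    gene_length_mean: int = 4004      # mean annotated gene span
    gene_length_sd: int = 1200
    genes_in_centromere: bool = False
    gypsy_background: float = 0.05    # Gypsy coverage outside centromeres
    gypsy_centromere: float = 0.30    # Gypsy coverage inside centromeres
    gypsy_element_len: int = 5000


@dataclass
class GenomeBundle:
    """A synthetic genome with annotations and its truth manifest."""

    genome: list[SeqRecord]
    genes: list[GeneModel]
    gypsy: list[Interval]
    manifest: dict
    config: GenomeConfig

    def chrom_lengths(self) -> dict[str, int]:
        return {r.id: len(r.seq) for r in self.genome}

    def record(self, chrom: str) -> SeqRecord:
        return next(r for r in self.genome if r.id == chrom)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        from . import io as tio
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": out / "genome.fasta",
            "genes": out / "genes.gff3",
            "gypsy": out / "gypsy.bed",
            "manifest": out / "truth.json",
        }
        tio.write_fasta(self.genome, paths["genome"])
        tio.write_gff_genes(self.genes, paths["genes"])
        tio.write_bed(self.gypsy, paths["gypsy"])
        paths["manifest"].write_text(json.dumps(self.manifest, indent=1, sort_keys=True))
        return paths


# ---------------------------------------------------------------------------
# genome simulation

def simulate_genome(cfg: GenomeConfig, seed: int) -> GenomeBundle:
    """Build a genome with planted telomeres, centromeres, genes and Gypsy.

    Identical (cfg, seed) pairs produce byte-identical outputs.
    """
    rng = np.random.default_rng(seed)
    records: list[SeqRecord] = []
    genes: list[GeneModel] = []
    gypsy: list[Interval] = []
    manifest: dict = {
        "seed": int(seed),
        "motif5": cfg.motif5,
        "motif3": cfg.motif3,
        "chromosomes": {},
    }

    for spec in cfg.chromosomes:
        tel5_bp = spec.tel5 * len(cfg.motif5)
        tel3_bp = spec.tel3 * len(cfg.motif3)
        if tel5_bp + tel3_bp > spec.length:
            raise ValueError(
                f"{spec.name}: telomere arrays ({tel5_bp}+{tel3_bp} bp) exceed "
                f"chromosome length {spec.length}")
        seq = bytearray(rng.choice(_BASES, size=spec.length).tobytes())
        seq[:tel5_bp] = (cfg.motif5 * spec.tel5).encode()
        if tel3_bp:
            seq[-tel3_bp:] = (cfg.motif3 * spec.tel3).encode()

        cen_truth: list[tuple[int, int]] = []
        n_cen = len(spec.centromeres)
        for ci, cen in enumerate(spec.centromeres):
            if not (0.0 <= cen.divergence <= 0.5):
                raise ValueError(f"{spec.name}: monomer divergence must be in [0, 0.5]")
            if cen.start is not None:
                start = cen.start
            else:
                # centre a single array; spread twins evenly
                start = (spec.length * (ci + 1)) // (n_cen + 1) - cen.length // 2
            end = start + cen.length
            if start < tel5_bp or end > spec.length - tel3_bp:
                raise ValueError(f"{spec.name}: centromere [{start},{end}) does not fit")
            arr = _tandem_array(cen, cfg, rng)
            seq[start:end] = arr
            cen_truth.append((start, end))

        protected = [(0, tel5_bp)] if tel5_bp else []
        if tel3_bp:
            protected.append((spec.length - tel3_bp, spec.length))
        _scrub_motifs(seq, protected, [cfg.motif5, cfg.motif3], rng)
        records.append(SeqRecord(id=spec.name, seq=seq.decode()))

        chrom_genes = _place_genes(spec, cfg, cen_truth, tel5_bp, tel3_bp, rng)
        genes.extend(chrom_genes)
        gypsy.extend(_place_gypsy(spec, cfg, cen_truth, rng))

        manifest["chromosomes"][spec.name] = {
            "length": spec.length,
            "tel5": spec.tel5,
            "tel3": spec.tel3,
            "centromeres": [[s, e] for s, e in cen_truth],
            "n_genes": len(chrom_genes),
        }
    return GenomeBundle(genome=records, genes=genes, gypsy=gypsy,
                        manifest=manifest, config=cfg)


def _tandem_array(cen: CentromereSpec, cfg: GenomeConfig, rng) -> bytes:
    """Tile a scrubbed random monomer and apply per-base divergence."""
    while True:
        monomer = rng.choice(_BASES, size=cen.monomer_len).tobytes()
        doubled = (monomer + monomer).decode()
        if cfg.motif5 not in doubled and cfg.motif3 not in doubled:
            break
    arr = np.frombuffer(monomer * cen.copies, dtype=np.uint8).copy()
    if cen.divergence > 0:
        hit = np.nonzero(rng.random(arr.size) < cen.divergence)[0]
        shift = rng.integers(1, 4, size=hit.size)
        code = {65: 0, 67: 1, 71: 2, 84: 3}
        codes = np.array([code[b] for b in arr[hit]])
        arr[hit] = _BASES[(codes + shift) % 4]
    return arr.tobytes()


def _scrub_motifs(seq: bytearray, protected: list[tuple[int, int]],
                  motifs: list[str], rng) -> None:
    """Remove motif occurrences lying (partly) outside protected intervals.

    Each offending occurrence gets one base outside the protected spans
    swapped for a different random base; rescans until clean.
    """
    protected = sorted(protected)

    def shielded(pos: int) -> bool:
        i = bisect_right([s for s, _ in protected], pos) - 1
        return i >= 0 and protected[i][0] <= pos < protected[i][1]

    for _ in range(20):  # converges in 1-2 passes in practice
        dirty = False
        s = bytes(seq)
        for motif in motifs:
            m = motif.encode()
            i = s.find(m)
            while i != -1:
                span = range(i, i + len(m))
                if not all(shielded(p) for p in span):
                    j = next(p for p in span if not shielded(p))
                    old = seq[j]
                    choices = [b for b in _BASES.tolist() if b != old]
                    seq[j] = choices[int(rng.integers(0, 3))]
                    dirty = True
                i = s.find(m, i + 1)
        if not dirty:
            return
    raise RuntimeError("motif scrubbing did not converge")


def _place_genes(spec: ChromosomeSpec, cfg: GenomeConfig,
                 cen_truth: list[tuple[int, int]], tel5_bp: int, tel3_bp: int,
                 rng) -> list[GeneModel]:
    genes: list[GeneModel] = []
    pos = tel5_bp + int(rng.integers(1000, max(2000, cfg.gene_spacing)))
    idx = 0
    limit = spec.length - tel3_bp - 200
    while pos < limit:
        length = int(np.clip(rng.normal(cfg.gene_length_mean, cfg.gene_length_sd),
                             200, cfg.gene_length_mean * 3))
        start, end = pos, min(pos + length, limit)
        in_cen = any(s < end and start < e for s, e in cen_truth)
        if end > start and (cfg.genes_in_centromere or not in_cen):
            idx += 1
            genes.append(GeneModel(
                gene_id=f"{spec.name}g{idx:05d}", chrom=spec.name,
                start=start, end=end,
                strand="+" if rng.random() < 0.5 else "-", rank=idx - 1))
        if in_cen:
            # jump to the end of the centromere rather than trickling through it
            pos = max(e for s, e in cen_truth if s < end)
        pos += int(rng.exponential(cfg.gene_spacing)) + 200
    return genes


def _place_gypsy(spec: ChromosomeSpec, cfg: GenomeConfig,
                 cen_truth: list[tuple[int, int]], rng) -> list[Interval]:
    out: list[Interval] = []

    def fill(lo: int, hi: int, coverage: float) -> None:
        if coverage <= 0 or hi - lo < cfg.gypsy_element_len:
            return
        step = int(cfg.gypsy_element_len / coverage)
        pos = lo + int(rng.integers(0, step))
        while pos + cfg.gypsy_element_len <= hi:
            out.append(Interval(spec.name, pos, pos + cfg.gypsy_element_len, "Gypsy"))
            pos += step + int(rng.integers(0, max(1, step // 4)))

    bounds = [0] + [b for s, e in sorted(cen_truth) for b in (s, e)] + [spec.length]
    for i in range(0, len(bounds) - 1, 2):
        fill(bounds[i], bounds[i + 1], cfg.gypsy_background)
    for s, e in cen_truth:
        fill(s, e, cfg.gypsy_centromere)
    out.sort(key=lambda iv: iv.start)
    return out


# ---------------------------------------------------------------------------
# terminal reads

def simulate_terminal_reads(bundle: GenomeBundle, chrom: str, end: str,
                            n_reads: int, extension: int, error_rate: float,
                            seed: int,
                            span_range: tuple[int, int] = (5000, 15000),
                            ) -> tuple[list[SeqRecord], list[TerminalAlignment]]:
    """Reads spanning one chromosome terminus, overhanging it with extra
    telomere repeats.

    ``extension`` is the maximum overhang in bp; per-read overhangs are
    spread evenly over [0, extension] (in whole motif units) so the
    deepest read always carries the full extension. Each read's true
    total repeat count (planted terminal repeats + overhang repeats) is
    recorded in the bundle manifest under ``terminal_reads``.
    """
    if extension < 0:
        raise ValueError("extension must be >= 0")
    if not (0.0 <= error_rate < 0.3):
        raise ValueError("error_rate must be in [0, 0.3)")
    if end not in ("5prime", "3prime"):
        raise ValueError("end must be 5prime or 3prime")
    rng = np.random.default_rng(seed)
    rec = bundle.record(chrom)
    L = len(rec.seq)
    cfg = bundle.config
    motif = cfg.motif5 if end == "5prime" else cfg.motif3
    planted = bundle.manifest["chromosomes"][chrom]["tel5" if end == "5prime" else "tel3"]

    reads: list[SeqRecord] = []
    alns: list[TerminalAlignment] = []
    truth: dict[str, int] = {}
    if n_reads > 0:
        max_extra = extension // len(motif)
        extras = np.unique(np.round(np.linspace(0, max_extra, n_reads)).astype(int)) \
            if n_reads > 1 else np.array([max_extra])
        extras = np.resize(extras, n_reads)
        rng.shuffle(extras)
        # guarantee the deepest overhang is present regardless of rounding
        extras[int(rng.integers(0, n_reads))] = max_extra
    for i in range(int(n_reads)):
        extra = int(extras[i])
        span = int(rng.integers(span_range[0], span_range[1] + 1))
        span = min(span, L)
        tail = motif * extra
        if end == "3prime":
            t_start, t_end = L - span, L
            fwd = rec.seq[t_start:] + tail
            q_start_f, q_end_f = 0, span
        else:
            t_start, t_end = 0, span
            fwd = tail + rec.seq[:span]
            q_start_f, q_end_f = len(tail), len(tail) + span
        fwd = _apply_errors(fwd, error_rate, rng)
        qlen = len(fwd)
        read_id = f"{chrom}_{end}_read{i + 1:03d}"
        if rng.random() < 0.5:
            strand, seq_out = "+", fwd
            q_start, q_end = q_start_f, q_end_f
        else:
            strand, seq_out = "-", revcomp(fwd)
            q_start, q_end = qlen - q_end_f, qlen - q_start_f
        reads.append(SeqRecord(id=read_id, seq=seq_out))
        alns.append(TerminalAlignment(
            read_id=read_id, read_len=qlen, chrom=chrom,
            target_start=t_start, target_end=t_end, strand=strand,
            mapq=60, query_start=q_start, query_end=q_end))
        truth[read_id] = planted + extra
    bundle.manifest.setdefault("terminal_reads", {})[f"{chrom}:{end}"] = truth
    return reads, alns


def _apply_errors(seq: str, rate: float, rng) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    for j in hit:
        choices = [b for b in _BASES.tolist() if b != arr[j]]
        arr[j] = choices[int(rng.integers(0, 3))]
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# protein family

@dataclass
class FamilyMemberSpec:
    member_id: str
    residue: str = "T"              # SRS6 position-8 truth label
    identity: float = 0.95          # target identity to its template
    derive_from: str | None = None  # another member id, or None for the anchor
    length: int | None = None       # None keeps anchor length (in-filter range)
    chrom: str | None = None
    rank: int | None = None         # gene rank the member occupies


@dataclass
class FamilyConfig:
    members: list[FamilyMemberSpec]
    anchor_len: int = 521
    srs6_start: int = 470
    srs6_end: int = 482
    diagnostic_position: int = 8
    cluster_max_gap: int = 8
    filter_min_aa: int = 400
    filter_max_aa: int = 600


@dataclass
class FamilyBundle:
    anchor: SeqRecord
    proteins: list[SeqRecord]
    hits: list[dict]
    truth: dict

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        from . import io as tio
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {"proteins": out / "family.faa", "hits": out / "family_hits.tsv",
                 "anchor": out / "anchor.faa"}
        tio.write_fasta(self.proteins, paths["proteins"])
        tio.write_fasta([self.anchor], paths["anchor"])
        with open(paths["hits"], "w") as fh:
            fh.write("# target acc tlen query acc qlen evalue score\n")
            for h in self.hits:
                fh.write(f"{h['target']} - {h['tlen']} family_domain - 120 "
                         f"{h['evalue']:.2e} {h['score']:.1f}\n")
        return paths


def simulate_family(cfg: FamilyConfig, seed: int,
                    bundle: GenomeBundle | None = None) -> FamilyBundle:
    """Generate an anchored protein family with planted SRS6 residues.

    Members derive from a shared random anchor (or from another member,
    for controlled pairwise identity): exactly round((1-identity)*L)
    positions outside the SRS6 window are substituted, then the SRS6
    diagnostic residue is written in. Members with a ``length`` outside
    the filter range become decoys (flagged ``filter_excluded`` in the
    truth). When a genome bundle is given, members with (chrom, rank)
    placements take over the id of the gene at that rank, and the truth
    records the resulting cluster layout.
    """
    if not (0 <= cfg.srs6_start < cfg.srs6_end <= cfg.anchor_len):
        raise ValueError("SRS6 coordinates outside anchor length")
    if cfg.srs6_end - cfg.srs6_start < cfg.diagnostic_position:
        raise ValueError("SRS6 window shorter than the diagnostic position")
    rng = np.random.default_rng(seed)
    aa = np.array(list(_AA20))
    anchor_seq = "".join(rng.choice(aa, size=cfg.anchor_len))
    anchor = SeqRecord(id="SRS6_ANCHOR", seq=anchor_seq)
    diag_idx = cfg.srs6_start + cfg.diagnostic_position - 1

    made: dict[str, str] = {}
    proteins: list[SeqRecord] = []
    hits: list[dict] = []
    truth_members: dict[str, dict] = {}
    for spec in cfg.members:
        template = made[spec.derive_from] if spec.derive_from else anchor_seq
        seq = list(template)
        n_mut = round((1.0 - spec.identity) * len(template))
        eligible = np.array([i for i in range(len(template))
                             if not (cfg.srs6_start <= i < cfg.srs6_end)])
        for i in rng.choice(eligible, size=min(n_mut, eligible.size), replace=False):
            seq[i] = str(rng.choice(aa[aa != seq[i]]))
        if diag_idx < len(seq):
            seq[diag_idx] = spec.residue
        seq_s = "".join(seq)
        if spec.length is not None and spec.length != len(seq_s):
            if spec.length < len(seq_s):
                seq_s = seq_s[:spec.length]
            else:
                seq_s += "".join(rng.choice(aa, size=spec.length - len(seq_s)))
        made[spec.member_id] = seq_s
        proteins.append(SeqRecord(id=spec.member_id, seq=seq_s))
        hits.append({"target": spec.member_id, "tlen": len(seq_s),
                     "evalue": float(10.0 ** -rng.uniform(50, 150)),
                     "score": float(rng.uniform(300, 700))})
        excluded = not (cfg.filter_min_aa <= len(seq_s) <= cfg.filter_max_aa)
        truth_members[spec.member_id] = {
            "residue": spec.residue,
            "length": len(seq_s),
            "filter_excluded": excluded,
            "chrom": spec.chrom,
            "rank": spec.rank,
        }

    truth = {
        "srs6_start": cfg.srs6_start,
        "srs6_end": cfg.srs6_end,
        "diagnostic_position": cfg.diagnostic_position,
        "members": truth_members,
        "clusters": _truth_clusters(cfg, truth_members),
    }
    if bundle is not None:
        _occupy_gene_slots(bundle, truth_members)
        bundle.manifest["family"] = truth
    return FamilyBundle(anchor=anchor, proteins=proteins, hits=hits, truth=truth)


def _truth_clusters(cfg: FamilyConfig, members: dict[str, dict]) -> list[list[str]]:
    """Expected clusters by sweeping sorted ranks: a gap > max_gap splits."""
    placed: dict[str, list[tuple[int, str]]] = {}
    for mid, m in members.items():
        if m["chrom"] is not None and m["rank"] is not None and not m["filter_excluded"]:
            placed.setdefault(m["chrom"], []).append((m["rank"], mid))
    clusters: list[list[str]] = []
    for chrom in sorted(placed):
        entries = sorted(placed[chrom])
        group = [entries[0]]
        for e in entries[1:]:
            if e[0] - group[-1][0] > cfg.cluster_max_gap:
                if len(group) >= 2:
                    clusters.append([mid for _, mid in group])
                group = []
            group.append(e)
        if len(group) >= 2:
            clusters.append([mid for _, mid in group])
    return clusters


def _occupy_gene_slots(bundle: GenomeBundle, members: dict[str, dict]) -> None:
    """Rename the gene at each member's (chrom, rank) to the member id."""
    by_chrom: dict[str, list[int]] = {}
    for i, g in enumerate(bundle.genes):
        by_chrom.setdefault(g.chrom, []).append(i)
    for mid, m in members.items():
        if m["chrom"] is None or m["rank"] is None:
            continue
        slots = by_chrom.get(m["chrom"], [])
        ranked = sorted(slots, key=lambda i: bundle.genes[i].start)
        if m["rank"] >= len(ranked):
            raise ValueError(f"member {mid}: rank {m['rank']} exceeds gene count "
                             f"on {m['chrom']}")
        i = ranked[m["rank"]]
        g = bundle.genes[i]
        bundle.genes[i] = GeneModel(gene_id=mid, chrom=g.chrom, start=g.start,
                                    end=g.end, strand=g.strand, rank=g.rank)


# ---------------------------------------------------------------------------
# expression

def simulate_expression(gene_ids: list[str], seed: int,
                        tissues: tuple[str, ...] = ("F", "FB", "L", "S", "RJ", "R"),
                        replicates: int = 3,
                        planted_means: dict[str, dict[str, float]] | None = None):
    """FPKM matrix (genes x tissue replicates) with exact planted tissue means.

    Replicates are symmetric around the planted mean, so the per-tissue
    mean equals the planted value exactly; unplanted cells draw from a
    lognormal background.
    """
    import pandas as pd
    rng = np.random.default_rng(seed)
    planted_means = planted_means or {}
    cols = [f"{t}{r + 1}" for t in tissues for r in range(replicates)]
    data = {}
    for gid in gene_ids:
        row = []
        for t in tissues:
            mean = planted_means.get(gid, {}).get(t)
            if mean is None:
                mean = float(rng.lognormal(1.5, 1.0))
            spread = 0.1 * mean
            offsets = np.linspace(-spread, spread, replicates)
            row.extend(max(v, 0.0) for v in (mean + offsets))
        data[gid] = row
    return pd.DataFrame.from_dict(data, orient="index", columns=cols)


# ---------------------------------------------------------------------------
# assembly corruption

def corrupt_assembly(records: list[SeqRecord], sub_rate: float,
                     seed: int) -> tuple[list[SeqRecord], int]:
    """Substitute bases independently at ``sub_rate``; returns the exact count."""
    if not (0.0 <= sub_rate <= 0.01):
        raise ValueError("sub_rate must be in [0, 0.01]")
    rng = np.random.default_rng(seed)
    out: list[SeqRecord] = []
    count = 0
    for rec in records:
        arr = np.frombuffer(rec.seq.encode(), dtype=np.uint8).copy()
        is_base = np.isin(arr, _BASES)
        hit = np.nonzero((rng.random(arr.size) < sub_rate) & is_base)[0]
        if hit.size:
            code = np.zeros(256, dtype=np.int64)
            for ci, b in enumerate(_BASES.tolist()):
                code[b] = ci
            shift = rng.integers(1, 4, size=hit.size)
            arr[hit] = _BASES[(code[arr[hit]] + shift) % 4]
        count += int(hit.size)
        out.append(SeqRecord(id=rec.id, seq=arr.tobytes().decode(),
                             description=rec.description))
    return out, count


# ---------------------------------------------------------------------------
# canned study-scale configurations

def telomere_study_config() -> GenomeConfig:
    """Nine 1 Mb pseudochromosomes, 17 telomeric ends spanning 111-2673
    repeat copies and one end with just 2 copies (not a telomere)."""
    counts = [(500, 2673), (300, 450), (111, 600), (200, 350), (2, 800),
              (150, 400), (250, 500), (120, 700), (1000, 1200)]
    return GenomeConfig(chromosomes=[
        ChromosomeSpec(name=f"Chr{i + 1}", length=1_000_000, tel5=c5, tel3=c3)
        for i, (c5, c3) in enumerate(counts)
    ])


def centromere_study_config() -> GenomeConfig:
    """Four 5 Mb chromosomes with 0.4-0.8 Mb centromeric arrays; the last
    chromosome carries twin equal arrays that should be flagged ambiguous."""
    def cen(n: int) -> CentromereSpec:
        return CentromereSpec(monomer_len=171, copies=n, divergence=0.02)
    chroms = [
        ChromosomeSpec("Chr1", 5_000_000, tel5=120, tel3=150, centromeres=[cen(2340)]),
        ChromosomeSpec("Chr2", 5_000_000, tel5=130, tel3=140, centromeres=[cen(3510)]),
        ChromosomeSpec("Chr3", 5_000_000, tel5=110, tel3=160, centromeres=[cen(4678)]),
        ChromosomeSpec("Chr4", 5_000_000, tel5=125, tel3=135,
                       centromeres=[cen(2924), cen(2924)]),
    ]
    return GenomeConfig(chromosomes=chroms)


def demo_config() -> GenomeConfig:
    """Small combined genome for the one-shot end-to-end run: three 2 Mb
    chromosomes with centromeres, full telomeres except a truncated
    Chr3 3' end (20 repeat copies) left for patching."""
    def cen(n: int) -> CentromereSpec:
        return CentromereSpec(monomer_len=171, copies=n, divergence=0.02)
    chroms = [
        ChromosomeSpec("Chr1", 2_000_000, tel5=150, tel3=300, centromeres=[cen(1755)]),
        ChromosomeSpec("Chr2", 2_000_000, tel5=111, tel3=220, centromeres=[cen(2047)]),
        ChromosomeSpec("Chr3", 2_000_000, tel5=180, tel3=20, centromeres=[cen(1462)]),
    ]
    return GenomeConfig(chromosomes=chroms)


def demo_family_config() -> FamilyConfig:
    """Seven-member B-ring hydroxylase family: six Thr/Ser members, one
    Ala member, a tandem pair at adjacent ranks, plus two length decoys."""
    members = [
        FamilyMemberSpec("FBH1", residue="T", identity=0.90, chrom="Chr1", rank=12),
        FamilyMemberSpec("FBH2", residue="T", identity=0.9136, derive_from="FBH1",
                         chrom="Chr1", rank=13),
        FamilyMemberSpec("FBH3", residue="S", identity=0.75, chrom="Chr2", rank=5),
        FamilyMemberSpec("FBH4", residue="T", identity=0.74, chrom="Chr2", rank=40),
        FamilyMemberSpec("FBH5", residue="S", identity=0.72, derive_from="FBH1",
                         chrom="Chr1", rank=20),
        FamilyMemberSpec("FBH6", residue="T", identity=0.73, chrom="Chr3", rank=8),
        FamilyMemberSpec("FBH7", residue="A", identity=0.70, chrom="Chr3", rank=30),
        FamilyMemberSpec("DECOY_SHORT", residue="G", identity=0.6, length=399),
        FamilyMemberSpec("DECOY_LONG", residue="G", identity=0.6, length=601),
    ]
    return FamilyConfig(members=members)
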