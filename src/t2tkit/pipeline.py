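"""End-to-end orchestration and assembly summary statistics.

``run_all`` drives the full QC chain — simulate (optional) → telomere
scan → terminal patch → rescan → centromere call → k-mer QV → family
mining — and emits one consolidated, versioned report whose fields can
be checked against the synthetic truth manifest.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import io as tio
from .centromere import (CentromereParams, TandemParams, call_centromeres,
                         find_tandem_arrays, window_features)
from .famscan import (classify_fbh, detect_gene_clusters, extract_srs6,
                      filter_family_candidates, global_align, percent_identity,
                      tissue_expression_summary)
from .models import PatchReport, SeqRecord
from .qv import assembly_kmer_survey, estimate_qv
from .simulate import (FamilyConfig, GenomeConfig, corrupt_assembly, demo_config,
                       demo_family_config, simulate_expression, simulate_family,
                       simulate_genome, simulate_terminal_reads)
from .telomere import (TelomereParams, call_telomeres, collect_terminal_reads,
                       patch_terminus, select_reference_read, telomere_count)

log = logging.getLogger("t2tkit")

REPORT_SCHEMA_VERSION = 1

_KNOWN_BLOCKS = {"seed", "out_dir", "simulate", "telomere", "centromere", "qv",
                 "famscan", "report_format"}


def assembly_summary(genome: list[SeqRecord]) -> dict:
    """Contiguity/composition summary: counts, N content, GC%, N50.

    GC% is (G+C)/(A+C+G+T), Ns excluded from the denominator, reported
    to one decimal. N50 is the length L such that sequences >= L hold at
    least half the total assembly.
    """
    if not genome:
        raise ValueError("empty genome")
    lengths = sorted((len(r.seq) for r in genome), reverse=True)
    total = sum(lengths)
    gc = at = n_count = 0
    for r in genome:
        gc += r.seq.count("G") + r.seq.count("C")
        at += r.seq.count("A") + r.seq.count("T")
        n_count += r.seq.count("N")
    acc = 0
    n50 = lengths[-1]
    for L in lengths:
        acc += L
        if acc * 2 >= total:
            n50 = L
            break
    return {
        "sequence_count": len(genome),
        "total_bp": total,
        "n_count": n_count,
        "gap_count": n_count,
        "gc_percent": round(100.0 * gc / (gc + at), 1) if gc + at else 0.0,
        "lengths": {r.id: len(r.seq) for r in genome},
        "contig_n50": n50,
    }


def validate_config(config: dict) -> dict:
    unknown = set(config) - _KNOWN_BLOCKS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = dict(config)
    cfg.setdefault("seed", 1)
    cfg.setdefault("report_format", "json")
    sim = cfg.get("simulate", {})
    for key in ("genome", "genes", "gypsy"):
        path = sim.get(key) if isinstance(sim, dict) else None
        if path is not None and not Path(path).exists():
            raise FileNotFoundError(f"config input {key!r}: {path} does not exist")
    return cfg


def patch_all_ends(genome: list[SeqRecord], reads: list[SeqRecord],
                   alignments, tel_params: TelomereParams,
                   screen_window: int = 50) -> tuple[list[SeqRecord], list[PatchReport]]:
    """Patch every chromosome end that has terminal reads on file."""
    reads_by_id = {r.id: r for r in reads}
    by_chrom = {r.id: r for r in genome}
    assigned = collect_terminal_reads(alignments, {r.id: len(r.seq) for r in genome},
                                      screen_window)
    reports: list[PatchReport] = []
    for rec in genome:
        for end in ("5prime", "3prime"):
            ids = assigned.get((rec.id, end), set())
            if not ids:
                reports.append(PatchReport(rec.id, end, -1, -1, 0, "no_reads"))
                continue
            motif = tel_params.motif5 if end == "5prime" else tel_params.motif3
            selection = select_reference_read(
                [reads_by_id[i] for i in sorted(ids)], motif, rec.id, end,
                strands={a.read_id: a.strand for a in alignments
                         if a.chrom == rec.id})
            anchor = next(a for a in alignments
                          if a.read_id == selection.reference_read and a.chrom == rec.id)
            patched, report = patch_terminus(by_chrom[rec.id], selection, anchor,
                                             reads_by_id[selection.reference_read],
                                             tel_params)
            by_chrom[rec.id] = patched
            reports.append(report)
    return [by_chrom[r.id] for r in genome], reports


def run_all(config: dict) -> dict:
    """One-shot QC run on a synthetic bundle; returns the consolidated report."""
    cfg = validate_config(config)
    seed = int(cfg["seed"])
    log.info("run_all: seed=%d config=%s", seed,
             json.dumps({k: v for k, v in cfg.items() if k != "out_dir"},
                        default=str, sort_keys=True))

    tel_params = TelomereParams(**cfg.get("telomere", {}))
    cen_cfg = dict(cfg.get("centromere", {}))
    tandem_params = TandemParams(**{
        k: cen_cfg.pop(k) for k in list(cen_cfg)
        if k in TandemParams.__dataclass_fields__})
    cen_params = CentromereParams(**cen_cfg)
    qv_cfg = dict(cfg.get("qv", {}))
    fam_cfg = dict(cfg.get("famscan", {}))

    # --- simulate -----------------------------------------------------------
    sim = cfg.get("simulate", {}) or {}
    genome_cfg: GenomeConfig = sim.get("genome_config") or demo_config()
    bundle = simulate_genome(genome_cfg, seed)
    family_cfg: FamilyConfig = sim.get("family_config") or demo_family_config()
    family = simulate_family(family_cfg, seed + 1, bundle)
    log.info("simulated %d chromosomes, %d genes, %d family proteins",
             len(bundle.genome), len(bundle.genes), len(family.proteins))

    # terminal reads for every end whose planted telomere is incomplete
    reads: list[SeqRecord] = []
    alns = []
    for spec in genome_cfg.chromosomes:
        for end, count in (("5prime", spec.tel5), ("3prime", spec.tel3)):
            if 0 < count < tel_params.min_repeats:
                r, a = simulate_terminal_reads(
                    bundle, spec.name, end, n_reads=sim.get("n_reads", 6),
                    extension=sim.get("extension", 130 * len(tel_params.motif3)),
                    error_rate=sim.get("read_error_rate", 0.0), seed=seed + 2)
                reads.extend(r)
                alns.extend(a)

    # --- telomeres, patch, rescan ------------------------------------------
    pre_calls = call_telomeres(bundle.genome, tel_params)
    patched_genome, patch_reports = patch_all_ends(
        bundle.genome, reads, alns, tel_params,
        screen_window=cfg.get("telomere", {}).get("screen_window", 50))
    post_calls = call_telomeres(patched_genome, tel_params)
    log.info("telomeres: %d before patch, %d after",
             telomere_count(pre_calls), telomere_count(post_calls))

    # --- centromeres --------------------------------------------------------
    arrays = []
    for rec in patched_genome:
        arrays.extend(find_tandem_arrays(rec.seq, rec.id, tandem_params))
    feats = window_features(patched_genome, arrays, bundle.genes, bundle.gypsy,
                            window=cen_params.window)
    cen_calls = call_centromeres(feats, cen_params, arrays=arrays)

    # --- QV -----------------------------------------------------------------
    sub_rate = qv_cfg.pop("corrupt_rate", 1e-4)
    corrupted, n_subs = corrupt_assembly(patched_genome, sub_rate, seed + 3)
    survey = assembly_kmer_survey(corrupted, patched_genome,
                                  k=qv_cfg.get("k", 21),
                                  read_kmer_min_count=qv_cfg.get(
                                      "read_kmer_min_count", 1))
    qv = estimate_qv(survey)
    log.info("QV: %d/%d unsupported k-mers -> %.2f (%d planted substitutions)",
             survey.assembly_missing, survey.assembly_total, qv, n_subs)

    # --- family mining ------------------------------------------------------
    members, dropped = filter_family_candidates(
        family.hits, family.proteins,
        min_aa=fam_cfg.get("min_aa", 400), max_aa=fam_cfg.get("max_aa", 600))
    clusters = detect_gene_clusters(members, bundle.genes,
                                    max_gap=fam_cfg.get("max_gap", 8))
    classifications = []
    for m in members:
        win = extract_srs6(m.protein, family.anchor,
                           family.truth["srs6_start"], family.truth["srs6_end"],
                           family.truth["diagnostic_position"])
        classifications.append(classify_fbh(win))

    member_ids = [m.gene_id for m in members]
    fpkm = simulate_expression(
        member_ids, seed + 4,
        planted_means=sim.get("planted_means",
                              {"FBH7": {"FB": 166.3}, "FBH2": {"FB": 7.505},
                               "FBH5": {"FB": 10.0}}))
    expr = tissue_expression_summary(fpkm, member_ids)

    pair_identity = None
    if len(members) >= 2:
        a, b = members[0], members[1]
        pair_identity = percent_identity(global_align(a.protein.seq, b.protein.seq))

    # --- report -------------------------------------------------------------
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": seed,
        "assembly": assembly_summary(patched_genome),
        "telomeres": {
            "count_pre_patch": telomere_count(pre_calls),
            "count_post_patch": telomere_count(post_calls),
            "per_end_counts": {f"{c.chrom}:{c.end}": c.repeat_count
                               for c in post_calls},
            "min_repeat_count": min((c.repeat_count for c in post_calls
                                     if c.is_telomere), default=0),
            "max_repeat_count": max((c.repeat_count for c in post_calls
                                     if c.is_telomere), default=0),
        },
        "patching": [vars(r) for r in patch_reports if r.status != "no_reads"],
        "centromeres": {
            c.chrom: {
                "selected": [c.selected.start, c.selected.end] if c.selected else None,
                "ambiguous": c.ambiguous,
                "n_candidates": len(c.candidates),
            } for c in cen_calls
        },
        "qv": {"value": round(qv, 2), "x": survey.assembly_missing,
               "y": survey.assembly_total, "k": survey.k,
               "planted_substitutions": n_subs, "planted_rate": sub_rate},
        "family": {
            "n_candidates": len(family.hits),
            "n_members": len(members),
            "dropped": dict(dropped),
            "clusters": [[m.gene_id for m in c.members] for c in clusters],
            "tandem_pairs": [p for c in clusters for p in c.tandem_pairs],
            "classifications": {c.member_id: c.label for c in classifications},
            "first_pair_identity_percent": pair_identity,
            "fold_ratios": expr["fold_ratios"],
        },
    }

    out_dir = cfg.get("out_dir")
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        bundle_paths = bundle.write(out / "synthetic")
        family.write(out / "synthetic")
        tio.write_fasta(patched_genome, out / "genome.patched.fasta")
        (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
        log.info("wrote report to %s (inputs under %s)", out / "report.json",
                 bundle_paths["genome"].parent)
    return report
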