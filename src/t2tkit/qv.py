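"""Consensus quality value (QV) from k-mer spectrum comparison.

Every base error in an assembly creates up to k assembly k-mers that
never occur in accurate short reads. Counting assembly k-mer positions
whose canonical k-mer is unsupported by the read k-mer set (X of Y)
gives the per-base error probability

    E = 1 - (1 - X/Y)^(1/k)

and the phred-scaled consensus quality QV = -10 log10(E). This is the
standard k-mer QV estimator used for assembly evaluation. k-mers are
canonical (min of forward and reverse complement); read k-mers seen
fewer than ``read_kmer_min_count`` times are treated as absent, which
filters k-mers created by sequencing errors in the reads themselves.
"""

from __future__ import annotations

import math

import numpy as np

from .models import KmerSurvey, SeqRecord

_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i

DEFAULT_K = 21
QV_CAP = 99.0


def _canonical_kmers(seq: str, k: int) -> np.ndarray:
    """Canonical k-mer codes for every position; windows containing N are dropped."""
    codes = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = len(codes)
    if n < k:
        return np.empty(0, dtype=np.uint64)
    m = n - k + 1
    valid = codes < 4
    safe = np.where(valid, codes, 0).astype(np.uint64)
    comp = np.uint64(3) - safe
    fwd = np.zeros(m, dtype=np.uint64)
    rev = np.zeros(m, dtype=np.uint64)
    ok = np.ones(m, dtype=bool)
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | safe[j:m + j]
        rev |= comp[j:m + j] << np.uint64(2 * j)
        ok &= valid[j:m + j]
    return np.minimum(fwd, rev)[ok]


def read_kmer_set(reads: list[SeqRecord], k: int, min_count: int = 2) -> np.ndarray:
    """Sorted array of canonical k-mer codes seen >= ``min_count`` times in reads."""
    parts = [_canonical_kmers(r.seq, k) for r in reads]
    if not parts:
        return np.empty(0, dtype=np.uint64)
    allk = np.concatenate(parts)
    if allk.size == 0:
        return allk
    values, counts = np.unique(allk, return_counts=True)
    return values[counts >= min_count]


def assembly_kmer_survey(assembly: list[SeqRecord], reads: list[SeqRecord],
                         k: int = DEFAULT_K,
                         read_kmer_min_count: int = 2) -> KmerSurvey:
    """Count assembly k-mer positions (Y) and those unsupported by reads (X)."""
    if k % 2 == 0 or k < 11:
        raise ValueError("k must be odd and >= 11")
    for rec in assembly:
        if len(rec.seq) < k:
            raise ValueError(f"assembly sequence {rec.id!r} shorter than k={k}")
    supported = read_kmer_set(reads, k, read_kmer_min_count)
    total = 0
    missing = 0
    for rec in assembly:
        kmers = _canonical_kmers(rec.seq, k)
        total += kmers.size
        if kmers.size:
            idx = np.searchsorted(supported, kmers)
            idx = np.clip(idx, 0, max(supported.size - 1, 0))
            if supported.size:
                missing += int(np.sum(supported[idx] != kmers))
            else:
                missing += kmers.size
    return KmerSurvey(k=k, assembly_total=total, assembly_missing=missing,
                      read_kmer_min_count=read_kmer_min_count)


def estimate_qv(survey: KmerSurvey, cap: float = QV_CAP) -> float:
    """Phred-scaled consensus quality from a k-mer survey."""
    if survey.assembly_total <= 0:
        raise ValueError("no valid assembly k-mers (Y = 0); QV undefined")
    x, y, k = survey.assembly_missing, survey.assembly_total, survey.k
    if x == 0:
        return cap
    err = 1.0 - (1.0 - x / y) ** (1.0 / k)
    return -10.0 * math.log10(err)
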