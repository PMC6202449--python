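"""Completeness-normalized genomic identity between two bins.

Two independent subsamples of one genome at completeness fractions cA and cB
share, in expectation, a fraction of k-mers equal to the completeness of the
bin NOT used in the containment denominator.  Dividing the raw containment
by that completeness therefore yields a statistic near 1 for same-organism
bins regardless of how incomplete either is, and near 0 for unrelated bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .formats_io import Contig

__all__ = ["IdentityResult", "kmer_set", "bin_identity"]


_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


def _seq_kmers(seq: str, k: int) -> np.ndarray:
    """Canonical k-mer codes of one sequence (windows with N skipped)."""
    if len(seq) < k:
        return np.empty(0, dtype=np.int64)
    codes = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    valid = codes >= 0
    n = len(seq) - k + 1
    c = np.where(valid, codes, 0)
    fwd = np.zeros(n, dtype=np.int64)
    rev = np.zeros(n, dtype=np.int64)
    ok = np.ones(n, dtype=bool)
    for j in range(k):
        fwd = (fwd << 2) | c[j : j + n]
        rev |= (3 - c[j : j + n]) << (2 * j)
        ok &= valid[j : j + n]
    canon = np.minimum(fwd, rev)
    return canon[ok]


def kmer_set(contigs: Iterable[Contig], k: int = 21) -> set[int]:
    """Canonical (strand-collapsed) k-mer set of a collection of contigs.

    k must be odd (so no k-mer is its own reverse complement) and within
    [11, 31] to fit 2-bit codes into int64.
    """
    if k % 2 == 0 or not 11 <= k <= 31:
        raise ValueError("k must be odd and within [11, 31]")
    out: set[int] = set()
    for c in contigs:
        out.update(_seq_kmers(c.seq, k).tolist())
    return out


@dataclass
class IdentityResult:
    bin_a: str
    bin_b: str
    k: int
    n_kmers_a: int
    n_kmers_b: int
    n_shared: int
    raw_containment: float
    completeness_a: float
    completeness_b: float
    normalized_identity: float


def bin_identity(
    contigs_a: Iterable[Contig],
    contigs_b: Iterable[Contig],
    completeness_a: float,
    completeness_b: float,
    k: int = 21,
    bin_a: str = "A",
    bin_b: str = "B",
) -> IdentityResult:
    """Containment on the smaller k-mer set, divided by the completeness of
    the OTHER bin and capped at 1.

    Completeness values are fractions in (0, 1], taken from an external QC
    table and never re-estimated here.
    """
    for name, c in (("A", completeness_a), ("B", completeness_b)):
        if not 0 < c <= 1:
            raise ValueError(f"completeness_{name} must be in (0, 1], got {c}")
    set_a = kmer_set(contigs_a, k=k)
    set_b = kmer_set(contigs_b, k=k)
    if not set_a or not set_b:
        raise ValueError("empty k-mer set; cannot compute identity")
    if len(set_a) < len(set_b):
        smaller, other, c_other = set_a, set_b, completeness_b
    elif len(set_b) < len(set_a):
        smaller, other, c_other = set_b, set_a, completeness_a
    else:
        # equal sizes: denominator is the same either way; take the larger
        # completeness so the result stays symmetric under argument swap
        smaller, other = set_a, set_b
        c_other = max(completeness_a, completeness_b)
    n_shared = len(smaller & other)
    raw = n_shared / len(smaller)
    return IdentityResult(
        bin_a=bin_a,
        bin_b=bin_b,
        k=k,
        n_kmers_a=len(set_a),
        n_kmers_b=len(set_b),
        n_shared=n_shared,
        raw_containment=raw,
        completeness_a=completeness_a,
        completeness_b=completeness_b,
        normalized_identity=min(1.0, raw / c_other),
    )
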