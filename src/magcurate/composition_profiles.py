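"""Tetranucleotide-frequency (TNF) profiles and divergence diagnostics.

A TNF vector holds the 136 canonical 4-mer frequencies of a sequence
(a 4-mer and its reverse complement share one slot; palindromes are counted
once).  Per-bin profiles summarise member TNFs and depths, and divergence
reports score a contig against its bin on the two signals that flag
collapsed multi-copy repeats: excess coverage and divergent composition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "N_CANONICAL",
    "CANONICAL_KMERS",
    "TNFVector",
    "BinProfile",
    "DivergenceReport",
    "UndefinedProfileError",
    "tnf_vector",
    "tnf_distance",
    "bin_profile",
    "divergence_report",
    "reverse_complement",
    "weighted_median",
]

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


def _build_canonical_map() -> tuple[np.ndarray, list[str]]:
    """Map each of the 256 4-mer codes to its canonical slot (0..135)."""
    bases = "ACGT"
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    canon_of_code = np.empty(256, dtype=np.int64)
    canon_strings: set[str] = set()
    kmers = []
    for code in range(256):
        k = "".join(
            bases[(code >> shift) & 3] for shift in (6, 4, 2, 0)
        )
        kmers.append(k)
        rc = "".join(comp[b] for b in reversed(k))
        canon_strings.add(min(k, rc))
    ordered = sorted(canon_strings)
    slot = {k: i for i, k in enumerate(ordered)}
    for code in range(256):
        k = kmers[code]
        rc = "".join(comp[b] for b in reversed(k))
        canon_of_code[code] = slot[min(k, rc)]
    return canon_of_code, ordered


_CANON_OF_CODE, CANONICAL_KMERS = _build_canonical_map()
N_CANONICAL = len(CANONICAL_KMERS)
assert N_CANONICAL == 136

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class UndefinedProfileError(ValueError):
    """Raised when a sequence yields no valid 4-mer window."""


@dataclass(frozen=True)
class TNFVector:
    """Canonical 4-mer frequencies (sum to 1) and the window count behind
    them."""

    values: np.ndarray
    n_windows: int

    def __post_init__(self) -> None:
        if self.values.shape != (N_CANONICAL,):
            raise ValueError(f"expected {N_CANONICAL} frequencies")
        if self.n_windows > 0 and abs(self.values.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1")


def tnf_vector(seq: str) -> TNFVector:
    """Count canonical 4-mers over all width-4 windows (step 1).

    Windows containing non-ACGT characters are skipped.  A sequence shorter
    than 4 or without any valid window raises :class:`UndefinedProfileError`.
    """
    if len(seq) < 4:
        raise UndefinedProfileError(
            f"sequence of length {len(seq)} has no 4-mer window"
        )
    codes = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    valid = codes >= 0
    # windows are valid where all four positions are ACGT
    w_valid = valid[:-3] & valid[1:-2] & valid[2:-1] & valid[3:]
    if not w_valid.any():
        raise UndefinedProfileError("no valid 4-mer window (all contain N)")
    c = np.where(valid, codes, 0)
    window_codes = (c[:-3] << 6) | (c[1:-2] << 4) | (c[2:-1] << 2) | c[3:]
    counts = np.bincount(
        _CANON_OF_CODE[window_codes[w_valid]], minlength=N_CANONICAL
    ).astype(float)
    n = int(w_valid.sum())
    return TNFVector(values=counts / n, n_windows=n)


def tnf_distance(a: TNFVector, b: TNFVector) -> float:
    """Euclidean distance between two TNF vectors."""
    return float(np.linalg.norm(a.values - b.values))


def weighted_median(values: Sequence[float], weights: Sequence[float]) -> float:
    """Smallest value whose cumulative weight reaches half the total."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.size == 0:
        raise ValueError("weighted_median of empty input")
    order = np.argsort(values, kind="stable")
    cum = np.cumsum(weights[order])
    idx = int(np.searchsorted(cum, cum[-1] / 2.0))
    return float(values[order][idx])


@dataclass
class BinProfile:
    """Length-weighted TNF centroid and depth summary of one bin."""

    bin_id: str
    centroid: TNFVector
    mean_intra: float
    sd_intra: Optional[float]  # undefined (None) for bins of < 3 contigs
    weighted_median_depth: float
    n_contigs: int


def bin_profile(contigs, bin_id: str = "") -> BinProfile:
    """Profile one bin's members.

    The centroid is the length-weighted mean of member TNF vectors,
    renormalized.  ``sd_intra`` is only defined for bins of at least three
    contigs; downstream z-scores are then unavailable (not zero).
    """
    contigs = list(contigs)
    if not contigs:
        raise ValueError("bin_profile of empty bin")
    tnfs = [tnf_vector(c.seq) for c in contigs]
    lengths = np.array([c.length for c in contigs], dtype=float)
    stacked = np.stack([t.values for t in tnfs])
    centroid_values = (stacked * lengths[:, None]).sum(axis=0) / lengths.sum()
    centroid_values = centroid_values / centroid_values.sum()
    centroid = TNFVector(
        values=centroid_values, n_windows=int(sum(t.n_windows for t in tnfs))
    )
    dists = np.array([float(np.linalg.norm(t.values - centroid_values)) for t in tnfs])
    sd_intra = float(dists.std(ddof=1)) if len(contigs) >= 3 else None
    return BinProfile(
        bin_id=bin_id,
        centroid=centroid,
        mean_intra=float(dists.mean()),
        sd_intra=sd_intra,
        weighted_median_depth=weighted_median(
            [c.depth for c in contigs], lengths
        ),
        n_contigs=len(contigs),
    )


@dataclass
class DivergenceReport:
    """Per-contig diagnostics against a bin profile."""

    contig_id: str
    bin_id: str
    tnf_distance: float
    tnf_z: Optional[float]
    coverage_ratio: float


def divergence_report(contig, profile: BinProfile) -> DivergenceReport:
    """Score a contig against a bin: TNF z-score vs the intra-bin distance
    distribution, and depth ratio vs the bin's length-weighted median depth."""
    d = tnf_distance(tnf_vector(contig.seq), profile.centroid)
    if profile.sd_intra is None or profile.sd_intra == 0:
        z: Optional[float] = None
    else:
        z = (d - profile.mean_intra) / profile.sd_intra
    if profile.weighted_median_depth <= 0:
        raise ValueError(
            f"bin {profile.bin_id!r} has non-positive median depth"
        )
    return DivergenceReport(
        contig_id=contig.id,
        bin_id=profile.bin_id,
        tnf_distance=d,
        tnf_z=z,
        coverage_ratio=contig.depth / profile.weighted_median_depth,
    )
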