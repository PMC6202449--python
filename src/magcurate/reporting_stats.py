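"""Summary statistics and bin accounting.

Quantiles use type-7 linear interpolation throughout — the one dialect that
reproduces the packaged QC fixture's printed interquartile ranges — and the
accounting operation counts bins by nature, phylum group and quality
thresholds from QC and rRNA tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as _scipy_stats

from .formats_io import (
    BinQCRecord,
    RRNARecord,
    load_taxon_groups,
)

__all__ = [
    "SummaryStats",
    "AccountingReport",
    "quantile_type7",
    "summary_stats",
    "pearson",
    "bin_accounting",
    "filter_ogs",
    "matrix_missingness",
]


def quantile_type7(values: Sequence[float], p: float) -> float:
    """Type-7 quantile: h = (n-1)p + 1 on sorted values, linear
    interpolation between adjacent order statistics."""
    if len(values) == 0:
        raise ValueError("quantile of empty list")
    if not 0 <= p <= 1:
        raise ValueError("p must be within [0, 1]")
    x = sorted(values)
    n = len(x)
    h = (n - 1) * p + 1
    lo = math.floor(h)
    frac = h - lo
    if lo >= n:
        return float(x[-1])
    return float(x[lo - 1] + frac * (x[lo] - x[lo - 1]) if frac else x[lo - 1])


@dataclass
class SummaryStats:
    n: int
    median: float
    q1: float
    q3: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def summary_stats(values: Sequence[float]) -> SummaryStats:
    if len(values) == 0:
        raise ValueError("summary_stats of empty list")
    return SummaryStats(
        n=len(values),
        median=quantile_type7(values, 0.5),
        q1=quantile_type7(values, 0.25),
        q3=quantile_type7(values, 0.75),
    )


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson correlation and its two-sided t-test p-value."""
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector has undefined correlation")
    r, p = _scipy_stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class AccountingReport:
    """Bin and rRNA counts, each tagged with the filter that produced it."""

    counts: dict[str, int] = field(default_factory=dict)
    filters: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, key: str) -> int:
        return self.counts[key]


def bin_accounting(
    qc: Sequence[BinQCRecord],
    rrna: Sequence[RRNARecord] = (),
    groups: Optional[Mapping[str, frozenset[str]]] = None,
) -> AccountingReport:
    """Count bins by nature, phylum group and completeness thresholds.

    Microbiome (M) bins are grouped by taxon through the packaged phylum
    synonym sets; taxa in no group count under ``bacteria_level_other``
    with a warning for labels other than plain ``Bacteria``.
    """
    if groups is None:
        groups = load_taxon_groups()
    bins = [r for r in qc if r.nature != "No"]
    c_bins = [r for r in bins if r.nature == "C"]
    m_bins = [r for r in bins if r.nature == "M"]
    u_bins = [r for r in bins if r.nature == "U"]

    proteo = groups.get("proteobacteria", frozenset())
    bacteroid = groups.get("bacteroidetes", frozenset())
    n_proteo = n_bacteroid = n_other = 0
    for r in m_bins:
        if r.taxon in proteo:
            n_proteo += 1
        elif r.taxon in bacteroid:
            n_bacteroid += 1
        else:
            if r.taxon != "Bacteria":
                warnings.warn(
                    f"taxon {r.taxon!r} not in any phylum group; counted as "
                    "Bacteria-level/other"
                )
            n_other += 1

    report = AccountingReport()

    def put(key: str, value: int, filt: str) -> None:
        report.counts[key] = value
        report.filters[key] = filt

    put("total", len(bins), "nature != No")
    put("cyanobacterial", len(c_bins), "nature == C")
    put("microbiome", len(m_bins), "nature == M")
    put("unclassified", len(u_bins), "nature == U")
    put("proteobacteria_group", n_proteo, "nature == M and taxon in proteobacteria group")
    put("bacteroidetes_group", n_bacteroid, "nature == M and taxon in bacteroidetes group")
    put("bacteria_level_other", n_other, "nature == M and taxon in no phylum group")
    put(
        "foreign_complete_ge90",
        sum(
            1
            for r in m_bins
            if r.completeness is not None and r.completeness >= 90
        ),
        "nature == M and completeness >= 90",
    )
    put(
        "cyano_medium_quality",
        sum(
            1
            for r in c_bins
            if r.completeness is not None
            and r.contamination is not None
            and r.completeness >= 90
            and r.contamination < 5
        ),
        "nature == C and completeness >= 90 and contamination < 5",
    )
    put("rrna_total", len(rrna), "all rRNA records")
    put(
        "rrna_direct_from_bin",
        sum(1 for r in rrna if r.direct_from_bin),
        "rRNA records predicted directly from a genome bin",
    )
    put(
        "rrna_unaffiliated",
        sum(1 for r in rrna if r.affiliated_bin is None),
        "rRNA records with no bin affiliation",
    )
    return report


def filter_ogs(
    og_counts: Mapping[str, Mapping[str, int]],
    min_organisms: int = 62,
    max_mean_copy: float = 1.1,
) -> list[str]:
    """Keep orthologous groups present in enough organisms at a low enough
    mean copy number.

    ``og_counts`` maps OG id -> per-organism gene copy counts.  An OG is
    kept iff the number of organisms with >= 1 copy reaches
    ``min_organisms`` and total copies per represented organism stays at or
    below ``max_mean_copy``.
    """
    kept = []
    for og_id, counts in og_counts.items():
        present = [c for c in counts.values() if c >= 1]
        if any(c < 0 for c in counts.values()):
            raise ValueError(f"negative copy count in OG {og_id!r}")
        if len(present) < min_organisms:
            continue
        if sum(present) / len(present) > max_mean_copy:
            continue
        kept.append(og_id)
    return kept


def matrix_missingness(
    present_counts: Mapping[str, int], total_positions: int
) -> float:
    """Percentage of missing character states in a supermatrix of
    ``len(present_counts)`` taxa by ``total_positions`` positions."""
    if total_positions <= 0:
        raise ValueError("total_positions must be positive")
    for taxon, count in present_counts.items():
        if not 0 <= count <= total_positions:
            raise ValueError(f"count for {taxon!r} out of range")
    n_taxa = len(present_counts)
    if n_taxa == 0:
        raise ValueError("no taxa")
    present = sum(present_counts.values())
    return 100.0 * (1.0 - present / (n_taxa * total_positions))
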