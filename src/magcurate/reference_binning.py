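"""A simplified composition+coverage binner with named presets, the
preset-selection rule over bin QC statistics, a bin-merge advisory and
MIMAG-style quality tiers.

The binner is deliberately NOT a re-implementation of any production tool:
contigs are clustered by single linkage over a composite criterion (TNF
distance below a threshold AND per-pair log2 depth ratio below a threshold).
Presets tighten both thresholds from ``verysensitive`` to ``superspecific``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .composition_profiles import tnf_vector
from .formats_io import NOBIN, BinQCRecord, Contig

__all__ = [
    "PRESET_ORDER",
    "PRESETS",
    "PresetConfig",
    "BinningResult",
    "MergeAdvice",
    "bin_contigs",
    "select_preset",
    "merge_advisory",
    "quality_tier",
]

PRESET_ORDER = (
    "verysensitive",
    "sensitive",
    "specific",
    "veryspecific",
    "superspecific",
)


@dataclass(frozen=True)
class PresetConfig:
    name: str
    tnf_threshold: float
    coverage_log_threshold: float
    min_contig_length: int = 2500
    min_bin_length: int = 50_000


PRESETS: dict[str, PresetConfig] = {
    "verysensitive": PresetConfig("verysensitive", 0.10, 1.5),
    "sensitive": PresetConfig("sensitive", 0.08, 1.2),
    "specific": PresetConfig("specific", 0.06, 1.0),
    "veryspecific": PresetConfig("veryspecific", 0.05, 0.8),
    "superspecific": PresetConfig("superspecific", 0.04, 0.6),
}


@dataclass
class BinningResult:
    """A partition of contigs into bins; unassigned contigs map to nobin."""

    preset: str
    assignments: dict[str, str]

    def bins(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for contig_id, bin_id in self.assignments.items():
            out.setdefault(bin_id, []).append(contig_id)
        return out

    def n_binned(self) -> int:
        return sum(1 for b in self.assignments.values() if b != NOBIN)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def bin_contigs(
    contigs: Sequence[Contig],
    depths: Mapping[str, float],
    preset: PresetConfig | str,
) -> BinningResult:
    """Single-linkage clustering of contigs under a preset.

    Contigs shorter than ``min_contig_length`` go straight to nobin; two
    contigs link when their TNF distance AND absolute log2 depth ratio are
    both within the preset's thresholds; clusters whose total length falls
    below ``min_bin_length`` dissolve to nobin.  Bins are numbered by
    decreasing total length (bin1 largest).
    """
    if isinstance(preset, str):
        preset = PRESETS[preset]
    for c in contigs:
        if c.id not in depths:
            raise KeyError(f"no depth entry for contig {c.id!r}")

    assignments: dict[str, str] = {}
    eligible = [c for c in contigs if c.length >= preset.min_contig_length]
    for c in contigs:
        if c.length < preset.min_contig_length:
            assignments[c.id] = NOBIN

    if eligible:
        tnfs = np.stack([tnf_vector(c.seq).values for c in eligible])
        log_depths = np.array(
            [np.log2(max(depths[c.id], 1e-12)) for c in eligible]
        )
        uf = _UnionFind(len(eligible))
        for i in range(len(eligible)):
            tnf_d = np.linalg.norm(tnfs[i + 1 :] - tnfs[i], axis=1)
            cov_d = np.abs(log_depths[i + 1 :] - log_depths[i])
            linked = np.nonzero(
                (tnf_d <= preset.tnf_threshold)
                & (cov_d <= preset.coverage_log_threshold)
            )[0]
            for off in linked:
                uf.union(i, i + 1 + int(off))

        clusters: dict[int, list[Contig]] = {}
        for i, c in enumerate(eligible):
            clusters.setdefault(uf.find(i), []).append(c)
        kept = [
            members
            for members in clusters.values()
            if sum(c.length for c in members) >= preset.min_bin_length
        ]
        kept.sort(key=lambda m: (-sum(c.length for c in m), m[0].id))
        kept_ids = {id(m) for m in kept}
        for rank, members in enumerate(kept, start=1):
            for c in members:
                assignments[c.id] = f"bin{rank}"
        for members in clusters.values():
            if id(members) not in kept_ids:
                for c in members:
                    assignments[c.id] = NOBIN
    return BinningResult(preset=preset.name, assignments=assignments)


# ---------------------------------------------------------------------------
# Preset selection


def _bin_key(record: BinQCRecord) -> tuple[float, float, float]:
    # lexicographic: min contamination, min strain heterogeneity,
    # max completeness; missing statistics compare as 0
    return (
        record.contamination if record.contamination is not None else 0.0,
        record.strain_heterogeneity
        if record.strain_heterogeneity is not None
        else 0.0,
        -(record.completeness if record.completeness is not None else 0.0),
    )


def select_preset(
    qc_by_preset: Mapping[str, Sequence[BinQCRecord]],
) -> str:
    """Pick the preset whose largest bin is best by (contamination,
    strain heterogeneity, completeness), recursing to next-largest bins on
    exact ties.  A persisting full tie returns the most sensitive preset.

    QC records must be supplied ordered by decreasing bin total length; nobin
    rows are ignored.  Presets with empty QC tables are excluded with a
    warning; if all are excluded this is an error.
    """
    candidates: dict[str, list[tuple[float, float, float]]] = {}
    for name, records in qc_by_preset.items():
        keys = [_bin_key(r) for r in records if r.nature != "No"]
        if not keys:
            warnings.warn(f"preset {name!r} has an empty QC table; excluded")
            continue
        candidates[name] = keys
    if not candidates:
        raise ValueError("no preset has a non-empty QC table")

    best = min(candidates.items(), key=lambda kv: (kv[1], _sensitivity(kv[0])))
    return best[0]


def _sensitivity(name: str) -> int:
    # more sensitive presets win full ties; unknown names sort last
    try:
        return PRESET_ORDER.index(name)
    except ValueError:
        return len(PRESET_ORDER)


# ---------------------------------------------------------------------------
# Merge advisory


@dataclass
class MergeAdvice:
    merge: bool
    reason: str


_ROOT_LABELS = {"", "root", "unclassified", "unclassified-root", "nobin"}


def _is_root(taxon: str) -> bool:
    return taxon.strip().lower() in _ROOT_LABELS


def merge_advisory(
    taxon_x: str,
    taxon_y: str,
    complementary: bool,
    taxonomy: Mapping[str, tuple[str, ...]],
) -> MergeAdvice:
    """Recommend merging two bins only when their marker-gene sets are
    complementary AND both taxon placements are non-root with one being an
    ancestor-or-equal of the other."""
    if not complementary:
        return MergeAdvice(False, "bins are not complementary")
    if _is_root(taxon_x) or _is_root(taxon_y):
        return MergeAdvice(
            False, "taxonomic placement not congruent: unclassified bin"
        )
    lx = taxonomy.get(taxon_x)
    ly = taxonomy.get(taxon_y)
    if lx is None or ly is None:
        unknown = taxon_x if lx is None else taxon_y
        return MergeAdvice(False, f"unknown taxon label {unknown!r}")
    shorter, longer = (lx, ly) if len(lx) <= len(ly) else (ly, lx)
    if longer[: len(shorter)] == shorter:
        return MergeAdvice(
            True, f"complementary and nested taxa ({taxon_x} / {taxon_y})"
        )
    return MergeAdvice(
        False,
        f"taxonomic placement not congruent ({taxon_x} vs {taxon_y})",
    )


# ---------------------------------------------------------------------------
# Quality tiers


def quality_tier(record: BinQCRecord, has_affiliated_rrna: bool) -> str:
    """MIMAG-style tier: medium at completeness >= 90 and contamination < 5;
    high additionally requires an affiliated SSU rRNA gene."""
    if record.completeness is None:
        raise ValueError(f"bin {record.bin_id!r}: completeness missing")
    contamination = record.contamination
    if contamination is None:
        raise ValueError(f"bin {record.bin_id!r}: contamination missing")
    if record.completeness >= 90 and contamination < 5:
        return "high" if has_affiliated_rrna else "medium"
    return "low"
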