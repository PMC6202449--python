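"""Why do rRNA-bearing contigs end up unbinned, and which bin should a
classified rRNA gene belong to?

``rrna_fate`` scores every locus-bearing contig against the TNF-nearest bin
of its metagenome and labels the loss mechanism (excess coverage, divergent
composition, both, or neither).  ``affiliate_rrna`` maps a classified locus
to the unique taxonomically congruent bin, if any.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .composition_profiles import (
    BinProfile,
    bin_profile,
    divergence_report,
    tnf_distance,
    tnf_vector,
)
from .formats_io import NOBIN, Contig, RRNALocus

__all__ = [
    "FateRecord",
    "DEFAULT_COVERAGE_RATIO_CUTOFF",
    "DEFAULT_TNF_Z_CUTOFF",
    "rrna_fate",
    "affiliate_rrna",
]

DEFAULT_COVERAGE_RATIO_CUTOFF = 1.5
DEFAULT_TNF_Z_CUTOFF = 2.0

VERDICTS = ("binned", "lost_coverage", "lost_composition", "lost_both", "lost_other")


@dataclass
class FateRecord:
    locus: RRNALocus
    host_bin: str
    nearest_bin: str
    coverage_ratio: float
    tnf_z: Optional[float]
    verdict: str


def _verdict(
    host_bin: str,
    coverage_ratio: float,
    tnf_z: Optional[float],
    ratio_cutoff: float,
    z_cutoff: float,
) -> str:
    if host_bin != NOBIN:
        return "binned"
    high_cov = coverage_ratio > ratio_cutoff
    high_z = tnf_z is not None and tnf_z > z_cutoff
    if high_cov and high_z:
        return "lost_both"
    if high_cov:
        return "lost_coverage"
    if high_z:
        return "lost_composition"
    return "lost_other"


def rrna_fate(
    loci: Sequence[RRNALocus],
    assignments: Mapping[str, str],
    contigs: Sequence[Contig],
    depths: Mapping[str, float],
    ratio_cutoff: float = DEFAULT_COVERAGE_RATIO_CUTOFF,
    z_cutoff: float = DEFAULT_TNF_Z_CUTOFF,
) -> list[FateRecord]:
    """Diagnose the binning fate of each rRNA locus.

    The nearest bin is the one whose TNF centroid is closest to the locus
    contig; coverage ratio and TNF z-score are computed against that bin's
    profile.  Cut-offs are explicit parameters so verdicts stay re-derivable
    from the reported raw scores.
    """
    by_id = {c.id: c for c in contigs}
    for locus in loci:
        if locus.contig_id not in by_id:
            raise KeyError(f"rRNA locus on unknown contig {locus.contig_id!r}")

    members: dict[str, list[Contig]] = {}
    for c in contigs:
        if c.id not in depths:
            raise KeyError(f"no depth entry for contig {c.id!r}")
        bin_id = assignments.get(c.id, NOBIN)
        if bin_id != NOBIN:
            # depth always comes from the depth table, not the FASTA object
            members.setdefault(
                bin_id, []
            ).append(Contig(id=c.id, seq=c.seq, depth=depths[c.id]))
    if not members:
        raise ValueError("no bins in binning result; cannot diagnose fate")
    profiles: dict[str, BinProfile] = {
        bin_id: bin_profile(mem, bin_id=bin_id)
        for bin_id, mem in members.items()
    }

    records = []
    for locus in loci:
        contig = by_id[locus.contig_id]
        tnf = tnf_vector(contig.seq)
        nearest = min(
            profiles.values(),
            key=lambda p: (tnf_distance(tnf, p.centroid), p.bin_id),
        )
        scored = Contig(
            id=contig.id, seq=contig.seq, depth=depths[contig.id]
        )
        report = divergence_report(scored, nearest)
        host_bin = assignments.get(contig.id, NOBIN)
        records.append(
            FateRecord(
                locus=locus,
                host_bin=host_bin,
                nearest_bin=nearest.bin_id,
                coverage_ratio=report.coverage_ratio,
                tnf_z=report.tnf_z,
                verdict=_verdict(
                    host_bin,
                    report.coverage_ratio,
                    report.tnf_z,
                    ratio_cutoff,
                    z_cutoff,
                ),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Affiliation by taxon congruence


def _congruent(
    label_a: str, label_b: str, taxonomy: Mapping[str, tuple[str, ...]]
) -> bool:
    la, lb = taxonomy.get(label_a), taxonomy.get(label_b)
    if la is None or lb is None:
        return label_a == label_b
    shorter, longer = (la, lb) if len(la) <= len(lb) else (lb, la)
    return longer[: len(shorter)] == shorter


def affiliate_rrna(
    locus_taxon: str,
    bin_taxa: Mapping[str, str],
    synonyms: Mapping[str, Sequence[str]],
    taxonomy: Mapping[str, tuple[str, ...]],
) -> Optional[str]:
    """Affiliate a classified rRNA locus to the unique congruent bin.

    The locus label is first expanded through the synonym map (e.g. a genus
    to its phylum); a bin is congruent when its taxon equals, contains or is
    contained by any expanded label.  Unclassified loci and ambiguous
    matches return ``None`` — a value, not an error.
    """
    locus_taxon = locus_taxon.strip()
    if not locus_taxon or locus_taxon.lower() in ("unclassified", "na", "root"):
        return None
    expanded = list(synonyms.get(locus_taxon, (locus_taxon,)))
    matches = []
    for bin_id, taxon in bin_taxa.items():
        if taxon.strip().lower() in ("", "unclassified", "root", "nobin"):
            continue
        if any(_congruent(e, taxon, taxonomy) for e in expanded):
            matches.append(bin_id)
    if len(matches) == 1:
        return matches[0]
    return None
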