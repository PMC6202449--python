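"""Foreign-sequence screening of a bin via fixed-length pseudo-reads.

A bin is split into non-overlapping 250-nt pseudo-reads, each read is
classified by its best homology hit (max bitscore, then min e-value, then
input order), and the foreign fraction is reported over classified reads
only.  An LCA classification rule is available behind a flag but is not the
default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .formats_io import Contig, HitRecord

__all__ = [
    "DEFAULT_WINDOW",
    "PseudoRead",
    "ScreenResult",
    "split_pseudoreads",
    "classify_read",
    "classify_read_lca",
    "screen_bin",
]

DEFAULT_WINDOW = 250


@dataclass(frozen=True)
class PseudoRead:
    """A fixed-length fragment of a contig; id is ``contigId:start``
    (1-based)."""

    id: str
    seq: str
    parent: str


def split_pseudoreads(
    contigs: Iterable[Contig],
    window: int = DEFAULT_WINDOW,
    keep_tail: bool = False,
) -> list[PseudoRead]:
    """Cut each contig into non-overlapping windows starting at offsets
    1, window+1, ...  The trailing fragment shorter than ``window`` is
    discarded unless ``keep_tail`` is set."""
    if window < 1:
        raise ValueError("window must be >= 1")
    reads = []
    for contig in contigs:
        n_full = len(contig.seq) // window
        for i in range(n_full):
            start = i * window
            reads.append(
                PseudoRead(
                    id=f"{contig.id}:{start + 1}",
                    seq=contig.seq[start : start + window],
                    parent=contig.id,
                )
            )
        tail_start = n_full * window
        if keep_tail and tail_start < len(contig.seq):
            reads.append(
                PseudoRead(
                    id=f"{contig.id}:{tail_start + 1}",
                    seq=contig.seq[tail_start:],
                    parent=contig.id,
                )
            )
    return reads


def classify_read(hits: Sequence[HitRecord]) -> Optional[tuple[str, ...]]:
    """Taxon path of the best hit: max bitscore, ties broken by min e-value,
    then by input order.  No hits -> None (unclassified)."""
    if not hits:
        return None
    best = hits[0]
    for h in hits[1:]:
        if h.bitscore > best.bitscore or (
            h.bitscore == best.bitscore and h.evalue < best.evalue
        ):
            best = h
    return best.taxon_path


def classify_read_lca(hits: Sequence[HitRecord]) -> Optional[tuple[str, ...]]:
    """Lowest-common-ancestor path across all hits (optional rule)."""
    if not hits:
        return None
    lca = list(hits[0].taxon_path)
    for h in hits[1:]:
        common = 0
        for a, b in zip(lca, h.taxon_path):
            if a != b:
                break
            common += 1
        lca = lca[:common]
        if not lca:
            return None
    return tuple(lca)


@dataclass
class ScreenResult:
    bin_id: str
    n_reads: int
    n_classified: int
    n_self: int
    n_foreign: int
    foreign_pct: Optional[float]  # None when no read classified
    breakdown: dict[str, int] = field(default_factory=dict)


def _is_self(
    taxon_path: tuple[str, ...], self_taxon: str, rank: int
) -> bool:
    """Self iff the path contains the self taxon at or below the comparison
    rank (0-based index into the path)."""
    return self_taxon in taxon_path[rank:]


def screen_bin(
    contigs: Sequence[Contig],
    hits: Sequence[HitRecord],
    self_taxon: str,
    rank: int = 1,
    window: int = DEFAULT_WINDOW,
    bin_id: str = "",
    lca: bool = False,
) -> ScreenResult:
    """Screen one bin for foreign pseudo-reads.

    ``rank`` is the 0-based depth in the taxon path at which self vs foreign
    is decided (1 = phylum for paths rooted at a domain).  The foreign
    percentage is computed over classified reads only; with zero classified
    reads it is explicitly missing, never 0.
    """
    if not self_taxon:
        raise ValueError("self_taxon must be non-empty")
    reads = split_pseudoreads(contigs, window=window)
    hits_by_read: dict[str, list[HitRecord]] = {}
    for h in hits:
        hits_by_read.setdefault(h.query_id, []).append(h)

    classify = classify_read_lca if lca else classify_read
    n_classified = n_self = n_foreign = 0
    breakdown: dict[str, int] = {}
    for read in reads:
        path = classify(hits_by_read.get(read.id, []))
        if path is None:
            continue
        n_classified += 1
        label = path[rank] if len(path) > rank else path[-1]
        breakdown[label] = breakdown.get(label, 0) + 1
        if _is_self(path, self_taxon, rank):
            n_self += 1
        else:
            n_foreign += 1
    foreign_pct = (
        100.0 * n_foreign / n_classified if n_classified else None
    )
    return ScreenResult(
        bin_id=bin_id,
        n_reads=len(reads),
        n_classified=n_classified,
        n_self=n_self,
        n_foreign=n_foreign,
        foreign_pct=foreign_pct,
        breakdown=breakdown,
    )
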