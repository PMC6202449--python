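"""Seeded synthetic metagenomic communities with truth labels.

Each genome is drawn from its own Markov chain (giving a genome-specific
oligonucleotide signature), fragmented into contigs at random breakpoints and
assigned per-contig depths around its coverage level.  Multi-copy rRNA
operons are modeled as a SHARED sequence from a separate chain and collapsed
into a single short, high-depth contig — the assembly behavior whose
downstream consequences the diagnostics in this package detect.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .formats_io import (
    Contig,
    RRNALocus,
    write_depth_table,
    write_fasta,
    write_rrna_gff,
)

__all__ = [
    "GenomeSpec",
    "TruthRow",
    "GenomeSpecError",
    "simulate_genome",
    "simulate_rrna_operon",
    "fragment_and_cover",
    "simulate_community",
    "write_truth_table",
    "read_truth_table",
    "demo_specs",
]

_BASES = "ACGT"

# the rRNA operon chain is shared by all genomes; its composition seed is a
# package constant so operon composition diverges from every genome background
RRNA_COMPOSITION_SEED = 987654321


class GenomeSpecError(ValueError):
    pass


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters of one synthetic genome."""

    name: str
    length: int
    coverage: float
    composition_seed: Optional[int]  # None -> uniform base probabilities
    markov_order: int = 2
    rrna_copies: int = 0
    rrna_length: int = 5000

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise GenomeSpecError("length must be positive")
        if self.coverage <= 0:
            raise GenomeSpecError("coverage must be positive")
        if not 0 <= self.markov_order <= 2:
            raise GenomeSpecError("markov_order must be 0, 1 or 2")
        if self.rrna_copies < 0:
            raise GenomeSpecError("rrna_copies must be >= 0")
        if self.rrna_copies > 0 and self.length < 10 * self.rrna_length:
            raise GenomeSpecError(
                "genome length must be >= 10x rrna_length when rRNA present"
            )


@dataclass(frozen=True)
class TruthRow:
    """Ground-truth label for one emitted contig."""

    contig_id: str
    genome: str
    is_rrna_contig: bool
    true_coverage: float


def _markov_sequence(
    length: int, order: int, composition_seed: Optional[int], rng_seed: int
) -> str:
    """Draw a sequence from a Markov chain whose transition rows are sampled
    from a flat Dirichlet parameterized by ``composition_seed``; a seed of
    ``None`` selects uniform base probabilities instead."""
    n_states = 4**order if order > 0 else 1
    if composition_seed is None:
        trans = np.full((n_states, 4), 0.25)
    else:
        comp_rng = np.random.default_rng(composition_seed)
        trans = comp_rng.dirichlet(np.ones(4), size=n_states)
    rng = np.random.default_rng(rng_seed)
    cum = np.cumsum(trans, axis=1)
    u = rng.random(length)
    if order == 0:
        codes = np.searchsorted(cum[0, :3], u, side="right")
        return "".join(_BASES[b] for b in codes)
    # first-three-thresholds rows as plain tuples keep the chain loop cheap
    rows = [tuple(row[:3]) for row in cum]
    out = []
    append = out.append
    state = 0
    mask = n_states - 1
    for x in u.tolist():
        c0, c1, c2 = rows[state]
        b = 0 if x < c0 else 1 if x < c1 else 2 if x < c2 else 3
        append(_BASES[b])
        state = ((state << 2) | b) & mask
    return "".join(out)


def simulate_genome(spec: GenomeSpec, rng_seed: int) -> str:
    """Deterministic genome background sequence for a spec and seed."""
    return _markov_sequence(
        spec.length, spec.markov_order, spec.composition_seed, rng_seed
    )


def simulate_rrna_operon(length: int, rng_seed: int) -> str:
    """The shared rRNA operon sequence (genome-independent composition)."""
    return _markov_sequence(length, 2, RRNA_COMPOSITION_SEED, rng_seed)


def _breakpoints(
    total: int, min_len: int, max_len: int, rng: np.random.Generator
) -> list[int]:
    """Successive contig lengths covering ``total`` exactly, each within
    [min_len, max_len] whenever geometrically possible."""
    if total < min_len:
        raise GenomeSpecError(
            f"sequence of {total} bp shorter than min contig length {min_len}"
        )
    lengths: list[int] = []
    remaining = total
    while remaining > max_len:
        ell = int(rng.integers(min_len, max_len + 1))
        if remaining - ell < min_len:
            ell = remaining - min_len
        lengths.append(ell)
        remaining -= ell
    lengths.append(remaining)
    return lengths


def _truncated_normal(
    mean: float, sd: float, rng: np.random.Generator
) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x >= 0:
            return float(x)
    return 0.0


def fragment_and_cover(
    genome: str,
    spec: GenomeSpec,
    rng_seed: int,
    min_contig_len: int = 2500,
    max_contig_len: int = 200_000,
    depth_cv: float = 0.05,
) -> tuple[list[Contig], list[TruthRow], list[RRNALocus]]:
    """Cut a genome into contigs with depths around the spec coverage.

    With ``rrna_copies >= 2`` all operon copies collapse into ONE contig of
    ``rrna_length`` whose depth is ``coverage * rrna_copies``; the emitted
    background therefore shrinks by ``rrna_copies * rrna_length``.  A single
    operon copy is embedded inside an ordinary contig instead.
    """
    rng = np.random.default_rng(rng_seed)
    contigs: list[Contig] = []
    truth: list[TruthRow] = []
    loci: list[RRNALocus] = []

    background = genome
    operon = ""
    if spec.rrna_copies > 0:
        # shared across genomes: same chain, same draw seed
        operon = simulate_rrna_operon(spec.rrna_length, RRNA_COMPOSITION_SEED)
        removed = spec.rrna_copies * spec.rrna_length
        if removed >= len(genome):
            raise GenomeSpecError("rRNA operons exceed genome length")
        background = genome[: len(genome) - removed]

    collapse = spec.rrna_copies >= 2
    embed_single = spec.rrna_copies == 1

    lengths = _breakpoints(len(background), min_contig_len, max_contig_len, rng)
    pos = 0
    pieces = []
    for ell in lengths:
        pieces.append(background[pos : pos + ell])
        pos += ell

    embed_idx = int(rng.integers(0, len(pieces))) if embed_single else -1
    for i, piece in enumerate(pieces):
        cid = f"{spec.name}_c{i + 1}"
        depth = _truncated_normal(spec.coverage, depth_cv * spec.coverage, rng)
        is_rrna = False
        if i == embed_idx:
            # single-copy operon rides inside an ordinary contig
            insert_at = len(piece) // 2
            piece = piece[:insert_at] + operon + piece[insert_at:]
            loci.append(
                RRNALocus(
                    contig_id=cid,
                    start=insert_at + 1,
                    end=insert_at + spec.rrna_length,
                )
            )
            is_rrna = True
        contigs.append(Contig(id=cid, seq=piece, depth=depth))
        truth.append(TruthRow(cid, spec.name, is_rrna, spec.coverage))

    if collapse:
        cid = f"{spec.name}_rrna"
        depth = spec.coverage * spec.rrna_copies
        contigs.append(Contig(id=cid, seq=operon, depth=depth))
        truth.append(TruthRow(cid, spec.name, True, spec.coverage))
        loci.append(RRNALocus(contig_id=cid, start=1, end=spec.rrna_length))
    return contigs, truth, loci


def simulate_community(
    specs: Sequence[GenomeSpec],
    rng_seed: int,
    out_dir: Optional[str | Path] = None,
    min_contig_len: int = 2500,
    max_contig_len: int = 200_000,
) -> tuple[list[Contig], list[TruthRow], list[RRNALocus]]:
    """Concatenate per-genome simulations; optionally write
    contigs.fasta / depth.tsv / truth.tsv / rrna.gff to ``out_dir``."""
    if not specs:
        raise GenomeSpecError("at least one genome spec required")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise GenomeSpecError(f"duplicate genome names in {names}")

    contigs: list[Contig] = []
    truth: list[TruthRow] = []
    loci: list[RRNALocus] = []
    for i, spec in enumerate(specs):
        genome = simulate_genome(spec, rng_seed + 1000 * i)
        c, t, l = fragment_and_cover(
            genome,
            spec,
            rng_seed + 1000 * i + 1,
            min_contig_len=min_contig_len,
            max_contig_len=max_contig_len,
        )
        contigs.extend(c)
        truth.extend(t)
        loci.extend(l)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta(contigs, out_dir / "contigs.fasta")
        write_depth_table(contigs, out_dir / "depth.tsv")
        write_truth_table(truth, out_dir / "truth.tsv")
        write_rrna_gff(loci, out_dir / "rrna.gff")
    return contigs, truth, loci


def write_truth_table(truth: Sequence[TruthRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tgenome\tis_rrna_contig\ttrue_coverage\n")
        for row in truth:
            fh.write(
                f"{row.contig_id}\t{row.genome}\t"
                f"{int(row.is_rrna_contig)}\t{row.true_coverage!r}\n"
            )


def read_truth_table(path: str | Path) -> list[TruthRow]:
    rows = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            if not line.strip():
                continue
            cid, genome, flag, cov = line.rstrip("\n").split("\t")
            rows.append(TruthRow(cid, genome, bool(int(flag)), float(cov)))
    return rows


def demo_specs(
    genome_length: int = 200_000,
    coverages: tuple[float, float] = (10.0, 40.0),
    rrna_copies: int = 4,
) -> list[GenomeSpec]:
    """The default two-genome demo community: two 200-kb genomes with
    distinct composition seeds and coverages, a 4-copy rRNA operon in the
    high-coverage genome."""
    return [
        GenomeSpec(
            name="g_low",
            length=genome_length,
            coverage=coverages[0],
            composition_seed=11,
        ),
        GenomeSpec(
            name="g_high",
            length=genome_length,
            coverage=coverages[1],
            composition_seed=42,
            rrna_copies=rrna_copies,
        ),
    ]
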