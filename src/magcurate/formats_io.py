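"""Readers and writers for the external formats the toolkit touches.

Contig FASTA, MetaBAT-style depth tables, bin membership tables, bin QC
tables, SSU rRNA summary tables, outfmt-6-like homology hit tables with a
trailing taxon-path column, and GFF-style rRNA locus lines.  All tabular
dialects are tab-separated UTF-8 with a mandatory header row; missing values
are written as ``na`` and parsed to ``None`` (never to 0).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO

NOBIN = "nobin"

_NA = "na"

__all__ = [
    "NOBIN",
    "Contig",
    "BinQCRecord",
    "RRNARecord",
    "HitRecord",
    "RRNALocus",
    "DuplicateIdError",
    "TableFormatError",
    "read_fasta",
    "write_fasta",
    "read_depth_table",
    "write_depth_table",
    "read_qc_table",
    "write_qc_table",
    "read_rrna_table",
    "write_rrna_table",
    "read_hits",
    "write_hits",
    "read_bins_table",
    "write_bins_table",
    "read_rrna_gff",
    "write_rrna_gff",
    "load_fixture_qc",
    "load_fixture_rrna",
    "load_taxonomy",
    "load_taxon_groups",
    "load_taxon_synonyms",
]


class DuplicateIdError(ValueError):
    """Raised when a FASTA file contains repeated sequence identifiers."""


class TableFormatError(ValueError):
    """Raised when a tabular input violates its documented schema."""


@dataclass
class Contig:
    """One assembly scaffold/contig with optional coverage and bin label."""

    id: str
    seq: str
    depth: float = 0.0
    bin_id: Optional[str] = None

    @property
    def length(self) -> int:
        return len(self.seq)

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError(f"contig {self.id!r}: depth must be >= 0")


@dataclass
class BinQCRecord:
    """One row of a CheckM-style bin QC table."""

    strain: str
    bin_id: str
    taxon: str
    nature: str  # one of C, M, U, No
    n_scaffolds: int
    length_pct: float
    coverage_med: float
    completeness: Optional[float]
    contamination: Optional[float]
    strain_heterogeneity: Optional[float] = None
    preset: Optional[str] = None

    VALID_NATURES = ("C", "M", "U", "No")

    def __post_init__(self) -> None:
        if self.nature not in self.VALID_NATURES:
            raise TableFormatError(
                f"nature must be one of {self.VALID_NATURES}, got {self.nature!r}"
            )
        if self.completeness is not None and not 0 <= self.completeness <= 100:
            raise TableFormatError(
                f"completeness out of [0, 100]: {self.completeness}"
            )


@dataclass
class RRNARecord:
    """One row of an SSU rRNA summary table.

    ``direct_from_bin`` is the table's asterisk convention: the gene was
    predicted directly from the affiliated genome bin rather than manually
    affiliated from the unbinned contigs.
    """

    strain: str
    taxon_label: str
    top_hit: str
    source_bin: str
    affiliated_bin: Optional[str]
    direct_from_bin: bool
    coverage: float

    def __post_init__(self) -> None:
        if self.direct_from_bin and self.affiliated_bin is None:
            raise TableFormatError(
                "direct_from_bin requires an affiliated bin"
            )


@dataclass
class HitRecord:
    """One line of an outfmt-6-like hit table with a trailing taxon path."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float
    taxon_path: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise TableFormatError("evalue must be >= 0")
        if not self.taxon_path:
            raise TableFormatError("taxon_path must be non-empty")


@dataclass
class RRNALocus:
    """An rRNA gene locus; coordinates are 1-based inclusive (GFF)."""

    contig_id: str
    start: int
    end: int
    strand: str = "+"
    taxon_label: str = "Unclassified"

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(
                f"invalid locus on {self.contig_id}: {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[Contig]:
    """Read contigs from a FASTA file.

    Ids are taken from the header up to the first whitespace (Biopython's
    record id); sequences are uppercased and U mapped to T.  Duplicate ids
    are a hard error.
    """
    contigs: list[Contig] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise DuplicateIdError(
                f"duplicate sequence id {record.id!r} in {path}"
            )
        seen.add(record.id)
        seq = str(record.seq).upper().replace("U", "T")
        contigs.append(Contig(id=record.id, seq=seq))
    return contigs


def write_fasta(contigs: Iterable[Contig], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.id}\n")
            for i in range(0, len(c.seq), width):
                fh.write(c.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Depth tables (MetaBAT dialect: contigName, contigLen, totalAvgDepth, ...)

DEPTH_COLUMNS = ["contigName", "contigLen", "totalAvgDepth"]


def read_depth_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in DEPTH_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"depth table missing columns {missing}")
    if df["contigName"].duplicated().any():
        dups = df.loc[df["contigName"].duplicated(), "contigName"].tolist()
        raise TableFormatError(f"duplicate contigs in depth table: {dups}")
    if (df["totalAvgDepth"] < 0).any():
        raise TableFormatError("negative depth in depth table")
    return df


def write_depth_table(contigs: Sequence[Contig], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "contigName": [c.id for c in contigs],
            "contigLen": [c.length for c in contigs],
            "totalAvgDepth": [c.depth for c in contigs],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def depth_lookup(depth: pd.DataFrame) -> dict[str, float]:
    return dict(zip(depth["contigName"], depth["totalAvgDepth"]))


# ---------------------------------------------------------------------------
# Bin QC tables (schema of the in-package table3.tsv fixture)

QC_COLUMNS = [
    "strain",
    "preset",
    "bin_id",
    "taxon",
    "nature",
    "n_scaffolds",
    "length_pct",
    "coverage_med",
    "completeness",
    "contamination",
    "strain_heterogeneity",
]


def _parse_optional_float(cell: str, what: str, row: int) -> Optional[float]:
    cell = cell.strip()
    if cell == "" or cell.lower() == _NA:
        return None
    try:
        return float(cell)
    except ValueError:
        raise TableFormatError(f"non-numeric {what} at data row {row}: {cell!r}")


def read_qc_table(path: str | Path) -> list[BinQCRecord]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != QC_COLUMNS:
            raise TableFormatError(
                f"QC table header mismatch: expected {QC_COLUMNS}, got {header}"
            )
        records = []
        for row_no, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != len(QC_COLUMNS):
                raise TableFormatError(
                    f"QC table row {row_no}: expected {len(QC_COLUMNS)} columns, "
                    f"got {len(cells)}"
                )
            d = dict(zip(QC_COLUMNS, cells))
            records.append(
                BinQCRecord(
                    strain=d["strain"],
                    preset=d["preset"] or None,
                    bin_id=d["bin_id"],
                    taxon=d["taxon"],
                    nature=d["nature"],
                    n_scaffolds=int(d["n_scaffolds"]),
                    length_pct=float(d["length_pct"]),
                    coverage_med=float(d["coverage_med"]),
                    completeness=_parse_optional_float(
                        d["completeness"], "completeness", row_no
                    ),
                    contamination=_parse_optional_float(
                        d["contamination"], "contamination", row_no
                    ),
                    strain_heterogeneity=_parse_optional_float(
                        d["strain_heterogeneity"], "strain heterogeneity", row_no
                    ),
                )
            )
    return records


def _fmt_optional(x: Optional[float]) -> str:
    return _NA if x is None else repr(x)


def write_qc_table(records: Iterable[BinQCRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(QC_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.strain,
                        r.preset or "",
                        r.bin_id,
                        r.taxon,
                        r.nature,
                        str(r.n_scaffolds),
                        repr(r.length_pct),
                        repr(r.coverage_med),
                        _fmt_optional(r.completeness),
                        _fmt_optional(r.contamination),
                        _fmt_optional(r.strain_heterogeneity),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# rRNA summary tables (schema of the in-package table4.tsv fixture)

RRNA_COLUMNS = [
    "strain",
    "taxon_label",
    "top_hit",
    "source_bin",
    "affiliated_bin",
    "coverage",
]


def read_rrna_table(path: str | Path) -> list[RRNARecord]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != RRNA_COLUMNS:
            raise TableFormatError(
                f"rRNA table header mismatch: expected {RRNA_COLUMNS}, got {header}"
            )
        records = []
        for line_no, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != len(RRNA_COLUMNS):
                raise TableFormatError(
                    f"rRNA table line {line_no}: expected {len(RRNA_COLUMNS)} "
                    f"columns, got {len(cells)}"
                )
            d = dict(zip(RRNA_COLUMNS, cells))
            affiliation = d["affiliated_bin"].strip()
            direct = affiliation.endswith("*")
            affiliated = affiliation.rstrip("*") or None
            try:
                coverage = float(d["coverage"])
            except ValueError:
                raise TableFormatError(
                    f"rRNA table line {line_no}: bad coverage {d['coverage']!r}"
                )
            records.append(
                RRNARecord(
                    strain=d["strain"],
                    taxon_label=d["taxon_label"],
                    top_hit=d["top_hit"],
                    source_bin=d["source_bin"],
                    affiliated_bin=affiliated,
                    direct_from_bin=direct,
                    coverage=coverage,
                )
            )
    return records


def write_rrna_table(records: Iterable[RRNARecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(RRNA_COLUMNS) + "\n")
        for r in records:
            affiliation = ""
            if r.affiliated_bin is not None:
                affiliation = r.affiliated_bin + ("*" if r.direct_from_bin else "")
            fh.write(
                "\t".join(
                    [
                        r.strain,
                        r.taxon_label,
                        r.top_hit,
                        r.source_bin,
                        affiliation,
                        f"{r.coverage:.2f}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Homology hit tables: 12 outfmt-6 columns + semicolon-separated taxon path

N_HIT_COLUMNS = 13


def read_hits(path: str | Path) -> list[HitRecord]:
    records: list[HitRecord] = []
    with open(path) as fh:
        header = fh.readline()
        if header and not header.startswith("query_id\t"):
            raise TableFormatError("hit table must start with a header row")
        for line_no, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != N_HIT_COLUMNS:
                raise TableFormatError(
                    f"hit table line {line_no}: expected {N_HIT_COLUMNS} columns, "
                    f"got {len(cells)}"
                )
            records.append(
                HitRecord(
                    query_id=cells[0],
                    subject_id=cells[1],
                    pct_identity=float(cells[2]),
                    aln_length=int(cells[3]),
                    mismatches=int(cells[4]),
                    gap_opens=int(cells[5]),
                    q_start=int(cells[6]),
                    q_end=int(cells[7]),
                    s_start=int(cells[8]),
                    s_end=int(cells[9]),
                    evalue=float(cells[10]),
                    bitscore=float(cells[11]),
                    taxon_path=tuple(t for t in cells[12].split(";") if t),
                )
            )
    return records


HIT_COLUMNS = [
    "query_id",
    "subject_id",
    "pct_identity",
    "aln_length",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "evalue",
    "bitscore",
    "taxon_path",
]


def write_hits(records: Iterable[HitRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(HIT_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.query_id,
                        r.subject_id,
                        repr(r.pct_identity),
                        str(r.aln_length),
                        str(r.mismatches),
                        str(r.gap_opens),
                        str(r.q_start),
                        str(r.q_end),
                        str(r.s_start),
                        str(r.s_end),
                        repr(r.evalue),
                        repr(r.bitscore),
                        ";".join(r.taxon_path),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Bin membership tables (contig_id, bin_id)


def read_bins_table(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("contig_id", "bin_id"):
        if col not in df.columns:
            raise TableFormatError(f"bins table missing column {col!r}")
    if df["contig_id"].duplicated().any():
        dups = df.loc[df["contig_id"].duplicated(), "contig_id"].tolist()
        raise TableFormatError(f"contig assigned to multiple bins: {dups}")
    return dict(zip(df["contig_id"], df["bin_id"]))


def write_bins_table(assignments: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tbin_id\n")
        for contig_id, bin_id in assignments.items():
            fh.write(f"{contig_id}\t{bin_id}\n")


# ---------------------------------------------------------------------------
# GFF-style rRNA locus lines (1-based inclusive coordinates)


def read_rrna_gff(path: str | Path) -> list[RRNALocus]:
    loci = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != 9:
                raise TableFormatError(
                    f"GFF line {line_no}: expected 9 columns, got {len(cells)}"
                )
            attrs = dict(
                kv.split("=", 1) for kv in cells[8].split(";") if "=" in kv
            )
            loci.append(
                RRNALocus(
                    contig_id=cells[0],
                    start=int(cells[3]),
                    end=int(cells[4]),
                    strand=cells[6] if cells[6] in ("+", "-") else "+",
                    taxon_label=attrs.get("taxon", "Unclassified"),
                )
            )
    return loci


def write_rrna_gff(loci: Iterable[RRNALocus], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for loc in loci:
            attrs = f"Name=rRNA_operon;taxon={loc.taxon_label}"
            fh.write(
                "\t".join(
                    [
                        loc.contig_id,
                        "magcurate",
                        "rRNA",
                        str(loc.start),
                        str(loc.end),
                        ".",
                        loc.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Packaged fixtures and reference tables


def _data_path(name: str) -> Path:
    return Path(importlib.resources.files("magcurate").joinpath("data", name))


def load_fixture_qc() -> list[BinQCRecord]:
    """The packaged bin QC fixture (72 rows: 55 bins + 17 nobins)."""
    return read_qc_table(_data_path("table3.tsv"))


def load_fixture_rrna() -> list[RRNARecord]:
    """The packaged SSU rRNA fixture (38 records)."""
    return read_rrna_table(_data_path("table4.tsv"))


def load_taxonomy() -> dict[str, tuple[str, ...]]:
    """Label -> full lineage tuple (root first) for the labels the QC and
    rRNA tables use."""
    df = pd.read_csv(_data_path("taxonomy.tsv"), sep="\t")
    return {
        row.label: tuple(row.lineage.split(";")) for row in df.itertuples()
    }


def load_taxon_groups() -> dict[str, frozenset[str]]:
    """Phylum-group name -> set of member taxon labels."""
    df = pd.read_csv(_data_path("taxon_groups.tsv"), sep="\t")
    return {
        group: frozenset(sub["label"])
        for group, sub in df.groupby("group")
    }


def load_taxon_synonyms() -> dict[str, tuple[str, ...]]:
    """rRNA classification label -> taxa it maps onto for bin affiliation."""
    df = pd.read_csv(_data_path("taxon_synonyms.tsv"), sep="\t")
    return {
        row.label: tuple(row.mapped_taxa.split(";")) for row in df.itertuples()
    }
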