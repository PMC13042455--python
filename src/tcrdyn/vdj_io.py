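"""Parsing of V(D)J contig annotation tables and paired alpha/beta clonotype calling.

Input is the 10x Genomics ``filtered_contig_annotations`` dialect: delimited
text, one row per assembled contig, with boolean quality flags per contig.
Clonotype calling follows a two-step quality control: (1) keep only contigs
that are cell-associated, high-confidence, productive and full-length, on
cells present in the scRNA-seq metadata whitelist; (2) per cell, select the
dominant TRA and dominant TRB contig (highest UMI support, ties broken by
read support, then by lexicographically smallest CDR3 nucleotide sequence).
Cells lacking a surviving chain of either locus are dropped.  Each unique
alpha/beta chain combination is one clonotype; all cells sharing it form a
T-cell clone, and a clone's copy number in a specimen is its cell count.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ContigRecord",
    "ContigDialect",
    "ClonotypeKey",
    "CellClonotype",
    "CloneTable",
    "VdjFormatError",
    "read_contigs",
    "records_from_frame",
    "read_metadata",
    "call_clonotypes",
    "build_clone_table",
    "clone_tables_by_specimen",
    "cells_to_frame",
    "write_cell_table",
    "write_clone_table",
]

METADATA_COLUMNS = ("barcode", "patient", "timepoint", "response", "subset")
TIMEPOINTS = ("pre", "post")
RESPONSES = ("PCR", "MPR", "nonMPR")


class VdjFormatError(ValueError):
    """Raised when an input table does not conform to the expected dialect."""


@dataclass(frozen=True)
class ContigRecord:
    """One assembled V(D)J contig for one cell barcode."""

    barcode: str
    chain: str
    v_gene: str
    j_gene: str
    cdr3_nt: str
    cdr3_aa: str
    umis: int
    reads: int
    productive: bool
    full_length: bool
    is_cell: bool
    high_confidence: bool

    def __post_init__(self) -> None:
        if self.umis < 0 or self.reads < 0:
            raise ValueError("umis and reads must be non-negative")


@dataclass(frozen=True)
class ContigDialect:
    """Column naming and token conventions of a contig annotation table.

    Defaults match 10x Cell Ranger ``filtered_contig_annotations.csv``.
    """

    sep: str = ","
    columns: Mapping[str, str] = field(
        default_factory=lambda: {
            "barcode": "barcode",
            "is_cell": "is_cell",
            "high_confidence": "high_confidence",
            "chain": "chain",
            "v_gene": "v_gene",
            "j_gene": "j_gene",
            "cdr3": "cdr3",
            "cdr3_nt": "cdr3_nt",
            "reads": "reads",
            "umis": "umis",
            "productive": "productive",
            "full_length": "full_length",
        }
    )
    true_tokens: frozenset[str] = frozenset({"true", "t", "yes", "1"})
    false_tokens: frozenset[str] = frozenset({"false", "f", "no", "0", "none", "nan", ""})


@dataclass(frozen=True)
class ClonotypeKey:
    """A paired alpha/beta clonotype identity.

    Identity is exact field-wise string equality of V segment, J segment and
    CDR3 for both chains.  The CDR3 fields hold nucleotide sequences by
    default; amino-acid grouping substitutes the aa CDR3 (see
    :func:`call_clonotypes` ``key_mode``).
    """

    tra_v: str
    tra_j: str
    tra_cdr3: str
    trb_v: str
    trb_j: str
    trb_cdr3: str

    def __post_init__(self) -> None:
        for name in ("tra_v", "tra_j", "tra_cdr3", "trb_v", "trb_j", "trb_cdr3"):
            if not getattr(self, name):
                raise ValueError(f"clonotype key field {name!r} must be non-empty")

    def as_string(self) -> str:
        return "|".join(
            (self.tra_v, self.tra_j, self.tra_cdr3, self.trb_v, self.trb_j, self.trb_cdr3)
        )

    @classmethod
    def from_string(cls, s: str) -> "ClonotypeKey":
        parts = s.split("|")
        if len(parts) != 6:
            raise ValueError(f"malformed clonotype key string: {s!r}")
        return cls(*parts)


@dataclass(frozen=True)
class CellClonotype:
    """A QC-passed cell with its paired clonotype and specimen metadata."""

    barcode: str
    clonotype: ClonotypeKey
    patient: str
    timepoint: str
    response: str
    subset: str


@dataclass
class CloneTable:
    """Per-specimen clonotype -> copy number map.

    Copy number is the number of cells carrying the clonotype; copy numbers
    sum to the number of QC-passed cells in the specimen.
    """

    specimen: tuple[str, str]  # (patient, timepoint)
    counts: dict[ClonotypeKey, int] = field(default_factory=dict)

    def total_cells(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.counts)


def _parse_bool(value: object, dialect: ContigDialect, column: str, line: int) -> bool:
    token = str(value).strip().lower()
    if token in dialect.true_tokens:
        return True
    if token in dialect.false_tokens:
        return False
    raise VdjFormatError(
        f"line {line}: cannot parse boolean value {value!r} in column {column!r}"
    )


def _parse_int(value: object, column: str, line: int) -> int:
    try:
        return int(value)
    except (TypeError, ValueError):
        raise VdjFormatError(
            f"line {line}: cannot parse integer value {value!r} in column {column!r}"
        ) from None


def read_contigs(path: str | Path, dialect: ContigDialect | None = None) -> list[ContigRecord]:
    """Read a contig annotation table into :class:`ContigRecord` objects.

    Parameters
    ----------
    path
        Delimited-text contig annotation file with a header row.
    dialect
        Column naming and token conventions; defaults to the 10x
        ``filtered_contig_annotations`` dialect.

    Raises
    ------
    VdjFormatError
        If a mandatory column is missing (the error names it), or a boolean
        or integer cell cannot be parsed (the error cites the line number,
        counting the header as line 1).
    """
    dialect = dialect or ContigDialect()
    df = pd.read_csv(path, sep=dialect.sep, dtype=str, keep_default_na=False)
    try:
        return records_from_frame(df, dialect)
    except VdjFormatError as exc:
        raise VdjFormatError(f"{path}: {exc}") from None


def records_from_frame(
    df: pd.DataFrame, dialect: ContigDialect | None = None
) -> list[ContigRecord]:
    """Convert an in-memory contig annotation table to :class:`ContigRecord`s.

    Same contract as :func:`read_contigs`; line numbers in errors count the
    header as line 1.
    """
    dialect = dialect or ContigDialect()
    missing = [col for col in dialect.columns.values() if col not in df.columns]
    if missing:
        raise VdjFormatError(
            f"missing mandatory column(s): {', '.join(sorted(missing))}"
        )
    c = dialect.columns
    records: list[ContigRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        row_map = dict(zip(df.columns, row))
        records.append(
            ContigRecord(
                barcode=row_map[c["barcode"]],
                chain=row_map[c["chain"]],
                v_gene=row_map[c["v_gene"]],
                j_gene=row_map[c["j_gene"]],
                cdr3_nt=row_map[c["cdr3_nt"]],
                cdr3_aa=row_map[c["cdr3"]],
                umis=_parse_int(row_map[c["umis"]], c["umis"], line),
                reads=_parse_int(row_map[c["reads"]], c["reads"], line),
                productive=_parse_bool(row_map[c["productive"]], dialect, c["productive"], line),
                full_length=_parse_bool(row_map[c["full_length"]], dialect, c["full_length"], line),
                is_cell=_parse_bool(row_map[c["is_cell"]], dialect, c["is_cell"], line),
                high_confidence=_parse_bool(
                    row_map[c["high_confidence"]], dialect, c["high_confidence"], line
                ),
            )
        )
    return records


def read_metadata(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read the cell metadata whitelist (barcode, patient, timepoint, response, subset)."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [col for col in METADATA_COLUMNS if col not in df.columns]
    if missing:
        raise VdjFormatError(
            f"{path}: metadata missing required column(s): {', '.join(missing)}"
        )
    if df["barcode"].duplicated().any():
        dup = df.loc[df["barcode"].duplicated(), "barcode"].iloc[0]
        raise VdjFormatError(f"metadata barcodes not unique (e.g. {dup!r})")
    return df


def _dominant(contigs: list[ContigRecord]) -> ContigRecord:
    # Highest UMI support; ties -> highest reads; ties -> smallest cdr3_nt.
    return min(contigs, key=lambda r: (-r.umis, -r.reads, r.cdr3_nt))


def call_clonotypes(
    contigs: Iterable[ContigRecord],
    metadata: pd.DataFrame,
    key_mode: str = "nt",
) -> list[CellClonotype]:
    """Two-step TCR QC and paired alpha/beta clonotype assignment.

    Step 1 drops contigs failing any of is_cell / high_confidence /
    productive / full_length, and contigs of cells absent from the metadata
    whitelist (cells that failed scRNA-seq quality control).  Step 2 picks
    per cell the dominant TRA and dominant TRB contig; cells without a
    surviving chain of both loci are dropped.

    Parameters
    ----------
    key_mode
        ``"nt"`` keys clonotypes by nucleotide CDR3 (stricter; default),
        ``"aa"`` by amino-acid CDR3.
    """
    if key_mode not in ("nt", "aa"):
        raise ValueError(f"key_mode must be 'nt' or 'aa', got {key_mode!r}")
    missing = [col for col in METADATA_COLUMNS if col not in metadata.columns]
    if missing:
        raise VdjFormatError(f"metadata missing required column(s): {', '.join(missing)}")
    if metadata["barcode"].duplicated().any():
        raise VdjFormatError("metadata barcodes not unique")

    meta_by_barcode = metadata.set_index("barcode")
    whitelist = set(meta_by_barcode.index)

    per_cell: dict[str, dict[str, list[ContigRecord]]] = collections.defaultdict(
        lambda: {"TRA": [], "TRB": []}
    )
    for rec in contigs:
        if not (rec.is_cell and rec.high_confidence and rec.productive and rec.full_length):
            continue
        if rec.barcode not in whitelist:
            continue
        if rec.chain in ("TRA", "TRB"):
            per_cell[rec.barcode][rec.chain].append(rec)

    cells: list[CellClonotype] = []
    for barcode in sorted(per_cell):
        chains = per_cell[barcode]
        if not chains["TRA"] or not chains["TRB"]:
            continue
        tra = _dominant(chains["TRA"])
        trb = _dominant(chains["TRB"])
        key = ClonotypeKey(
            tra_v=tra.v_gene,
            tra_j=tra.j_gene,
            tra_cdr3=tra.cdr3_nt if key_mode == "nt" else tra.cdr3_aa,
            trb_v=trb.v_gene,
            trb_j=trb.j_gene,
            trb_cdr3=trb.cdr3_nt if key_mode == "nt" else trb.cdr3_aa,
        )
        meta = meta_by_barcode.loc[barcode]
        cells.append(
            CellClonotype(
                barcode=barcode,
                clonotype=key,
                patient=str(meta["patient"]),
                timepoint=str(meta["timepoint"]),
                response=str(meta["response"]),
                subset=str(meta["subset"]),
            )
        )
    return cells


def build_clone_table(
    cells: Sequence[CellClonotype], specimen: tuple[str, str]
) -> CloneTable:
    """Count cells per clonotype for one (patient, timepoint) specimen."""
    patient, timepoint = specimen
    counts: dict[ClonotypeKey, int] = collections.Counter()
    for cell in cells:
        if (cell.patient, cell.timepoint) != (patient, timepoint):
            raise ValueError(
                f"cell {cell.barcode!r} belongs to specimen "
                f"{(cell.patient, cell.timepoint)}, not {specimen}"
            )
        counts[cell.clonotype] += 1
    return CloneTable(specimen=specimen, counts=dict(counts))


def clone_tables_by_specimen(cells: Sequence[CellClonotype]) -> dict[tuple[str, str], CloneTable]:
    """Group cells by (patient, timepoint) and build one clone table per specimen."""
    groups: dict[tuple[str, str], list[CellClonotype]] = collections.defaultdict(list)
    for cell in cells:
        groups[(cell.patient, cell.timepoint)].append(cell)
    return {
        spec: build_clone_table(group, spec) for spec, group in sorted(groups.items())
    }


_CELL_COLUMNS = [
    "barcode", "patient", "timepoint", "response", "subset",
    "tra_v", "tra_j", "tra_cdr3", "trb_v", "trb_j", "trb_cdr3",
]


def cells_to_frame(cells: Sequence[CellClonotype]) -> pd.DataFrame:
    """Per-cell clonotype assignments as a DataFrame (stable column order)."""
    rows = [
        {
            "barcode": c.barcode,
            "patient": c.patient,
            "timepoint": c.timepoint,
            "response": c.response,
            "subset": c.subset,
            "tra_v": c.clonotype.tra_v,
            "tra_j": c.clonotype.tra_j,
            "tra_cdr3": c.clonotype.tra_cdr3,
            "trb_v": c.clonotype.trb_v,
            "trb_j": c.clonotype.trb_j,
            "trb_cdr3": c.clonotype.trb_cdr3,
        }
        for c in cells
    ]
    return pd.DataFrame(rows, columns=_CELL_COLUMNS)


def write_cell_table(cells: Sequence[CellClonotype], path: str | Path) -> None:
    cells_to_frame(cells).to_csv(path, sep="\t", index=False)


def write_clone_table(table: CloneTable, path: str | Path) -> None:
    rows = [
        {
            "patient": table.specimen[0],
            "timepoint": table.specimen[1],
            "clonotype": key.as_string(),
            "copies": copies,
        }
        for key, copies in sorted(table.counts.items(), key=lambda kv: kv[0].as_string())
    ]
    pd.DataFrame(rows, columns=["patient", "timepoint", "clonotype", "copies"]).to_csv(
        path, sep="\t", index=False
    )
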