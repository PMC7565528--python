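"""Readers and writers for every external representation the pipeline touches.

All expression matrices are molecules × samples of log2 intensities, exchanged
as plain TSV (first column molecule ids, header row sample ids, empty cells
for missing values).  miRNA-target databases come in four simplified,
project-defined tab-separated dialects named after the services whose column
layouts they emulate (``targetscan``, ``microcosm``, ``mirtarbase``,
``mirwalk``); real database dumps are versioned and never read directly.
Gene sets use GMT semantics, external cohorts the GEO series-matrix flat-file
format, and ring networks a lossless JSON document.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LAYERS = ("mrna", "mirna", "protein")

#: Column layout of each simplified target-database dialect:
#: (miRNA column index, gene column index, has header row, comment prefix).
TARGET_DB_DIALECTS: dict[str, tuple[int, int, bool, str | None]] = {
    "targetscan": (0, 1, True, None),
    "microcosm": (1, 0, False, "#"),
    "mirtarbase": (1, 3, True, None),
    "mirwalk": (0, 2, True, None),
}


class FormatError(ValueError):
    """A file violates its declared on-disk format."""


class UsageError(ValueError):
    """An operation was called with arguments outside its contract."""


@dataclass
class ExpressionTable:
    """One molecular layer: molecules × samples of log2 intensities.

    ``data`` is a float DataFrame indexed by molecule id with sample-id
    columns; missing measurements are NaN (proteomics has structural
    missingness and is never imputed at I/O time).
    """

    data: pd.DataFrame
    layer: str

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise UsageError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate molecule ids: {dupes}")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dupes}")
        self.data = self.data.astype(float)

    @property
    def molecule_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def equals(self, other: "ExpressionTable", rtol: float = 1e-12) -> bool:
        if self.layer != other.layer:
            return False
        if self.molecule_ids != other.molecule_ids or self.sample_ids != other.sample_ids:
            return False
        a, b = self.values, other.values
        both_nan = np.isnan(a) & np.isnan(b)
        close = np.isclose(a, b, rtol=rtol, atol=0.0, equal_nan=True)
        return bool(np.all(close | both_nan))


@dataclass
class TargetDBFile:
    """One miRNA-target database: raw (miRNA, gene) pairs plus its name."""

    db_name: str
    records: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.db_name not in TARGET_DB_DIALECTS:
            raise UsageError(
                f"unknown database {self.db_name!r}; expected one of "
                f"{sorted(TARGET_DB_DIALECTS)}"
            )


class AliasTable:
    """Alias → official-gene-symbol map; official symbols are fixed points."""

    def __init__(self, mapping: Mapping[str, str] | None = None):
        self._map: dict[str, str] = {}
        if mapping:
            for alias, official in mapping.items():
                self.add(alias, official)

    def add(self, alias: str, official: str) -> None:
        self._map[alias] = official
        self._map.setdefault(official, official)  # keep officials fixed points

    def get(self, name: str) -> str | None:
        return self._map.get(name)

    def __contains__(self, name: str) -> bool:
        return name in self._map

    def __len__(self) -> int:
        return len(self._map)

    def items(self):
        return self._map.items()


@dataclass
class GeneSetCollection:
    """Named gene sets with GMT semantics (name, description, members)."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# expression TSV


def read_expression_tsv(path: str | Path, layer: str) -> ExpressionTable:
    """Read a molecules × samples TSV; empty cells become NaN, never zero."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        sample_ids = header[1:]
        ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            ids.append(row[0])
            vals: list[float] = []
            for col, cell in enumerate(row[1:], start=2):
                if cell == "":
                    vals.append(math.nan)
                    continue
                try:
                    vals.append(float(cell))
                except ValueError:
                    raise FormatError(
                        f"{path}: non-numeric value {cell!r} at row {lineno}, "
                        f"column {col}"
                    ) from None
            if len(vals) != len(sample_ids):
                raise FormatError(
                    f"{path}: row {lineno} has {len(vals)} values for "
                    f"{len(sample_ids)} samples"
                )
            rows.append(vals)
    frame = pd.DataFrame(rows, index=ids, columns=sample_ids, dtype=float)
    return ExpressionTable(frame, layer)


def write_expression_tsv(table: ExpressionTable, path: str | Path) -> None:
    """Write a table back to TSV; NaN becomes an empty cell (12 sig. digits)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["id", *table.sample_ids])
        for mol, row in zip(table.molecule_ids, table.values):
            writer.writerow(
                [mol, *("" if math.isnan(v) else format(v, ".12g") for v in row)]
            )


# ---------------------------------------------------------------------------
# GEO series matrix


def read_series_matrix(path: str | Path) -> tuple[ExpressionTable, pd.DataFrame]:
    """Parse a GEO series-matrix flat file.

    Returns the expression block (taken as already log-scaled) and a
    sample-metadata frame (one row per ``!Sample_*`` line, samples as
    columns) for downstream group assignment.
    """
    path = Path(path)
    meta_rows: dict[str, list[str]] = {}
    table_lines: list[list[str]] = []
    in_table = False
    saw_begin = saw_end = False
    with path.open() as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table, saw_begin = True, True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table, saw_end = False, True
                continue
            if in_table:
                table_lines.append([_dequote(c) for c in line.split("\t")])
            elif line.startswith("!Sample_"):
                key, *vals = line.split("\t")
                key = key[len("!Sample_") :]
                vals = [_dequote(v) for v in vals]
                # repeated keys (characteristics_ch1) get numbered suffixes
                base, n = key, 1
                while key in meta_rows:
                    n += 1
                    key = f"{base}.{n}"
                meta_rows[key] = vals
    if not (saw_begin and saw_end):
        raise FormatError(
            f"{path}: missing !series_matrix_table_begin/_end delimiters"
        )
    if not table_lines:
        raise FormatError(f"{path}: empty expression block")
    header = table_lines[0][1:]
    ids = [r[0] for r in table_lines[1:]]
    values = [
        [math.nan if c in ("", "null", "NA") else float(c) for c in r[1:]]
        for r in table_lines[1:]
    ]
    frame = pd.DataFrame(values, index=ids, columns=header, dtype=float)
    table = ExpressionTable(frame, "mrna")
    meta = pd.DataFrame.from_dict(meta_rows, orient="index", columns=header)
    return table, meta


def _dequote(cell: str) -> str:
    if len(cell) >= 2 and cell[0] == '"' and cell[-1] == '"':
        return cell[1:-1]
    return cell


# ---------------------------------------------------------------------------
# miRNA-target databases


def read_target_db(path: str | Path, dialect: str) -> TargetDBFile:
    """Extract raw (miRNA, gene) pairs from one database dialect.

    Pairs are taken verbatim; name standardization happens downstream in
    :mod:`tmeomix.mirdiana`.
    """
    if dialect not in TARGET_DB_DIALECTS:
        raise UsageError(
            f"unknown dialect {dialect!r}; expected one of {sorted(TARGET_DB_DIALECTS)}"
        )
    mirna_col, gene_col, has_header, comment = TARGET_DB_DIALECTS[dialect]
    path = Path(path)
    records: list[tuple[str, str]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or (comment and line.startswith(comment)):
                continue
            if has_header and lineno == 1:
                continue
            cells = line.split("\t")
            needed = max(mirna_col, gene_col)
            if len(cells) <= needed:
                raise FormatError(
                    f"{path}: line {lineno} has {len(cells)} columns, "
                    f"dialect {dialect!r} needs at least {needed + 1}"
                )
            records.append((cells[mirna_col], cells[gene_col]))
    if not records:
        logger.warning("target database %s (%s) is empty", path, dialect)
    return TargetDBFile(dialect, records)


def write_target_db(db: TargetDBFile, path: str | Path) -> None:
    """Write pairs in the dialect named by ``db.db_name``."""
    mirna_col, gene_col, has_header, comment = TARGET_DB_DIALECTS[db.db_name]
    width = max(mirna_col, gene_col) + 1
    path = Path(path)
    with path.open("w") as fh:
        if comment:
            fh.write(f"{comment} simplified {db.db_name} dialect\n")
        if has_header:
            header = ["filler"] * width
            header[mirna_col] = "mirna"
            header[gene_col] = "gene"
            fh.write("\t".join(header) + "\n")
        for mirna, gene in db.records:
            cells = ["."] * width
            cells[mirna_col] = mirna
            cells[gene_col] = gene
            fh.write("\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# alias table, GMT, network JSON


def read_alias_table(path: str | Path) -> AliasTable:
    """Read a two-column (alias, official symbol) TSV; header optional."""
    path = Path(path)
    table = AliasTable()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if len(cells) < 2:
                raise FormatError(f"{path}: line {lineno} needs 2 columns")
            if lineno == 1 and cells[0].lower() in ("alias", "synonym"):
                continue
            table.add(cells[0], cells[1])
    return table


def write_alias_table(table: AliasTable, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("alias\tofficial\n")
        for alias, official in sorted(table.items()):
            fh.write(f"{alias}\t{official}\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    path = Path(path)
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) < 3:
                raise FormatError(
                    f"{path}: line {lineno} has {len(cells)} fields; GMT needs "
                    "name, description and at least one member"
                )
            name, desc, *members = cells
            if name in sets:
                raise FormatError(f"{path}: duplicate set name {name!r} at line {lineno}")
            sets[name] = {m for m in members if m}
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name in collection.sets:
            desc = collection.descriptions.get(name, "")
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


def write_network_json(net, path: str | Path) -> None:
    """Serialize a ring network losslessly to JSON (read back with
    :func:`read_network_json`)."""
    with Path(path).open("w") as fh:
        json.dump(net.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_network_json(path: str | Path):
    from .network import RingNetwork  # local import avoids a cycle

    with Path(path).open() as fh:
        return RingNetwork.from_dict(json.load(fh))
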