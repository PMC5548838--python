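"""Parsing and indexing of microbe-disease association tables.

The input is a delimited text table (TSV by default, CSV accepted) with one
association per row, e.g. the genus-level literature-curated export of the
HMDAD database. Records are deduplicated into a 0/1 bipartite adjacency
matrix ``Y`` (rows = microbes, columns = diseases) that the kernel and
classifier modules consume.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Literal, Sequence, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationRecord",
    "AssociationTable",
    "AdjacencyNetwork",
    "FormatError",
    "EmptyInputError",
    "parse_association_table",
    "build_adjacency",
    "summarize",
    "write_edge_list",
    "write_dense_matrix",
]

_WS = re.compile(r"\s+")


class FormatError(ValueError):
    """The input table cannot be mapped to (microbe, disease) columns."""


class EmptyInputError(ValueError):
    """The input contains no usable association rows."""


def _norm_name(name: object) -> str:
    """Strip surrounding whitespace and collapse internal runs; case preserved."""
    return _WS.sub(" ", str(name).strip())


@dataclass(frozen=True)
class AssociationRecord:
    """One (microbe, disease) association, names whitespace-normalized."""

    microbe_name: str
    disease_name: str

    def __post_init__(self) -> None:
        if not self.microbe_name or not self.disease_name:
            raise ValueError("association record requires non-empty names")


@dataclass
class AssociationTable:
    """Ordered association records plus provenance counts.

    ``n_raw`` counts input rows (after skipping blank-name rows);
    ``n_distinct`` counts distinct (microbe, disease) pairs. The model
    consumes distinct pairs only; both counts are kept so duplicate rows in
    a curated export remain visible.
    """

    records: list[AssociationRecord]
    n_raw: int
    n_skipped: int = 0

    @property
    def n_distinct(self) -> int:
        return len(self.distinct_pairs())

    def distinct_pairs(self) -> set[tuple[str, str]]:
        return {(r.microbe_name, r.disease_name) for r in self.records}


@dataclass
class AdjacencyNetwork:
    """0/1 adjacency ``Y`` (nm x nd) with ordered name indexes.

    ``Y[i, j] = 1`` iff microbe ``microbe_index[i]`` is associated with
    disease ``disease_index[j]``. Every row and column has at least one 1:
    entities appear in the index only because they occur in a record.
    """

    Y: np.ndarray
    microbe_index: list[str]
    disease_index: list[str]
    ordering: str = "first-appearance"

    @property
    def nm(self) -> int:
        return self.Y.shape[0]

    @property
    def nd(self) -> int:
        return self.Y.shape[1]

    @property
    def n_associations(self) -> int:
        return int(self.Y.sum())

    def microbe_pos(self, name: str) -> int:
        return self.microbe_index.index(name)

    def disease_pos(self, name: str) -> int:
        return self.disease_index.index(name)

    def pairs(self) -> set[tuple[str, str]]:
        """Re-extract the (microbe, disease) pair set from Y."""
        ii, jj = np.nonzero(self.Y)
        return {
            (self.microbe_index[i], self.disease_index[j])
            for i, j in zip(ii.tolist(), jj.tolist())
        }


def parse_association_table(
    source: Union[str, Path, IO[str]],
    *,
    sep: str | None = None,
    microbe_col: str | int = 0,
    disease_col: str | int = 1,
    header: bool | None = None,
) -> AssociationTable:
    """Read a delimited association table into an :class:`AssociationTable`.

    Parameters
    ----------
    source
        Path or open text stream. UTF-8.
    sep
        Field delimiter; ``None`` auto-detects tab vs comma from the first line.
    microbe_col, disease_col
        Column names (requires a header) or 0-based positions.
    header
        Whether the first row is a header. ``None`` infers: a header is
        assumed when the columns are selected by name, otherwise the first
        row is inspected and treated as a header if it repeats nowhere as a
        data row and both selectors are positional defaults.

    Rows with a blank microbe or disease name are skipped with a logged
    row number; the skip count is recorded on the returned table.
    """
    by_name = isinstance(microbe_col, str) or isinstance(disease_col, str)
    if header is None:
        header = by_name

    if isinstance(source, (str, Path)):
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(path)
        text = path.read_text(encoding="utf-8")
    else:
        text = source.read()

    if not text.strip():
        raise EmptyInputError("association table is empty")

    if sep is None:
        first = text.splitlines()[0]
        sep = "\t" if "\t" in first else ","

    try:
        df = pd.read_csv(
            io.StringIO(text),
            sep=sep,
            header=0 if header else None,
            dtype=str,
            skip_blank_lines=True,
        )
    except pd.errors.ParserError as exc:  # pragma: no cover - malformed input
        raise FormatError(f"cannot parse delimited table: {exc}") from exc

    def _col(sel: str | int, role: str) -> pd.Series:
        if isinstance(sel, str):
            if sel not in df.columns:
                raise FormatError(
                    f"{role} column {sel!r} not found; available: {list(df.columns)}"
                )
            return df[sel]
        if sel >= df.shape[1]:
            raise FormatError(
                f"{role} column index {sel} out of range for {df.shape[1]} columns"
            )
        return df.iloc[:, sel]

    microbes = _col(microbe_col, "microbe")
    diseases = _col(disease_col, "disease")

    records: list[AssociationRecord] = []
    n_skipped = 0
    for row_no, (m, d) in enumerate(zip(microbes, diseases), start=1):
        mn = _norm_name(m) if not pd.isna(m) else ""
        dn = _norm_name(d) if not pd.isna(d) else ""
        if not mn or not dn:
            n_skipped += 1
            logger.warning("row %d skipped: blank microbe or disease name", row_no)
            continue
        records.append(AssociationRecord(mn, dn))

    if not records:
        raise EmptyInputError("no usable association rows after skipping blanks")
    if n_skipped:
        logger.info("skipped %d rows with blank names", n_skipped)

    return AssociationTable(records=records, n_raw=len(records), n_skipped=n_skipped)


def build_adjacency(
    table: AssociationTable,
    ordering: Literal["first-appearance", "lexicographic"] = "first-appearance",
) -> AdjacencyNetwork:
    """Build the indexed 0/1 adjacency matrix from an association table.

    Duplicate records contribute a single edge. Index order is by first
    appearance in the record stream (default) or lexicographic; the choice
    is recorded on the network so rankings are reproducible.
    """
    if not table.records:
        raise EmptyInputError("association table has no records")

    if ordering == "first-appearance":
        microbe_index = list(dict.fromkeys(r.microbe_name for r in table.records))
        disease_index = list(dict.fromkeys(r.disease_name for r in table.records))
    elif ordering == "lexicographic":
        microbe_index = sorted({r.microbe_name for r in table.records})
        disease_index = sorted({r.disease_name for r in table.records})
    else:
        raise ValueError(f"unknown ordering {ordering!r}")

    m_pos = {name: i for i, name in enumerate(microbe_index)}
    d_pos = {name: j for j, name in enumerate(disease_index)}
    Y = np.zeros((len(microbe_index), len(disease_index)), dtype=np.int8)
    for m, d in table.distinct_pairs():
        Y[m_pos[m], d_pos[d]] = 1

    return AdjacencyNetwork(Y, microbe_index, disease_index, ordering=ordering)


def network_from_pairs(
    pairs: Iterable[tuple[str, str]],
    ordering: Literal["first-appearance", "lexicographic"] = "first-appearance",
) -> AdjacencyNetwork:
    """Convenience: build a network straight from (microbe, disease) pairs."""
    records = [AssociationRecord(_norm_name(m), _norm_name(d)) for m, d in pairs]
    table = AssociationTable(records=records, n_raw=len(records))
    return build_adjacency(table, ordering=ordering)


def summarize(network: AdjacencyNetwork) -> dict:
    """Basic descriptive statistics of the bipartite network."""
    deg_m = network.Y.sum(axis=1)
    deg_d = network.Y.sum(axis=0)
    n_assoc = network.n_associations
    return {
        "nm": network.nm,
        "nd": network.nd,
        "n_associations": n_assoc,
        "density": n_assoc / (network.nm * network.nd),
        "microbe_degrees": {
            name: int(k) for name, k in zip(network.microbe_index, deg_m)
        },
        "disease_degrees": {
            name: int(k) for name, k in zip(network.disease_index, deg_d)
        },
    }


def write_edge_list(network: AdjacencyNetwork, path: Union[str, Path]) -> None:
    """Persist the network as a ``microbe<TAB>disease`` edge list."""
    path = Path(path)
    ii, jj = np.nonzero(network.Y)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("microbe\tdisease\n")
        for i, j in zip(ii.tolist(), jj.tolist()):
            fh.write(f"{network.microbe_index[i]}\t{network.disease_index[j]}\n")


def write_dense_matrix(
    values: np.ndarray,
    row_names: Sequence[str],
    col_names: Sequence[str],
    path: Union[str, Path],
) -> None:
    """Persist a labelled dense matrix as TSV with row/column headers."""
    df = pd.DataFrame(np.asarray(values), index=list(row_names), columns=list(col_names))
    df.to_csv(path, sep="\t")
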