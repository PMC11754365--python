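"""Contingency-table data model, long-format I/O, and multinomial MLEs.

Cells are stored dense. The single flat-indexing convention used throughout
the package is **row-major (C order) over the factors in declared order**:
cell ``(i, j, v)`` of a table with dims ``(I, J, V)`` sits at flat position
``(i * J + j) * V + v``. All reparameterizations, hypothesis systems and
reports refer to this order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ContingencyTable",
    "ProbabilityVector",
    "from_long_csv",
    "write_long_csv",
    "mle_probabilities",
    "write_probability_csv",
]


@dataclass
class ContingencyTable:
    """A dense table of non-negative integer counts over >= 1 factors.

    Parameters
    ----------
    counts
        Array of shape ``dims`` with non-negative integer entries.
    labels
        Optional per-factor level names, one list per factor.
    """

    counts: np.ndarray
    labels: list[list[str]] | None = None
    factor_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim < 1:
            raise ValueError("counts must have at least one dimension")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = np.asarray(self.counts)
            if not np.allclose(as_int, np.round(as_int)):
                raise ValueError("counts must be integer-valued")
            self.counts = np.round(as_int).astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        for d in self.counts.shape:
            if d < 2:
                raise ValueError(
                    f"every factor needs >= 2 levels, got dims {self.counts.shape}"
                )
        if self.labels is not None:
            for ax, lv in enumerate(self.labels):
                if len(lv) != self.counts.shape[ax]:
                    raise ValueError(f"labels for factor {ax} do not match dims")

    @property
    def dims(self) -> tuple[int, ...]:
        return self.counts.shape

    @property
    def n(self) -> int:
        """Total count."""
        return int(self.counts.sum())

    @property
    def n_cells(self) -> int:
        """Number of cells D."""
        return int(self.counts.size)

    def flat(self) -> np.ndarray:
        """Counts flattened in the package's row-major cell order."""
        return self.counts.reshape(-1)

    def copy(self) -> "ContingencyTable":
        return ContingencyTable(
            self.counts.copy(),
            None if self.labels is None else [list(x) for x in self.labels],
            None if self.factor_names is None else list(self.factor_names),
        )


@dataclass
class ProbabilityVector:
    """Per-cell probabilities in the package's flat cell order."""

    values: np.ndarray
    dims: tuple[int, ...]
    # optional metadata, e.g. cells forced to zero by a simulation design
    star_cells: tuple[tuple[int, ...], ...] = field(default=())

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).reshape(-1)
        self.dims = tuple(int(d) for d in self.dims)
        if self.values.size != int(np.prod(self.dims)):
            raise ValueError("length of values does not match product of dims")
        if (self.values < 0).any() or (self.values > 1).any():
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(self.values.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1 (within 1e-12)")

    def cell_index(self, multi_index: tuple[int, ...]) -> int:
        """Flat position of a multi-index under the row-major convention."""
        return int(np.ravel_multi_index(multi_index, self.dims))

    def __getitem__(self, multi_index: tuple[int, ...]) -> float:
        return float(self.values[self.cell_index(multi_index)])


def mle_probabilities(table: ContingencyTable) -> ProbabilityVector:
    """Maximum-likelihood cell probabilities ``counts / n`` of a multinomial."""
    n = table.n
    if n == 0:
        raise ValueError("cannot estimate probabilities from an empty table (n = 0)")
    return ProbabilityVector(table.flat() / n, table.dims)


def _read_long(path, factor_columns, count_column) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype={c: str for c in factor_columns})
    missing = [c for c in (*factor_columns, count_column) if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s) in {path}: {missing}")
    return df


def from_long_csv(path, factor_columns, count_column="count") -> ContingencyTable:
    """Read a long-format CSV/TSV (one column per factor plus a count column).

    Factor levels are taken in **file order of first appearance** (stable);
    combinations absent from the file are stored with count 0.  Duplicate
    combinations and negative or non-integer counts are rejected.
    """
    factor_columns = list(factor_columns)
    df = _read_long(path, factor_columns, count_column)

    levels: list[list[str]] = []
    for col in factor_columns:
        seen = list(dict.fromkeys(df[col].tolist()))
        levels.append(seen)
    dims = tuple(len(lv) for lv in levels)
    for ax, d in enumerate(dims):
        if d < 2:
            raise ValueError(
                f"factor '{factor_columns[ax]}' has {d} level(s); every factor "
                "needs >= 2"
            )

    counts = np.zeros(dims, dtype=np.int64)
    filled = np.zeros(dims, dtype=bool)
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        rec = row._asdict()
        idx = tuple(levels[a].index(rec[c]) for a, c in enumerate(factor_columns))
        if filled[idx]:
            raise ValueError(
                f"duplicate factor combination {idx} at file row {row_no} of {path}"
            )
        c = rec[count_column]
        cf = float(c)
        if cf < 0 or cf != int(cf):
            raise ValueError(
                f"count {c!r} at file row {row_no} is not a non-negative integer"
            )
        counts[idx] = int(cf)
        filled[idx] = True
    return ContingencyTable(counts, labels=levels, factor_names=factor_columns)


def write_long_csv(table: ContingencyTable, path, count_column="count") -> None:
    """Write a table in long format; the exact inverse of :func:`from_long_csv`."""
    dims = table.dims
    names = table.factor_names or [f"factor{a + 1}" for a in range(len(dims))]
    labels = table.labels or [[str(i + 1) for i in range(d)] for d in dims]
    rows = []
    for idx in np.ndindex(*dims):
        rows.append(
            {**{names[a]: labels[a][i] for a, i in enumerate(idx)},
             count_column: int(table.counts[idx])}
        )
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def write_probability_csv(pi: ProbabilityVector, path) -> None:
    """Write a flattened probability vector with multi-index columns."""
    rows = []
    for idx in np.ndindex(*pi.dims):
        rows.append(
            {**{f"factor{a + 1}": i + 1 for a, i in enumerate(idx)},
             "probability": pi[idx]}
        )
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
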