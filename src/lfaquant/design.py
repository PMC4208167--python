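"""Two-level orthogonal screening designs (L4, L8, L12).

The shipped catalogue covers the regular fractions L4(2^3) and L8(2^7)
(Sylvester-Hadamard construction) and the non-regular Plackett-Burman
L12(2^11) used for ten-factor camera-parameter screening.  Cells hold level
indices 1/2; every column is balanced and every column pair shows each of
the four level combinations equally often.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import hadamard

from .exceptions import DesignError, InputError

# Plackett-Burman N=12 generator row; remaining rows are its cyclic shifts
# plus a closing all-low row.
_PB12_FIRST_ROW = np.array([1, 1, -1, 1, 1, 1, -1, -1, -1, 1, -1], dtype=int)


@dataclass(frozen=True)
class OrthogonalArray:
    """A two-level orthogonal array with cells in {1, 2}."""

    name: str
    cells: np.ndarray  # shape (n_runs, n_columns)

    @property
    def n_runs(self) -> int:
        return self.cells.shape[0]

    @property
    def n_columns(self) -> int:
        return self.cells.shape[1]

    def column(self, index: int) -> np.ndarray:
        return self.cells[:, index]

    def validate(self) -> None:
        """Check balance and pairwise orthogonality; raise DesignError if broken."""
        cells = self.cells
        n, k = cells.shape
        if not np.isin(cells, (1, 2)).all():
            raise DesignError("array cells must be level indices 1 or 2")
        for j in range(k):
            if (cells[:, j] == 1).sum() != n // 2:
                raise DesignError(f"column {j} is not balanced")
        for a in range(k):
            for b in range(a + 1, k):
                for la in (1, 2):
                    for lb in (1, 2):
                        count = ((cells[:, a] == la) & (cells[:, b] == lb)).sum()
                        if count != n // 4:
                            raise DesignError(
                                f"columns {a},{b} combination ({la},{lb}) "
                                f"occurs {count} times, expected {n // 4}"
                            )

    def to_dataframe(self, labels: list[str] | None = None) -> pd.DataFrame:
        labels = labels or default_labels(self.n_columns)
        df = pd.DataFrame(self.cells, columns=labels)
        df.insert(0, "run_index", np.arange(1, self.n_runs + 1))
        return df


def default_labels(n_columns: int) -> list[str]:
    """Column letters A, B, C, ... as used on response tables."""
    return list(string.ascii_uppercase[:n_columns])


def _sylvester_cells(n_runs: int) -> np.ndarray:
    signs = hadamard(n_runs)[:, 1:]  # drop the all-ones column
    return np.where(signs == 1, 1, 2)


def _pb12_cells() -> np.ndarray:
    rows = [np.roll(_PB12_FIRST_ROW, i) for i in range(11)]
    rows.append(-np.ones(11, dtype=int))
    signs = np.array(rows)
    return np.where(signs == 1, 1, 2)


_CATALOGUE: dict[str, np.ndarray] = {}


def _catalogue() -> dict[str, np.ndarray]:
    if not _CATALOGUE:
        _CATALOGUE["L4"] = _sylvester_cells(4)
        _CATALOGUE["L8"] = _sylvester_cells(8)
        _CATALOGUE["L12"] = _pb12_cells()
    return _CATALOGUE


def get_array(name: str) -> OrthogonalArray:
    try:
        cells = _catalogue()[name]
    except KeyError:
        raise DesignError(
            f"unknown design {name!r}; catalogued designs are L4, L8, L12"
        ) from None
    return OrthogonalArray(name=name, cells=cells.copy())


def generate_orthogonal_array(n_factors: int) -> OrthogonalArray:
    """Smallest catalogued two-level array with at least ``n_factors`` columns.

    Ten camera parameters therefore land on the 12-run L12(2^11); its
    spare eleventh column stays unassigned and serves as the error column.
    """
    if n_factors < 1:
        raise InputError("n_factors must be at least 1")
    if n_factors > 11:
        raise DesignError(
            "designs with more than 11 two-level factors are not catalogued; "
            "the largest shipped array is L12 (11 columns)"
        )
    for name in ("L4", "L8", "L12"):
        array = get_array(name)
        if array.n_columns >= n_factors:
            return array
    raise AssertionError("unreachable")


@dataclass(frozen=True)
class FactorAssignment:
    """A control factor mapped onto one array column.

    ``level_values`` are the two concrete device settings and are treated as
    opaque labels (booleans, numbers, or tokens such as "Auto").
    """

    factor_id: str
    name: str
    column: int
    level_values: tuple = field(default=(1, 2))

    def value(self, level: int):
        return self.level_values[level - 1]


def assign_factors(
    factors: list[dict] | list[tuple], array: OrthogonalArray
) -> list[FactorAssignment]:
    """Assign factors to the leading array columns, in the order given.

    Each entry is a mapping with keys id/name/level1/level2 (or a tuple in
    that order).  Remaining columns are retained unassigned as error columns.
    """
    out: list[FactorAssignment] = []
    if len(factors) > array.n_columns:
        raise InputError(
            f"{len(factors)} factors do not fit on {array.name} "
            f"({array.n_columns} columns)"
        )
    for col, spec in enumerate(factors):
        if isinstance(spec, dict):
            extra = set(spec) - {"id", "name", "level1", "level2"}
            if extra:
                raise InputError(f"unknown factor keys: {sorted(extra)}")
            fid, name = str(spec["id"]), str(spec.get("name", spec["id"]))
            levels = (spec["level1"], spec["level2"])
        else:
            fid, name, lv1, lv2 = spec
            levels = (lv1, lv2)
        out.append(FactorAssignment(fid, name, col, levels))
    ids = [f.factor_id for f in out]
    if len(set(ids)) != len(ids):
        raise InputError("factor ids must be unique")
    return out


def error_columns(array: OrthogonalArray, assignment: list[FactorAssignment]) -> list[int]:
    """Columns left unassigned (the classical error columns, e.g. column K)."""
    used = {f.column for f in assignment}
    return [j for j in range(array.n_columns) if j not in used]


def column_labels(array: OrthogonalArray, assignment: list[FactorAssignment] | None) -> list[str]:
    """Per-column labels: factor ids where assigned, fresh letters elsewhere."""
    if assignment is None:
        return default_labels(array.n_columns)
    labels = [""] * array.n_columns
    for f in assignment:
        labels[f.column] = f.factor_id
    pool = [c for c in string.ascii_uppercase if c not in set(labels)]
    it = iter(pool)
    for j, lab in enumerate(labels):
        if not lab:
            labels[j] = next(it)
    return labels
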