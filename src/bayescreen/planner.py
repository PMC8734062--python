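"""Iteration counts for sequential testing: how many consecutive positive
results are needed before the posterior reaches a target PPV.

Inverting the n-test posterior for n gives the continuous requirement

    n = ln[ rho*(1-phi) / (phi*(1-rho)) ] / ln[ a/(1-b) ]
      = (logit(rho) - logit(phi)) / ln(LR+)

i.e. the target-to-prior log-odds gap divided by the log-odds gained per
positive test.  Tests are discrete, so the clinically usable count is the
ceiling of that value.  The sign of ln(LR+) = ln[a/(1-b)] partitions tests
into three regimes: a+b > 1 (informative, the count is finite), a+b = 1
(uninformative, no number of repeats moves the prior) and a+b < 1 (each
positive is evidence against disease, the target can never be reached
from below).
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .core import TestCharacteristics, _check_probability, _logit, sequential_ppv

__all__ = [
    "Feasibility",
    "IterationRequirement",
    "ReferenceTable",
    "TableclothGrid",
    "UnreachableTargetError",
    "required_iterations_continuous",
    "required_iterations",
    "build_reference_table",
    "tablecloth_grid",
    "DEFAULT_ROW_KEYS",
    "DEFAULT_COLUMN_KEYS",
    "DEFAULT_TARGETS",
]

#: tolerance for detecting the uninformative boundary a + b = 1
UNINFORMATIVE_TOL = 1e-12

#: ln(LR+) rows and prevalence columns of the standard reference tables
DEFAULT_ROW_KEYS: tuple[float, ...] = tuple(0.5 * k for k in range(1, 11))
DEFAULT_COLUMN_KEYS: tuple[float, ...] = (0.02, 0.05, 0.07, 0.1, 0.15, 0.2)
DEFAULT_TARGETS: tuple[float, ...] = (0.99, 0.95, 0.75, 0.50)

#: token used for infeasible cells in CSV exports (null in JSON)
INFEASIBLE_TOKEN = "INF"


class UnreachableTargetError(ValueError):
    """A target PPV of exactly 1 cannot be reached by finitely many tests."""


class Feasibility(str, Enum):
    FEASIBLE = "feasible"
    ALREADY_SATISFIED = "already_satisfied"
    INFEASIBLE_UNINFORMATIVE = "infeasible_uninformative"  # a + b = 1
    INFEASIBLE_NEGATIVE = "infeasible_negative"  # a + b < 1
    UNREACHABLE = "unreachable"  # prior of 0 cannot be moved


@dataclass(frozen=True)
class IterationRequirement:
    """Continuous and integer iteration counts with a feasibility label.

    ``continuous_n`` is the real-valued solution of the posterior
    equation (negative when the prior already exceeds the target, NaN
    when the test is uninformative).  ``n_i`` is its ceiling, floored at
    0, or None when no finite count reaches the target.
    ``achieved_ppv`` is the posterior actually attained after ``n_i``
    all-positive tests (the prior itself when ``n_i`` = 0).
    """

    continuous_n: float
    n_i: int | None
    feasibility: Feasibility
    target_ppv: float
    achieved_ppv: float | None


def _resolve_log_lr(test_or_log_lr: Union[TestCharacteristics, float]) -> float:
    if isinstance(test_or_log_lr, TestCharacteristics):
        return test_or_log_lr.log_positive_likelihood_ratio
    value = float(test_or_log_lr)
    if not math.isfinite(value):
        raise ValueError(f"ln(LR+) must be finite, got {value!r}")
    return value


def _check_target(target: float) -> float:
    target = float(target)
    if target >= 1.0:
        raise UnreachableTargetError(
            "a target PPV of 1 (or more) is unreachable: the required "
            "iteration count diverges for any prevalence below 1"
        )
    if target <= 0.0:
        raise ValueError(f"target PPV must be in (0, 1), got {target!r}")
    return target


def required_iterations_continuous(
    test_or_log_lr: Union[TestCharacteristics, float],
    prevalence: float,
    target: float,
) -> float:
    """Real-valued number of consecutive positives needed to reach ``target``.

    The formula depends on (a, b) only through ln(LR+) = ln[a/(1-b)], so
    the first argument may be either a :class:`TestCharacteristics` or a
    ln(LR+) value directly (as the reference tables are keyed).

    Requires 0 < prevalence < 1, 0 < target < 1 and ln(LR+) != 0.
    The result is negative when the prior already exceeds the target, and
    negative for informative targets when a + b < 1 (ln(LR+) < 0).
    """
    log_lr = _resolve_log_lr(test_or_log_lr)
    target = _check_target(target)
    phi = _check_probability(prevalence, "prevalence")
    if not 0.0 < phi < 1.0:
        raise ValueError(
            f"prevalence must be strictly inside (0, 1), got {phi!r}"
        )
    if abs(log_lr) <= UNINFORMATIVE_TOL:
        raise ZeroDivisionError(
            "ln(LR+) = 0 (a + b = 1): an uninformative test never changes "
            "the prior, no iteration count exists"
        )
    return (_logit(target) - _logit(phi)) / log_lr


def required_iterations(
    test: TestCharacteristics, prevalence: float, target: float
) -> IterationRequirement:
    """Integer iteration requirement with feasibility classification.

    The classification follows the sign of ln(LR+):

    * a + b < 1: positive results lower the posterior; the target is
      never reached (``infeasible_negative``).
    * a + b = 1: the posterior equals the prior at every n
      (``infeasible_uninformative``).
    * prior >= target: zero tests needed (``already_satisfied``).
    * prior = 0: no evidence moves a prior of zero (``unreachable``).
    * otherwise ``feasible`` with n_i = ceil(continuous n) >= 1.
    """
    target = _check_target(target)
    phi = _check_probability(prevalence, "prevalence")
    a, b = test.sensitivity, test.specificity

    def cont(p: float) -> float:
        if 0.0 < p < 1.0:
            return required_iterations_continuous(test, p, target)
        return math.nan

    if a + b < 1.0 - UNINFORMATIVE_TOL:
        return IterationRequirement(
            continuous_n=cont(phi),
            n_i=None,
            feasibility=Feasibility.INFEASIBLE_NEGATIVE,
            target_ppv=target,
            achieved_ppv=None,
        )
    if abs(a + b - 1.0) <= UNINFORMATIVE_TOL:
        return IterationRequirement(
            continuous_n=math.nan,
            n_i=None,
            feasibility=Feasibility.INFEASIBLE_UNINFORMATIVE,
            target_ppv=target,
            achieved_ppv=None,
        )
    if phi >= target:
        return IterationRequirement(
            continuous_n=cont(phi),
            n_i=0,
            feasibility=Feasibility.ALREADY_SATISFIED,
            target_ppv=target,
            achieved_ppv=phi,
        )
    if phi == 0.0:
        return IterationRequirement(
            continuous_n=math.nan,
            n_i=None,
            feasibility=Feasibility.UNREACHABLE,
            target_ppv=target,
            achieved_ppv=None,
        )
    n_cont = required_iterations_continuous(test, phi, target)
    n_i = max(1, math.ceil(n_cont))
    achieved = sequential_ppv(test, phi, n_i).posterior
    return IterationRequirement(
        continuous_n=n_cont,
        n_i=n_i,
        feasibility=Feasibility.FEASIBLE,
        target_ppv=target,
        achieved_ppv=achieved,
    )


def _round_half_up(x: float, digits: int = 2) -> float:
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ReferenceTable:
    """Grid of continuous iteration counts, ln(LR+) rows x prevalence columns.

    Cell values are rounded half-up to 2 decimals for display; the
    clinically usable count is the ceiling of the *unrounded* value.
    """

    target_ppv: float
    row_keys: tuple[float, ...]
    column_keys: tuple[float, ...]
    cells: np.ndarray = field(repr=False)  # shape (rows, columns), 2-dp floats

    def cell(self, row_key: float, column_key: float) -> float:
        i = self.row_keys.index(row_key)
        j = self.column_keys.index(column_key)
        return float(self.cells[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.cells, index=list(self.row_keys), columns=list(self.column_keys)
        ).rename_axis("ln_LR+")

    # ---- serialisation (comma-separated, "." decimal, "#" metadata) ----

    def to_csv(self) -> str:
        buf = io.StringIO()
        buf.write(
            f"# bayescreen reference table: target_ppv={self.target_ppv:g}; "
            "cells = continuous test iterations, 2 dp\n"
        )
        buf.write("ln_LR+," + ",".join(f"{c:g}" for c in self.column_keys) + "\n")
        for key, row in zip(self.row_keys, self.cells):
            cells = ",".join(
                INFEASIBLE_TOKEN if not math.isfinite(v) else f"{v:.2f}"
                for v in row
            )
            buf.write(f"{key:g},{cells}\n")
        return buf.getvalue()

    @classmethod
    def from_csv(cls, text: str) -> "ReferenceTable":
        target = math.nan
        rows: list[list[float]] = []
        row_keys: list[float] = []
        column_keys: tuple[float, ...] = ()
        for line in text.splitlines():
            if line.startswith("#"):
                for part in line.lstrip("# ").split(";"):
                    if "target_ppv=" in part:
                        target = float(part.split("target_ppv=")[1].strip())
                continue
            if not line.strip():
                continue
            fields = line.split(",")
            if fields[0] == "ln_LR+":
                column_keys = tuple(float(c) for c in fields[1:])
                continue
            row_keys.append(float(fields[0]))
            rows.append(
                [math.nan if c == INFEASIBLE_TOKEN else float(c) for c in fields[1:]]
            )
        return cls(
            target_ppv=target,
            row_keys=tuple(row_keys),
            column_keys=column_keys,
            cells=np.asarray(rows, dtype=float),
        )

    def to_json(self) -> str:
        cells = [
            [None if not math.isfinite(v) else v for v in row] for row in self.cells
        ]
        return json.dumps(
            {
                "target_ppv": self.target_ppv,
                "row_keys": list(self.row_keys),
                "column_keys": list(self.column_keys),
                "cells": cells,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ReferenceTable":
        obj = json.loads(text)
        cells = np.asarray(
            [[math.nan if v is None else v for v in row] for row in obj["cells"]],
            dtype=float,
        )
        return cls(
            target_ppv=obj["target_ppv"],
            row_keys=tuple(obj["row_keys"]),
            column_keys=tuple(obj["column_keys"]),
            cells=cells,
        )


def build_reference_table(
    target: float,
    row_keys: Sequence[float] | None = None,
    column_keys: Sequence[float] | None = None,
) -> ReferenceTable:
    """Reference table of continuous iteration counts for one target PPV.

    Rows are ln(LR+) values (must be > 0), columns are prevalences in
    (0, 1).  The default grid is ln(LR+) in {0.5, 1.0, ..., 5.0} by
    prevalence in {0.02, 0.05, 0.07, 0.1, 0.15, 0.2}, with targets
    conventionally taken from {0.99, 0.95, 0.75, 0.50}.
    """
    target = _check_target(target)
    rows = tuple(float(r) for r in (row_keys if row_keys is not None else DEFAULT_ROW_KEYS))
    cols = tuple(float(c) for c in (column_keys if column_keys is not None else DEFAULT_COLUMN_KEYS))
    if not rows or not cols:
        raise ValueError("row_keys and column_keys must be non-empty")
    for r in rows:
        if not (math.isfinite(r) and r > 0.0):
            raise ValueError(f"ln(LR+) row keys must be positive, got {r!r}")
    for c in cols:
        if not 0.0 < c < 1.0:
            raise ValueError(f"prevalence column keys must be in (0, 1), got {c!r}")
    cells = np.empty((len(rows), len(cols)), dtype=float)
    for i, r in enumerate(rows):
        for j, c in enumerate(cols):
            cells[i, j] = _round_half_up(required_iterations_continuous(r, c, target))
    return ReferenceTable(
        target_ppv=target, row_keys=rows, column_keys=cols, cells=cells
    )


@dataclass(frozen=True)
class TableclothGrid:
    """Integer iteration counts over a (sensitivity, specificity,
    prevalence) lattice for a fixed target PPV — the "tablecloth" surface.

    ``values[i, j, k]`` is n_i at (a_grid[i], b_grid[j], phi_grid[k]);
    NaN marks cells where no finite count reaches the target, and the
    parallel ``feasibility`` array carries the classification labels.
    """

    target_ppv: float
    a_grid: tuple[float, ...]
    b_grid: tuple[float, ...]
    phi_grid: tuple[float, ...]
    values: np.ndarray = field(repr=False)  # float; NaN = infeasible
    feasibility: np.ndarray = field(repr=False)  # dtype=object of Feasibility

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame: one row per lattice point."""
        records = []
        for i, a in enumerate(self.a_grid):
            for j, b in enumerate(self.b_grid):
                for k, phi in enumerate(self.phi_grid):
                    v = self.values[i, j, k]
                    records.append(
                        {
                            "sensitivity": a,
                            "specificity": b,
                            "prevalence": phi,
                            "n_i": None if math.isnan(v) else int(v),
                            "feasibility": self.feasibility[i, j, k].value,
                        }
                    )
        return pd.DataFrame.from_records(records)

    def to_csv(self) -> str:
        buf = io.StringIO()
        buf.write(f"# bayescreen tablecloth grid: target_ppv={self.target_ppv:g}\n")
        buf.write("sensitivity,specificity,prevalence,n_i,feasibility\n")
        for i, a in enumerate(self.a_grid):
            for j, b in enumerate(self.b_grid):
                for k, phi in enumerate(self.phi_grid):
                    v = self.values[i, j, k]
                    n = INFEASIBLE_TOKEN if math.isnan(v) else int(v)
                    buf.write(
                        f"{a:g},{b:g},{phi:g},{n},"
                        f"{self.feasibility[i, j, k].value}\n"
                    )
        return buf.getvalue()

    def to_json(self) -> str:
        return json.dumps(
            {
                "target_ppv": self.target_ppv,
                "a_grid": list(self.a_grid),
                "b_grid": list(self.b_grid),
                "phi_grid": list(self.phi_grid),
                "values": [
                    [
                        [None if math.isnan(v) else int(v) for v in row]
                        for row in plane
                    ]
                    for plane in self.values
                ],
                "feasibility": [
                    [[f.value for f in row] for row in plane]
                    for plane in self.feasibility
                ],
            },
            indent=2,
        )


def tablecloth_grid(
    target: float,
    a_grid: Sequence[float],
    b_grid: Sequence[float],
    phi_grid: Sequence[float],
) -> TableclothGrid:
    """Evaluate :func:`required_iterations` at every lattice point."""
    target = _check_target(target)
    a_grid = tuple(float(a) for a in a_grid)
    b_grid = tuple(float(b) for b in b_grid)
    phi_grid = tuple(float(p) for p in phi_grid)
    if not (a_grid and b_grid and phi_grid):
        raise ValueError("all three grids must be non-empty")
    shape = (len(a_grid), len(b_grid), len(phi_grid))
    values = np.full(shape, math.nan)
    feas = np.empty(shape, dtype=object)
    for i, a in enumerate(a_grid):
        for j, b in enumerate(b_grid):
            test = TestCharacteristics(a, b)
            for k, phi in enumerate(phi_grid):
                req = required_iterations(test, phi, target)
                feas[i, j, k] = req.feasibility
                if req.n_i is not None:
                    values[i, j, k] = req.n_i
    return TableclothGrid(
        target_ppv=target,
        a_grid=a_grid,
        b_grid=b_grid,
        phi_grid=phi_grid,
        values=values,
        feasibility=feas,
    )
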