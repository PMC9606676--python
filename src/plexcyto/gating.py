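"""Flow-cytometry-style gating on the cell database.

Gates are regions of measurement space — 1D thresholds, 2D rectangles,
2D polygons — combined into logical expressions with AND / OR / NOT
(Python ``&``, ``|``, ``~``).  Evaluation is pure, row-wise, and
independent of row order; every fraction this module reports can be
reproduced by brute-force counting over the table.  The default boundary
rule is lower-inclusive / upper-exclusive, overridable per edge.

Plot helpers (histogram, dot plot) are a thin convenience layer; all the
science lives in the membership computation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .io import Position, PositionList


class GateExpr:
    """Base of the gate-expression tree; supports ``& | ~``."""

    def evaluate(self, table: pd.DataFrame) -> np.ndarray:
        raise NotImplementedError

    def __and__(self, other: "GateExpr") -> "GateExpr":
        return _And(self, other)

    def __or__(self, other: "GateExpr") -> "GateExpr":
        return _Or(self, other)

    def __invert__(self) -> "GateExpr":
        return _Not(self)

    def to_dict(self) -> dict:
        raise NotImplementedError

    @staticmethod
    def from_dict(d: dict) -> "GateExpr":
        kind = d["kind"]
        if kind == "and":
            return _And(GateExpr.from_dict(d["a"]), GateExpr.from_dict(d["b"]))
        if kind == "or":
            return _Or(GateExpr.from_dict(d["a"]), GateExpr.from_dict(d["b"]))
        if kind == "not":
            return _Not(GateExpr.from_dict(d["a"]))
        if kind == "threshold1D":
            return ThresholdGate(d["parameter"], d.get("low"), d.get("high"),
                                 d.get("low_inclusive", True),
                                 d.get("high_inclusive", False))
        if kind == "rectangle2D":
            return RectangleGate(d["x_parameter"], d["y_parameter"],
                                 tuple(d["x_bounds"]), tuple(d["y_bounds"]),
                                 d.get("low_inclusive", True),
                                 d.get("high_inclusive", False))
        if kind == "polygon2D":
            return PolygonGate(d["x_parameter"], d["y_parameter"],
                               [tuple(v) for v in d["vertices"]],
                               d.get("boundary_inclusive", True))
        raise ValueError(f"unknown gate kind {kind!r}")


def _column(table: pd.DataFrame, name: str) -> np.ndarray:
    if name not in table.columns:
        raise KeyError(f"parameter {name!r} not in table; available: "
                       f"{list(table.columns)}")
    return table[name].to_numpy()


@dataclass(frozen=True)
class _And(GateExpr):
    a: GateExpr
    b: GateExpr

    def evaluate(self, table):
        return self.a.evaluate(table) & self.b.evaluate(table)

    def to_dict(self):
        return {"kind": "and", "a": self.a.to_dict(), "b": self.b.to_dict()}


@dataclass(frozen=True)
class _Or(GateExpr):
    a: GateExpr
    b: GateExpr

    def evaluate(self, table):
        return self.a.evaluate(table) | self.b.evaluate(table)

    def to_dict(self):
        return {"kind": "or", "a": self.a.to_dict(), "b": self.b.to_dict()}


@dataclass(frozen=True)
class _Not(GateExpr):
    a: GateExpr

    def evaluate(self, table):
        return ~self.a.evaluate(table)

    def to_dict(self):
        return {"kind": "not", "a": self.a.to_dict()}


@dataclass(frozen=True)
class ThresholdGate(GateExpr):
    """1D interval gate; omit a bound to leave that side open."""
    parameter: str
    low: float | None = None
    high: float | None = None
    low_inclusive: bool = True
    high_inclusive: bool = False

    def evaluate(self, table):
        x = _column(table, self.parameter)
        m = np.ones(len(x), dtype=bool)
        if self.low is not None:
            m &= (x >= self.low) if self.low_inclusive else (x > self.low)
        if self.high is not None:
            m &= (x <= self.high) if self.high_inclusive else (x < self.high)
        return m

    def to_dict(self):
        return {"kind": "threshold1D", "parameter": self.parameter,
                "low": self.low, "high": self.high,
                "low_inclusive": self.low_inclusive,
                "high_inclusive": self.high_inclusive}


@dataclass(frozen=True)
class RectangleGate(GateExpr):
    x_parameter: str
    y_parameter: str
    x_bounds: tuple[float, float]
    y_bounds: tuple[float, float]
    low_inclusive: bool = True
    high_inclusive: bool = False

    def __post_init__(self):
        if not (self.x_bounds[0] < self.x_bounds[1]
                and self.y_bounds[0] < self.y_bounds[1]):
            raise ValueError("rectangle bounds must satisfy low < high")

    def evaluate(self, table):
        gx = ThresholdGate(self.x_parameter, *self.x_bounds,
                           self.low_inclusive, self.high_inclusive)
        gy = ThresholdGate(self.y_parameter, *self.y_bounds,
                           self.low_inclusive, self.high_inclusive)
        return gx.evaluate(table) & gy.evaluate(table)

    def to_dict(self):
        return {"kind": "rectangle2D", "x_parameter": self.x_parameter,
                "y_parameter": self.y_parameter,
                "x_bounds": list(self.x_bounds), "y_bounds": list(self.y_bounds),
                "low_inclusive": self.low_inclusive,
                "high_inclusive": self.high_inclusive}


class PolygonGate(GateExpr):
    """Simple-polygon gate; boundary points are members by default."""

    def __init__(self, x_parameter: str, y_parameter: str,
                 vertices: Sequence[tuple[float, float]],
                 boundary_inclusive: bool = True):
        self.x_parameter = x_parameter
        self.y_parameter = y_parameter
        self.vertices = [tuple(map(float, v)) for v in vertices]
        self.boundary_inclusive = boundary_inclusive
        self._poly = Polygon(self.vertices)
        if not self._poly.is_valid:
            raise ValueError("polygon is self-intersecting or degenerate")

    def evaluate(self, table):
        x = _column(table, self.x_parameter)
        y = _column(table, self.y_parameter)
        test = self._poly.covers if self.boundary_inclusive \
            else self._poly.contains
        return np.fromiter((test(Point(px, py)) for px, py in zip(x, y)),
                           dtype=bool, count=len(x))

    def to_dict(self):
        return {"kind": "polygon2D", "x_parameter": self.x_parameter,
                "y_parameter": self.y_parameter,
                "vertices": [list(v) for v in self.vertices],
                "boundary_inclusive": self.boundary_inclusive}


def write_gate(expr: GateExpr, path: str | Path) -> Path:
    Path(path).write_text(json.dumps(expr.to_dict(), indent=1))
    return Path(path)


def read_gate(path: str | Path) -> GateExpr:
    return GateExpr.from_dict(json.loads(Path(path).read_text()))


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def apply_gate(table: pd.DataFrame, expr: GateExpr
               ) -> tuple[np.ndarray, pd.DataFrame, float]:
    """Row-wise membership, the member sub-table, and the member fraction."""
    membership = np.asarray(expr.evaluate(table), dtype=bool)
    sub = table.loc[membership]
    fraction = float(membership.mean()) if len(table) else 0.0
    return membership, sub, fraction


def threshold_positive(table: pd.DataFrame, spot_channel: str,
                       min_spots: int) -> np.ndarray:
    """Spot-count positivity: member iff ``n_spots > min_spots`` (strict).

    A cell with exactly ``min_spots`` spots is negative — the rule is the
    strict ``> threshold`` convention used for RNA-spot positivity.
    """
    if min_spots < 0:
        raise ValueError("min_spots must be nonnegative")
    col = f"{spot_channel}__nspots"
    if col not in table.columns:
        raise KeyError(f"spot-count column {col!r} not in table")
    return table[col].to_numpy() > min_spots


def crosstab(table: pd.DataFrame, expr_rows: GateExpr, expr_cols: GateExpr
             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """2x2 cross-tabulation of two gates.

    Returns (counts, row-conditional fractions); fractions sum to 1 per
    row.  An empty table is an error.
    """
    if len(table) == 0:
        raise ValueError("cannot cross-tabulate an empty table")
    r = np.asarray(expr_rows.evaluate(table), dtype=bool)
    c = np.asarray(expr_cols.evaluate(table), dtype=bool)
    counts = pd.DataFrame(
        [[int((r & c).sum()), int((r & ~c).sum())],
         [int((~r & c).sum()), int((~r & ~c).sum())]],
        index=["rows+", "rows-"], columns=["cols+", "cols-"])
    row_sums = counts.sum(axis=1).replace(0, 1)
    fractions = counts.div(row_sums, axis=0)
    return counts, fractions


def select_coordinates(table: pd.DataFrame, expr: GateExpr) -> PositionList:
    """Stage positions of member cells (one per cell, labeled by id)."""
    for col in ("x_um", "y_um"):
        if col not in table.columns:
            raise KeyError(f"stage-coordinate column {col!r} not in table")
    membership, sub, _ = apply_gate(table, expr)
    return PositionList([
        Position(f"cell_{int(row.cell_id)}", float(row.x_um), float(row.y_um))
        for row in sub.itertuples(index=False)])


def make_population_mask(cells: np.ndarray, table: pd.DataFrame,
                         expr: GateExpr, class_value: int | None = None
                         ) -> np.ndarray:
    """Image of the gated population: member cells keep their labels (or
    take ``class_value``), everything else is zeroed."""
    cells = np.asarray(cells)
    present = set(np.unique(cells)) - {0}
    known = set(table["cell_id"].tolist())
    missing = present - known
    if missing:
        raise ValueError(f"labels absent from the table: {sorted(missing)[:10]}")
    membership, sub, _ = apply_gate(table, expr)
    member_ids = np.asarray(sub["cell_id"], dtype=np.int64)
    keep = np.isin(cells, member_ids)
    if class_value is not None:
        return np.where(keep, class_value, 0).astype(cells.dtype)
    return np.where(keep, cells, 0)


# --------------------------------------------------------------------------
# plotting (non-contractual convenience)
# --------------------------------------------------------------------------

def histogram(table: pd.DataFrame, parameter: str, bins: int = 64, ax=None,
              log: bool = False):
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    ax.hist(_column(table, parameter), bins=bins, log=log)
    ax.set_xlabel(parameter)
    ax.set_ylabel("events")
    return ax


def dot_plot(table: pd.DataFrame, x_parameter: str, y_parameter: str,
             expr: GateExpr | None = None, ax=None):
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    x = _column(table, x_parameter)
    y = _column(table, y_parameter)
    if expr is None:
        ax.scatter(x, y, s=4)
    else:
        m = expr.evaluate(table)
        ax.scatter(x[~m], y[~m], s=4, c="gray")
        ax.scatter(x[m], y[m], s=4, c="red")
    ax.set_xlabel(x_parameter)
    ax.set_ylabel(y_parameter)
    return ax
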