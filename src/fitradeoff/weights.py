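"""Partial-information weight space over the ranked simplex.

The decision-maker never states scale constants directly.  A strict ranking
of the criteria defines the initial polytope

    phi = { k : k_(1) > k_(2) > ... > k_(n),  sum k_i = 1,  k_i >= 0 }

and every answered tradeoff question adds one linear constraint tying a
lower-ranked constant to a fraction of a higher-ranked one, shrinking the
polytope.  All queries against the space (value maxima, per-criterion
bounds, feasible ratio intervals) are linear programs solved with HiGHS.

Strict inequalities are closed with a small epsilon ``delta``.  For the
ranking this is additive (k_r >= k_{r+1} + delta); for tradeoff statements
it is applied to the ratio, k_j <= k_i * (v - delta), so that the cut on
the feasible interval of k_j / k_i is exactly delta wide regardless of the
magnitude of k_i.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "TradeoffStatement",
    "LinearConstraint",
    "WeightSpace",
    "WeightBounds",
    "InfeasibleSpaceError",
    "InconsistentStatementError",
    "space_from_ranking",
    "add_statement",
    "max_additive_value",
    "weight_bounds",
    "ratio_bounds",
    "ranked_simplex_vertices",
]

DEFAULT_DELTA = 1e-6
DEFAULT_INDIFF_TOL = 1e-6


class InfeasibleSpaceError(ValueError):
    """The weight space contains no feasible scale-constant vector."""


class InconsistentStatementError(InfeasibleSpaceError):
    """A tradeoff statement contradicts the constraints already recorded."""

    def __init__(self, statement: "TradeoffStatement"):
        self.statement = statement
        super().__init__(
            f"statement {statement} makes the weight space infeasible"
        )


@dataclass(frozen=True)
class TradeoffStatement:
    """One answered tradeoff question.

    The question opposes a hypothetical consequence with normalized value
    ``level`` on the higher-ranked criterion ``upper`` (worst on every other
    criterion) against the best consequence on the lower-ranked criterion
    ``lower`` (worst elsewhere).  Under the additive model the two are worth
    k_upper * level and k_lower, so the answer locates k_lower / k_upper
    relative to ``level``:

    - ``"a"``  (hypothetical preferred):  k_lower <  k_upper * level
    - ``"b"``  (best-on-lower preferred): k_lower >  k_upper * level
    - ``"indifferent"``:                  k_lower == k_upper * level (band)
    """

    upper: str
    lower: str
    level: float
    answer: Literal["a", "b", "indifferent"]

    def __post_init__(self):
        if self.answer not in ("a", "b", "indifferent"):
            raise ValueError(f"unknown answer {self.answer!r}")
        if not 0.0 < self.level < 1.0:
            raise ValueError(
                f"hypothetical level must have normalized value in (0, 1), got {self.level}"
            )


@dataclass(frozen=True)
class LinearConstraint:
    """coeffs . k  <relation>  bound, coefficients in ranking order."""

    coeffs: tuple[float, ...]
    relation: Literal["<=", ">=", "="]
    bound: float
    origin: str = ""

    def as_leq(self) -> list[tuple[np.ndarray, float]]:
        """Rows (a, b) meaning a . k <= b."""
        a = np.asarray(self.coeffs, dtype=float)
        if self.relation == "<=":
            return [(a, self.bound)]
        if self.relation == ">=":
            return [(-a, -self.bound)]
        return [(a, self.bound), (-a, -self.bound)]


@dataclass(frozen=True)
class WeightSpace:
    """Ranking plus accumulated linear constraints over the scale constants.

    ``criteria`` is the ranking: index 0 is the most important criterion.
    The simplex constraints (sum = 1, k >= 0) are implicit.  Instances are
    immutable; :func:`add_statement` returns a new space.
    """

    criteria: tuple[str, ...]
    constraints: tuple[LinearConstraint, ...] = ()
    statements: tuple[TradeoffStatement, ...] = ()
    delta: float = DEFAULT_DELTA
    indiff_tol: float = DEFAULT_INDIFF_TOL

    @property
    def n(self) -> int:
        return len(self.criteria)

    def index(self, criterion: str) -> int:
        try:
            return self.criteria.index(criterion)
        except ValueError:
            raise KeyError(f"criterion {criterion!r} not in weight space") from None

    def rank_of(self, criterion: str) -> int:
        """1-based rank (1 = most important)."""
        return self.index(criterion) + 1

    # -- LP building blocks ---------------------------------------------
    def _inequalities(self) -> tuple[np.ndarray, np.ndarray]:
        rows, rhs = [], []
        for con in self.constraints:
            for a, b in con.as_leq():
                rows.append(a)
                rhs.append(b)
        if not rows:
            return np.zeros((0, self.n)), np.zeros(0)
        return np.vstack(rows), np.asarray(rhs)

    def solve(self, objective: np.ndarray, *, maximize: bool = True):
        """Optimize a linear objective over the space; returns (value, k)."""
        A_ub, b_ub = self._inequalities()
        c = -np.asarray(objective, float) if maximize else np.asarray(objective, float)
        res = linprog(
            c,
            A_ub=A_ub if A_ub.size else None,
            b_ub=b_ub if b_ub.size else None,
            A_eq=np.ones((1, self.n)),
            b_eq=[1.0],
            bounds=[(0.0, 1.0)] * self.n,
            method="highs",
        )
        if res.status == 2:
            raise InfeasibleSpaceError("weight space is infeasible")
        if not res.success:  # pragma: no cover - solver failure
            raise RuntimeError(f"LP failed: {res.message}")
        value = -res.fun if maximize else res.fun
        return float(value), res.x

    def is_feasible(self) -> bool:
        try:
            self.solve(np.zeros(self.n))
        except InfeasibleSpaceError:
            return False
        return True

    def contains(self, k, tol: float = 1e-9) -> bool:
        """Whether a weight vector (array in ranking order, or mapping by
        criterion id) satisfies the simplex and all stored constraints."""
        if hasattr(k, "keys"):
            k = [k[c] for c in self.criteria]
        k = np.asarray(k, dtype=float)
        if k.shape != (self.n,):
            raise ValueError(f"expected {self.n} weights, got {k.size}")
        if (k < -tol).any() or abs(k.sum() - 1.0) > tol:
            return False
        A_ub, b_ub = self._inequalities()
        return bool((A_ub @ k <= b_ub + tol).all()) if A_ub.size else True

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "criteria": list(self.criteria),
            "delta": self.delta,
            "indiff_tol": self.indiff_tol,
            "constraints": [
                {
                    "coeffs": list(c.coeffs),
                    "relation": c.relation,
                    "bound": c.bound,
                    "origin": c.origin,
                }
                for c in self.constraints
            ],
            "statements": [
                {
                    "upper": s.upper,
                    "lower": s.lower,
                    "level": s.level,
                    "answer": s.answer,
                }
                for s in self.statements
            ],
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "WeightSpace":
        return cls(
            criteria=tuple(d["criteria"]),
            delta=d.get("delta", DEFAULT_DELTA),
            indiff_tol=d.get("indiff_tol", DEFAULT_INDIFF_TOL),
            constraints=tuple(
                LinearConstraint(
                    tuple(c["coeffs"]), c["relation"], c["bound"], c.get("origin", "")
                )
                for c in d["constraints"]
            ),
            statements=tuple(
                TradeoffStatement(**s) for s in d.get("statements", [])
            ),
        )


@dataclass(frozen=True)
class WeightBounds:
    """Per-criterion [lower, upper] intervals for the scale constants."""

    criteria: tuple[str, ...]
    lower: tuple[float, ...]
    upper: tuple[float, ...]

    def __getitem__(self, criterion: str) -> tuple[float, float]:
        i = self.criteria.index(criterion)
        return self.lower[i], self.upper[i]

    def nested_within(self, outer: "WeightBounds", tol: float = 1e-9) -> bool:
        """True if every interval is contained in ``outer``'s interval."""
        if self.criteria != outer.criteria:
            raise ValueError("bounds refer to different criteria")
        return all(
            lo >= olo - tol and hi <= ohi + tol
            for lo, hi, olo, ohi in zip(self.lower, self.upper, outer.lower, outer.upper)
        )

    def width(self) -> float:
        return float(max(h - l for l, h in zip(self.lower, self.upper)))


def space_from_ranking(
    ranking: Sequence[str],
    *,
    delta: float = DEFAULT_DELTA,
    indiff_tol: float = DEFAULT_INDIFF_TOL,
) -> WeightSpace:
    """Weight space of a strict importance ranking.

    Adds k_(r) >= k_(r+1) + delta for consecutive ranks on top of the
    implicit simplex constraints.
    """
    ranking = list(ranking)
    if len(set(ranking)) != len(ranking):
        raise ValueError("ranking contains ties or repeated criteria")
    if len(ranking) < 2:
        raise ValueError("ranking needs at least two criteria")
    n = len(ranking)
    cons = []
    for r in range(n - 1):
        coeffs = [0.0] * n
        coeffs[r] = 1.0
        coeffs[r + 1] = -1.0
        cons.append(
            LinearConstraint(
                tuple(coeffs), ">=", delta, origin=f"ranking:{ranking[r]}>{ranking[r+1]}"
            )
        )
    return WeightSpace(
        criteria=tuple(ranking),
        constraints=tuple(cons),
        delta=delta,
        indiff_tol=indiff_tol,
    )


def _statement_constraints(space: WeightSpace, stmt: TradeoffStatement):
    i = space.index(stmt.upper)
    j = space.index(stmt.lower)
    if i >= j:
        raise ValueError(
            f"statement must oppose a higher-ranked criterion to a lower-ranked "
            f"one; got {stmt.upper!r} (rank {i + 1}) vs {stmt.lower!r} (rank {j + 1})"
        )

    def row(scale_i: float):
        coeffs = [0.0] * space.n
        coeffs[j] = 1.0
        coeffs[i] = -scale_i
        return tuple(coeffs)

    origin = f"statement:{stmt.upper}/{stmt.lower}@{stmt.level:.6g}={stmt.answer}"
    if stmt.answer == "a":
        # hypothetical preferred: k_j < k_i * v, closed multiplicatively
        return [LinearConstraint(row(stmt.level - space.delta), "<=", 0.0, origin)]
    if stmt.answer == "b":
        return [LinearConstraint(row(stmt.level + space.delta), ">=", 0.0, origin)]
    return [
        LinearConstraint(row(stmt.level + space.indiff_tol), "<=", 0.0, origin),
        LinearConstraint(row(stmt.level - space.indiff_tol), ">=", 0.0, origin),
    ]


def add_statement(space: WeightSpace, stmt: TradeoffStatement) -> WeightSpace:
    """Return a new space with the statement's constraint added.

    Raises :class:`InconsistentStatementError` if the enlarged constraint
    set is infeasible; the input space is never modified.
    """
    new = replace(
        space,
        constraints=space.constraints + tuple(_statement_constraints(space, stmt)),
        statements=space.statements + (stmt,),
    )
    if not new.is_feasible():
        raise InconsistentStatementError(stmt)
    return new


def _objective_for(space: WeightSpace, problem, alternative: str) -> np.ndarray:
    """Normalized values of ``alternative`` aligned to the space's ranking."""
    u = problem.normalized().loc[alternative]
    return np.array([u[c] for c in space.criteria])


def max_additive_value(
    space: WeightSpace, problem, alternative: str
) -> tuple[float, dict[str, float]]:
    """LP maximum of the alternative's additive value over the space.

    Returns the maximum and the maximizing weight vector as a mapping
    keyed by criterion id.
    """
    obj = _objective_for(space, problem, alternative)
    value, k = space.solve(obj, maximize=True)
    return value, dict(zip(space.criteria, (float(x) for x in k)))


def weight_bounds(space: WeightSpace) -> WeightBounds:
    """Per-criterion min/max of k_i over the space (2n LPs)."""
    lows, highs = [], []
    for i in range(space.n):
        e = np.zeros(space.n)
        e[i] = 1.0
        lo, _ = space.solve(e, maximize=False)
        hi, _ = space.solve(e, maximize=True)
        lows.append(lo)
        highs.append(hi)
    return WeightBounds(space.criteria, tuple(lows), tuple(highs))


def ratio_bounds(space: WeightSpace, upper: str, lower: str) -> tuple[float, float]:
    """Feasible interval of the ratio k_lower / k_upper over the space.

    Solved exactly by the Charnes–Cooper transformation: substitute
    y = k / k_upper, s = 1 / k_upper, which turns each affine constraint
    a.k <= b into a.y - b*s <= 0 and the simplex into sum(y) = s, y_up = 1.
    Valid because the ranking keeps k_upper strictly positive.
    """
    i = space.index(upper)
    j = space.index(lower)
    n = space.n
    A_ub, b_ub = space._inequalities()
    # columns: y_1..y_n, s
    A = np.hstack([A_ub, -b_ub[:, None]]) if A_ub.size else np.zeros((0, n + 1))
    rows_eq = np.zeros((2, n + 1))
    rows_eq[0, :n] = 1.0
    rows_eq[0, n] = -1.0  # sum(y) = s
    rows_eq[1, i] = 1.0  # y_upper = 1
    b_eq = [0.0, 1.0]
    bounds = [(0.0, None)] * n + [(1.0, None)]  # s = 1/k_upper >= 1
    out = []
    for maximize in (False, True):
        c = np.zeros(n + 1)
        c[j] = -1.0 if maximize else 1.0
        res = linprog(
            c,
            A_ub=A if A.size else None,
            b_ub=np.zeros(A.shape[0]) if A.size else None,
            A_eq=rows_eq,
            b_eq=b_eq,
            bounds=bounds,
            method="highs",
        )
        if res.status == 2:
            raise InfeasibleSpaceError("weight space is infeasible")
        if not res.success:  # pragma: no cover
            raise RuntimeError(f"ratio LP failed: {res.message}")
        out.append(float(res.x[j]))
    return out[0], out[1]


def ranked_simplex_vertices(n: int) -> np.ndarray:
    """Vertices of the weakly-ranked simplex {k1>=...>=kn>=0, sum=1}.

    These are the n equal-weight prefixes (1/m, ..., 1/m, 0, ..., 0); any
    linear functional attains its extremum over the ranked simplex at one
    of them.  Useful as an enumeration oracle for the LP routines.
    """
    v = np.zeros((n, n))
    for m in range(1, n + 1):
        v[m - 1, :m] = 1.0 / m
    return v
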