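"""Additive multi-attribute value model.

A choice problem is a set of alternatives evaluated on benefit criteria
through a raw consequence matrix.  Each criterion gets an affine value
function that maps the observed column range onto [0, 1] (min–max), and the
global value of an alternative is the weighted sum of its per-criterion
values, v(a) = sum_i k_i * u_i(x_ai), with scale constants k_i >= 0 summing
to one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Criterion",
    "Alternative",
    "ValueFunction",
    "DecisionProblem",
    "DegenerateCriterionError",
    "minmax_value",
]

#: tolerance on |sum(k) - 1| when validating a weight vector
DEFAULT_WEIGHT_SUM_TOL = 1e-9


class DegenerateCriterionError(ValueError):
    """Raised when a criterion's observed scores are constant.

    A constant column carries no preferential information and the min–max
    map is undefined on it.
    """

    def __init__(self, criterion: str):
        self.criterion = criterion
        super().__init__(
            f"criterion {criterion!r} is degenerate: all alternatives share "
            "the same raw score, so its value function is undefined"
        )


@dataclass(frozen=True)
class Criterion:
    """A benefit criterion (higher raw score is always better)."""

    id: str
    label: str = ""
    direction: str = "max"

    def __post_init__(self):
        if self.direction != "max":
            raise ValueError(
                f"criterion {self.id!r}: only benefit ('max') criteria are supported"
            )


@dataclass(frozen=True)
class Alternative:
    id: str
    label: str = ""


@dataclass(frozen=True)
class ValueFunction:
    """Affine min–max value function for one criterion.

    Maps the observed worst raw score to 0 and the observed best to 1.
    """

    criterion: str
    minimum: float
    maximum: float

    def __post_init__(self):
        if not (np.isfinite(self.minimum) and np.isfinite(self.maximum)):
            raise ValueError(f"criterion {self.criterion!r}: non-finite range")
        if self.maximum < self.minimum:
            raise ValueError(f"criterion {self.criterion!r}: max < min")

    @property
    def degenerate(self) -> bool:
        return self.maximum == self.minimum

    def __call__(self, raw: float) -> float:
        return minmax_value(raw, self)


def minmax_value(raw: float, vf: ValueFunction) -> float:
    """Normalized value of ``raw`` under ``vf``: (raw - min) / (max - min)."""
    if vf.degenerate:
        raise DegenerateCriterionError(vf.criterion)
    return (raw - vf.minimum) / (vf.maximum - vf.minimum)


def _unique_ids(items: Iterable, what: str) -> list[str]:
    ids = [it.id for it in items]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate {what} ids: {dupes}")
    return ids


class DecisionProblem:
    """Alternatives, criteria, and the raw consequence matrix binding them.

    Parameters
    ----------
    alternatives, criteria
        Sequences of :class:`Alternative` / :class:`Criterion` (bare id
        strings are promoted).
    matrix
        Raw consequences, one row per alternative, one column per criterion.
        Accepts a DataFrame (reindexed by id) or an array in declaration
        order.  Must be complete and finite.

    Value functions are fitted from the matrix columns on construction.
    """

    def __init__(
        self,
        alternatives: Sequence[Alternative | str],
        criteria: Sequence[Criterion | str],
        matrix,
    ):
        self.alternatives = tuple(
            a if isinstance(a, Alternative) else Alternative(a) for a in alternatives
        )
        self.criteria = tuple(
            c if isinstance(c, Criterion) else Criterion(c) for c in criteria
        )
        alt_ids = _unique_ids(self.alternatives, "alternative")
        crit_ids = _unique_ids(self.criteria, "criterion")

        if isinstance(matrix, pd.DataFrame):
            missing_r = set(alt_ids) - set(matrix.index)
            missing_c = set(crit_ids) - set(matrix.columns)
            if missing_r or missing_c:
                raise ValueError(
                    f"matrix missing rows {sorted(missing_r)} / columns {sorted(missing_c)}"
                )
            mat = matrix.loc[alt_ids, crit_ids].astype(float)
        else:
            arr = np.asarray(matrix, dtype=float)
            if arr.shape != (len(alt_ids), len(crit_ids)):
                raise ValueError(
                    f"matrix shape {arr.shape} does not match "
                    f"({len(alt_ids)} alternatives, {len(crit_ids)} criteria)"
                )
            mat = pd.DataFrame(arr, index=alt_ids, columns=crit_ids)
        if mat.isna().any().any():
            raise ValueError("consequence matrix has missing cells")
        if not np.isfinite(mat.to_numpy()).all():
            raise ValueError("consequence matrix has non-finite entries")
        self.matrix = mat
        self.value_functions = {
            c: ValueFunction(c, float(mat[c].min()), float(mat[c].max()))
            for c in crit_ids
        }

    # -- identity helpers ------------------------------------------------
    @property
    def alternative_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def criterion_ids(self) -> list[str]:
        return list(self.matrix.columns)

    # -- normalization ---------------------------------------------------
    def normalized(self) -> pd.DataFrame:
        """Min–max normalized matrix; every column spans [0, 1]."""
        cols = {}
        for c in self.criterion_ids:
            vf = self.value_functions[c]
            if vf.degenerate:
                raise DegenerateCriterionError(c)
            cols[c] = (self.matrix[c] - vf.minimum) / (vf.maximum - vf.minimum)
        return pd.DataFrame(cols, index=self.matrix.index)

    def normalized_row(self, alternative: str) -> np.ndarray:
        return self.normalized().loc[alternative].to_numpy()

    # -- additive value --------------------------------------------------
    def _weights_array(
        self, weights, tol: float = DEFAULT_WEIGHT_SUM_TOL
    ) -> np.ndarray:
        if isinstance(weights, Mapping):
            missing = set(self.criterion_ids) - set(weights)
            if missing:
                raise ValueError(f"weights missing criteria {sorted(missing)}")
            w = np.array([float(weights[c]) for c in self.criterion_ids])
        else:
            w = np.asarray(weights, dtype=float)
            if w.shape != (len(self.criterion_ids),):
                raise ValueError(
                    f"weight vector length {w.size} != {len(self.criterion_ids)} criteria"
                )
        if (w < 0).any():
            raise ValueError("negative weight")
        if abs(w.sum() - 1.0) > tol:
            raise ValueError(f"weights sum to {w.sum()!r}, not 1 within {tol}")
        return w

    def value(
        self,
        alternative: str,
        weights,
        *,
        weight_sum_tol: float = DEFAULT_WEIGHT_SUM_TOL,
    ) -> float:
        """Global additive value sum_i k_i * u_i(x_i) of one alternative.

        ``weights`` is a mapping keyed by criterion id or an array in
        criterion declaration order; it must be a point of the simplex
        (non-negative, summing to 1 within ``weight_sum_tol``).
        """
        w = self._weights_array(weights, weight_sum_tol)
        u = self.normalized().loc[alternative].to_numpy()
        return float(u @ w)

    def values(self, weights, *, weight_sum_tol=DEFAULT_WEIGHT_SUM_TOL) -> pd.Series:
        """Additive values of all alternatives at one weight vector."""
        w = self._weights_array(weights, weight_sum_tol)
        return self.normalized() @ w

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "alternatives": [
                {"id": a.id, "label": a.label} for a in self.alternatives
            ],
            "criteria": [{"id": c.id, "label": c.label} for c in self.criteria],
            "matrix": [
                [float(x) for x in self.matrix.loc[a]] for a in self.alternative_ids
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DecisionProblem":
        return cls(
            [Alternative(**a) for a in d["alternatives"]],
            [Criterion(**c) for c in d["criteria"]],
            np.array(d["matrix"], dtype=float),
        )

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "DecisionProblem":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(json.loads(text))

    def __repr__(self):
        return (
            f"DecisionProblem({len(self.alternatives)} alternatives x "
            f"{len(self.criteria)} criteria)"
        )
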