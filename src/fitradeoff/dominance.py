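"""Potential-optimality filtering over a partial-information weight space.

An alternative is potentially optimal if some feasible weight vector makes
it at least as good as every other alternative.  Alternatives that are not
are dominated everywhere in the space and can be excluded before (and
during) elicitation.  The test is a single LP per alternative: maximize the
slack s subject to v(alt, k) >= v(b, k) + s for every rival b and k in the
space.  Elimination is deliberately conservative — ties at the boundary
keep the alternative, so the true best is never dropped by rounding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .weights import InfeasibleSpaceError, WeightSpace, max_additive_value

__all__ = [
    "PotentialOptimalSet",
    "is_potentially_optimal",
    "filter_potentially_optimal",
    "ELIMINATION_SLACK",
]

#: an alternative is eliminated only if its best achievable slack is below this
ELIMINATION_SLACK = -1e-7


@dataclass(frozen=True)
class PotentialOptimalSet:
    """Outcome of the dominance filter.

    ``certificates`` holds, per alternative, the witness weight vector when
    it survives and the (negative) optimal slack when it is eliminated.
    ``max_values`` / ``argmax_weights`` are the survivors' LP maxima.
    """

    survivors: tuple[str, ...]
    eliminated: tuple[str, ...]
    max_values: dict[str, float]
    argmax_weights: dict[str, dict[str, float]]
    certificates: dict[str, object]

    def __contains__(self, alternative: str) -> bool:
        return alternative in self.survivors


def _slack_lp(space: WeightSpace, problem, alternative: str):
    """Maximize s s.t. v(alt,k) - v(b,k) >= s for all b, k in space."""
    norm = problem.normalized()
    order = list(space.criteria)
    u_alt = norm.loc[alternative, order].to_numpy()
    rivals = [a for a in problem.alternative_ids if a != alternative]
    n = space.n
    A_ub, b_ub = space._inequalities()
    rows = [np.append(a, 0.0) for a in A_ub]  # existing constraints, s free
    rhs = list(b_ub)
    for b in rivals:
        diff = norm.loc[b, order].to_numpy() - u_alt
        rows.append(np.append(diff, 1.0))  # (u_b - u_alt).k + s <= 0
        rhs.append(0.0)
    c = np.zeros(n + 1)
    c[n] = -1.0  # maximize s
    res = linprog(
        c,
        A_ub=np.vstack(rows) if rows else None,
        b_ub=np.asarray(rhs) if rows else None,
        A_eq=np.hstack([np.ones((1, n)), np.zeros((1, 1))]),
        b_eq=[1.0],
        bounds=[(0.0, 1.0)] * n + [(None, None)],
        method="highs",
    )
    if res.status == 2:
        raise InfeasibleSpaceError("weight space is infeasible")
    if not res.success:  # pragma: no cover
        raise RuntimeError(f"slack LP failed: {res.message}")
    return float(res.x[n]), dict(zip(order, (float(x) for x in res.x[:n])))


def is_potentially_optimal(
    space: WeightSpace,
    problem,
    alternative: str,
    *,
    slack_tol: float = ELIMINATION_SLACK,
):
    """Whether some feasible weight vector makes ``alternative`` best.

    Returns ``(flag, certificate)``: the witness weights if potentially
    optimal, else the optimal (negative) slack quantifying how far the
    alternative falls short everywhere in the space.
    """
    if len(problem.alternative_ids) == 1:
        _, k = max_additive_value(space, problem, alternative)
        return True, k
    slack, witness = _slack_lp(space, problem, alternative)
    if slack >= slack_tol:
        return True, witness
    return False, slack


def filter_potentially_optimal(
    space: WeightSpace, problem, *, slack_tol: float = ELIMINATION_SLACK
) -> PotentialOptimalSet:
    """Split the alternatives into potentially optimal survivors and
    dominated, excluded ones; survivors carry their LP maximum value and
    the maximizing weights."""
    survivors, eliminated = [], []
    max_values, argmax, certs = {}, {}, {}
    for alt in problem.alternative_ids:
        ok, cert = is_potentially_optimal(space, problem, alt, slack_tol=slack_tol)
        certs[alt] = cert
        if ok:
            survivors.append(alt)
            v, k = max_additive_value(space, problem, alt)
            max_values[alt] = v
            argmax[alt] = k
        else:
            eliminated.append(alt)
    if not survivors:  # pragma: no cover - impossible for feasible spaces
        raise RuntimeError("no potentially optimal alternative in a feasible space")
    return PotentialOptimalSet(
        tuple(survivors), tuple(eliminated), max_values, argmax, certs
    )
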