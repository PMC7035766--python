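"""Questionnaire aggregation and the criteria/subcriteria tree.

The decision matrix of the case study is not observed directly: a
specialist scores every (alternative, subcriterion) pair on a 0-5 scale,
and criterion-level consequences are the unweighted sums of those scores
over each criterion's subcriteria.  Nurse panels additionally rate the
relevance of subcriteria on a 1-5 Likert scale; those ratings are
aggregated to per-subcriterion means and inform the specialist
qualitatively, but do not enter the matrix numerically (a weighted-sum
hook exists for studies that want them to).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import DecisionProblem

__all__ = [
    "Subcriterion",
    "CriterionNode",
    "CriteriaTree",
    "LikertResponseSet",
    "SpecialistScoreMatrix",
    "validate_tree",
    "aggregate_likert_mean",
    "aggregate_specialist_sum",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding for display (3.455 -> 3.46, not banker's)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Subcriterion:
    id: str
    label: str = ""


@dataclass(frozen=True)
class CriterionNode:
    id: str
    label: str = ""
    subcriteria: tuple[Subcriterion, ...] = ()


class CriteriaTree:
    """Two-level hierarchy: criteria, each owning ordered subcriteria."""

    def __init__(self, criteria: Sequence[CriterionNode]):
        self.criteria = tuple(criteria)
        crit_ids = [c.id for c in self.criteria]
        if len(set(crit_ids)) != len(crit_ids):
            raise ValueError("duplicate criterion ids in tree")
        leaves = [s.id for c in self.criteria for s in c.subcriteria]
        if len(set(leaves)) != len(leaves):
            dupes = sorted({l for l in leaves if leaves.count(l) > 1})
            raise ValueError(f"subcriterion ids shared between criteria: {dupes}")
        self._leaf_parent = {
            s.id: c.id for c in self.criteria for s in c.subcriteria
        }

    @property
    def criterion_ids(self) -> list[str]:
        return [c.id for c in self.criteria]

    @property
    def leaf_ids(self) -> list[str]:
        return [s.id for c in self.criteria for s in c.subcriteria]

    def parent_of(self, leaf: str) -> str:
        return self._leaf_parent[leaf]

    def n_leaves(self) -> int:
        return len(self._leaf_parent)

    def leaves_under(self, criterion: str) -> list[str]:
        for c in self.criteria:
            if c.id == criterion:
                return [s.id for s in c.subcriteria]
        raise KeyError(criterion)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "criteria": [
                {
                    "id": c.id,
                    "label": c.label,
                    "subcriteria": [
                        {"id": s.id, "label": s.label} for s in c.subcriteria
                    ],
                }
                for c in self.criteria
            ]
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "CriteriaTree":
        return cls(
            [
                CriterionNode(
                    c["id"],
                    c.get("label", ""),
                    tuple(
                        Subcriterion(s["id"], s.get("label", ""))
                        for s in c["subcriteria"]
                    ),
                )
                for c in d["criteria"]
            ]
        )

    @classmethod
    def from_json(cls, source: str | Path) -> "CriteriaTree":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(json.loads(text))

    def __repr__(self):
        return f"CriteriaTree({len(self.criteria)} criteria, {self.n_leaves()} subcriteria)"


def validate_tree(tree: CriteriaTree, approved: Iterable[str]) -> CriteriaTree:
    """Prune the tree to the subcriteria approved by the decision group.

    Criteria left with no approved subcriterion are dropped entirely.
    """
    approved = set(approved)
    unknown = approved - set(tree.leaf_ids)
    if unknown:
        raise ValueError(f"approved ids not in tree: {sorted(unknown)}")
    pruned = []
    for c in tree.criteria:
        subs = tuple(s for s in c.subcriteria if s.id in approved)
        if subs:
            pruned.append(CriterionNode(c.id, c.label, subs))
    return CriteriaTree(pruned)


class LikertResponseSet:
    """Respondent x subcriterion integer scores on a bounded Likert scale."""

    def __init__(
        self,
        scores: pd.DataFrame | Mapping,
        scale: tuple[int, int] = (1, 5),
    ):
        if not isinstance(scores, pd.DataFrame):
            scores = pd.DataFrame(scores)
        if scores.empty:
            raise ValueError("empty response set")
        lo, hi = scale
        bad = scores.stack().pipe(lambda s: s[(s < lo) | (s > hi)])
        if len(bad):
            raise ValueError(
                f"scores outside Likert scale [{lo}, {hi}]: "
                f"{bad.index.tolist()[:5]}"
            )
        self.scores = scores  # rows: respondents, columns: subcriteria
        self.scale = scale

    @classmethod
    def from_long(cls, df: pd.DataFrame, scale=(1, 5)) -> "LikertResponseSet":
        """Build from long-format columns (respondent, subcriterion, score)."""
        wide = df.pivot(index="respondent", columns="subcriterion", values="score")
        na = wide.isna()
        if na.any().any():
            missing = [(r, c) for r in na.index for c in na.columns if na.loc[r, c]]
            raise ValueError(f"missing responses: {missing[:5]}")
        return cls(wide, scale)


def aggregate_likert_mean(responses: LikertResponseSet) -> pd.Series:
    """Arithmetic mean rating per subcriterion over all respondents."""
    return responses.scores.mean(axis=0)


class SpecialistScoreMatrix:
    """Alternative x subcriterion scores on the 0-5 quality scale."""

    def __init__(self, scores: pd.DataFrame, scale: tuple[float, float] = (0, 5)):
        if not isinstance(scores, pd.DataFrame):
            scores = pd.DataFrame(scores)
        lo, hi = scale
        vals = scores.to_numpy(dtype=float)
        if ((vals < lo) | (vals > hi)).any():
            raise ValueError(f"specialist scores must lie in [{lo}, {hi}]")
        self.scores = scores  # rows: alternatives, columns: subcriteria
        self.scale = scale

    @classmethod
    def from_long(cls, df: pd.DataFrame, scale=(0, 5)) -> "SpecialistScoreMatrix":
        """Build from long-format columns (alternative, subcriterion, score).

        Row/column order follows first appearance in the file.
        """
        wide = df.pivot(index="alternative", columns="subcriterion", values="score")
        wide = wide.reindex(
            index=df["alternative"].drop_duplicates(),
            columns=df["subcriterion"].drop_duplicates(),
        )
        na = wide.isna()
        if na.any().any():
            missing = [(r, c) for r in na.index for c in na.columns if na.loc[r, c]]
            raise ValueError(f"missing (alternative, subcriterion) cells: {missing[:5]}")
        return cls(wide, scale)

    @property
    def alternative_ids(self) -> list[str]:
        return list(self.scores.index)


def aggregate_specialist_sum(
    scores: SpecialistScoreMatrix,
    tree: CriteriaTree,
    *,
    leaf_weights: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Criterion-level consequence matrix from subcriterion scores.

    Each (alternative, criterion) entry is the sum of the alternative's
    scores over that criterion's subcriteria.  ``leaf_weights`` optionally
    turns this into a weighted sum (e.g. nurse relevance means); by default
    every subcriterion counts equally with weight 1.
    """
    missing = set(tree.leaf_ids) - set(scores.scores.columns)
    if missing:
        raise ValueError(f"score matrix missing subcriteria: {sorted(missing)}")
    cols = {}
    for crit in tree.criterion_ids:
        leaves = tree.leaves_under(crit)
        block = scores.scores[leaves]
        if leaf_weights is not None:
            w = pd.Series({l: float(leaf_weights[l]) for l in leaves})
            cols[crit] = block.mul(w, axis=1).sum(axis=1)
        else:
            cols[crit] = block.sum(axis=1)
    return pd.DataFrame(cols, index=scores.scores.index)


def problem_from_scores(
    scores: SpecialistScoreMatrix,
    tree: CriteriaTree,
    *,
    leaf_weights: Mapping[str, float] | None = None,
) -> DecisionProblem:
    """Aggregate and wrap into a :class:`DecisionProblem` in one step."""
    matrix = aggregate_specialist_sum(scores, tree, leaf_weights=leaf_weights)
    return DecisionProblem(list(matrix.index), list(matrix.columns), matrix)
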