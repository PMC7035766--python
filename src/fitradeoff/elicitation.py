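"""Interactive elicitation loop.

The session alternates between shrinking the weight space with answered
tradeoff questions and re-filtering the alternatives for potential
optimality, stopping when a single alternative survives, the questioner is
exhausted, or a question cap is reached.  The question generator is a
bisection strategy: among the ranked criterion pairs it picks the one whose
feasible ratio interval k_lower / k_upper is widest and asks about its
midpoint, so each answer halves that interval and the polytope contracts
geometrically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Iterable, Literal, Protocol, Sequence

import numpy as np

from .dominance import PotentialOptimalSet, filter_potentially_optimal
from .weights import (
    DEFAULT_DELTA,
    DEFAULT_INDIFF_TOL,
    TradeoffStatement,
    WeightBounds,
    WeightSpace,
    ratio_bounds,
    space_from_ranking,
    weight_bounds,
)

__all__ = [
    "Question",
    "Answer",
    "SessionConfig",
    "SessionRecord",
    "SessionLog",
    "Recommendation",
    "ScriptedAnswers",
    "SimulatedDM",
    "next_question",
    "run_session",
]

Answer = Literal["a", "b", "indifferent"]


@dataclass(frozen=True)
class Question:
    """A tradeoff question on a ranked criterion pair.

    Consequence A: hypothetical level on ``upper`` with normalized value
    ``level``, worst on every other criterion.  Consequence B: best on
    ``lower``, worst elsewhere.  ``level`` must lie strictly in (0, 1).
    """

    upper: str
    lower: str
    level: float

    def __post_init__(self):
        if not 0.0 < self.level < 1.0:
            raise ValueError(f"question level must be in (0, 1), got {self.level}")

    def statement(self, answer: Answer) -> TradeoffStatement:
        return TradeoffStatement(self.upper, self.lower, self.level, answer)

    def render(self) -> str:
        return (
            f"Which do you prefer?\n"
            f"  (A) {self.upper} at {self.level:.4f} of its range, worst elsewhere\n"
            f"  (B) best on {self.lower}, worst elsewhere\n"
            f"  (I) indifferent"
        )


@dataclass
class SessionConfig:
    """Tunables of an elicitation session."""

    delta: float = DEFAULT_DELTA
    indiff_tol: float = DEFAULT_INDIFF_TOL
    max_questions: int = 50
    strategy: str = "bisection"
    #: ratio intervals narrower than this are considered resolved and are
    #: not asked about again (floor keeps the delta-closed cuts feasible)
    min_ratio_width: float = 1e-5

    def __post_init__(self):
        if self.max_questions < 0:
            raise ValueError("max_questions must be >= 0")
        if self.min_ratio_width < 8 * self.delta:
            self.min_ratio_width = 8 * self.delta


@dataclass(frozen=True)
class SessionRecord:
    question: Question
    answer: Answer
    n_survivors: int
    bounds: WeightBounds


@dataclass
class SessionLog:
    records: list[SessionRecord] = field(default_factory=list)

    def append(self, rec: SessionRecord) -> None:
        if self.records and rec.n_survivors > self.records[-1].n_survivors:
            raise ValueError("survivor count increased along the session")
        self.records.append(rec)

    def __len__(self):
        return len(self.records)

    def to_ndjson(self, path: str | Path | None = None) -> str:
        lines = []
        for r in self.records:
            lines.append(
                json.dumps(
                    {
                        "question": asdict(r.question),
                        "answer": r.answer,
                        "n_survivors": r.n_survivors,
                        "bounds": {
                            c: [lo, hi]
                            for c, lo, hi in zip(
                                r.bounds.criteria, r.bounds.lower, r.bounds.upper
                            )
                        },
                    },
                    sort_keys=True,
                )
            )
        text = "\n".join(lines) + ("\n" if lines else "")
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass(frozen=True)
class Recommendation:
    """Final answer of a session."""

    alternative: str
    value: float
    weights: dict[str, float]
    bounds: WeightBounds
    survivors: tuple[str, ...]
    termination: str
    n_questions: int

    def to_dict(self) -> dict:
        return {
            "alternative": self.alternative,
            "value": self.value,
            "weights": self.weights,
            "bounds": {
                c: [lo, hi]
                for c, lo, hi in zip(
                    self.bounds.criteria, self.bounds.lower, self.bounds.upper
                )
            },
            "survivors": list(self.survivors),
            "termination": self.termination,
            "n_questions": self.n_questions,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


# ---------------------------------------------------------------------------
# answer sources


class AnswerSource(Protocol):
    def answer(self, question: Question) -> Answer | None: ...


class ScriptedAnswers:
    """Replays a recorded session: a list of (criterion pair, answer).

    The pair sequence dictates which ratio each question probes; the
    hypothetical level itself is chosen live by the bisection rule
    (midpoint of the pair's current feasible ratio interval).
    """

    def __init__(self, entries: Sequence[tuple[tuple[str, str], Answer] | dict]):
        norm = []
        for e in entries:
            if isinstance(e, dict):
                pair, ans = tuple(e["pair"]), e["answer"]
            else:
                pair, ans = tuple(e[0]), e[1]
            ans = ans.lower()
            if ans not in ("a", "b", "indifferent"):
                raise ValueError(f"unknown scripted answer {ans!r}")
            norm.append((pair, ans))
        self.entries: list[tuple[tuple[str, str], Answer]] = norm
        self._pos = 0

    @classmethod
    def from_json(cls, source: str | Path) -> "ScriptedAnswers":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        data = json.loads(text)
        entries = data["answers"] if isinstance(data, dict) else data
        return cls(entries)

    @property
    def exhausted(self) -> bool:
        return self._pos >= len(self.entries)

    def next_pair(self) -> tuple[str, str] | None:
        if self.exhausted:
            return None
        return self.entries[self._pos][0]

    def answer(self, question: Question) -> Answer | None:
        if self.exhausted:
            return None
        pair, ans = self.entries[self._pos]
        if pair != (question.upper, question.lower):
            raise ValueError(
                f"scripted pair {pair} does not match question "
                f"({question.upper}, {question.lower})"
            )
        self._pos += 1
        return ans


class SimulatedDM:
    """A decision-maker answering consistently with hidden true weights.

    For a question (upper i, lower j, level v) it compares k_i * v with
    k_j: answers "a" if k_i * v exceeds k_j by more than the indifference
    band, "b" if it falls short by more than the band, else "indifferent".
    """

    def __init__(self, true_weights: dict[str, float], band: float = 0.0):
        if band < 0:
            raise ValueError("indifference band must be >= 0")
        self.true_weights = dict(true_weights)
        self.band = band

    def answer(self, question: Question) -> Answer:
        ki = self.true_weights[question.upper]
        kj = self.true_weights[question.lower]
        hypo = ki * question.level
        if hypo > kj + self.band:
            return "a"
        if hypo < kj - self.band:
            return "b"
        return "indifferent"


class CallableAnswers:
    """Adapts a plain callable(question) -> answer-or-None."""

    def __init__(self, fn: Callable[[Question], Answer | None]):
        self._fn = fn

    def answer(self, question: Question) -> Answer | None:
        return self._fn(question)


def _as_source(source) -> AnswerSource:
    if hasattr(source, "answer"):
        return source
    if callable(source):
        return CallableAnswers(source)
    if isinstance(source, (list, tuple)):
        return ScriptedAnswers(source)
    raise TypeError(f"cannot interpret {type(source).__name__} as an answer source")


# ---------------------------------------------------------------------------
# question generation


def _ranked_pairs(space: WeightSpace) -> list[tuple[str, str]]:
    crit = space.criteria
    return [(crit[i], crit[j]) for i in range(len(crit)) for j in range(i + 1, len(crit))]


def _midpoint_question(
    space: WeightSpace, pair: tuple[str, str]
) -> tuple[Question | None, float]:
    lo, hi = ratio_bounds(space, pair[0], pair[1])
    mid = 0.5 * (lo + hi)
    mid = min(max(mid, 1e-12), 1 - 1e-12)
    return Question(pair[0], pair[1], mid), hi - lo


def next_question(
    space: WeightSpace,
    problem=None,
    *,
    strategy: str = "bisection",
    min_ratio_width: float = 1e-5,
    survivors: Sequence[str] | None = None,
) -> Question | None:
    """Pick the next tradeoff question, or None if no pair is informative.

    The bisection strategy probes the ranked pair whose feasible ratio
    interval is widest, at its midpoint.  ``survivors`` (when given) must
    contain more than one alternative; asking with a single survivor is an
    error, the session is already decided.
    """
    if strategy != "bisection":
        raise ValueError(f"unknown strategy {strategy!r}")
    if survivors is not None and len(survivors) <= 1:
        raise ValueError("next_question called with a single surviving alternative")
    best, best_width = None, min_ratio_width
    for pair in _ranked_pairs(space):
        q, width = _midpoint_question(space, pair)
        if width > best_width:
            best, best_width = q, width
    return best


# ---------------------------------------------------------------------------
# session loop


def _recommend(
    pos: PotentialOptimalSet,
    bounds: WeightBounds,
    termination: str,
    n_questions: int,
) -> Recommendation:
    # several survivors: highest LP max value, ties broken by id
    chosen = min(pos.survivors, key=lambda a: (-pos.max_values[a], a))
    return Recommendation(
        alternative=chosen,
        value=pos.max_values[chosen],
        weights=pos.argmax_weights[chosen],
        bounds=bounds,
        survivors=pos.survivors,
        termination=termination,
        n_questions=n_questions,
    )


def run_session(
    problem,
    ranking: Sequence[str],
    answer_source,
    config: SessionConfig | None = None,
    *,
    on_question: Callable[[Question, Answer, int], None] | None = None,
) -> tuple[Recommendation, SessionLog]:
    """Run the elicitation loop to a recommendation.

    ``answer_source`` may be a :class:`ScriptedAnswers` (which also fixes
    the pair sequence), a :class:`SimulatedDM`, any object with an
    ``answer(question)`` method, a callable, or a list of scripted
    entries.  Returning ``None`` from the source ends the session.

    Inconsistent answers surface as
    :class:`~fitradeoff.weights.InconsistentStatementError` with the log
    accumulated so far attached as ``error.session_log``.
    """
    config = config or SessionConfig()
    source = _as_source(answer_source)
    space = space_from_ranking(
        ranking, delta=config.delta, indiff_tol=config.indiff_tol
    )
    pos = filter_potentially_optimal(space, problem)
    log = SessionLog()
    asked = 0
    termination = None
    while True:
        if len(pos.survivors) == 1:
            termination = "single survivor"
            break
        if asked >= config.max_questions:
            termination = "question limit reached"
            break
        scripted_pair = source.next_pair() if hasattr(source, "next_pair") else None
        if scripted_pair is not None:
            q, _ = _midpoint_question(space, scripted_pair)
        else:
            if hasattr(source, "next_pair"):  # scripted and exhausted
                termination = "answers exhausted"
                break
            q = next_question(
                space,
                problem,
                strategy=config.strategy,
                min_ratio_width=config.min_ratio_width,
            )
            if q is None:
                termination = "no informative question"
                break
        ans = source.answer(q)
        if ans is None:
            termination = "answers exhausted"
            break
        try:
            from .weights import add_statement

            space = add_statement(space, q.statement(ans))
        except Exception as err:
            err.session_log = log  # type: ignore[attr-defined]
            raise
        pos = filter_potentially_optimal(space, problem)
        asked += 1
        log.append(SessionRecord(q, ans, len(pos.survivors), weight_bounds(space)))
        if on_question is not None:
            on_question(q, ans, len(pos.survivors))
    bounds = weight_bounds(space)
    return _recommend(pos, bounds, termination, asked), log
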