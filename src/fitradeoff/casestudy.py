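"""Packaged triage-protocol case study.

Five internationally established emergency triage protocols (ATS, CTAS,
MTS, ESI, SET) are compared on four benefit criteria — Guidelines, Ease of
Evaluation, Ease of Use, Ease of Implementation — refined into 27
subcriteria.  The package ships the study's inputs as plain-text fixtures:
the criteria tree, the specialist's 0-5 subcriterion scores, the nurse
panel's Likert relevance means, the protocol/subcriterion coverage table,
the decision-makers' criteria ranking, and their recorded seven-answer
elicitation session.  Everything needed to replay the selection end to end
runs offline from here.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .aggregation import (
    CriteriaTree,
    SpecialistScoreMatrix,
    aggregate_specialist_sum,
)
from .elicitation import Recommendation, ScriptedAnswers, SessionConfig, SessionLog, run_session
from .model import DecisionProblem

__all__ = [
    "load_criteria_tree",
    "load_specialist_scores",
    "load_nurse_means",
    "load_protocol_profile",
    "load_ranking",
    "load_answer_script",
    "build_problem",
    "replay_session",
]

import json


def _data(name: str):
    return resources.files("fitradeoff.data") / name


def load_criteria_tree() -> CriteriaTree:
    """The validated criteria tree: 4 criteria, 27 subcriteria."""
    return CriteriaTree.from_dict(json.loads(_data("criteria_tree.json").read_text()))


def load_specialist_scores() -> SpecialistScoreMatrix:
    """Specialist's alternative x subcriterion scores (0-5 scale)."""
    with resources.as_file(_data("specialist_scores.csv")) as p:
        df = pd.read_csv(p)
    return SpecialistScoreMatrix.from_long(df)


def load_nurse_means() -> pd.Series:
    """Nurse panel's mean relevance rating per subcriterion (1-5 Likert).

    Covers the three criteria whose subcriteria touch the triage routine
    directly; these means informed the specialist qualitatively and do not
    enter the decision matrix numerically.
    """
    with resources.as_file(_data("nurse_means.csv")) as p:
        df = pd.read_csv(p)
    return df.set_index("subcriterion")["mean"]


def load_protocol_profile() -> pd.DataFrame:
    """Literature coverage of each subcriterion by each protocol
    (1 satisfactory, 0.5 sparse, 0 none).  Background fixture only."""
    with resources.as_file(_data("protocol_profile.csv")) as p:
        return pd.read_csv(p)


def _case() -> dict:
    return json.loads(_data("case_study.json").read_text())


def load_ranking() -> list[str]:
    """Decision-makers' importance ranking of the four criteria."""
    return list(_case()["ranking"])


def load_answer_script() -> ScriptedAnswers:
    """The recorded seven-answer session (criterion pairs and answers)."""
    return ScriptedAnswers(_case()["answers"])


def build_problem() -> DecisionProblem:
    """Aggregate specialist scores into the criterion-level decision problem."""
    matrix = aggregate_specialist_sum(load_specialist_scores(), load_criteria_tree())
    return DecisionProblem(list(matrix.index), list(matrix.columns), matrix)


def replay_session(
    config: SessionConfig | None = None,
) -> tuple[Recommendation, SessionLog]:
    """Replay the recorded session end to end and return the recommendation."""
    return run_session(
        build_problem(), load_ranking(), load_answer_script(), config
    )
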