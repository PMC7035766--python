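import itertools

import numpy as np
import pytest

from fitradeoff import DecisionProblem, casestudy, space_from_ranking

#: published criterion-level decision matrix of the triage study
#: (alternative -> scores for guidelines, ease_of_evaluation, ease_of_use,
#:  ease_of_implementation)
PUBLISHED_MATRIX = {
    "ATS": (25, 24, 17, 5),
    "CTAS": (15, 29, 20, 8),
    "MTS": (13, 10, 22, 12),
    "ESI": (15, 5, 13, 5),
    "SET": (10, 15, 26, 12),
}
MATRIX_COLUMNS = (
    "guidelines",
    "ease_of_evaluation",
    "ease_of_use",
    "ease_of_implementation",
)

#: final scale constants of the published session
FINAL_WEIGHTS = {
    "guidelines": 0.3058,
    "ease_of_use": 0.2676,
    "ease_of_implementation": 0.2389,
    "ease_of_evaluation": 0.1877,
}


@pytest.fixture(scope="session")
def case_problem():
    return casestudy.build_problem()


@pytest.fixture(scope="session")
def case_ranking():
    return casestudy.load_ranking()


@pytest.fixture()
def ranked_space(case_ranking):
    return space_from_ranking(case_ranking)


@pytest.fixture()
def zero_delta_space(case_ranking):
    return space_from_ranking(case_ranking, delta=0.0)


def random_problem(rng, n_alts=5, n_crits=4, lo=0, hi=30):
    """Small random integer problem with non-degenerate columns."""
    while True:
        mat = rng.integers(lo, hi + 1, size=(n_alts, n_crits))
        if (mat.min(axis=0) < mat.max(axis=0)).all():
            break
    return DecisionProblem(
        [f"a{i}" for i in range(n_alts)],
        [f"c{j}" for j in range(n_crits)],
        mat.astype(float),
    )


def ranked_grid(n, step=0.01):
    """All weight vectors k1 >= ... >= kn >= 0 summing to 1 on a grid."""
    total = round(1 / step)
    pts = []
    for combo in itertools.product(range(total, -1, -1), repeat=n - 1):
        rest = total - sum(combo)
        k = combo + (rest,)
        if rest >= 0 and all(k[i] >= k[i + 1] for i in range(n - 1)):
            pts.append(k)
    return np.array(pts, dtype=float) / total
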