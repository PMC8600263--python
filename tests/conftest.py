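import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from crosspas.io_formats import ExpressionMatrix, GeneSetCollection, SurvivalTable

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_expr() -> ExpressionMatrix:
    """3 genes x 4 samples; the worked PAS example.

    g1=[1,2,3,4], g2=[4,3,2,1], g3=[1,1,4,4] so the per-gene ±1 scores are
    (-1,-1,+1,+1), (+1,+1,-1,-1), (-1,-1,+1,+1).
    """
    return ExpressionMatrix(
        ["g1", "g2", "g3"],
        ["s1", "s2", "s3", "s4"],
        np.array([[1.0, 2, 3, 4], [4, 3, 2, 1], [1, 1, 4, 4]]),
    )


@pytest.fixture
def tiny_sets() -> GeneSetCollection:
    return GeneSetCollection({
        "PW_ALL": ("all three genes", frozenset({"g1", "g2", "g3"})),
        "PW_G1": ("single gene", frozenset({"g1"})),
    })


def make_survival(times, events, prefix="s") -> SurvivalTable:
    ids = [f"{prefix}{i + 1}" for i in range(len(times))]
    return SurvivalTable(ids, np.asarray(times, float), np.asarray(events))


@pytest.fixture
def survival_factory():
    return make_survival


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
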