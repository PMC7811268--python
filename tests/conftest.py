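import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from lipidregnet.lipidome import LipidomeMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def matrix_from_amounts(amounts: dict[str, dict[tuple[str, int], float]]
                        ) -> LipidomeMatrix:
    """Build a LipidomeMatrix from {species: {(condition, replicate): amount}}."""
    rows = [
        {"species": sp, "condition": cond, "replicate": rep, "amount": val}
        for sp, cells in amounts.items()
        for (cond, rep), val in cells.items()
    ]
    return LipidomeMatrix.from_long(pd.DataFrame(rows))


@pytest.fixture
def tiny_matrix() -> LipidomeMatrix:
    """Three classes, two conditions, two replicates; exact-arithmetic values."""
    return matrix_from_amounts({
        "TAG 52:3": {("NT", 1): 2.0, ("NT", 2): 2.0, ("LT", 1): 4.6, ("LT", 2): 4.6},
        "PC 34:1": {("NT", 1): 1.0, ("NT", 2): 1.0, ("LT", 1): 0.5, ("LT", 2): 0.5},
        "PC 36:2": {("NT", 1): 1.0, ("NT", 2): 1.0, ("LT", 1): 1.5, ("LT", 2): 1.5},
        "MGDG 36:6(18:3/18:3)": {("NT", 1): 2.0, ("NT", 2): 2.0,
                                 ("LT", 1): 2.0, ("LT", 2): 2.0},
    })


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic lipidome (seed 7), shared across read-only tests."""
    from lipidregnet.simulate import default_lipidome_spec, simulate_lipidome

    return simulate_lipidome(default_lipidome_spec(seed=7))


@pytest.fixture(scope="session")
def default_expression():
    from lipidregnet.simulate import default_expression_spec, simulate_expression

    return simulate_expression(default_expression_spec(seed=7))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
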