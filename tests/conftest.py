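import numpy as np
import pandas as pd
import pytest

from brcadel.containers import ExpressionMatrix
from brcadel.simulate import CohortConfig


@pytest.fixture
def small_config():
    """Compact cohort: quick to simulate, still spans deleted + neutral bands."""
    return CohortConfig(
        n_case=6, n_control=8,
        genome=(
            ("13", "13q13", 8, 6, 20), ("13", "13q14", 8, 6, 20),
            ("13", "13q21", 8, 6, 20),
            ("14", "14q24", 8, 6, 20), ("14", "14q31", 8, 6, 20),
            ("2", "2p12", 8, 6, 20), ("2", "2q23", 8, 6, 20),
        ),
        deleted_regions=(("13", "13q13", "13q14"), ("14", "14q24", "14q31")),
        tumor_fraction_range=(0.8, 0.95),
        seed=11,
    )


@pytest.fixture
def two_group_matrix():
    rng = np.random.default_rng(0)
    n1, n2, g = 5, 6, 30
    values = rng.normal(7, 1, size=(g, n1 + n2)) * rng.uniform(0.5, 2, size=(g, 1))
    samples = [f"s{i}" for i in range(n1 + n2)]
    labels = pd.Series(["BRCA2"] * n1 + ["BRCAX"] * n2, index=samples)
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=[f"g{i}" for i in range(g)], columns=samples),
        labels=labels,
    )
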