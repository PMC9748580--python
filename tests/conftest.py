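"""Shared fixtures: tiny simulated datasets and hand-built tables."""

import numpy as np
import pandas as pd
import pytest

from mglmmvb import (
    MarkerSpec,
    build_design,
    read_long_table,
    scenario_truth,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def gaussian_design_small():
    """Three Gaussian markers, 8 subjects — small enough for the dense path."""
    truth = scenario_truth(1)
    dataset, u = simulate_dataset(truth, m=8, seed=3)
    return build_design(dataset), truth, u


@pytest.fixture(scope="session")
def mixed_design_small():
    """Gaussian + Poisson + Bernoulli markers, 8 subjects."""
    truth = scenario_truth(2)
    dataset, u = simulate_dataset(truth, m=8, seed=5)
    return build_design(dataset), truth, u


@pytest.fixture
def one_marker_table():
    """One subject, one Gaussian marker, two visits."""
    return pd.DataFrame(
        {
            "subject": [1, 1],
            "marker": ["bilirubin", "bilirubin"],
            "time": [0.0, 1.0],
            "response": [1.2, 2.4],
        }
    )


@pytest.fixture
def one_marker_spec():
    return [
        MarkerSpec(
            name="bilirubin",
            family="gaussian",
            fixed=("intercept", "time"),
            random=("intercept",),
        )
    ]


def make_mixed_design(m=6, seed=0, scenario=2):
    truth = scenario_truth(scenario)
    dataset, _ = simulate_dataset(truth, m=m, seed=seed)
    return build_design(dataset)


@pytest.fixture
def two_marker_dataset():
    """Two markers with unequal design sizes on three subjects."""
    rng = np.random.default_rng(11)
    rows = []
    for s in range(3):
        for r, marker in enumerate(["hba1c", "ascites"]):
            for j in range(4 + s):
                rows.append(
                    {
                        "subject": s,
                        "marker": marker,
                        "time": j / 3.0,
                        "age": rng.normal(),
                        "response": rng.normal() if r == 0 else float(rng.random() < 0.5),
                    }
                )
    table = pd.DataFrame(rows)
    specs = [
        MarkerSpec("hba1c", "gaussian", fixed=("intercept", "time"), random=("intercept", "time")),
        MarkerSpec("ascites", "bernoulli", fixed=("intercept", "age"), random=("intercept",)),
    ]
    return read_long_table(table, specs), specs
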