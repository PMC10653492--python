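"""Shared fixtures: reference parameter sets, simulated cohorts, and the
replicated Monte Carlo study reused by the statistical tests.

Everything is generated programmatically from fixed seeds; nothing is read
from disk.
"""

from __future__ import annotations

import pytest

from ggfrailty import (
    Scenario,
    ThetaGG,
    build_life_table,
    run_mc_study,
    sample_lifespans,
)

THETA_HET = ThetaGG(a=0.0001, b=0.1, sigma2=0.2)
THETA_GOMP = ThetaGG(a=0.0001, b=0.1, sigma2=0.0)


@pytest.fixture(scope="session")
def gompertz_table():
    """Life table from a Gompertz cohort of 10,000 (no deceleration)."""
    return build_life_table(sample_lifespans(10_000, THETA_GOMP, rng_seed=101))


@pytest.fixture(scope="session")
def gg_table():
    """Life table from a gamma-Gompertz cohort of 10,000 (sigma2 = 0.2)."""
    return build_life_table(sample_lifespans(10_000, THETA_HET, rng_seed=202))


@pytest.fixture(scope="session")
def mc_study_200():
    """200-replicate ML+MAP study on the three reference scenarios.

    Session-scoped because it is by far the most expensive fixture; the
    bias/SD comparisons, the shrinkage property and the large-cohort
    recovery test all draw on the same replicate spread.
    """
    scenarios = [
        Scenario(ThetaGG(0.0001, 0.1, 0.2)),
        Scenario(ThetaGG(0.0001, 0.1, 0.8)),
        Scenario(ThetaGG(0.00001, 0.1, 0.8)),
    ]
    return run_mc_study(scenarios, reps=200, methods=("ML", "MAP"), seed=1234)


def summary_cell(study, scenario_label, method, parameter, column):
    row = study.summary[
        (study.summary.scenario == scenario_label)
        & (study.summary.method == method)
        & (study.summary.parameter == parameter)
    ]
    assert len(row) == 1
    return float(row[column].iloc[0])
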