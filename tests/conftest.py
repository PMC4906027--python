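"""Shared fixtures and helpers for the esmar test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from esmar.panel_io import LongPanel, StudyDesign
from esmar.dgp import ThreeLevelARParams, TwoLevelARParams, simulate_ar3

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_panel(rows, outcome_name="y"):
    """Build a LongPanel from (person, day, beep, y) tuples."""
    df = pd.DataFrame(rows, columns=["person", "day", "beep", "y"])
    return LongPanel(df, outcome_name=outcome_name)


def balanced_panel(n_persons, n_days, n_beeps, values=None):
    """A complete balanced panel with deterministic or supplied outcomes."""
    rows = []
    k = 0
    for p in range(1, n_persons + 1):
        for d in range(1, n_days + 1):
            for b in range(1, n_beeps + 1):
                y = values[k] if values is not None else float(10 * p + d + 0.1 * b)
                rows.append((p, d, b, y))
                k += 1
    return make_panel(rows)


@pytest.fixture(scope="session")
def small_3l_panel():
    """A small panel simulated from the three-level AR(1) process."""
    params = ThreeLevelARParams(50.0, 0.2, 0.15, 8.0, 0.15, 0.1, 5.0, 10.0, -0.3, -0.2, 0.1)
    return simulate_ar3(params, StudyDesign(12, 4, 6), np.random.default_rng(2024))


@pytest.fixture(scope="session")
def small_3l_lagged(small_3l_panel):
    from esmar.lagging import build_predictors

    return build_predictors(small_3l_panel)
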