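"""Shared fixtures: small synthetic cohorts and one trained risk network.

Heavier objects are session-scoped so the expensive steps (network training)
run once per test session.
"""

from __future__ import annotations

import numpy as np
import pytest

from aidmark import (
    CoxRiskNet,
    GeneratorConfig,
    Preprocessor,
    TrainConfig,
    generate_cohort,
)
from aidmark.preprocess import collapse_to_encoded


@pytest.fixture(scope="session")
def small_cohort():
    """1200-patient default cohort (20 mixed markers, 45% censoring, 20% missing)."""
    cfg = GeneratorConfig(n_patients=1200, seed=11)
    cohort, outcome, truth = generate_cohort(cfg)
    return cohort, outcome, truth


@pytest.fixture(scope="session")
def trained_bundle():
    """Linear 20-marker cohort (n=2000, 35% censoring) with a trained network.

    Returns (cohort, outcome, truth, preprocessor, expanded, results, rc, encoded).
    """
    cfg = GeneratorConfig(n_patients=2000, censor_rate=0.35, missing_rate=0.2, seed=42)
    cohort, outcome, truth = generate_cohort(cfg)
    pp = Preprocessor()
    expanded = pp.fit_transform(cohort)
    results = CoxRiskNet(expanded, outcome).fit(TrainConfig(seed=42))
    rc = results.explain()
    encoded = collapse_to_encoded(expanded)
    return cohort, outcome, truth, pp, expanded, results, rc, encoded


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
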