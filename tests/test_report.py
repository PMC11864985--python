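"""Survival reports: KM estimation, risk groups, explainable KM, clinician guide."""

import numpy as np
import pandas as pd
import pytest

from aidmark import SurvivalOutcome, true_risk
from aidmark.lrp import RelevanceMatrix
from aidmark.report import (
    clinician_guide,
    explainable_km,
    km_estimate,
    plot_clinician_guide,
    plot_km_curves,
    risk_group_km,
)


def _outcome(time, event):
    """Bypass the >=1 event guard for degenerate report fixtures."""
    out = SurvivalOutcome.__new__(SurvivalOutcome)
    out.time = np.asarray(time, dtype=float)
    out.event = np.asarray(event, dtype=bool)
    out.endpoint = "OS"
    out.index = None
    return out


def brute_force_km(time, event):
    """Risk-set oracle: S(t) = prod over event times (1 - d/n)."""
    times = np.unique(time[event])
    surv = []
    s = 1.0
    for t in times:
        at_risk = (time >= t).sum()
        deaths = ((time == t) & event).sum()
        s *= 1 - deaths / at_risk
        surv.append(s)
    return times, np.array(surv)


class TestKMEstimate:
    def test_three_events_product_limit(self):
        km = km_estimate(_outcome([1, 2, 3], [1, 1, 1]))
        assert km.survival_at(1) == pytest.approx(2 / 3)
        assert km.survival_at(2) == pytest.approx(1 / 3)
        assert km.survival_at(3) == pytest.approx(0.0)

    def test_censoring_shrinks_risk_set(self):
        """Hand oracle: censored at 1, events at 2 and 3 -> S(2)=1/2, S(3)=0."""
        km = km_estimate(_outcome([1, 2, 3], [0, 1, 1]))
        assert km.survival_at(2) == pytest.approx(0.5)
        assert km.survival_at(3) == pytest.approx(0.0)

    def test_all_censored_flat_curve(self):
        km = km_estimate(_outcome([5, 8, 2], [0, 0, 0]))
        assert (km.survival == 1.0).all()
        assert km.median == np.inf

    def test_matches_brute_force_on_random_small_cohorts(self, rng):
        for _ in range(50):
            n = rng.integers(1, 21)
            time = rng.integers(1, 10, size=n).astype(float)
            event = rng.random(n) < 0.6
            km = km_estimate(_outcome(time, event))
            times, surv = brute_force_km(time, event)
            for t, s in zip(times, surv):
                assert km.survival_at(t) == pytest.approx(s)

    def test_survival_monotone_from_one(self, rng):
        km = km_estimate(_outcome(rng.exponential(5, 40), rng.random(40) < 0.5))
        assert km.survival_at(0) == 1.0
        assert (np.diff(km.survival) <= 1e-12).all()


class TestRiskGroupKM:
    def test_group_medians_monotone_on_true_risk(self, small_cohort):
        cohort, outcome, truth = small_cohort
        risks = true_risk(cohort, truth)
        curves, groups = risk_group_km(risks, outcome, k=5)
        medians = [c.median for c in curves]
        finite = [m for m in medians if np.isfinite(m)]
        # higher risk group -> shorter median survival
        assert all(a >= b for a, b in zip(finite, finite[1:]))

    def test_single_group_is_pooled_km(self, small_cohort):
        _, outcome, _ = small_cohort
        curves, _ = risk_group_km(np.random.default_rng(0).normal(size=len(outcome)),
                                  outcome, k=1)
        pooled = km_estimate(outcome)
        np.testing.assert_allclose(curves[0].survival, pooled.survival)

    def test_group_sizes_near_equal(self, small_cohort):
        _, outcome, _ = small_cohort
        _, groups = risk_group_km(np.random.default_rng(1).normal(size=len(outcome)),
                                  outcome, k=5)
        counts = np.bincount(groups.group)[1:]
        assert counts.max() - counts.min() <= 1

    def test_plot_writes_file(self, small_cohort, tmp_path):
        _, outcome, truth = small_cohort
        curves, _ = risk_group_km(truth.linear_predictor.to_numpy(), outcome, k=3)
        plot_km_curves(curves, tmp_path / "km.png")
        assert (tmp_path / "km.png").stat().st_size > 0


def _rc_fixture(n=120, seed=0):
    rng = np.random.default_rng(seed)
    time = np.sort(rng.exponential(100, size=n))
    event = rng.random(n) < 0.7
    event[0] = True
    rc = pd.DataFrame({
        "grows": np.arange(n, dtype=float) / n,          # |RC| rises with OS rank
        "flat": np.full(n, 0.4),
        "noisy": rng.normal(size=n),
    })
    out = SurvivalOutcome(time, event)
    rel = RelevanceMatrix(rc=rc, bias_absorbed=pd.Series(0.0, index=rc.index),
                          risk=rc.sum(axis=1))
    return rel, out


class TestExplainableKM:
    def test_monotone_marker_scaled_zero_to_one(self):
        rel, out = _rc_fixture()
        df = explainable_km(rel, out, markers=["grows"], min_patients=10)
        line = df[df["marker"] == "grows"]["mi_scaled"].to_numpy()
        assert line[0] == pytest.approx(0.0, abs=1e-9)
        assert line[-1] == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(line) >= -1e-9).all()

    def test_constant_marker_flat_zero(self):
        rel, out = _rc_fixture()
        df = explainable_km(rel, out, markers=["flat"], min_patients=10)
        assert (df[df["marker"] == "flat"]["mi_scaled"] == 0.0).all()

    def test_sparse_marker_excluded(self):
        rel, out = _rc_fixture()
        mask = pd.DataFrame(False, index=rel.rc.index, columns=rel.rc.columns)
        deceased = np.flatnonzero(out.event)
        mask.loc[deceased[39:], "noisy"] = True  # present in only 39 deceased
        df = explainable_km(rel, out, markers=["noisy"], mask=mask, min_patients=40)
        assert "noisy" not in set(df["marker"]) - {"__km__"}

    def test_recency_window_filter(self):
        rel, out = _rc_fixture()
        age = pd.DataFrame(0.0, index=rel.rc.index, columns=rel.rc.columns)
        age["noisy"] = 10_000.0  # stale measurements everywhere
        df = explainable_km(rel, out, markers=["noisy"], measurement_age=age,
                            min_patients=10)
        assert "noisy" not in set(df["marker"]) - {"__km__"}

    def test_marker_order_invariance(self):
        rel, out = _rc_fixture()
        a = explainable_km(rel, out, markers=["grows", "noisy"], min_patients=10)
        b = explainable_km(rel, out, markers=["noisy", "grows"], min_patients=10)
        for m in ("grows", "noisy"):
            np.testing.assert_allclose(a[a["marker"] == m]["mi_scaled"],
                                       b[b["marker"] == m]["mi_scaled"])

    def test_km_overlay_present(self):
        rel, out = _rc_fixture()
        df = explainable_km(rel, out, markers=["grows"], min_patients=10)
        assert "__km__" in set(df["marker"])

    def test_requires_deceased(self):
        rel, out = _rc_fixture()
        with pytest.raises(ValueError, match="deceased"):
            explainable_km(rel, _outcome(out.time, np.zeros(len(out.time))), markers=["grows"])


@pytest.fixture(scope="module")
def guide_inputs(small_cohort):
    cohort, outcome, truth = small_cohort
    risks = true_risk(cohort, truth)
    rc = pd.DataFrame(np.random.default_rng(2).normal(size=cohort.values.shape),
                      index=cohort.values.index, columns=cohort.values.columns)
    rel = RelevanceMatrix(rc=rc, bias_absorbed=pd.Series(0.0, index=rc.index),
                          risk=pd.Series(risks, index=rc.index))
    return cohort, outcome, rel, risks


class TestClinicianGuide:
    def test_profile_sorted_and_present_only(self, guide_inputs):
        cohort, outcome, rel, risks = guide_inputs
        g = clinician_guide(5, cohort, rel, risks, outcome)
        assert (np.diff(g.profile["rc"]) <= 1e-12).all()
        assert not g.profile["value"].isna().any()
        assert len(g.profile) == (~cohort.values.loc[5].isna()).sum()

    def test_similar_set_contains_patient(self, guide_inputs):
        cohort, outcome, rel, risks = guide_inputs
        g = clinician_guide(5, cohort, rel, risks, outcome, n_similar=100)
        assert g.n_similar == 100
        # the nearest-risk neighbourhood always contains the patient: its own
        # distance is zero, so the reported median uses it
        order = np.argsort(np.abs(risks - risks[5]), kind="stable")[:100]
        assert 5 in order

    def test_small_cohort_uses_everyone(self, guide_inputs):
        cohort, outcome, rel, risks = guide_inputs
        sub = cohort.values.index[:50]
        small = cohort.values.loc[sub]
        from aidmark.cohort import CohortTable

        small_cohort_obj = CohortTable(values=small, schema=cohort.schema,
                                       entity=cohort.entity.loc[sub])
        rel_small = RelevanceMatrix(rc=rel.rc.loc[sub],
                                    bias_absorbed=rel.bias_absorbed.loc[sub],
                                    risk=rel.risk.loc[sub])
        g = clinician_guide(5, small_cohort_obj, rel_small, risks[:50],
                            outcome.subset(np.arange(50)))
        assert g.n_similar == 50

    def test_identical_patients_identical_guides(self, guide_inputs):
        cohort, outcome, rel, risks = guide_inputs
        # clone patient 5's data onto patient 6
        vals = cohort.values.copy()
        vals.loc[6] = vals.loc[5]
        from aidmark.cohort import CohortTable

        c2 = CohortTable(values=vals, schema=cohort.schema, entity=cohort.entity)
        rc2 = rel.rc.copy()
        rc2.loc[6] = rc2.loc[5]
        risks2 = risks.copy()
        risks2[6] = risks2[5]
        rel2 = RelevanceMatrix(rc=rc2, bias_absorbed=rel.bias_absorbed,
                               risk=pd.Series(risks2, index=rc2.index))
        g5 = clinician_guide(5, c2, rel2, risks2, outcome)
        g6 = clinician_guide(6, c2, rel2, risks2, outcome)
        assert g5.risk == g6.risk
        np.testing.assert_allclose(g5.profile["rc"], g6.profile["rc"])
        assert g5.median_survival_similar == g6.median_survival_similar

    def test_plot_writes_file(self, guide_inputs, tmp_path):
        cohort, outcome, rel, risks = guide_inputs
        g = clinician_guide(3, cohort, rel, risks, outcome)
        plot_clinician_guide(g, tmp_path / "guide.png")
        assert (tmp_path / "guide.png").stat().st_size > 0
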