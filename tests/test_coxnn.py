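"""Risk network: Cox loss, training schedule, concordance, cross-validation."""

import numpy as np
import pandas as pd
import pytest

from aidmark import (
    CoxRiskNet,
    GeneratorConfig,
    Preprocessor,
    SurvivalOutcome,
    TrainConfig,
    build_network,
    concordance,
    cross_validate,
    generate_cohort,
    true_risk,
)
from aidmark.cohort import CohortTable, MarkerSpec
from aidmark.coxnn import CoxNet, cox_partial_loss_grad, merge_small_entities


def naive_cox_loss(scores, time, event):
    """Independent O(n^2) oracle: Breslow negative partial log-likelihood / events."""
    ll = 0.0
    for i in range(len(time)):
        if event[i]:
            risk_set = scores[time >= time[i]]
            ll += scores[i] - np.log(np.exp(risk_set).sum())
    return -ll / event.sum()


class TestCoxLoss:
    def test_matches_naive_enumeration(self, rng):
        for trial in range(20):
            n = rng.integers(3, 40)
            time = rng.integers(1, 8, size=n).astype(float)  # plenty of ties
            event = rng.random(n) < 0.7
            if event.sum() == 0:
                continue
            s = rng.normal(size=n)
            loss, _ = cox_partial_loss_grad(s, time, event)
            assert loss == pytest.approx(naive_cox_loss(s, time, event), rel=1e-10)

    def test_gradient_matches_finite_differences(self, rng):
        n = 25
        time = rng.integers(1, 6, size=n).astype(float)
        event = rng.random(n) < 0.6
        event[0] = True
        s = rng.normal(size=n)
        _, grad = cox_partial_loss_grad(s, time, event)
        eps = 1e-6
        for j in range(0, n, 5):
            sp, sm = s.copy(), s.copy()
            sp[j] += eps
            sm[j] -= eps
            num = (cox_partial_loss_grad(sp, time, event)[0]
                   - cox_partial_loss_grad(sm, time, event)[0]) / (2 * eps)
            assert grad[j] == pytest.approx(num, abs=1e-6)

    def test_requires_events(self):
        with pytest.raises(ValueError, match="event"):
            cox_partial_loss_grad(np.zeros(3), np.arange(3.0), np.zeros(3, bool))


class TestNetwork:
    def test_hidden_width_is_ten_times_input(self):
        net = build_network(20, seed=0)
        assert net.hidden_width == 200 and net.input_width == 20

    def test_same_seed_same_weights(self):
        a, b = build_network(7, seed=3), build_network(7, seed=3)
        np.testing.assert_array_equal(a.W1, b.W1)
        np.testing.assert_array_equal(a.W2, b.W2)

    def test_zero_input_zero_bias_gives_zero_risk(self):
        net = build_network(5, seed=0)
        net.b1[:] = 0.0
        net.b2 = 0.0
        assert net.predict_risk(np.zeros((1, 5)))[0] == 0.0

    def test_zero_weights_constant_output(self):
        net = CoxNet(W1=np.zeros((4, 40)), b1=np.zeros(40), W2=np.zeros(40), b2=1.7)
        assert np.allclose(net.predict_risk(np.random.default_rng(0).normal(size=(6, 4))), 1.7)

    def test_monotone_in_single_input_for_nonnegative_weights(self, rng):
        net = CoxNet(W1=rng.uniform(0, 1, size=(3, 30)), b1=np.zeros(30),
                     W2=rng.uniform(0, 1, size=30), b2=0.0)
        grid = np.linspace(-2, 2, 31)
        X = np.zeros((31, 3))
        X[:, 1] = grid
        risks = net.predict_risk(X)
        assert (np.diff(risks) >= -1e-12).all()

    def test_width_mismatch_rejected(self):
        with pytest.raises(ValueError, match="width"):
            build_network(4).predict_risk(np.zeros((2, 5)))

    def test_json_roundtrip(self, tmp_path):
        net = build_network(6, seed=1)
        net.to_json(tmp_path / "net.json")
        back = CoxNet.from_json(tmp_path / "net.json")
        np.testing.assert_array_equal(net.W1, back.W1)
        np.testing.assert_allclose(net.predict_risk(np.ones((1, 6))),
                                   back.predict_risk(np.ones((1, 6))))


class TestConcordance:
    def test_worked_example_five_sixths(self):
        """Brute force over all 6 comparable pairs of 4 uncensored patients."""
        out = SurvivalOutcome(np.array([1.0, 2, 3, 4]), np.ones(4, bool))
        assert concordance(np.array([4.0, 3, 1, 2]), out) == pytest.approx(5 / 6)

    def test_perfect_antiranking_scores_one(self):
        t = np.array([3.0, 1, 4, 2, 5])
        out = SurvivalOutcome(t, np.ones(5, bool))
        assert concordance(-t, out) == 1.0

    def test_all_tied_risks_score_half(self):
        out = SurvivalOutcome(np.array([1.0, 2, 3]), np.ones(3, bool))
        assert concordance(np.zeros(3), out) == 0.5

    def test_invariant_under_monotone_transform(self, rng):
        t = rng.exponential(size=50)
        out = SurvivalOutcome(t, rng.random(50) < 0.6)
        if not out.event.any():
            out.event[0] = True
        r = rng.normal(size=50)
        c = concordance(r, out)
        assert concordance(np.exp(r), out) == pytest.approx(c)
        assert concordance(3 * r + 5, out) == pytest.approx(c)

    def test_no_comparable_pairs_signalled(self):
        out = SurvivalOutcome(np.array([2.0, 3.0]), np.array([False, True]))
        # only the later patient has an event: no pair is comparable
        with pytest.raises(ValueError, match="comparable"):
            concordance(np.array([1.0, 2.0]), out)


class TestTraining:
    def test_strong_signal_reaches_oracle_band(self, trained_bundle):
        cohort, outcome, truth, pp, expanded, results, _, _ = trained_bundle
        c_model = results.concordance()
        assert c_model > 0.7
        # the model only sees observed values; the fair oracle zero-imputes
        # (the mean, after standardization) the 20% missing entries
        observed = truth.pre_missing.where(~cohort.values.isna(), 0.0)
        c_obs_oracle = concordance(
            observed.to_numpy() @ truth.beta.to_numpy(), outcome)
        assert c_model > c_obs_oracle - 0.05

    def test_pure_noise_cohort_near_chance(self):
        cfg = GeneratorConfig(n_patients=800, beta=np.zeros(20), missing_rate=0.0, seed=21)
        cohort, outcome, _ = generate_cohort(cfg)
        pp = Preprocessor()
        X = pp.fit_transform(cohort)
        res = CoxRiskNet(X, outcome).fit(TrainConfig(seed=21))
        cfg2 = GeneratorConfig(n_patients=800, beta=np.zeros(20), missing_rate=0.0, seed=22)
        cohort2, outcome2, _ = generate_cohort(cfg2)
        c = concordance(res.predict_risk(pp.transform(cohort2).matrix), outcome2)
        assert 0.45 <= c <= 0.55

    def test_fixed_seed_reproducible(self, small_cohort):
        cohort, outcome, _ = small_cohort
        X = Preprocessor().fit_transform(cohort)
        a = CoxRiskNet(X, outcome).fit(TrainConfig(seed=5))
        b = CoxRiskNet(X, outcome).fit(TrainConfig(seed=5))
        assert a.history["best_val_loss"] == b.history["best_val_loss"]
        np.testing.assert_array_equal(a.net.W1, b.net.W1)

    def test_best_weights_not_worse_than_any_epoch(self, trained_bundle):
        history = trained_bundle[5].history
        assert history["best_val_loss"] == pytest.approx(min(history["val_loss"]))

    def test_no_events_rejected(self):
        X = np.random.default_rng(0).normal(size=(50, 3))
        out = SurvivalOutcome(np.arange(1.0, 51), np.ones(50, bool))
        out.event[:] = False
        out.event[0] = True  # lone event ends up in one side of the split
        with pytest.raises(ValueError):
            CoxRiskNet(X, out).fit(TrainConfig(seed=0, epochs_per_stage=2))

    def test_summary_mentions_architecture(self, trained_bundle):
        s = trained_bundle[5].summary()
        assert "hidden width" in s and "concordance" in s


@pytest.fixture(scope="module")
def cv_result():
    cfg = GeneratorConfig(n_patients=900, seed=33)
    cohort, outcome, _ = generate_cohort(cfg)
    X = Preprocessor().fit_transform(cohort)
    return cross_validate(X, outcome, cohort.entity,
                          TrainConfig(seed=33, epochs_per_stage=15)), cohort, outcome


class TestCrossValidation:
    def test_each_patient_in_exactly_one_test_fold(self, cv_result):
        cv, cohort, _ = cv_result
        assert not cv.fold_of.index.duplicated().any()
        all_test = set(cv.fold_of.index)
        for sp in cv.splits:
            assert set(sp["test"]).issubset(set(range(cohort.n_patients)))
        # the five test splits are disjoint
        assert sum(len(sp["test"]) for sp in cv.splits) == len(all_test)

    def test_discard_rules_applied(self, cv_result):
        cv, _, _ = cv_result
        pe = cv.per_entity
        small = pe[(pe["n"] < 10) | (pe["events"] < 5)]
        assert (~small["kept"]).all()
        assert small["cindex"].isna().all()
        kept = pe[pe["kept"]]
        assert kept["cindex"].between(0, 1).all()

    def test_pan_cindex_within_bounds(self, cv_result):
        cv, _, _ = cv_result
        assert len(cv.pan_cindex) == 5
        assert all(0.0 <= c <= 1.0 for c in cv.pan_cindex)

    def test_small_entities_merged(self):
        e = pd.Series(["a"] * 50 + ["b"] * 3 + ["c"] * 47)
        merged = merge_small_entities(e, min_count=5)
        assert set(merged.unique()) == {"a", "c", "other"}
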