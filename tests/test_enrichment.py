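import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit
from sklearn.metrics import roc_auc_score

import dcenrich as d
from dcenrich.risk_models import FittedBinaryModel, ModelError


def _stub(label_ll_k_n):
    ll, k, n = label_ll_k_n
    return FittedBinaryModel(covariates=[], coef=np.empty(0), intercept=0.0,
                             log_likelihood=ll, n=n, k=k,
                             predicted=np.full(n, 0.5))


def _sim_fit(rng, n=500, b1=0.032, b2=0.0, rate=41 / 323):
    """Logistic cohort: GRACE-like score + optional true/null added marker."""
    g = rng.normal(97, 26, n)
    m = rng.normal(0, 1, n)
    b0 = float(logit(rate)) - b1 * 97
    y = (rng.random(n) < expit(b0 + b1 * g + b2 * m)).astype(int)
    if not 0 < y.sum() < n:
        return None
    base = d.fit_logistic(pd.DataFrame({"g": g}), y)
    full = d.fit_logistic(pd.DataFrame({"g": g, "m": m}), y)
    return base, full, y


class TestLRT:
    def test_identical_models_null_result(self, rng):
        base, _, _ = _sim_fit(rng)
        res = d.likelihood_ratio_test(base, base)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 1.0

    def test_null_added_marker_calibrated(self):
        rng = np.random.default_rng(11)
        rej = trials = 0
        for _ in range(1000):
            out = _sim_fit(rng, n=500, b2=0.0)
            if out is None:
                continue
            base, full, _ = out
            trials += 1
            rej += d.likelihood_ratio_test(full, base).p_value < 0.05
        assert 0.035 <= rej / trials <= 0.065

    def test_strong_marker_detected(self, rng):
        base, full, _ = _sim_fit(rng, n=4000, b2=1.0)
        res = d.likelihood_ratio_test(full, base)
        assert res.p_value < 1e-6 and res.df == 1

    def test_non_nested_rejected(self, rng):
        out1 = _sim_fit(rng)
        base, full, y = out1
        other = d.fit_logistic(
            pd.DataFrame({"z": np.arange(base.n, dtype=float)}), y)
        with pytest.raises(ModelError, match="nested"):
            d.likelihood_ratio_test(other, base)


class TestAICc:
    def test_single_model(self):
        t = d.aicc_table([("only", _stub((-100.0, 2, 300)))])
        assert t.rows[0]["delta"] == 0.0
        assert t.rows[0]["weight"] == pytest.approx(1.0)

    def test_loglik_difference_maps_to_delta(self):
        t = d.aicc_table([("a", _stub((-100.0, 2, 300))),
                          ("b", _stub((-105.0, 2, 300)))])
        assert t["b"]["delta"] == pytest.approx(10.0)
        assert t["a"]["weight"] / t["b"]["weight"] == pytest.approx(np.exp(5.0))

    def test_hand_computed_three_models(self):
        specs = [("m1", (-380.0, 2, 323)), ("m2", (-375.0, 3, 323)),
                 ("m3", (-371.0, 3, 323))]
        t = d.aicc_table([(lab, _stub(s)) for lab, s in specs])
        for lab, (ll, k, n) in specs:
            expect = -2 * ll + 2 * k + 2 * k * (k + 1) / (n - k - 1)
            assert t[lab]["aicc"] == pytest.approx(expect, abs=1e-9)
        assert sum(r["weight"] for r in t.rows) == pytest.approx(1.0, abs=1e-12)
        assert t.rows[0]["aicc"] == min(r["aicc"] for r in t.rows)
        assert t.rows[0]["weight"] == max(r["weight"] for r in t.rows)

    def test_small_sample_guard(self):
        with pytest.raises(ModelError, match="n - k - 1"):
            d.aicc_table([("bad", _stub((-10.0, 5, 6)))])


class TestNRI:
    def test_reference_counts_dc(self):
        # reported reclassification counts for adding DC to the score
        res = d.nri_from_counts(22, 19, 41, 123, 159, 282)
        assert res.nri_e == pytest.approx(0.073, abs=5e-4)
        assert res.nri_ne == pytest.approx(0.128, abs=5e-4)
        # the printed total (0.200) rounds the components before summing
        # (0.073 + 0.128 = 0.201); exact value is 3/41 + 36/282 = 0.20083
        assert res.nri == pytest.approx(3 / 41 + 36 / 282, abs=1e-12)
        assert res.nri == pytest.approx(0.200, abs=1e-3)

    def test_reference_counts_lfhf(self):
        res = d.nri_from_counts(20, 21, 41, 132, 150, 282)
        assert res.nri == pytest.approx(-1 / 41 + 18 / 282, abs=1e-12)
        assert res.nri == pytest.approx(0.040, abs=1e-3)

    def test_no_movement_zero(self):
        res = d.nri_from_counts(0, 0, 10, 0, 0, 10)
        assert res.nri == 0.0 and res.degenerate

    def test_identical_probabilities_zero(self, rng):
        p = rng.random(100)
        y = (rng.random(100) < 0.3).astype(int)
        assert d.continuous_nri(p, p, y).nri == 0.0

    def test_continuous_consistent_with_counts(self, rng):
        p_old = rng.random(200)
        p_new = p_old + rng.choice([-0.05, 0.0, 0.05], 200)
        y = (rng.random(200) < 0.3).astype(int)
        res = d.continuous_nri(p_old, p_new, y)
        ref = d.nri_from_counts(res.up_e, res.down_e, res.n_e,
                                res.up_ne, res.down_ne, res.n_ne)
        assert res.nri == ref.nri and res.nri_se == ref.nri_se
        assert res.up_e + res.down_e + res.tie_e == res.n_e
        assert res.up_ne + res.down_ne + res.tie_ne == res.n_ne

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            d.nri_from_counts(30, 20, 41, 0, 0, 10)


class TestIDI:
    def test_hand_example(self):
        p_old = [0.2, 0.4, 0.3, 0.1]
        p_new = [0.3, 0.5, 0.2, 0.1]
        y = [1, 1, 0, 0]
        res = d.idi(p_old, p_new, y)
        assert res.idi_e == pytest.approx(0.10)
        assert res.idi_ne == pytest.approx(0.05)
        assert res.idi == pytest.approx(0.15)

    def test_identical_probabilities_zero(self, rng):
        p = rng.random(60)
        y = (rng.random(60) < 0.4).astype(int)
        assert d.idi(p, p, y).idi == 0.0

    def test_slope_difference_equals_component_sum(self, rng):
        # the implementation asserts the two formulations agree to 1e-12;
        # exercise it on many random inputs
        for _ in range(20):
            n = int(rng.integers(20, 200))
            p_old, p_new = rng.random(n), rng.random(n)
            y = (rng.random(n) < 0.4).astype(int)
            if 0 < y.sum() < n:
                res = d.idi(p_old, p_new, y)
                assert res.idi == pytest.approx(res.idi_e + res.idi_ne,
                                                abs=1e-15)


class TestROC:
    def test_perfect_separation(self):
        score = np.r_[np.zeros(20), np.ones(20)]
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        roc = d.roc_analysis(score, y)
        assert roc.auc == 1.0
        assert roc.youden_j == pytest.approx(1.0)

    def test_youden_identity_reference_row(self):
        # sensitivity 48.8%, specificity 85.5% -> J = 0.343
        assert d.youden_index(0.488, 0.855) == pytest.approx(0.343, abs=5e-4)

    def test_null_score_auc_near_half(self, rng):
        score = rng.normal(size=2000)
        y = (rng.random(2000) < 0.3).astype(int)
        assert d.roc_analysis(score, y).auc == pytest.approx(0.5, abs=0.03)

    def test_mann_whitney_equals_trapezoidal(self, rng):
        score = rng.integers(0, 20, 500).astype(float)  # heavy ties
        y = (rng.random(500) < 0.35).astype(int)
        roc = d.roc_analysis(score, y)
        assert roc.auc == pytest.approx(roc_auc_score(y, score), abs=1e-10)

    def test_constant_score_degenerate(self):
        roc = d.roc_analysis(np.ones(50), np.r_[np.ones(10, int),
                                                np.zeros(40, int)])
        assert roc.degenerate and roc.auc == 0.5

    def test_harrells_c_attached_with_times(self, rng):
        n = 300
        score = rng.normal(size=n)
        t = rng.exponential(np.exp(-score))
        y = np.ones(n, int)
        roc = d.roc_analysis(score, y[: n // 2].tolist() + [0] * (n - n // 2),
                             times=t)
        assert roc.c_statistic is not None and 0.5 < roc.c_statistic <= 1.0

    def test_delong_vs_hanley_same_scale(self, rng):
        score = rng.normal(size=400)
        y = (rng.random(400) < expit(score)).astype(int)
        a = d.roc_analysis(score, y, se_method="delong")
        b = d.roc_analysis(score, y, se_method="hanley")
        assert a.auc_se == pytest.approx(b.auc_se, rel=0.5)

    def test_sensitivity_monotone_in_threshold(self, rng):
        score = rng.normal(size=300)
        y = (rng.random(300) < 0.3).astype(int)
        roc = d.roc_analysis(score, y)
        order = np.argsort(roc.thresholds)  # ascending thresholds
        assert np.all(np.diff(roc.sensitivity[order]) <= 1e-12)


class TestCalibration:
    def test_null_marker_type1_error(self):
        """NRI and IDI z-tests stay near nominal size for a pure-noise marker."""
        rng = np.random.default_rng(99)
        rej_nri = rej_idi = trials = 0
        for _ in range(400):
            out = _sim_fit(rng, n=323, b2=0.0)
            if out is None:
                continue
            base, full, y = out
            trials += 1
            rej_nri += d.continuous_nri(base.predicted, full.predicted,
                                        y).nri_p < 0.05
            rej_idi += d.idi(base.predicted, full.predicted, y).idi_p < 0.05
        assert 0.02 <= rej_nri / trials <= 0.08
        assert 0.02 <= rej_idi / trials <= 0.08

    def test_informative_marker_positive_gain(self):
        """A marker calibrated to a ~0.05 AUC gain yields NRI, IDI > 0."""
        rng = np.random.default_rng(17)
        pos = trials = 0
        for _ in range(100):
            out = _sim_fit(rng, n=323, b2=0.68)
            if out is None:
                continue
            base, full, y = out
            trials += 1
            pos += (d.continuous_nri(base.predicted, full.predicted, y).nri > 0
                    and d.idi(base.predicted, full.predicted, y).idi > 0)
        assert pos / trials >= 0.95


# ---------------------------------------------------------- property tests

from hypothesis import given, settings, strategies as st


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.floats(-400, -50), st.integers(2, 5)),
                min_size=1, max_size=6))
def test_akaike_weights_normalised_and_ordered(models):
    """Weights sum to 1 and the minimum-AICc model carries the maximum weight."""
    fits = [(f"m{i}", _stub((ll, k, 400))) for i, (ll, k) in enumerate(models)]
    table = d.aicc_table(fits)
    assert sum(r["weight"] for r in table.rows) == pytest.approx(1.0, abs=1e-12)
    assert table.rows[0]["delta"] == 0.0
    assert table.rows[0]["weight"] == max(r["weight"] for r in table.rows)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(0, 2**32 - 1))
def test_nri_counts_and_components_consistent(seed):
    """continuous_nri equals nri_from_counts applied to its own counted moves,
    and the movement counts exhaust each outcome class."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, 120))
    y = (rng.random(n) < 0.4).astype(int)
    if not 0 < y.sum() < n:
        return
    p_old = rng.random(n)
    p_new = np.where(rng.random(n) < 0.3, p_old, rng.random(n))  # some ties
    res = d.continuous_nri(p_old, p_new, y)
    ref = d.nri_from_counts(res.up_e, res.down_e, res.n_e,
                            res.up_ne, res.down_ne, res.n_ne)
    assert res.nri == ref.nri
    assert res.nri_e + res.nri_ne == pytest.approx(res.nri, abs=1e-15)
    assert res.up_e + res.down_e + res.tie_e == res.n_e
    assert res.up_ne + res.down_ne + res.tie_ne == res.n_ne
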