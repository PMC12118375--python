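import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import kneetray as kt
from kneetray.size_model import (MODEL_SIZES, PREDICTORS,
                                 FemoralSizeClassifier, merge_narrow,
                                 normalize_size, predict_probabilities,
                                 predict_size, reference_log_odds)

X0 = {"sex_female": 1.0, "height_cm": 168.0, "weight_kg": 82.0,
      "bmi": 29.1, "side_right": 0.0}


def _zero_model(classes=MODEL_SIZES):
    k = len(classes)
    return FemoralSizeClassifier.from_parameters(
        classes, np.zeros((k, 5)), np.zeros(k))


class TestSizeLabels:
    @pytest.mark.parametrize("raw,want", [
        (2.0, "2"), ("2.5", "2.5"), ("4n", "4N"), (4, "4"), ("1.5", "1.5")])
    def test_normalize(self, raw, want):
        assert normalize_size(raw) == want

    def test_unknown_size_rejected(self):
        with pytest.raises(ValueError):
            normalize_size("7")

    def test_narrow_merges_into_four(self):
        assert list(merge_narrow(["4N", "4", "3"])) == ["4", "4", "3"]


class TestPrediction:
    def test_zero_coefficients_give_uniform_probabilities(self):
        probs = predict_probabilities(_zero_model(), X0)
        assert np.allclose(probs, 1 / 7)

    def test_binary_logit_closed_form(self):
        slopes = np.array([[0.0] * 5, [0.3, 0.01, 0.02, -0.1, 0.2]])
        icept = np.array([0.0, -1.0])
        m = FemoralSizeClassifier.from_parameters(["3", "4"], slopes, icept)
        x = np.array([1.0, 170.0, 80.0, 27.7, 1.0])
        eta = icept[1] + slopes[1] @ x
        p = m.predict_proba(x.reshape(1, -1))[0]
        assert p[0] == pytest.approx(1 / (1 + np.exp(eta)))
        assert p[1] == pytest.approx(np.exp(eta) / (1 + np.exp(eta)))

    def test_three_class_softmax_matches_manual_arithmetic(self):
        slopes = np.array([[0.0] * 5,
                           [0.5, 0.05, -0.02, 0.03, 0.2],
                           [-0.7, 0.10, 0.01, -0.05, 0.1]])
        icept = np.array([0.0, -9.0, -17.0])
        m = FemoralSizeClassifier.from_parameters(["3", "4", "5"], slopes, icept)
        x = np.array([0.0, 172.0, 90.0, 30.4, 1.0])
        eta = icept + slopes @ x
        want = np.exp(eta) / np.exp(eta).sum()
        assert np.allclose(m.predict_proba(x.reshape(1, -1))[0], want)

    def test_argmax_prediction_and_tie_toward_smaller_size(self):
        m = FemoralSizeClassifier.from_parameters(
            ["3", "4"], np.zeros((2, 5)), np.array([0.0, -0.4]))
        assert predict_size(m, X0) == "3"
        tie = _zero_model(["2.5", "3"])
        assert predict_size(tie, X0) == "2.5"

    @given(st.integers(0, 2 ** 32 - 1))
    def test_probabilities_are_a_simplex(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 8))
        m = FemoralSizeClassifier.from_parameters(
            MODEL_SIZES[:k], rng.normal(0, 0.3, (k, 5)), rng.normal(0, 1, k))
        x = rng.normal([0.5, 168, 85, 30, 0.5], [0.5, 10, 15, 5, 0.5], (3, 5))
        p = m.predict_proba(x)
        assert np.all(p >= 0) and np.all(p <= 1)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-9)

    def test_height_monotonicity_of_linear_predictor(self):
        m = FemoralSizeClassifier.from_parameters(
            MODEL_SIZES, reference_log_odds().to_numpy(), np.zeros(7))
        lo = dict(X0, height_cm=160.0)
        hi = dict(X0, height_cm=175.0)
        k6 = list(m.classes_).index("6")
        eta = lambda d: m.decision_function(
            np.array([[d[p] for p in PREDICTORS]]))[0]
        assert eta(hi)[k6] > eta(lo)[k6]  # positive height slope for size 6

    def test_unfitted_model_raises(self):
        from sklearn.exceptions import NotFittedError
        with pytest.raises(NotFittedError):
            FemoralSizeClassifier().predict_proba(np.zeros((1, 5)))


class TestFit:
    def test_single_class_rejected(self):
        X = np.tile([1.0, 165, 80, 29.4, 0.0], (10, 1))
        with pytest.raises(ValueError, match="single class"):
            FemoralSizeClassifier().fit(X, ["3"] * 10)

    def test_missing_reference_falls_back_with_warning(self, small_cohort):
        sub = small_cohort[small_cohort["femur_size"].isin(["4", "5"])]
        with pytest.warns(UserWarning, match="reference"):
            m = kt.fit_size_model(sub)
        assert m.reference_used_ in {"4", "5"}

    def test_matches_statsmodels_on_well_conditioned_data(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(5)
        n = 4000
        X = pd.DataFrame({
            "sex_female": (rng.random(n) < 0.6).astype(float),
            "height_cm": rng.normal(169, 9, n),
            "weight_kg": rng.normal(85, 15, n),
            "bmi": rng.normal(30, 5, n),  # independent here: no collinearity
            "side_right": (rng.random(n) < 0.5).astype(float),
        })
        B = np.array([[0.0] * 5,
                      [0.5, 0.05, -0.02, 0.03, 0.2],
                      [-0.7, 0.10, 0.01, -0.05, 0.1]])
        a = np.array([0.0, -9.0, -17.0])
        eta = a + X.to_numpy() @ B.T
        p = np.exp(eta - eta.max(1, keepdims=True))
        p /= p.sum(1, keepdims=True)
        yi = (rng.random(n)[:, None] > p.cumsum(1)).sum(1)
        y = np.array(["3", "4", "5"])[yi]

        mine = FemoralSizeClassifier(ridge=0.0).fit(X, y)
        ref = sm.MNLogit(pd.Categorical(y, categories=["3", "4", "5"]).codes,
                         sm.add_constant(X.to_numpy())).fit(disp=0)
        got = np.column_stack(
            [np.r_[mine.intercept_[list(mine.classes_).index(c)],
                   mine.coef_[list(mine.classes_).index(c)]] for c in ["4", "5"]])
        assert np.abs(got - np.asarray(ref.params)).max() < 1e-5
        p1 = 6
        got_se = np.column_stack(
            [np.sqrt(np.diag(mine.covariance_)[j * p1:(j + 1) * p1]) for j in range(2)])
        assert np.abs(got_se[1:] - np.asarray(ref.bse)[1:]).max() < 1e-6

    def test_fit_beats_intercept_only_likelihood(self, small_cohort):
        m = kt.fit_size_model(small_cohort)
        X = kt.design_matrix(small_cohort)
        y = merge_narrow(small_cohort["femur_size"])
        counts = pd.Series(y).value_counts()
        ll_null = float((counts * np.log(counts / counts.sum())).sum())
        assert m.log_likelihood(X, y) > ll_null


class TestParameterRecovery:
    """Refit on 100,000 cases drawn from the known generating coefficients."""

    WELL_POPULATED = ["2", "2.5", "4", "5", "6"]  # >=500 expected cases

    def _errors(self, model):
        true = reference_log_odds()
        classes = list(model.classes_)
        rows = [classes.index(c) for c in self.WELL_POPULATED]
        est = model.coef_[rows]
        ref = true.loc[self.WELL_POPULATED].to_numpy()
        return est, ref

    def test_slopes_within_three_standard_errors(self, recovery_model):
        est, ref = self._errors(recovery_model)
        p1 = len(PREDICTORS) + 1
        classes = list(recovery_model.classes_)
        for c, e_row, r_row in zip(self.WELL_POPULATED, est, ref):
            j = recovery_model._others.index(c)
            for m_idx in range(len(PREDICTORS)):
                se = np.sqrt(recovery_model.covariance_[
                    j * p1 + 1 + m_idx, j * p1 + 1 + m_idx])
                assert abs(e_row[m_idx] - r_row[m_idx]) < 3 * se

    def test_aggregate_slope_error_below_ten_percent(self, recovery_model):
        est, ref = self._errors(recovery_model)
        assert np.linalg.norm(est - ref) / np.linalg.norm(ref) < 0.10

    def test_centered_intercepts_recovered(self, recovery_model, recovery_cohort):
        # compare at the same centering point (the training means)
        true_alpha = kt.cohort.calibrate_intercepts(kt.GeneratorConfig(n=0))
        B_true = reference_log_odds().to_numpy()
        center = recovery_model.center_
        classes = list(recovery_model.classes_)
        ref3 = classes.index("3")
        for c in self.WELL_POPULATED:
            k = classes.index(c)
            kt_idx = list(MODEL_SIZES).index(c)
            want = (true_alpha[c] + B_true[kt_idx] @ center
                    - (true_alpha["3"] + B_true[list(MODEL_SIZES).index("3")] @ center))
            got = (recovery_model.intercept_centered_[k]
                   - recovery_model.intercept_centered_[ref3])
            assert got == pytest.approx(want, abs=0.1)

    def test_height_effect_direction_for_largest_size(self, recovery_model):
        ors = recovery_model.odds_ratios()
        row = ors[(ors["size"] == "6") & (ors["predictor"] == "height_cm")]
        assert float(row["odds_ratio"].iloc[0]) > 1.0

    def test_predictive_recovery(self, recovery_model):
        # the identified quantity is the predictive distribution, which must
        # match the generating one even though individual collinear slopes
        # wander along the flat direction of the design
        from kneetray.cohort import _sample_predictors, calibrate_intercepts
        cfg = kt.GeneratorConfig(n=0)
        rng = np.random.default_rng(123)
        Xf = _sample_predictors(rng, cfg, 20_000)
        alpha = calibrate_intercepts(cfg)
        B = reference_log_odds().to_numpy()
        z = alpha.to_numpy() + Xf[list(PREDICTORS)].to_numpy() @ B.T
        z -= z.max(axis=1, keepdims=True)
        p_true = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
        p_fit = recovery_model.predict_proba(Xf[list(PREDICTORS)])
        assert list(recovery_model.classes_) == list(MODEL_SIZES)
        assert np.abs(p_fit - p_true).mean() < 0.01


class TestOddsRatiosAndSerialization:
    def test_definitional_odds_ratios(self):
        slopes = np.zeros((2, 5))
        slopes[1, 0] = np.log(2.0)
        m = FemoralSizeClassifier.from_parameters(["3", "4"], slopes, np.zeros(2))
        ors = m.odds_ratios().set_index("predictor")
        assert ors.loc["sex_female", "odds_ratio"] == pytest.approx(2.0)
        assert ors.loc["height_cm", "odds_ratio"] == pytest.approx(1.0)
        assert ors.attrs["ci_available"] is False

    def test_fitted_cis_bracket_the_estimate(self, small_cohort):
        m = kt.fit_size_model(small_cohort)
        ors = m.odds_ratios()
        assert ors.attrs["ci_available"]
        ok = (ors["ci_low"] <= ors["odds_ratio"]) & (ors["odds_ratio"] <= ors["ci_high"])
        assert ok.all()

    def test_json_round_trip(self, small_cohort):
        m = kt.fit_size_model(small_cohort)
        m2 = FemoralSizeClassifier.from_json(m.to_json())
        X = kt.design_matrix(small_cohort).head(20)
        assert np.allclose(m.predict_proba(X), m2.predict_proba(X))
        assert list(m2.classes_) == list(m.classes_)
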