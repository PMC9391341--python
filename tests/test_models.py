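"""Dose models: OLS/robust equivalences, recovery, prediction, model reduction."""

import numpy as np
import pytest

import raddose as rd
from raddose.models import build_design, irls_tukey
from raddose.simulate import true_net_signal_array

from conftest import PUB_B, PUB_K


def _synthetic_nd(k=PUB_K, doses=(2, 4, 6, 8, 10), times=(1.0, 2.0, 4.0), reps=3):
    dose = np.repeat([d for d in doses for _ in times], reps).astype(float)
    time = np.repeat(list(times) * len(doses), reps).astype(float)
    n = true_net_signal_array(dose, time, *k)
    return n, time, dose


class TestEq1Fit:
    def test_ols_equals_closed_form(self):
        rng = np.random.default_rng(4)
        n, time, dose = _synthetic_nd()
        dose = dose + rng.normal(0, 0.5, dose.size)
        fit = rd.fit_eq1(n, time, dose, loss="ols")
        X, _ = build_design(n, time)
        beta_oracle, *_ = np.linalg.lstsq(X, dose, rcond=None)
        np.testing.assert_allclose([fit.k1, fit.k2, fit.k3], beta_oracle, atol=1e-10)

    def test_robust_equals_ols_when_weights_all_one(self):
        """On noise-free data the MAD scale collapses and every bisquare
        weight is 1; the robust solution is exactly the OLS solution."""
        n, time, dose = _synthetic_nd()
        r = rd.fit_eq1(n, time, dose, loss="robust")
        o = rd.fit_eq1(n, time, dose, loss="ols")
        assert (r.k1, r.k2, r.k3) == (o.k1, o.k2, o.k3)

    def test_noiseless_recovery_to_six_decimals(self):
        n, time, dose = _synthetic_nd()
        for loss in ("robust", "ols"):
            fit = rd.fit_eq1(n, time, dose, loss=loss)
            np.testing.assert_allclose([fit.k1, fit.k2, fit.k3], PUB_K, atol=1e-6)
            assert fit.converged

    def test_robust_resists_outliers(self):
        rng = np.random.default_rng(7)
        n, time, dose = _synthetic_nd(reps=6)
        noisy = dose + rng.normal(0, 0.2, dose.size)
        noisy[::15] += 15.0  # gross contamination
        kr = rd.fit_eq1(n, time, noisy, loss="robust")
        ko = rd.fit_eq1(n, time, noisy, loss="ols")
        err_r = np.abs(np.array([kr.k1, kr.k2, kr.k3]) - PUB_K).sum()
        err_o = np.abs(np.array([ko.k1, ko.k2, ko.k3]) - PUB_K).sum()
        assert err_r < err_o

    def test_robust_close_to_ols_without_outliers(self):
        rng = np.random.default_rng(12)
        n, time, dose = _synthetic_nd(reps=10)
        noisy = dose + rng.normal(0, 0.3, dose.size)
        kr = rd.fit_eq1(n, time, noisy, loss="robust")
        ko = rd.fit_eq1(n, time, noisy, loss="ols")
        assert abs(kr.k1 - ko.k1) < ko.se_k1
        assert abs(kr.k2 - ko.k2) < ko.se_k2
        assert abs(kr.k3 - ko.k3) < ko.se_k3

    def test_degenerate_all_zero(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        fit = rd.fit_eq1(np.zeros(4), time, np.zeros(4), loss="ols")
        assert fit.k3 == pytest.approx(0.0, abs=1e-12)
        raw, _ = rd.predict_dose_eq1(fit, np.zeros(4), time)
        np.testing.assert_allclose(raw, 0.0, atol=1e-12)

    def test_input_validation(self):
        with pytest.raises(rd.ValidationError):
            rd.fit_eq1([1.0, 2.0], [1.0, 1.0], [1.0, 2.0])  # < 4 samples
        with pytest.raises(rd.ValidationError):
            rd.fit_eq1([1, 2, 3, 4], [1, 1, 1, 1], [5, 5, 5, 5])  # one nonzero dose

    def test_irls_breakdown_guard(self):
        X = np.ones((6, 1))
        y = np.array([0.0, 0, 0, 100, 100, 100])
        beta, w, scale, converged, _ = irls_tukey(X, y)
        assert converged


class TestPredictEq1:
    def _fit(self, k=PUB_K):
        return rd.Eq1Fit(*k, 0.1, 0.1, 0.1, 0.0, 0.0, 0.0, "ols", True, 1)

    def test_zero_everything(self):
        raw, floored = rd.predict_dose_eq1(self._fit(), [0.0], [0.0])
        assert raw[0] == 0.0 and floored[0] == 0.0

    def test_linear_case(self):
        raw, _ = rd.predict_dose_eq1(self._fit((1.0, 0.0, 0.0)), [2.5], [4.0])
        assert raw[0] == pytest.approx(2.5)

    def test_direct_arithmetic(self):
        raw, _ = rd.predict_dose_eq1(self._fit(), [2.0], [1.0])
        assert raw[0] == pytest.approx(0.906 * 2 + 0.274 * 4 + 0.549 * 1, abs=1e-12)

    def test_flooring_and_negative_time(self):
        raw, floored = rd.predict_dose_eq1(self._fit((1.0, 0.0, 0.0)), [-3.0], [0.0])
        assert raw[0] == -3.0 and floored[0] == 0.0
        with pytest.raises(rd.ValidationError):
            rd.predict_dose_eq1(self._fit(), [1.0], [-1.0])

    def test_unconverged_fit_refuses_to_predict(self):
        fit = self._fit()
        fit.converged = False
        with pytest.raises(rd.FitError):
            rd.predict_dose_eq1(fit, [1.0], [1.0])


class TestQuadraticModel:
    def _cohort(self, seed=0, sex_gap=0.0, n_per=10):
        rng = np.random.default_rng(seed)
        from raddose.simulate import true_net_signal_qpcr

        doses = np.repeat([0.0, 1, 2, 3, 4, 6, 8], n_per)
        sex = np.tile([0.0, 1.0], doses.size // 2)
        n = np.array([true_net_signal_qpcr(d, *PUB_B) for d in doses])
        n = n + sex_gap * sex + rng.normal(0, 0.3, doses.size)
        return n, doses, sex

    def test_sex_flip_symmetry_zeroes_sex_terms(self):
        n, dose, sex = self._cohort(seed=1)
        n2 = np.concatenate([n, n])
        dose2 = np.concatenate([dose, dose])
        sex2 = np.concatenate([np.zeros_like(sex), np.ones_like(sex)])
        model = rd.QuadraticDoseRegressor(include_sex_terms=True).fit(
            np.column_stack([n2, sex2]), dose2
        )
        np.testing.assert_allclose(
            model.params_[["Sex", "SexN", "SexN2"]].to_numpy(), 0.0, atol=1e-8
        )
        reduced, dropped = rd.reduce_model(model)
        assert dropped
        # reduction cannot change predictions when sex coefficients are 0
        np.testing.assert_allclose(
            reduced.predict(n2[:, None]),
            model.predict(np.column_stack([n2, sex2])),
            atol=1e-8,
        )

    def test_single_sex_rejected(self):
        n, dose, _ = self._cohort()
        with pytest.raises(rd.ValidationError, match="reduced"):
            rd.QuadraticDoseRegressor(include_sex_terms=True).fit(
                np.column_stack([n, np.zeros_like(n)]), dose
            )

    def test_reduce_keeps_full_model_when_sex_significant(self):
        n, dose, sex = self._cohort(seed=3, sex_gap=2.0)
        model = rd.fit_quadratic_sex_model(n, dose, sex)
        kept, dropped = rd.reduce_model(model)
        assert not dropped
        assert kept is model

    def test_predict_intercept_and_arithmetic(self):
        n, dose, _ = self._cohort(seed=5)
        model = rd.QuadraticDoseRegressor().fit(n[:, None], dose)
        raw, _ = rd.predict_dose_quadratic(model, np.array([0.0]))
        assert raw[0] == pytest.approx(model.params_["Intercept"])
        # closed-form check against the published coefficient values
        b = PUB_B
        manual = b[0] + b[1] * (-2.0) + b[2] * 4.0
        assert manual == pytest.approx(2.592 + 1.570 + 0.192, abs=1e-12)

    def test_sex_model_requires_sex_at_predict(self):
        n, dose, sex = self._cohort(seed=6)
        model = rd.fit_quadratic_sex_model(n, dose, sex)
        with pytest.raises(rd.ValidationError):
            rd.predict_dose_quadratic(model, n)


class TestFitMetrics:
    def test_identity(self):
        m = rd.fit_metrics([1.0, 2, 3], [1.0, 2, 3])
        assert m.rmse == 0.0 and m.r2 == 1.0

    def test_constant_offset_closed_form(self):
        d = np.array([0.0, 2, 4, 8])
        m = rd.fit_metrics(d + 1.0, d)
        assert m.rmse == pytest.approx(1.0)
        ss_tot = np.sum((d - d.mean()) ** 2)
        assert m.r2 == pytest.approx(1 - d.size / ss_tot)

    def test_mean_predictor_gives_zero_r2(self):
        d = np.array([0.0, 2, 4, 8])
        m = rd.fit_metrics(np.full(4, d.mean()), d)
        assert m.r2 == pytest.approx(0.0)

    def test_zero_variance_flagged(self):
        m = rd.fit_metrics([1.0, 2.0], [3.0, 3.0])
        assert not m.r2_defined and np.isnan(m.r2)


class TestTimeStructures:
    def test_variant_count_and_true_structure_wins(self):
        rng = np.random.default_rng(2)
        n, time, dose = _synthetic_nd(reps=4)
        noisy = dose + rng.normal(0, 0.4, dose.size)
        table = rd.compare_time_structures(n, time, noisy, n_splits=15, base_seed=0)
        assert len(table) == 12
        assert set(table["loss"]) == {"robust", "ols"}
        best = table.iloc[0]
        assert best["time_structure"] == "sqrt" and best["additive"]

    def test_single_time_point_declared_tied(self):
        n, time, dose = _synthetic_nd(times=(1.0,), reps=4)
        table = rd.compare_time_structures(n, time, dose, n_splits=5)
        assert table["tied"].all()
        assert (table["rank"] == 1).all()


class TestRecoveryProperties:
    def test_parameter_recovery_with_noise(self):
        """Over repeated seeds, mean estimates stay within ~2 sampling SDs
        of the generating coefficients (both models, moderate noise)."""
        ests = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            n, time, dose = _synthetic_nd(reps=4)
            noisy_n = n + rng.normal(0, 0.15, n.size)
            fit = rd.fit_eq1(noisy_n, time, dose, loss="robust")
            ests.append([fit.k1, fit.k2, fit.k3])
        ests = np.array(ests)
        sd = ests.std(axis=0, ddof=1)
        assert (np.abs(ests.mean(axis=0) - PUB_K) < 2 * sd).all()
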