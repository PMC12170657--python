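"""Correlation, linear regression, RBF kernel, and SVR tuning."""

import math

import numpy as np
import pandas as pd
import pytest

from tcaqspr import (
    ConfigurationError,
    ConstantColumnError,
    DegenerateFitError,
    SVRSpec,
    feature_scaling,
    fit_lr,
    pearson_matrix,
    rbf_kernel,
    select_best_index,
    tune_svr,
)
from tcaqspr.qspr import LRFit


class TestPearsonMatrix:
    def test_exact_linear_relation_gives_unity(self):
        x = pd.DataFrame({"t": [1.0, 2, 3, 4]}, index=list("abcd"))
        y = pd.DataFrame({"p": [3.0, 5, 7, 9]}, index=list("abcd"))  # 2x + 1
        assert pearson_matrix(x, y).r.at["t", "p"] == pytest.approx(1.0)

    def test_constant_column_reported_not_zeroed(self):
        x = pd.DataFrame({"t": [1.0, 1, 1]}, index=list("abc"))
        y = pd.DataFrame({"p": [1.0, 2, 3]}, index=list("abc"))
        with pytest.raises(ConstantColumnError, match="t"):
            pearson_matrix(x, y)

    def test_too_few_observations(self):
        x = pd.DataFrame({"t": [1.0, 2]}, index=list("ab"))
        with pytest.raises(ValueError):
            pearson_matrix(x, x.rename(columns={"t": "p"}))

    def test_published_correlations(self, heavy_ref, allh_ref, props):
        heavy = pearson_matrix(heavy_ref.values, props).r
        allh = pearson_matrix(allh_ref.values, props).r
        assert heavy.at["H", "BP"] == pytest.approx(0.8180, abs=5e-5)
        assert allh.at["D", "MR"] == pytest.approx(0.9250, abs=5e-5)


class TestFitLR:
    def test_exact_fit(self):
        x = np.arange(10.0)
        f = fit_lr(x, 2 * x)
        assert f.r2 == pytest.approx(1.0)
        assert f.rmse == pytest.approx(0.0, abs=1e-12)

    def test_published_boiling_point_row(self, heavy_ref, props):
        f = fit_lr(heavy_ref.values["H"], props["BP"], "BP", "H")
        assert f.r2 == pytest.approx(0.6692, abs=5e-5)
        assert f.rmse == pytest.approx(37.3973, abs=5e-5)

    def test_parameter_recovery_at_vanishing_noise(self):
        rng = np.random.default_rng(42)
        x = rng.uniform(0, 10, 100)
        y = 3.0 + 0.5 * x + rng.normal(0, 1e-9, 100)
        f = fit_lr(x, y)
        assert f.intercept == pytest.approx(3.0, abs=1e-3)
        assert f.slope == pytest.approx(0.5, abs=1e-3)

    def test_r2_is_squared_pearson(self, heavy_ref, props):
        x = heavy_ref.values["D"].to_numpy()
        y = props["P"].to_numpy()
        r = np.corrcoef(x, y)[0, 1]
        assert fit_lr(x, y).r2 == pytest.approx(r**2, abs=1e-12)

    def test_rmse_symmetric_in_actual_vs_predicted(self, heavy_ref, props):
        f = fit_lr(heavy_ref.values["H"], props["BP"])
        pred = f.predict(heavy_ref.values["H"].to_numpy())
        actual = props["BP"].to_numpy()
        fwd = math.sqrt(np.mean((actual - pred) ** 2))
        rev = math.sqrt(np.mean((pred - actual) ** 2))
        assert f.rmse == pytest.approx(fwd) == pytest.approx(rev)

    def test_constant_descriptor_rejected(self):
        with pytest.raises(DegenerateFitError):
            fit_lr([1.0, 1, 1, 1], [1.0, 2, 3, 4])


class TestRBFKernel:
    def test_identical_vectors(self):
        assert rbf_kernel([1.0, 2], [1.0, 2], alpha=0.7) == 1.0

    def test_closed_form(self):
        assert rbf_kernel([0.0], [1.0], alpha=1.0) == pytest.approx(math.exp(-1))

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x, y = rng.normal(size=4), rng.normal(size=4)
            k = rbf_kernel(x, y, alpha=0.3)
            assert k == rbf_kernel(y, x, alpha=0.3)
            assert 0 < k <= 1

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError):
            rbf_kernel([1.0], [2.0], alpha=0.0)


class TestFeatureScaling:
    def test_standardization_and_roundtrip(self):
        z, t = feature_scaling([1.0, 2.0, 3.0])
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(t.invert(z), [1.0, 2.0, 3.0], atol=1e-12)

    def test_constant_column_rejected(self):
        with pytest.raises(ConstantColumnError):
            feature_scaling([2.0, 2.0, 2.0])


class TestTuneSVR:
    def test_grid_has_forty_combinations(self):
        assert SVRSpec().grid_size == 40

    def test_deterministic_given_seed(self, heavy_ref, props):
        spec = SVRSpec(seed=7)
        args = (heavy_ref.values["H"].to_numpy(), props["BP"].to_numpy(), spec)
        assert tune_svr(*args) == tune_svr(*args)

    def test_chosen_parameters_lie_in_grid(self, allh_ref, props):
        spec = SVRSpec(seed=42)
        r = tune_svr(allh_ref.values["DH"].to_numpy(), props["MV"].to_numpy(), spec)
        assert r.C in spec.c_grid
        assert r.epsilon in spec.epsilon_grid
        assert r.gamma in spec.gamma_modes

    def test_noiseless_linear_data_fits_nearly_perfectly(self):
        rng = np.random.default_rng(42)
        x = rng.uniform(0, 10, 100)
        r = tune_svr(x, 2 * x, SVRSpec(seed=42))
        assert r.test_r2 >= 0.99

    def test_too_few_observations(self):
        with pytest.raises(ConfigurationError):
            tune_svr(np.arange(5.0), np.arange(5.0), SVRSpec())

    def test_invalid_grid_rejected(self):
        with pytest.raises(ConfigurationError):
            SVRSpec(c_grid=())
        with pytest.raises(ConfigurationError):
            SVRSpec(c_grid=(-1.0,))


class TestSelectBestIndex:
    @staticmethod
    def lr(prop, ix, r2):
        return LRFit(property=prop, index=ix, mode=None, intercept=0, slope=1,
                     r2=r2, rmse=0.0, n=15)

    def test_argmax_by_r2(self):
        best = select_best_index([self.lr("BP", "A", 0.3), self.lr("BP", "B", 0.9)])
        assert best["BP"].index == "B"

    def test_tie_breaks_lexicographically(self):
        best = select_best_index([self.lr("BP", "WW", 0.5), self.lr("BP", "D", 0.5)])
        assert best["BP"].index == "D"

    def test_fixture_molar_refractivity_prefers_detour(self, allh_ref, props):
        fits = [
            fit_lr(allh_ref.values[ix], props["MR"], "MR", ix)
            for ix in allh_ref.values.columns
        ]
        assert select_best_index(fits)["MR"].index == "D"
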