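import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from phenoqc.errors import EstimationError
from phenoqc.model import (
    SymptomLagModel,
    bhy_adjust,
    fit_grid,
    grid_from_frame,
    significance_grid,
)
from phenoqc.simulate import TruthConfig, simulate_weekly_table

from conftest import brute_force_bhy

RECOVERY_TRUTH = TruthConfig(
    beta0=0.5, beta=(-0.3, 0.2, 0.001, 0.002, -0.1),
    sigma_subject=0.3, sigma_resid=0.2, true_lag=1,
)


class TestMixedModelFit:
    def test_recovers_generative_coefficients(self):
        tab = simulate_weekly_table(50, 12, RECOVERY_TRUTH, np.random.default_rng(1))
        res = SymptomLagModel.from_weekly(tab, "overall", 1).fit()
        beta = np.array(RECOVERY_TRUTH.beta)
        est = res.params.iloc[1:].to_numpy()
        se = res.bse.iloc[1:].to_numpy()
        assert np.all(np.abs(est - beta) < 4 * se)
        assert res.sigma2_subject == pytest.approx(0.09, abs=0.06)
        assert res.sigma2_resid == pytest.approx(0.04, abs=0.02)
        assert res.converged

    def test_zero_subject_variance_limit_matches_ols(self):
        truth = TruthConfig(beta0=0.5, beta=(-0.3, 0.2, 0.001, 0.002, -0.1),
                            sigma_subject=0.0, true_lag=1)
        tab = simulate_weekly_table(20, 8, truth, np.random.default_rng(0))
        model = SymptomLagModel.from_weekly(tab, "overall", 1)
        res = model.fit()
        assert res.sigma2_subject < 1e-8
        ols = sm.OLS(model.endog, model.exog).fit()
        assert np.abs(res.params.to_numpy() - ols.params.to_numpy()).max() < 1e-6

    def test_constant_covariate_dropped_with_warning(self):
        tab = simulate_weekly_table(20, 8, RECOVERY_TRUTH, np.random.default_rng(2))
        tab["T"] = 3.0
        with pytest.warns(UserWarning, match="constant covariate"):
            model = SymptomLagModel.from_weekly(tab, "overall", 1)
        assert model.dropped_terms == ["T"]
        res = model.fit()
        assert "T" not in res.params.index
        row = res.to_frame().set_index("term").loc["T"]
        assert np.isnan(row["estimate"])

    def test_too_few_subjects_rejected(self):
        tab = simulate_weekly_table(1, 12, RECOVERY_TRUTH, np.random.default_rng(3))
        with pytest.raises(EstimationError, match="subjects"):
            SymptomLagModel.from_weekly(tab, "overall", 1)

    def test_too_few_rows_rejected(self):
        tab = simulate_weekly_table(2, 3, RECOVERY_TRUTH, np.random.default_rng(3))
        with pytest.raises(EstimationError, match="rows"):
            SymptomLagModel.from_weekly(tab, "overall", 2)

    def test_summary_reports_original_scale(self):
        tab = simulate_weekly_table(30, 10, RECOVERY_TRUTH, np.random.default_rng(4))
        res = SymptomLagModel.from_weekly(tab, "overall", 1).fit()
        s = res.summary()
        assert list(s.index) == ["Intercept", "A", "G", "V", "C", "T"]
        # CI brackets the estimate and is consistent with the SE
        half = (s["ci_high"] - s["ci_low"]) / 2
        assert np.allclose(half, 1.959963984540054 * s["se"], rtol=1e-6)
        assert s.attrs["estimator"] == "REML"


class TestBHY:
    def test_worked_rejection_set(self):
        # c(4) = 25/12 gives step-up thresholds 0.006, 0.012, 0.018, 0.024
        flags = bhy_adjust([0.001, 0.01, 0.02, 0.9], q=0.05)
        assert flags.tolist() == [True, True, False, False]

    def test_single_pvalue_reduces_to_plain_threshold(self):
        assert bhy_adjust([0.04], q=0.05).tolist() == [True]
        assert bhy_adjust([0.06], q=0.05).tolist() == [False]

    def test_all_ones_reject_none_and_empty_ok(self):
        assert not bhy_adjust([1.0, 1.0, 1.0], q=0.05).any()
        assert bhy_adjust([], q=0.05).size == 0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            bhy_adjust([0.0, 0.5], q=0.05)
        with pytest.raises(ValueError):
            bhy_adjust([0.5], q=1.5)

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(300):
            m = int(rng.integers(1, 21))
            # mix tiny and moderate p-values to straddle the thresholds
            p = np.where(
                rng.random(m) < 0.5,
                rng.uniform(1e-5, 0.05, m),
                rng.uniform(0.0, 1.0, m),
            )
            p = np.clip(p, 1e-12, 1.0)
            assert bhy_adjust(p, 0.05).tolist() == brute_force_bhy(p, 0.05).tolist()


class TestSignificanceGrid:
    def grid(self, seed=5, lags=(1, 2)):
        tab = simulate_weekly_table(30, 10, RECOVERY_TRUTH, np.random.default_rng(seed))
        return significance_grid(fit_grid(tab, ["overall"], list(lags)))

    def test_sign_matches_coefficient_and_fdr_implies_raw(self):
        frame = self.grid().frame
        nonzero = frame[frame["estimate"].notna()]
        assert (nonzero["sign"] == np.sign(nonzero["estimate"])).all()
        assert frame.loc[frame["significant_fdr"], "significant_raw"].all()

    def test_cell_definitions(self):
        frame = grid_from_frame(
            pd.DataFrame(
                {
                    "covariate": ["A", "G"],
                    "domain": "mood",
                    "lag": 1,
                    "estimate": [0.2, -0.1],
                    "se": [0.05, 0.1],
                    "pvalue": [0.01, 1.0],
                }
            )
        ).frame
        assert frame.loc[0, "sign"] == 1
        assert frame.loc[0, "neglog10p"] == pytest.approx(2.0)
        assert frame.loc[0, "significant_raw"]
        assert frame.loc[1, "neglog10p"] == 0.0
        assert not frame.loc[1, "significant_raw"] and not frame.loc[1, "significant_fdr"]

    def test_per_lag_family_corrects_within_lags(self):
        tab = simulate_weekly_table(30, 10, RECOVERY_TRUTH, np.random.default_rng(6))
        fits = fit_grid(tab, ["overall"], [1, 2])
        g_global = significance_grid(fits, family="global").frame
        g_perlag = significance_grid(fits, family="per-lag").frame
        lag1 = g_perlag["lag"] == 1
        assert g_perlag.loc[lag1, "significant_fdr"].tolist() == bhy_adjust(
            g_perlag.loc[lag1, "pvalue"], 0.05
        ).tolist()
        assert set(g_global.columns) == set(g_perlag.columns)

    def test_strong_effect_detected_after_correction(self):
        # a large completion-count effect should survive BY correction
        truth = TruthConfig(beta0=0.5, beta=(0.0, 0.0, 0.0, 0.0, -0.4),
                            sigma_subject=0.3, sigma_resid=0.2, true_lag=1)
        hits = 0
        for seed in range(20):
            tab = simulate_weekly_table(50, 12, truth, np.random.default_rng(1000 + seed))
            g = significance_grid(fit_grid(tab, ["overall"], [1, 2]))
            cell = g.frame[(g.frame["covariate"] == "T") & (g.frame["lag"] == 1)]
            hits += int(cell["significant_fdr"].iloc[0])
        assert hits >= 18
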