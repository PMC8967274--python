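"""Range contrasts, OLS machinery, AIC selection, and cline analysis."""

import numpy as np
import pandas as pd
import pytest

from thermperf.config import SimConfig
from thermperf.errors import DataError, ModelError
from thermperf.inference import (
    aic_select,
    cline_analysis,
    fit_ols,
    interpret,
    range_contrast,
)
from thermperf.synthetic_data import gen_climate, gen_true_tpcs


def _per_draw(native, invasive):
    """Build a per-draw table; native/invasive are {pop: [values per draw]}."""
    rows = []
    for label, d in (("native", native), ("invasive", invasive)):
        for pop, vals in d.items():
            for i, v in enumerate(vals):
                rows.append(
                    {"draw": i, "population_id": pop, "range_label": label, "t_opt": v}
                )
    return pd.DataFrame(rows)


class TestRangeContrast:
    def test_constant_difference(self):
        df = _per_draw({"N1": [22, 24]}, {"I1": [21, 23]})
        c = range_contrast(df, "t_opt")
        assert c.mean_diff == pytest.approx(1.0)
        assert c.cri_lo == pytest.approx(1.0)
        assert c.cri_hi == pytest.approx(1.0)
        assert c.significant

    def test_identical_groups_not_significant(self):
        df = _per_draw({"N1": [22, 24, 23]}, {"I1": [22, 24, 23]})
        c = range_contrast(df, "t_opt")
        assert c.mean_diff == 0.0
        assert not c.significant

    def test_label_swap_negates(self):
        rng = np.random.default_rng(0)
        nat = {f"N{i}": rng.normal(24, 1, 40) for i in range(3)}
        inv = {f"I{i}": rng.normal(23, 1, 40) for i in range(2)}
        df = _per_draw(nat, inv)
        c = range_contrast(df, "t_opt")
        swapped = df.copy()
        swapped["range_label"] = swapped["range_label"].map(
            {"native": "invasive", "invasive": "native"}
        )
        c2 = range_contrast(swapped, "t_opt")
        assert c2.mean_diff == pytest.approx(-c.mean_diff)
        assert c2.cri_lo == pytest.approx(-c.cri_hi)
        assert c2.cri_hi == pytest.approx(-c.cri_lo)

    def test_empty_range_raises(self):
        df = _per_draw({"N1": [22.0]}, {})
        with pytest.raises(DataError):
            range_contrast(df, "t_opt")


class TestOLS:
    def test_noiseless_line(self):
        x = np.arange(5, dtype=float)
        y = 2 * x
        X = np.column_stack([np.ones(5), x])
        res = fit_ols(y, X, ["intercept", "x"])
        assert res.coefficients[1] == pytest.approx(2.0, abs=1e-12)
        assert res.adj_r2 == pytest.approx(1.0)

    def test_noiseless_range_effect(self):
        x = np.array([0, 1, 2, 3, 4, 5], dtype=float)
        r = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        y = x + 2 * r
        X = np.column_stack([np.ones(6), x, r, x * r])
        res = fit_ols(y, X, ["intercept", "x", "range", "interaction"])
        assert res.coefficients[1] == pytest.approx(1.0, abs=1e-9)
        assert res.coefficients[2] == pytest.approx(2.0, abs=1e-8)
        assert res.coefficients[3] == pytest.approx(0.0, abs=1e-9)

    def test_matches_normal_equation_oracle(self, rng):
        n = 31
        x = rng.normal(size=n)
        r = (rng.random(n) < 0.4).astype(float)
        X = np.column_stack([np.ones(n), x, r, x * r])
        y = 1.0 + 0.5 * x - 0.3 * r + rng.normal(0, 0.4, n)
        res = fit_ols(y, X, ["intercept", "x", "range", "interaction"])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(res.coefficients, beta, atol=1e-10)

    def test_residuals_orthogonal_to_design(self, rng):
        n = 40
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
        y = rng.normal(size=n)
        res = fit_ols(y, X, ["intercept", "a", "b"])
        resid = y - X @ res.coefficients
        assert np.max(np.abs(X.T @ resid)) < 1e-8

    def test_adjusted_r2_formula(self, rng):
        n, k = 31, 3  # k slopes + intercept handled inside
        x = rng.normal(size=n)
        r = (rng.random(n) < 0.5).astype(float)
        X = np.column_stack([np.ones(n), x, r])
        y = 0.2 * x + rng.normal(0, 1.0, n)
        res = fit_ols(y, X, ["intercept", "x", "range"])
        yhat = X @ res.coefficients
        r2 = 1 - np.sum((y - yhat) ** 2) / np.sum((y - y.mean()) ** 2)
        k_slopes = X.shape[1] - 1
        adj = 1 - (1 - r2) * (n - 1) / (n - k_slopes - 1)
        assert res.adj_r2 == pytest.approx(adj, rel=1e-10)

    def test_adjusted_r2_can_be_negative(self, rng):
        n = 13
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)  # pure noise
        res = fit_ols(y, X, ["intercept", "x"])
        assert res.adj_r2 < 1

    def test_interaction_never_increases_rss(self, rng):
        n = 31
        x = rng.normal(size=n)
        r = (rng.random(n) < 0.5).astype(float)
        y = x + rng.normal(0, 1, n)
        X_red = np.column_stack([np.ones(n), x, r])
        X_full = np.column_stack([X_red, x * r])
        res_r = fit_ols(y, X_red, ["intercept", "x", "range"])
        res_f = fit_ols(y, X_full, ["intercept", "x", "range", "interaction"])
        rss_r = np.sum((y - X_red @ res_r.coefficients) ** 2)
        rss_f = np.sum((y - X_full @ res_f.coefficients) ** 2)
        assert rss_f <= rss_r + 1e-10

    def test_rank_deficiency_names_columns(self):
        x = np.arange(6, dtype=float)
        X = np.column_stack([np.ones(6), x, 2 * x])
        with pytest.raises(ModelError, match="dup"):
            fit_ols(x, X, ["intercept", "x", "dup"])

    def test_aic_counts_variance_parameter(self, rng):
        # AIC = -2 llf + 2 (k + 1), the convention of mainstream GLM output
        import statsmodels.api as sm

        n = 20
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        res = fit_ols(y, X, ["intercept", "x"])
        llf = sm.OLS(y, X).fit().llf
        assert res.aic == pytest.approx(-2 * llf + 2 * 3)


class TestAICSelect:
    def _pair(self, y, x, r):
        n = len(y)
        X_full = np.column_stack([np.ones(n), x, r, x * r])
        X_red = np.column_stack([np.ones(n), x, r])
        full = fit_ols(y, X_full, ["intercept", "x", "range", "interaction"],
                       has_interaction=True)
        red = fit_ols(y, X_red, ["intercept", "x", "range"])
        return full, red

    def test_strong_interaction_selects_full(self):
        rng = np.random.default_rng(5)
        wins = 0
        for _ in range(100):
            n = 60
            x = rng.normal(size=n)
            r = (rng.random(n) < 0.5).astype(float)
            y = x + 2.0 * x * r + rng.normal(0, 0.3, n)
            full, red = self._pair(y, x, r)
            wins += aic_select(full, red) is full
        assert wins > 95

    def test_no_interaction_mostly_selects_reduced(self):
        rng = np.random.default_rng(6)
        wins = 0
        for _ in range(100):
            n = 31
            x = rng.normal(size=n)
            r = (rng.random(n) < 0.5).astype(float)
            y = x + rng.normal(0, 1.0, n)
            full, red = self._pair(y, x, r)
            wins += aic_select(full, red) is red
        assert wins > 50

    def test_tie_breaks_to_reduced(self):
        rng = np.random.default_rng(7)
        n = 20
        x = rng.normal(size=n)
        r = (rng.random(n) < 0.5).astype(float)
        full, red = self._pair(x + rng.normal(0, 1, n), x, r)
        red_tied = fit_ols(
            x + 0,
            np.column_stack([np.ones(n), x, r]),
            ["intercept", "x", "range"],
        )
        red_tied.aic = full.aic  # exact tie
        assert aic_select(full, red_tied) is red_tied

    def test_mismatched_n_raises(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=20)
        r = np.zeros(20)
        r[:10] = 1
        full, _ = self._pair(x + rng.normal(size=20), x, r)
        _, red = self._pair(x[:15] + rng.normal(size=15), x[:15], r[:15])
        with pytest.raises(ModelError):
            aic_select(full, red)


class TestClineAnalysis:
    def _derived_from_truth(self, cfg):
        climate = gen_climate(cfg)
        truths = gen_true_tpcs(cfg, climate)
        derived = truths[["population_id", "range_label", "t_opt", "t_breadth"]]
        return derived, climate

    def test_recovers_native_mat_slope(self):
        cfg = SimConfig(
            seed=13,
            truth_mode="cline",
            cline_slope_topt_mat=0.15,
            pop_scatter_topt_sd=0.1,
            pop_scatter_breadth_sd=0.0,
        )
        derived, climate = self._derived_from_truth(cfg)
        report = cline_analysis(derived, climate)
        fam = next(
            f for f in report.families if f.response == "t_opt" and f.predictor == "mat"
        )
        assert fam.sub_models["native"].slope == pytest.approx(0.15, abs=0.05)

    def test_constant_response_gives_zero_slopes(self):
        cfg = SimConfig(seed=3, truth_mode="fixed")
        derived, climate = self._derived_from_truth(cfg)
        report = cline_analysis(derived, climate)
        for fam in report.families:
            assert fam.full.coefficients[1] == pytest.approx(0.0, abs=1e-8)
            assert fam.reduced.adj_r2 <= 0.0 + 1e-12
            for sub in fam.sub_models.values():
                assert sub.slope == pytest.approx(0.0, abs=1e-8)

    def test_null_rejection_rate_calibrated(self):
        """No true clines: beta1 t-test rejects at about the nominal 5%."""
        from scipy.stats import binom

        reps = 200
        rejections = 0
        for rep in range(reps):
            cfg = SimConfig(
                seed=50_000 + rep,
                truth_mode="cline",
                cline_slope_topt_mat=0.0,
                cline_slope_breadth_seasonality=0.0,
                pop_scatter_topt_sd=0.8,
                pop_scatter_breadth_sd=0.0,
            )
            derived, climate = self._derived_from_truth(cfg)
            report = cline_analysis(derived, climate)
            fam = next(
                f
                for f in report.families
                if f.response == "t_opt" and f.predictor == "mat"
            )
            rejections += fam.reduced.pvalue("mat") < 0.05
        lo, hi = binom.interval(0.95, reps, 0.05)
        assert lo <= rejections <= hi, f"{rejections}/{reps} rejections"

    def test_missing_climate_raises(self):
        cfg = SimConfig(seed=3, truth_mode="fixed")
        derived, climate = self._derived_from_truth(cfg)
        with pytest.raises(DataError):
            cline_analysis(derived, climate.iloc[:-1])

    def test_final_model_is_min_aic(self):
        cfg = SimConfig(seed=17, truth_mode="cline")
        derived, climate = self._derived_from_truth(cfg)
        report = cline_analysis(derived, climate)
        for fam in report.families:
            assert fam.final.aic == min(fam.full.aic, fam.reduced.aic)
            assert fam.interpretation in ("divergent clines", "parallel cline", "no cline")
        frame = report.to_frame()
        assert frame["final"].sum() == len(report.families)


def test_interpret_labels():
    class _Stub:
        has_interaction = True
        predictor = "mat"

        def pvalue(self, name):
            return {"interaction": 0.01, "mat": 0.5}[name]

    assert interpret(_Stub()) == "divergent clines"
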