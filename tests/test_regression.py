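"""OLS fitting, AIC stepwise selection, correlations and sensitivity refits."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf
from scipy import stats

from sedimet.regression import (
    FULL_GROUP_SPEC,
    RBIO_FULL_SPEC,
    SIMPLE_SPEC,
    ModelSpec,
    fit_linear_model,
    leverage_exclusion_refit,
    pearson_correlation,
    rbio_models,
    spearman_correlation,
    stepwise_select,
)


def _line_table(x, y):
    return pd.DataFrame({"Itot_mW_m2": x, "Rtot_g_m2": y})


def _nested_specs(full: ModelSpec):
    """All hierarchical submodels of a full spec (tiny lattice, exhaustive)."""
    out = []
    for r in range(len(full.terms) + 1):
        for terms in itertools.combinations(full.terms, r):
            try:
                out.append(ModelSpec(full.response, terms))
            except ValueError:
                continue  # violates hierarchy
    return out


class TestFitLinearModel:
    def test_noiseless_line_recovered_exactly(self):
        x = np.array([1.0, 2.0, 4.0, 7.0])
        res = fit_linear_model(_line_table(x, 3 + 2 * x), SIMPLE_SPEC)
        assert res.params.iloc[0] == pytest.approx(3.0, abs=1e-10)
        assert res.params.iloc[1] == pytest.approx(2.0, abs=1e-10)
        assert res.rsquared == pytest.approx(1.0)

    def test_hand_computed_ols(self):
        # x=(1,2,3), y=(2,2,5): Sxy/Sxx = 3/2, intercept 0, R2 = 1 - RSS/SYY = 0.75
        res = fit_linear_model(_line_table([1, 2, 3], [2, 2, 5]), SIMPLE_SPEC)
        assert res.params.iloc[1] == pytest.approx(1.5)
        assert res.params.iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert res.rsquared == pytest.approx(0.75)

    def test_flume_simple_fit(self, flume_table):
        res = fit_linear_model(flume_table, SIMPLE_SPEC)
        assert res.params.iloc[0] == pytest.approx(35.11, abs=0.02)
        assert res.params.iloc[1] == pytest.approx(0.36, abs=0.02)
        assert res.rsquared == pytest.approx(0.682, abs=0.002)
        assert res.rsquared_adj == pytest.approx(0.672, abs=0.002)
        assert res.fvalue == pytest.approx(64.43, abs=0.05)

    def test_intercept_ci_contains_abiotic_control(self, flume_table):
        """The fitted abiotic baseline is consistent with the defaunated
        control (32.25 g/m2)."""
        ci = fit_linear_model(flume_table, SIMPLE_SPEC).conf_int
        lo, hi = ci.loc["Intercept"]
        assert lo < 32.25 < hi

    def test_aic_convention_counts_residual_variance(self, flume_table):
        """AIC = -2 logLik + 2 (p+1): the Gaussian closed form
        n log(RSS/n) + n log(2 pi) + n + 2(p+1), and statsmodels' OLS AIC
        plus exactly 2."""
        res = fit_linear_model(flume_table, SIMPLE_SPEC)
        sm = smf.ols("Rtot_g_m2 ~ Itot_mW_m2", flume_table).fit()
        assert res.aic == pytest.approx(sm.aic + 2.0, abs=1e-9)
        n = res.nobs
        rss = float(np.sum(res.residuals**2))
        closed = n * np.log(rss / n) + n * np.log(2 * np.pi) + n + 2 * 3
        assert res.aic == pytest.approx(closed, abs=1e-9)

    def test_residuals_orthogonal_to_design(self, flume_table):
        res = fit_linear_model(flume_table, FULL_GROUP_SPEC)
        sm = smf.ols(FULL_GROUP_SPEC.formula(), flume_table)
        assert np.allclose(sm.exog.T @ res.residuals, 0.0, atol=1e-6)

    def test_rank_deficiency_names_collinear_terms(self, flume_table):
        t = flume_table.copy()
        t["dup"] = 2.0 * t["Itot_mW_m2"]
        spec = ModelSpec("Rtot_g_m2", ("Itot_mW_m2", "dup"))
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            fit_linear_model(t, spec)

    def test_too_few_observations(self):
        with pytest.raises(ValueError, match="observations"):
            fit_linear_model(_line_table([1, 2], [1, 2]), SIMPLE_SPEC)


class TestStepwise:
    def test_flume_trace_matches_reported_selection(self, flume_table):
        """Full interaction -> additive -> simple, with the three AICs of the
        published comparison, selecting the model without the categorical."""
        trace = stepwise_select(flume_table, FULL_GROUP_SPEC)
        assert trace.aics == pytest.approx([270.397, 268.133, 265.712], abs=0.1)
        assert trace.selected.terms == ("Itot_mW_m2",)

    def test_selection_agrees_with_exhaustive_enumeration(self, flume_table):
        best = min(
            (fit_linear_model(flume_table, s).aic, s.terms)
            for s in _nested_specs(FULL_GROUP_SPEC)
            if "Itot_mW_m2" in s.terms or not s.terms
        )
        trace = stepwise_select(flume_table, FULL_GROUP_SPEC)
        assert fit_linear_model(flume_table, trace.selected).aic == pytest.approx(best[0])

    def test_strong_group_offset_retains_categorical(self, flume_table):
        rng = np.random.default_rng(5)
        t = flume_table.copy()
        offs = t.functional_group.map(
            {"deep": 0.0, "intermediate_IBB": 120.0, "shallow": -120.0}
        )
        t["Rtot_g_m2"] = 35.0 + 0.36 * t.Itot_mW_m2 + offs + rng.normal(0, 10, len(t))
        trace = stepwise_select(t, FULL_GROUP_SPEC)
        assert "functional_group" in trace.selected.terms
        # exhaustive oracle over the same lattice
        best = min(
            (fit_linear_model(t, s).aic, s.terms) for s in _nested_specs(FULL_GROUP_SPEC)
        )
        assert fit_linear_model(t, trace.selected).aic == pytest.approx(best[0])

    def test_single_predictor_trace(self, flume_table):
        trace = stepwise_select(flume_table, SIMPLE_SPEC)
        assert len(trace.steps) == 1
        assert trace.selected == SIMPLE_SPEC

    def test_extra_zero_coefficient_usually_raises_aic(self):
        """Adding a truly-null predictor increases AIC in most replicates."""
        rng = np.random.default_rng(123)
        wins = 0
        n_rep = 200
        for _ in range(n_rep):
            x = rng.uniform(0, 10, 24)
            junk = rng.normal(size=24)
            y = 1.0 + 0.5 * x + rng.normal(0, 1, 24)
            t = pd.DataFrame({"Rtot_g_m2": y, "Itot_mW_m2": x, "junk": junk})
            simple = fit_linear_model(t, SIMPLE_SPEC).aic
            bigger = fit_linear_model(t, ModelSpec("Rtot_g_m2", ("Itot_mW_m2", "junk"))).aic
            wins += bigger > simple
        assert wins / n_rep > 0.5


class TestCorrelations:
    def test_flume_rank_and_product_moment(self, flume_table):
        """On these data the product-moment correlations are 0.83/0.37 and
        the rank correlations 0.76/0.56 (the relationship is linear, but the
        extreme treatments compress the ranks)."""
        x, y = flume_table.Itot_mW_m2, flume_table.Rtot_g_m2
        assert pearson_correlation(x, y)[0] == pytest.approx(0.826, abs=0.001)
        assert spearman_correlation(x, y)[0] == pytest.approx(0.761, abs=0.001)
        n = flume_table.density_ind_m2
        assert pearson_correlation(n, y)[0] == pytest.approx(0.370, abs=0.001)
        assert spearman_correlation(n, y)[0] == pytest.approx(0.560, abs=0.001)

    def test_closed_form_small_case(self):
        # rho = 1 - 6*sum(d^2)/(n(n^2-1)) with d^2 summing to 6
        rho, _ = spearman_correlation([1, 2, 3], [3, 1, 2])
        assert rho == pytest.approx(-0.5)

    def test_invariant_under_monotone_transform(self, flume_table):
        x, y = flume_table.Itot_mW_m2, flume_table.Rtot_g_m2
        base = spearman_correlation(x, y)[0]
        assert spearman_correlation(np.log(x), y)[0] == pytest.approx(base)
        assert spearman_correlation(x, y**3)[0] == pytest.approx(base)

    def test_equals_pearson_on_ranks(self, flume_table):
        x, y = flume_table.Itot_mW_m2, flume_table.Rtot_g_m2
        rho = spearman_correlation(x, y)[0]
        r = stats.pearsonr(stats.rankdata(x), stats.rankdata(y)).statistic
        assert rho == pytest.approx(r, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman_correlation([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            pearson_correlation([1, 1, 1], [1, 2, 3])


class TestLeverageExclusion:
    def test_flume_without_two_extremes(self, flume_table):
        res, excluded = leverage_exclusion_refit(flume_table, k=2)
        assert len(excluded) == 2
        assert res.params.iloc[1] == pytest.approx(0.17, abs=0.01)
        assert res.pvalues.iloc[1] < 0.05

    def test_k_zero_is_plain_fit(self, flume_table):
        res, excluded = leverage_exclusion_refit(flume_table, k=0)
        full = fit_linear_model(flume_table, SIMPLE_SPEC)
        assert len(excluded) == 0
        assert res.params.equals(full.params)

    def test_noiseless_line_slope_unchanged(self):
        x = np.linspace(1, 20, 12)
        t = _line_table(x, 4 + 0.5 * x)
        for k in (1, 3, 5):
            res, _ = leverage_exclusion_refit(t, k=k)
            assert res.params.iloc[1] == pytest.approx(0.5, abs=1e-10)

    def test_ties_at_boundary_all_dropped(self):
        x = [1.0, 2.0, 3.0, 9.0, 9.0, 9.0]
        t = _line_table(x, [1.0, 2.1, 2.9, 9.2, 8.8, 9.1])
        _, excluded = leverage_exclusion_refit(t, k=1)
        assert len(excluded) == 3  # all rows tied at the k-th largest value

    def test_k_too_large_rejected(self, flume_table):
        with pytest.raises(ValueError):
            leverage_exclusion_refit(flume_table, k=31)


class TestRbioModels:
    def test_flume_selects_intercept_only(self, flume_table):
        trace, selected, canonical = rbio_models(flume_table)
        assert trace.selected.terms == ()
        assert selected.params.iloc[0] == pytest.approx(0.47, abs=0.01)
        lo, hi = selected.conf_int.iloc[0]
        assert (lo, hi) == (pytest.approx(0.09, abs=0.01), pytest.approx(0.84, abs=0.01))
        assert selected.pvalues.iloc[0] == pytest.approx(0.017, abs=0.002)
        aics = [canonical[k].aic for k in ("interaction", "additive", "intercept_only")]
        assert aics == sorted(aics, reverse=True)

    def test_constant_response(self, flume_table):
        t = flume_table.copy()
        t["Rbio_g_mW"] = 0.5
        _, selected, canonical = rbio_models(t)
        assert selected.params.iloc[0] == pytest.approx(0.5)
        assert canonical["additive"].rsquared == pytest.approx(0.0, abs=1e-9)

    def test_density_signal_retained(self, flume_table):
        rng = np.random.default_rng(7)
        t = flume_table.copy()
        t["Rbio_g_mW"] = 0.1 + 0.02 * t.density_ind_m2 + rng.normal(0, 0.3, len(t))
        trace, selected, _ = rbio_models(t)
        assert "density_ind_m2" in trace.selected.terms
        best = min(
            (fit_linear_model(t, s).aic, s.terms) for s in _nested_specs(RBIO_FULL_SPEC)
        )
        assert fit_linear_model(t, trace.selected).aic == pytest.approx(best[0])

    def test_missing_rbio_column_is_error(self, flume_table):
        with pytest.raises(ValueError, match="Rbio"):
            rbio_models(flume_table.drop(columns="Rbio_g_mW"))
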