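import math
import subprocess
import sys

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import statsmodels.api as sm

from franciscana_availability.simulate import GeneratorConfig, generate
from franciscana_availability.surface_model import (
    AR1,
    INDEPENDENT,
    CandidateModel,
    CorrelationStructure,
    ModelFit,
    akaike_weights,
    all_subsets,
    correlation_matrix,
    fit_all_subsets,
    fit_mixed_model,
    model_average,
    prepare_response,
    relative_importance,
    select_autocorrelation,
)

from conftest import make_session


def synthetic_table(
    n_groups=60, cycles=4, phi=0.5, sigma_group=0.3, sigma_resid=0.4, seed=0
):
    cfg = GeneratorConfig(
        n_groups=n_groups,
        mean_cycles=float(cycles),
        max_cycles=cycles,
        phi=phi,
        sigma_group=sigma_group,
        sigma_resid=sigma_resid,
        p_reaction=0.0,
        p_lowconf=0.0,
        seed=seed,
    )
    return prepare_response(generate(cfg))


class TestPrepareResponse:
    def test_log_transform(self):
        table = prepare_response([make_session(durations=((16.0, 48.0),))])
        assert table.loc[0, "y"] == pytest.approx(math.log(0.25))

    def test_one_over_e(self):
        d = math.e - 1.0
        table = prepare_response([make_session(durations=((1.0, d),))])
        assert table.loc[0, "y"] == pytest.approx(-1.0)

    def test_covariates_carried_from_session(self):
        s = make_session(durations=((16.0, 48.0),), group_size=6, tide_m=1.1)
        table = prepare_response([s])
        assert table.loc[0, "large"] == 1.0
        assert table.loc[0, "tide_m"] == 1.1

    def test_row_order(self, filtered):
        kept, _ = filtered
        table = prepare_response(kept)
        assert len(table) == 248
        key = list(zip(table.group_id, table.cycle_index))
        assert key == sorted(key)


class TestCorrelationMatrix:
    def test_ar1_powers(self):
        R = correlation_matrix(AR1, 3, [0.5])
        expected = np.array(
            [[1, 0.5, 0.25], [0.5, 1, 0.5], [0.25, 0.5, 1]]
        )
        np.testing.assert_allclose(R, expected)

    def test_zero_phi_is_identity(self):
        np.testing.assert_allclose(correlation_matrix(AR1, 4, [0.0]), np.eye(4))

    def test_arma10_equals_ar1(self):
        arma = CorrelationStructure("arma", p=1, q=0)
        np.testing.assert_allclose(
            correlation_matrix(arma, 5, [0.5]),
            correlation_matrix(AR1, 5, [0.5]),
            atol=1e-12,
        )

    def test_nonstationary_rejected(self):
        with pytest.raises(ValueError):
            correlation_matrix(AR1, 3, [1.0])
        with pytest.raises(ValueError):
            correlation_matrix(CorrelationStructure("arma", 2, 1), 4, [0.9, 0.4, 0.2])

    @given(
        phi=st.floats(-0.95, 0.95),
        theta=st.floats(-0.9, 0.9),
        n=st.integers(2, 8),
    )
    @settings(max_examples=60, derandomize=True)
    def test_symmetric_positive_definite(self, phi, theta, n):
        arma = CorrelationStructure("arma", p=1, q=1)
        R = correlation_matrix(arma, n, [phi, theta])
        np.testing.assert_allclose(R, R.T, atol=1e-12)
        assert np.linalg.eigvalsh(R).min() > 0


class TestFitMixedModel:
    def test_reduces_to_ols_without_random_terms(self):
        """With no random intercept and independent residuals the ML fit
        equals ordinary least squares (statsmodels oracle)."""
        table = synthetic_table(phi=0.0, sigma_group=0.0, seed=4)
        model = CandidateModel(
            frozenset({"group_size_class", "tide_m"}),
            INDEPENDENT,
            random_intercept=False,
        )
        fit = fit_mixed_model(table, model)
        X = sm.add_constant(table[["large", "tide_m"]])
        ols = sm.OLS(table["y"], X).fit()
        assert fit.coefficients["intercept"][0] == pytest.approx(
            ols.params["const"], abs=1e-8
        )
        assert fit.coefficients["large"][0] == pytest.approx(
            ols.params["large"], abs=1e-8
        )
        assert fit.loglik == pytest.approx(ols.llf, abs=1e-6)

    def test_recovers_generating_coefficients_when_iid(self):
        table = synthetic_table(
            n_groups=150, phi=0.0, sigma_group=0.0, seed=5
        )
        model = CandidateModel(frozenset({"group_size_class"}), INDEPENDENT)
        fit = fit_mixed_model(table, model)
        beta, se = fit.coefficients["large"]
        assert beta == pytest.approx(0.44, abs=3 * se)

    def test_duplicating_groups_preserves_coefficients(self):
        table = synthetic_table(n_groups=40, seed=6)
        dup = table.copy()
        dup["group_id"] = dup["group_id"] + "_copy"
        doubled = pd.concat([table, dup], ignore_index=True)
        m = CandidateModel(frozenset({"group_size_class"}), AR1)
        f1 = fit_mixed_model(table, m)
        f2 = fit_mixed_model(doubled, m)
        assert f2.coefficients["large"][0] == pytest.approx(
            f1.coefficients["large"][0], abs=1e-4
        )

    def test_loglik_dominates_embedded_ols(self, filtered):
        """The ML optimum cannot fall below the same family evaluated at
        sigma_group = 0, phi = 0 (the OLS point)."""
        kept, _ = filtered
        table = prepare_response(kept)
        m_full = CandidateModel(frozenset({"group_size_class"}), AR1)
        m_ols = CandidateModel(
            frozenset({"group_size_class"}), INDEPENDENT, random_intercept=False
        )
        assert (
            fit_mixed_model(table, m_full).loglik
            >= fit_mixed_model(table, m_ols).loglik - 1e-6
        )

    def test_aic_identity(self, filtered):
        kept, _ = filtered
        fit = fit_mixed_model(
            prepare_response(kept), CandidateModel(frozenset(), AR1)
        )
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.k)
        # intercept + sigma_group + sigma_resid + phi
        assert fit.k == 4

    def test_matches_nlme_oracle(self, tmp_path):
        """loglik/AIC/coefficients/variance components agree with R nlme
        (lme with corAR1), fitted by ML on the same data."""
        table = synthetic_table(n_groups=40, cycles=4, seed=99)
        csv = tmp_path / "d.csv"
        table.to_csv(csv, index=False)
        rscript = (
            "suppressMessages(library(nlme));"
            f"d <- read.csv('{csv}');"
            "m <- lme(y ~ large + tide_m, random = ~1|group_id,"
            " correlation = corAR1(form = ~cycle_index|group_id),"
            " data = d, method = 'ML');"
            "cat(logLik(m), AIC(m), fixef(m)['large'],"
            " as.numeric(VarCorr(m)[1,2]), m$sigma,"
            " coef(m$modelStruct$corStruct, unconstrained=FALSE), sep=',')"
        )
        proc = subprocess.run(
            ["Rscript", "-e", rscript], capture_output=True, text=True
        )
        assert proc.returncode == 0, proc.stderr
        ll, aic, beta, sg, sr, phi = map(float, proc.stdout.strip().split(","))
        fit = fit_mixed_model(
            table, CandidateModel(frozenset({"group_size_class", "tide_m"}), AR1)
        )
        assert fit.loglik == pytest.approx(ll, abs=1e-3)
        assert fit.aic == pytest.approx(aic, abs=1e-2)
        assert fit.coefficients["large"][0] == pytest.approx(beta, abs=1e-3)
        assert fit.sigma_group == pytest.approx(sg, abs=1e-3)
        assert fit.sigma_resid == pytest.approx(sr, abs=1e-3)
        assert fit.phi[0] == pytest.approx(phi, abs=1e-3)


class TestSelectAutocorrelation:
    def test_prefers_ar1_under_serial_correlation(self):
        table = synthetic_table(n_groups=100, cycles=5, phi=0.6, seed=21)
        report = select_autocorrelation(table)
        assert report.prefers_ar1
        assert report.phi > 0.3

    def test_indifferent_without_serial_correlation(self):
        table = synthetic_table(n_groups=150, cycles=5, phi=0.0, seed=22)
        report = select_autocorrelation(table)
        # AR-1 adds one parameter; without signal the penalty dominates
        assert report.delta < 2.5


class TestModelSet:
    @pytest.mark.parametrize("n_preds, expected", [(5, 32), (0, 1), (2, 4)])
    def test_all_subsets_count(self, n_preds, expected):
        preds = (
            "group_size_class",
            "calves",
            "depth_m",
            "transparency_cm",
            "tide_m",
        )[:n_preds]
        models = all_subsets(preds)
        assert len(models) == expected
        assert all(m.correlation == AR1 for m in models)


class TestAkaikeWeights:
    def test_two_models(self):
        w = akaike_weights([100.0, 102.0])
        assert w[0] == pytest.approx(math.e / (math.e + 1), abs=1e-4)
        assert w == pytest.approx([0.7311, 0.2689], abs=1e-4)

    def test_single_model(self):
        assert akaike_weights([123.4]) == pytest.approx([1.0])

    def test_shift_invariance_and_normalisation(self):
        aics = np.array([482.85, 483.99, 484.51, 484.72, 484.83])
        w = akaike_weights(aics)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(w, akaike_weights(aics + 57.0), atol=1e-12)

    def test_published_delta_ratio_law(self):
        """Two models separated by delta AIC = 1.14 must have weight ratio
        exp(-0.57) ~ 0.565, consistent with the published 0.12/0.22."""
        w = akaike_weights([482.85, 483.99])
        assert w[1] / w[0] == pytest.approx(math.exp(-0.57), abs=1e-9)
        assert 0.12 / 0.22 == pytest.approx(math.exp(-0.57), abs=0.03)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            akaike_weights([])


def _stub_fit(predictors, betas, ses, aic=100.0):
    model = CandidateModel(frozenset(predictors), AR1)
    coeffs = {"intercept": (0.0, 0.1)}
    for p, b, s in zip(predictors, betas, ses):
        from franciscana_availability.surface_model import _DESIGN_COLUMNS

        coeffs[_DESIGN_COLUMNS[p]] = (b, s)
    return ModelFit(
        model=model,
        coefficients=coeffs,
        sigma_group=0.1,
        sigma_resid=0.2,
        phi=(0.3,),
        loglik=-(aic - 2 * 4) / 2,
        k=4,
        aic=aic,
        converged=True,
    )


class TestAveraging:
    def test_relative_importance_limits(self):
        fits = [
            _stub_fit(["group_size_class"], [1.0], [0.1]),
            _stub_fit([], [], []),
        ]
        ri = relative_importance(fits, [0.5, 0.5])
        assert ri["group_size_class"] == pytest.approx(0.5)
        assert ri["tide_m"] == 0.0
        ri_all = relative_importance(fits[:1], [1.0])
        assert ri_all["group_size_class"] == 1.0

    def test_single_model_identity(self):
        fits = [_stub_fit(["tide_m"], [0.06], [0.14])]
        avg = model_average(fits, [1.0])
        assert avg["tide_m"] == pytest.approx((0.06, 0.14))

    def test_full_average_shrinks_absent_coefficients(self):
        fits = [
            _stub_fit(["group_size_class"], [1.0], [0.0]),
            _stub_fit([], [], []),
        ]
        avg = model_average(fits, [0.6, 0.4], mode="full")
        assert avg["group_size_class"][0] == pytest.approx(0.6)
        cond = model_average(fits, [0.6, 0.4], mode="conditional")
        assert cond["group_size_class"][0] == pytest.approx(1.0)

    def test_equal_betas_recover_common_se(self):
        fits = [
            _stub_fit(["depth_m"], [0.3], [0.05]),
            _stub_fit(["depth_m", "tide_m"], [0.3, 0.1], [0.05, 0.2]),
        ]
        avg = model_average(fits, [0.5, 0.5])
        assert avg["depth_m"] == pytest.approx((0.3, 0.05))


class TestFitAllSubsets:
    def test_group_size_dominates_on_fixture(self, filtered):
        """On data built with a group-size effect and null environmental
        covariates, the best model contains group size and its relative
        importance exceeds every other predictor's."""
        kept, _ = filtered
        summary = fit_all_subsets(prepare_response(kept))
        assert len(summary.fits) == 32
        assert sum(summary.weights) == pytest.approx(1.0, abs=1e-9)
        assert min(summary.delta) == 0.0
        assert "group_size_class" in summary.best.model.predictors
        ri = summary.ri
        assert all(
            ri["group_size_class"] > ri[p]
            for p in ri
            if p != "group_size_class"
        )
        assert summary.averaged["group_size_class"][0] > 0
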