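"""Factorial OLS fit: coefficients, inference, diagnostics, predictions."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize as sciopt

from extractopt import dataset
from extractopt.design import STUDY_FACTORS, DesignPoint, FactorSpec, build_full_factorial, model_matrix
from extractopt import ffd_model
from extractopt.ffd_model import (
    SingularDesignError,
    fit_ols,
    fit_response,
    fit_statistics,
    predict,
    significant_terms,
    term_pvalues,
)

# published coefficient vectors (response units per coded unit)
PUBLISHED_COEFFICIENTS = {
    "dpph": [215.49, 83.26, 70.72, -0.22, -10.00, 9.77, 5.37, 17.28],
    "frap": [318.45, 99.05, 86.16, 4.82, -20.49, -0.58, 28.64, 27.26],
    "tpc": [190.90, 86.75, 27.04, 9.47, 2.81, 2.79, 3.22, 3.83],
    "tfc": [305.96, 31.41, 34.52, 26.07, 21.15, -7.89, -5.19, 6.09],
    "htc": [310.52, 152.80, 101.96, -48.99, 105.06, -1.61, -47.88, -8.10],
}


@pytest.mark.parametrize("response", sorted(PUBLISHED_COEFFICIENTS))
def test_coefficients_reproduce_published_equations(assay_fits, response):
    fit = assay_fits[response]
    np.testing.assert_allclose(
        fit.coef_vector, PUBLISHED_COEFFICIENTS[response], atol=0.02
    )


def test_significance_pattern(assay_fits):
    # temperature and ethanol drive every antioxidant response; time (and the
    # temperature x ethanol interaction) additionally matter for flavonoids
    # and hydrolyzable tannins
    assert significant_terms(assay_fits["dpph"]) == ("temperature", "ethanol")
    assert significant_terms(assay_fits["frap"]) == ("temperature", "ethanol")
    assert significant_terms(assay_fits["tpc"]) == ("temperature", "ethanol")
    assert set(significant_terms(assay_fits["tfc"])) == {
        "temperature", "ethanol", "time", "temperature:ethanol",
    }
    assert set(significant_terms(assay_fits["htc"])) >= {"temperature", "ethanol", "time"}


def test_dpph_pvalues(dpph_fit):
    assert dpph_fit.p_values["temperature"] < 0.0001
    assert dpph_fit.p_values["ethanol"] < 0.0001
    assert dpph_fit.p_values["time"] == pytest.approx(0.9839, abs=5e-4)


def test_term_pvalue_table_flags(dpph_fit):
    tab = term_pvalues(dpph_fit)
    assert bool(tab.loc["temperature", "significant"])
    assert not bool(tab.loc["time", "significant"])


def test_fit_statistics_reproduce_published_diagnostics(assay_fits):
    s = fit_statistics(assay_fits["dpph"])
    assert s.r2 == pytest.approx(0.8262, abs=5e-4)
    assert s.adj_r2 == pytest.approx(0.7622, abs=5e-4)
    assert s.pred_r2 == pytest.approx(0.6632, abs=5e-4)
    assert s.std_dev == pytest.approx(48.41, abs=0.01)
    assert s.mean == pytest.approx(215.54, abs=0.01)
    assert s.cv_pct == pytest.approx(22.46, abs=0.01)
    assert s.adequate_precision == pytest.approx(12.9832, rel=5e-3)
    assert s.is_adequate
    frap = fit_statistics(assay_fits["frap"])
    assert frap.r2 == pytest.approx(0.7873, abs=5e-4)
    assert frap.adequate_precision == pytest.approx(11.8708, rel=5e-3)


def test_ctc_model_flagged_inadequate(assay_fits):
    s = fit_statistics(assay_fits["ctc"])
    assert s.pred_r2 < 0
    assert not s.is_adequate


def test_fit_is_deterministic_and_df_correct(dpph_fit):
    assert dpph_fit.df_residual == 19
    # residuals orthogonal to every model column
    dots = dpph_fit.matrix.values.T @ dpph_fit.residuals
    assert np.abs(dots).max() < 1e-6 * np.abs(dpph_fit.y).sum()


def test_intercept_identity_on_study_design(assay_fits):
    # all columns except X3 have zero mean over this design, so
    # b0 = ybar - b3 * mean(X3)
    for fit in assay_fits.values():
        x3_mean = fit.matrix.column("time").mean()
        assert fit.coefficients["intercept"] == pytest.approx(
            fit.y.mean() - fit.coefficients["time"] * x3_mean, rel=1e-10
        )


def test_press_at_least_sse_and_interactions_never_hurt_r2(oak_table, assay_fits):
    mm_full = oak_table.model_matrix()
    mm_main = type(mm_full)(terms=mm_full.terms[:4], values=mm_full.values[:, :4],
                            factor_names=mm_full.factor_names)
    for r, fit in assay_fits.items():
        s = fit_statistics(fit)
        assert s.press >= fit.sse
        reduced = fit_ols(mm_main, oak_table.response(r), r)
        assert fit_statistics(fit).r2 >= fit_statistics(reduced).r2 - 1e-12


def test_refit_of_fitted_values_is_idempotent(dpph_fit, oak_table):
    refit = fit_ols(oak_table.model_matrix(), dpph_fit.fitted, "dpph_hat")
    assert fit_statistics(refit).r2 == pytest.approx(1.0, abs=1e-12)
    np.testing.assert_allclose(refit.coef_vector, dpph_fit.coef_vector, atol=1e-8)


def test_constant_response_gives_zero_effects(oak_table):
    fit = fit_ols(oak_table.model_matrix(), np.full(27, 7.0), "const")
    assert fit.coefficients["intercept"] == pytest.approx(7.0)
    assert np.abs(fit.coef_vector[1:]).max() < 1e-10


def test_rank_deficient_matrix_rejected(oak_table):
    mm = oak_table.model_matrix()
    bad = type(mm)(terms=mm.terms, values=mm.values.copy(), factor_names=mm.factor_names)
    bad.values[:, 7] = bad.values[:, 1]  # duplicate a column
    with pytest.raises(SingularDesignError):
        fit_ols(bad, oak_table.response("dpph"))


def test_normal_equations_match_brute_force_minimization():
    # tiny 5-run instance: direct numerical minimization of the squared error
    # is the independent oracle for the least-squares solution
    rng = np.random.default_rng(7)
    facs = (FactorSpec("a", -1.0, 0.0, 1.0), FactorSpec("b", -1.0, 0.0, 1.0))
    pts = [
        DesignPoint.from_natural(facs, dict(a=a, b=b))
        for a, b in [(-1, -1), (1, -1), (-1, 1), (1, 1), (0, 0)]
    ]
    mm = model_matrix(pts)
    X = mm.values[:, :4]  # intercept, a, b, ab — full rank on 5 runs
    mm4 = type(mm)(terms=mm.terms[:4], values=X, factor_names=mm.factor_names)
    for _ in range(5):
        y = rng.normal(size=5)
        fit = fit_ols(mm4, y)
        sol = sciopt.minimize(lambda b: ((y - X @ b) ** 2).sum(), np.zeros(4), method="Nelder-Mead",
                              options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 20000})
        np.testing.assert_allclose(fit.coef_vector, sol.x, rtol=1e-6, atol=1e-6)


@pytest.mark.parametrize(
    "settings, expected",
    [
        (dict(temperature=80, ethanol=40, time=24), 391.67),
        (dict(temperature=79.986, ethanol=39.388, time=16.281), 365.925),
    ],
)
def test_dpph_predictions_at_published_settings(dpph_fit, settings, expected):
    point = DesignPoint.from_natural(STUDY_FACTORS, settings)
    assert predict(dpph_fit, point).fit == pytest.approx(expected, abs=0.05)


def test_prediction_at_centre_equals_intercept(dpph_fit):
    centre = DesignPoint.from_coded(STUDY_FACTORS, dict(temperature=0, ethanol=0, time=0))
    assert predict(dpph_fit, centre).fit == pytest.approx(dpph_fit.coefficients["intercept"])


def test_multi_response_prediction_with_interval(assay_fits):
    # at the joint optimum (80 degC, 40 %, 19.8 h) the models reproduce the
    # published predictions, SE of fit and 95% prediction interval
    point = DesignPoint.from_natural(STUDY_FACTORS, dict(temperature=80, ethanol=40, time=19.8))
    p = predict(assay_fits["dpph"], point)
    assert p.fit == pytest.approx(378.7, abs=0.15)
    assert p.se_fit == pytest.approx(32.1, rel=0.01)
    assert p.pi95_low == pytest.approx(257.2, rel=0.01)
    assert p.pi95_high == pytest.approx(500.2, rel=0.01)
    assert predict(assay_fits["tfc"], point).fit == pytest.approx(404.4, abs=0.15)
    # the reported FRAP value corresponds to the unrounded optimum time
    # (~19.77 h), so 19.8 h lands within a short distance of it
    assert predict(assay_fits["frap"], point).fit == pytest.approx(519.1, abs=0.3)
    assert p.pi95_low < p.fit < p.pi95_high
    assert (p.fit - p.pi95_low) == pytest.approx(p.pi95_high - p.fit)


def test_extrapolated_prediction_flagged(dpph_fit):
    point = DesignPoint.from_natural(STUDY_FACTORS, dict(temperature=95, ethanol=20, time=6))
    assert predict(dpph_fit, point).extrapolated


def test_residual_normality_data_shape(dpph_fit):
    qq = ffd_model.residual_normality_data(dpph_fit)
    assert len(qq) == 27
    assert (np.diff(qq["residual"]) >= 0).all()
    assert (np.diff(qq["normal_quantile"]) > 0).all()


def test_fit_report_serializable(dpph_fit):
    import json

    doc = json.dumps(ffd_model.fit_report(dpph_fit))
    assert "adequate_precision" in doc
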