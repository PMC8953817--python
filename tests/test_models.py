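"""Poisson fits, AIC ranking arithmetic, contrasts and environment ANOVA."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mitecomm import models
from mitecomm.datamodel import EnvironmentTable, ValidationError
from mitecomm.models import (
    ModelFit, fit_model, fit_candidates, rank_models, model_contrasts,
    response_tables, screen_collinearity, env_anova_tukey,
)
from mitecomm.synthetic import generate
from conftest import make_community
from _specs import offset_spec, flat_env, PLOTS


def _stub(formula, LL, K, n=250):
    return ModelFit(response="abundance", formula=formula, LL=LL, K=K, n=n,
                    params=pd.Series(dtype=float), bse=pd.Series(dtype=float),
                    converged=True, random_site=False)


# -- responses & screening ---------------------------------------------------

def test_response_tables():
    com = make_community([[2, 0, 3], [0, 0, 0]], ["A", "B"])
    r = response_tables(com)
    assert r.loc["s0", "abundance"] == 5 and r.loc["s0", "richness"] == 2
    assert r.loc["s1", "abundance"] == 0 and r.loc["s1", "richness"] == 0


def test_response_conserves_totals(preset_data):
    community, _ = preset_data
    from mitecomm.structure import plot_summaries
    assert (response_tables(community)["abundance"].sum()
            == plot_summaries(community).loc["pooled", "abundance"])


def _env_from(df):
    base = pd.DataFrame({
        "VegCovr": 60.0, "H": 60.0, "Ts": 15.0, "pH": 5.0, "RPs": 1.3,
    }, index=df.index)
    for c in df.columns:
        base[c] = df[c]
    return EnvironmentTable(base)


def test_screen_keeps_orthogonal():
    rng = np.random.default_rng(0)
    Z = np.linalg.qr(rng.normal(size=(60, 3)))[0]
    env = _env_from(pd.DataFrame(
        {"Ts": 15 + Z[:, 0], "pH": 5 + Z[:, 1], "RPs": 1.3 + 0.1 * Z[:, 2]},
        index=[f"s{i}" for i in range(60)]))
    assert screen_collinearity(env) == list(env.table.columns)


def test_screen_drops_duplicate_and_correlated():
    rng = np.random.default_rng(1)
    Z = np.linalg.qr(rng.normal(size=(60, 3)))[0]
    idx = [f"s{i}" for i in range(60)]
    # VegCovr and H are near-duplicates (r = 0.95); Ts orthogonal
    env = _env_from(pd.DataFrame({
        "VegCovr": 60 + Z[:, 0],
        "H": 60 + 0.95 * Z[:, 0] + math.sqrt(1 - 0.95**2) * Z[:, 1],
        "Ts": 15 + Z[:, 2]}, index=idx))
    kept = screen_collinearity(env, threshold=3.0)
    # pairwise r = 0.95 -> VIF = 1/(1-0.9025) = 10.3 > 3; tie broken by
    # declaration order so the earlier column survives
    assert "VegCovr" in kept and "H" not in kept and "Ts" in kept

    dup = _env_from(pd.DataFrame({"VegCovr": 60 + Z[:, 0],
                                  "H": 60 + Z[:, 0]}, index=idx))
    kept = screen_collinearity(dup, threshold=3.0)
    assert kept.count("VegCovr") + kept.count("H") >= 1
    assert len([c for c in kept if c in ("VegCovr", "H")]) == 1


# -- fitting -----------------------------------------------------------------

def test_intercept_only_closed_form():
    y = pd.Series([3, 5, 4], index=["a", "b", "c"])
    fit = fit_model(y, None, None, "1")
    rate = math.exp(fit.params["Intercept"])
    assert rate == pytest.approx(4.0, rel=1e-6)
    assert fit.LL == pytest.approx(stats.poisson.logpmf(y, 4.0).sum(), rel=1e-9)
    assert fit.K == 1


def test_noise_covariate_never_decreases_ll(preset_data):
    community, env = preset_data
    resp = response_tables(community)["abundance"]
    base = fit_model(resp, env, community.plot_of, "treatment",
                     plots=community.plots)
    bigger = fit_model(resp, env, community.plot_of, "treatment + pH",
                       plots=community.plots)
    assert bigger.LL >= base.LL - 1e-8


def test_random_site_boundary_collapses_to_glm(preset_data):
    """Site == plot is confounded with treatment: the variance component
    hits the boundary and the mixed LL equals the plain Poisson LL."""
    community, env = preset_data
    resp = response_tables(community)["abundance"]
    plain = fit_model(resp, env, community.plot_of, "treatment",
                      plots=community.plots)
    mixed = fit_model(resp, env, community.plot_of, "treatment",
                      random_site=True, plots=community.plots)
    assert mixed.sigma2_site == pytest.approx(0.0, abs=1e-6)
    assert mixed.LL == pytest.approx(plain.LL, abs=1e-8)
    assert mixed.K == plain.K + 1


def test_random_site_absorbs_plot_variation(preset_data):
    """Without the treatment term the plot-level heterogeneity goes into
    the random intercept: positive variance, LL above the plain GLM."""
    community, env = preset_data
    resp = response_tables(community)["abundance"]
    plain = fit_model(resp, None, community.plot_of, "1")
    mixed = fit_model(resp, None, community.plot_of, "1", random_site=True)
    assert mixed.sigma2_site > 0.01
    assert mixed.LL > plain.LL + 10


def test_coefficient_recovery_with_known_offsets():
    offsets = {"CG": 0.0, "A": 0.5, "B": -0.3, "C": 0.2, "D": 1.0}
    com, _ = generate(offset_spec(offsets), 123)
    resp = response_tables(com)["abundance"]
    fit = fit_model(resp, None, com.plot_of, "treatment", plots=PLOTS)
    for lev in ("A", "B", "C", "D"):
        est, se = fit.params[f"treatment[{lev}]"], fit.bse[f"treatment[{lev}]"]
        assert abs(est - offsets[lev]) <= 2 * se


# -- ranking -----------------------------------------------------------------

def test_rank_models_weights_and_shift_invariance():
    fits = [_stub("m1", -545.63, 6), _stub("m2", -545.47, 7), _stub("m3", -560.0, 7)]
    tab = rank_models(fits)
    assert tab["weight"].sum() == pytest.approx(1.0)
    assert tab.iloc[0]["model"] == "m1" and tab.iloc[0]["delta"] == 0.0
    shifted = [_stub(f.formula, f.LL + 100.0, f.K) for f in fits]
    tab2 = rank_models(shifted)
    np.testing.assert_allclose(tab["delta"], tab2["delta"], atol=1e-9)
    np.testing.assert_allclose(tab["weight"], tab2["weight"], atol=1e-12)


def test_rank_single_model():
    tab = rank_models([_stub("only", -10.0, 2)])
    assert tab["delta"].iloc[0] == 0.0 and tab["weight"].iloc[0] == 1.0


def test_rank_mixed_n_errors():
    with pytest.raises(ValidationError):
        rank_models([_stub("a", -10, 2, n=100), _stub("b", -9, 2, n=99)])


def test_aicc_converges_to_aic():
    f = _stub("m", -1000.0, 6, n=10**6)
    assert abs(f.aicc - f.aic) < 1e-3


# -- contrasts ---------------------------------------------------------------

def test_contrasts_sign_and_adjustment(preset_data):
    community, env = preset_data
    resp = response_tables(community)["abundance"]
    fit = fit_model(resp, env, community.plot_of, "treatment",
                    plots=community.plots)
    contr = model_contrasts(fit, "CG")
    assert set(contr["contrast"]) == {"CG-A", "CG-B", "CG-C", "CG-D"}
    # D carries far more individuals than the control: strongly negative
    d_row = contr.set_index("contrast").loc["CG-D"]
    assert d_row["estimate"] < -1.0
    # single-step adjustment can only inflate the marginal p
    for _, row in contr.iterrows():
        p_raw = 2 * stats.norm.sf(abs(row["z"]))
        assert row["p_adj"] >= p_raw - 1e-9


def test_contrast_recovers_planted_log_ratio():
    offsets = {"CG": 0.0, "A": 0.0, "B": 0.0, "C": 0.0, "D": 3.0}
    com, _ = generate(offset_spec(offsets, n_per_plot=30), 5)
    resp = response_tables(com)["abundance"]
    fit = fit_model(resp, None, com.plot_of, "treatment", plots=PLOTS)
    row = model_contrasts(fit, "CG").set_index("contrast").loc["CG-D"]
    assert abs(row["estimate"] - (-3.0)) <= 2 * row["SE"]


def test_contrasts_require_treatment():
    with pytest.raises(ValidationError):
        model_contrasts(_stub("1", -10, 1))


# -- environment ANOVA / Tukey -----------------------------------------------

def test_anova_two_groups_equals_t_squared():
    rng = np.random.default_rng(0)
    idx = [f"s{i}" for i in range(40)]
    vals = np.concatenate([rng.normal(0, 1, 20), rng.normal(0.8, 1, 20)])
    env = _env_from(pd.DataFrame({"Ts": 15 + vals}, index=idx))
    plot_of = pd.Series(["A"] * 20 + ["B"] * 20, index=idx)
    anova, _ = env_anova_tukey(env, plot_of, variables=["Ts"])
    t = stats.ttest_ind(vals[:20], vals[20:]).statistic
    assert anova["F"].iloc[0] == pytest.approx(t**2, rel=1e-9)


def test_anova_zero_variance_errors():
    idx = [f"s{i}" for i in range(8)]
    env = _env_from(pd.DataFrame({"Ts": [15.0] * 8}, index=idx))
    plot_of = pd.Series(["A"] * 4 + ["B"] * 4, index=idx)
    with pytest.raises(ValidationError, match="Ts"):
        env_anova_tukey(env, plot_of, variables=["Ts"])


def test_tukey_detects_planted_shift():
    """A 1.5-SD mean shift between two of five groups (n=50) is flagged
    by the Tukey-adjusted p at far below 0.001."""
    em, es = flat_env()
    em.loc["D", "Ts"] = em.loc["CG", "Ts"] + 1.5 * es.loc["CG", "Ts"]
    from mitecomm.synthetic import GeneratorSpec
    occ = pd.DataFrame(0.5, index=list(PLOTS), columns=["sp0", "sp1"])
    spec = GeneratorSpec(plots=PLOTS, samples_per_plot=50, env_means=em,
                         env_sds=es, occupancy=occ)
    hits = 0
    for s in range(20):
        com, env = generate(spec, 60_000 + s)
        _, tukey = env_anova_tukey(env, com.plot_of, variables=["Ts"])
        row = tukey.set_index("contrast")["p_adj"]
        p = row.get("CG-D", row.get("D-CG"))
        hits += p < 0.001
    assert hits >= 19


def test_full_candidate_ranking_prefers_treatment_structure(preset_data):
    """On the study preset the plot factor dominates every candidate that
    lacks it (the planted plot offsets are large)."""
    community, env = preset_data
    fits = fit_candidates(community, env, "richness")
    tab = rank_models(fits)
    assert len(fits) == 15
    assert "treatment" in tab.iloc[0]["model"]
    assert tab["weight"].sum() == pytest.approx(1.0)
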