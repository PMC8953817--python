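"""Poisson models of per-sample abundance and richness with
information-theoretic model selection, plus environment ANOVA/Tukey.

Candidate models are Poisson GLMs (log link) of per-sample abundance or
species richness on the treatment factor and environment covariates,
optionally with a Gaussian random intercept per site integrated by
Laplace approximation (site and treatment coincide in a one-site-per-
plot design, so the variance component routinely collapses to the
boundary and the fit reduces to the plain GLM; the variance component
still counts as a parameter).

Ranking uses AIC = -2LL + 2K by default, with the small-sample AICc
( + 2K(K+1)/(n-K-1) ) available by flag; Akaike weights are
w_i = exp(-delta_i/2) / sum exp(-delta/2), and models with delta_i < 2
are flagged competitive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import f_oneway, multivariate_normal
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .datamodel import CommunityMatrix, EnvironmentTable, ValidationError, ENV_VARIABLES

BOUNDARY_VAR = 1e-8


# ---------------------------------------------------------------------------
# responses and collinearity screening
# ---------------------------------------------------------------------------

def response_tables(community: CommunityMatrix) -> pd.DataFrame:
    """Per-sample abundance (row sum), richness (nonzero species), plot."""
    return pd.DataFrame({
        "abundance": community.counts.sum(axis=1),
        "richness": (community.counts > 0).sum(axis=1),
        "plot": community.plot_of,
    })


def _ols_vif(df: pd.DataFrame) -> pd.Series:
    # constant columns cannot inflate nor be inflated: VIF 1 by convention
    sd = df.std(ddof=1)
    varying = list(sd.index[sd > 0])
    out = pd.Series(1.0, index=df.columns)
    if len(varying) < 2:
        return out
    X = ((df[varying] - df[varying].mean()) / sd[varying]).to_numpy()
    R = np.corrcoef(X, rowvar=False)
    for j, name in enumerate(varying):
        others = [i for i in range(len(varying)) if i != j]
        sub = R[np.ix_(others, others)]
        rj = R[others, j]
        try:
            r2 = float(rj @ np.linalg.solve(sub, rj))
        except np.linalg.LinAlgError:
            r2 = 1.0
        out[name] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def screen_collinearity(env: EnvironmentTable, threshold: float = 3.0) -> list[str]:
    """Iteratively drop the highest-VIF covariate until all VIF <= threshold.

    Ties break by declaration order (the earlier column is kept).
    Returns the retained covariate names in declaration order.
    """
    cols = [c for c in env.table.columns]
    while len(cols) > 1:
        vif = _ols_vif(env.table[cols])
        worst = vif.idxmax()
        # idxmax takes the first maximum; drop the LAST tied column so the
        # earlier-declared covariate survives
        tied = [c for c in cols if vif[c] == vif[worst]]
        worst = tied[-1]
        if vif[worst] <= threshold:
            break
        cols.remove(worst)
    return cols


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

@dataclass
class ModelFit:
    response: str
    formula: str
    LL: float
    K: int
    n: int
    params: pd.Series
    bse: pd.Series
    converged: bool
    random_site: bool
    sigma2_site: float = 0.0
    cov_params: pd.DataFrame | None = field(default=None, repr=False)
    aic_: float | None = None

    @property
    def aic(self) -> float:
        return -2.0 * self.LL + 2.0 * self.K

    @property
    def aicc(self) -> float:
        if self.n - self.K - 1 <= 0:
            return math.inf
        return self.aic + 2.0 * self.K * (self.K + 1) / (self.n - self.K - 1)

    def criterion(self, kind: str = "aic") -> float:
        return self.aic if kind == "aic" else self.aicc


def _parse_formula(formula: str) -> list[str]:
    terms = [t.strip() for t in formula.split("+")]
    return [t for t in terms if t and t != "1"]


def _design(formula: str, env: EnvironmentTable | None, plot_of: pd.Series | None,
            reference: str, plots: tuple[str, ...] | None = None,
            index=None) -> pd.DataFrame:
    terms = _parse_formula(formula)
    if index is None:
        index = plot_of.index if plot_of is not None else env.table.index
    X = pd.DataFrame({"Intercept": np.ones(len(index))}, index=index)
    for t in terms:
        if t == "treatment":
            if plot_of is None:
                raise ValidationError("treatment term needs a plot assignment")
            levels = [p for p in (plots or sorted(plot_of.unique()))]
            if reference not in levels:
                raise ValidationError(f"reference {reference!r} not a plot level")
            for lev in levels:
                if lev == reference:
                    continue
                X[f"treatment[{lev}]"] = (plot_of == lev).astype(float)
        else:
            if env is None or t not in env.table.columns:
                raise ValidationError(f"unknown model term {t!r}")
            X[t] = env.table.loc[index, t]
    return X


def _poisson_laplace(y: np.ndarray, X: np.ndarray, gidx: np.ndarray,
                     n_groups: int, max_iter: int = 200, tol: float = 1e-8):
    """Poisson GLMM with one Gaussian random intercept, Laplace-approximated.

    Returns (LL, beta, bse, sigma2, converged).  The inner step finds the
    joint (beta, u) mode by damped Newton; the outer step profiles the
    random-intercept variance on the log scale.
    """
    n, p = X.shape
    Z = np.zeros((n, n_groups))
    Z[np.arange(n), gidx] = 1.0
    Xt = np.hstack([X, Z])
    lgy = gammaln(y + 1).sum()

    def joint_mode(s2):
        theta = np.zeros(p + n_groups)
        theta[0] = math.log(max(y.mean(), 0.1))
        pen = np.concatenate([np.zeros(p), np.full(n_groups, 1.0 / s2)])

        def joint_ll(th):
            eta = Xt @ th
            return float((y * eta - np.exp(eta)).sum() - lgy
                         - 0.5 * (pen * th**2).sum()
                         - 0.5 * n_groups * math.log(2 * math.pi * s2))

        ll = joint_ll(theta)
        ok = False
        for _ in range(max_iter):
            eta = np.clip(Xt @ theta, -30, 30)
            mu = np.exp(eta)
            grad = Xt.T @ (y - mu) - pen * theta
            H = (Xt * mu[:, None]).T @ Xt + np.diag(pen)
            H[np.diag_indices_from(H)] += 1e-10
            step = np.linalg.solve(H, grad)
            t = 1.0
            while t > 1e-8:
                cand = theta + t * step
                cll = joint_ll(cand)
                if cll >= ll - 1e-12:
                    break
                t /= 2.0
            theta, new_ll = theta + t * step, joint_ll(theta + t * step)
            if abs(new_ll - ll) < tol:
                ll = new_ll
                ok = True
                break
            ll = new_ll
        mu = np.exp(np.clip(Xt @ theta, -30, 30))
        H_uu = np.array([mu[gidx == g].sum() for g in range(n_groups)]) + 1.0 / s2
        lap = ll + 0.5 * n_groups * math.log(2 * math.pi) - 0.5 * np.log(H_uu).sum()
        return lap, theta, mu, ok

    def neg_lap(log_s2):
        return -joint_mode(math.exp(log_s2))[0]

    res = minimize_scalar(neg_lap, bounds=(math.log(BOUNDARY_VAR), math.log(25.0)),
                          method="bounded", options={"xatol": 1e-6})
    s2 = math.exp(res.x)
    lap, theta, mu, ok = joint_mode(s2)
    at_boundary = s2 <= BOUNDARY_VAR * 2.5
    beta = theta[:p]
    # fixed-effect covariance from the joint Hessian, marginalising u
    pen = np.concatenate([np.zeros(p), np.full(n_groups, 1.0 / s2)])
    H = (Xt * mu[:, None]).T @ Xt + np.diag(pen)
    cov = np.linalg.inv(H)[:p, :p]
    return lap, beta, cov, (BOUNDARY_VAR if at_boundary else s2), ok, at_boundary


def fit_model(response: pd.Series, env: EnvironmentTable | None,
              plot_of: pd.Series | None, formula: str,
              random_site: bool = False, reference: str = "CG",
              plots: tuple[str, ...] | None = None,
              response_name: str = "abundance") -> ModelFit:
    """Fit one Poisson (or Laplace random-intercept Poisson) candidate.

    ``formula`` is a '+'-joined term list over ``treatment`` and
    environment covariate names ("1" = intercept only).  K counts the
    fixed coefficients plus one per variance component.
    """
    y = response.to_numpy(dtype=float)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValidationError("response must be non-negative integers")
    Xdf = _design(formula, env, plot_of, reference, plots, index=response.index)
    X = Xdf.to_numpy(dtype=float)
    n, p = X.shape

    glm = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    if not random_site:
        cov = pd.DataFrame(glm.cov_params(), index=Xdf.columns, columns=Xdf.columns)
        return ModelFit(response_name, formula, float(glm.llf), p, n,
                        pd.Series(glm.params, index=Xdf.columns),
                        pd.Series(glm.bse, index=Xdf.columns),
                        bool(glm.converged), False, cov_params=cov)

    if plot_of is None:
        raise ValidationError("random_site requires a plot assignment")
    levels = sorted(plot_of.unique())
    gidx = plot_of.map({l: i for i, l in enumerate(levels)}).to_numpy()
    lap, beta, cov, s2, ok, at_boundary = _poisson_laplace(y, X, gidx, len(levels))
    if at_boundary:
        # variance at the boundary: the mixed fit collapses to the GLM
        lap = float(glm.llf)
        beta = np.asarray(glm.params)
        cov = np.asarray(glm.cov_params())
        s2 = 0.0
        ok = bool(glm.converged)
    covdf = pd.DataFrame(cov, index=Xdf.columns, columns=Xdf.columns)
    return ModelFit(response_name, formula, float(lap), p + 1, n,
                    pd.Series(beta, index=Xdf.columns),
                    pd.Series(np.sqrt(np.diag(cov)), index=Xdf.columns),
                    ok, True, sigma2_site=float(s2), cov_params=covdf)


def fit_candidates(community: CommunityMatrix, env: EnvironmentTable,
                   response: str = "abundance", candidates=None,
                   random_site: bool = True, reference: str = "CG") -> list[ModelFit]:
    """Fit the candidate model set for one response."""
    from .datamodel import DEFAULT_CANDIDATES
    candidates = list(candidates) if candidates is not None else list(DEFAULT_CANDIDATES)
    resp = response_tables(community)[response]
    fits = []
    for formula in candidates:
        fits.append(fit_model(resp, env, community.plot_of, formula,
                              random_site=random_site, reference=reference,
                              plots=community.plots, response_name=response))
    return fits


def rank_models(fits: list[ModelFit], criterion: str = "aic") -> pd.DataFrame:
    """AIC/AICc ranking table with delta_i, Akaike weights, competitive flag.

    Non-converged fits are excluded from the ranking; mixed-n candidate
    sets are an error.
    """
    if not fits:
        raise ValidationError("empty candidate set")
    ns = {f.n for f in fits}
    if len(ns) > 1:
        raise ValidationError(f"candidate models fit on different n: {sorted(ns)}")
    usable = [f for f in fits if f.converged]
    if not usable:
        raise ValidationError("no converged candidate model")
    crit = np.array([f.criterion(criterion) for f in usable])
    delta = crit - crit.min()
    w = np.exp(-delta / 2.0)
    w = w / w.sum()
    out = pd.DataFrame({
        "model": [f.formula for f in usable],
        "LL": [f.LL for f in usable],
        "K": [f.K for f in usable],
        criterion: crit,
        "delta": delta,
        "weight": w,
        "competitive": delta < 2.0,
    }).sort_values("weight", ascending=False).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# multiple comparisons
# ---------------------------------------------------------------------------

def model_contrasts(fit: ModelFit, reference: str = "CG") -> pd.DataFrame:
    """Reference-vs-treatment contrasts on the linear-predictor scale.

    Contrast "REF-X" estimates eta_REF - eta_X = -beta_X; adjusted
    p-values use the single-step max-|z| multivariate-normal adjustment
    over the contrast family (the same family-wise correction as
    standard multiple-comparison software).
    """
    terms = [c for c in fit.params.index if c.startswith("treatment[")]
    if not terms:
        raise ValidationError("best model does not include treatment")
    if fit.cov_params is None:
        raise ValidationError("fit lacks a coefficient covariance matrix")
    est = -fit.params[terms].to_numpy()
    V = fit.cov_params.loc[terms, terms].to_numpy()
    se = np.sqrt(np.diag(V))
    z = est / se
    R = V / np.outer(se, se)
    R = (R + R.T) / 2.0 + 1e-10 * np.eye(len(terms))
    padj = []
    for zi in z:
        a = abs(zi)
        inside = multivariate_normal(mean=np.zeros(len(terms)), cov=R,
                                     allow_singular=True, seed=0).cdf(
            np.full(len(terms), a), lower_limit=np.full(len(terms), -a))
        padj.append(min(1.0, max(0.0, 1.0 - float(inside))))
    labels = [f"{reference}-{t[len('treatment['):-1]}" for t in terms]
    return pd.DataFrame({"contrast": labels, "estimate": est, "SE": se,
                         "z": z, "p_adj": padj})


def env_anova_tukey(env: EnvironmentTable, plot_of: pd.Series,
                    variables=None, alpha: float = 0.05):
    """One-way ANOVA and Tukey HSD per environment variable.

    Returns ``(anova, tukey)``: the ANOVA table has one row per variable
    (between-group df, MS, F, p); the Tukey table one row per variable x
    plot pair (diff of means, 95% studentized-range limits, adjusted p).
    Zero within-group variance is an error naming the variable.
    """
    variables = list(variables) if variables is not None else list(ENV_VARIABLES)
    plot_of = plot_of.loc[env.samples]
    groups = sorted(plot_of.unique())
    if len(groups) < 2 or any((plot_of == g).sum() < 2 for g in groups):
        raise ValidationError("ANOVA needs >= 2 plots with >= 2 samples each")
    anova_rows, tukey_rows = [], []
    for var in variables:
        x = env.table[var]
        arrs = [x[plot_of == g].to_numpy() for g in groups]
        if all(np.var(a) == 0 for a in arrs):
            raise ValidationError(f"zero within-group variance for {var!r}")
        grand = x.mean()
        ssb = sum(len(a) * (a.mean() - grand) ** 2 for a in arrs)
        dfb = len(groups) - 1
        F, p = f_oneway(*arrs)
        anova_rows.append({"variable": var, "df": dfb, "MS": ssb / dfb,
                           "F": float(F), "p": float(p)})
        tk = pairwise_tukeyhsd(x.to_numpy(), plot_of.to_numpy(), alpha=alpha)
        df = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
        for _, row in df.iterrows():
            tukey_rows.append({
                "variable": var,
                "contrast": f"{row['group1']}-{row['group2']}",
                "diff": float(row["meandiff"]),
                "lower": float(row["lower"]),
                "upper": float(row["upper"]),
                "p_adj": float(row["p-adj"]),
            })
    return pd.DataFrame(anova_rows), pd.DataFrame(tukey_rows)
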