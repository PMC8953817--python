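"""Bray-Curtis dissimilarity, NMDS, ANOSIM and constrained correspondence
analysis (CCA) with forward selection, VIF screening and permutation
inference.

The ordination machinery is written directly on the matrix algebra:

* CCA chi-square double-standardizes the (optionally ln(x+1)
  transformed) community matrix into Q = (P - r c^T) / sqrt(r c^T),
  projects it onto the row-weighted, centered constraint matrix, and
  eigen-decomposes the fitted part via SVD.  Total inertia is ||Q||^2_F
  (the sum of all correspondence-analysis eigenvalues); constrained
  inertia is the summed canonical eigenvalues.
* NMDS minimizes Kruskal stress-1 by SMACOF iterations with monotone
  (isotonic) regression disparities, multiple starts, and returns the
  best configuration centered and rotated to principal axes.
* ANOSIM ranks all off-diagonal dissimilarities (average ranks on ties)
  and computes R = (mean between-group rank - mean within-group rank) /
  (M/2); significance by random relabelling of samples.

Permutation p-values use the add-one convention
p = (1 + #{perm >= obs}) / (1 + n_perm), so p >= 1/(1+n_perm) > 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .datamodel import CommunityMatrix, EnvironmentTable, ValidationError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------

@dataclass
class DissimilarityMatrix:
    """Symmetric sample x sample dissimilarities in [0, 1]."""

    labels: list[str]
    d: np.ndarray

    @property
    def condensed(self) -> np.ndarray:
        return squareform(self.d, checks=False)

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        if self.d.ndim != 2 or self.d.shape[0] != self.d.shape[1]:
            raise ValidationError("dissimilarity matrix must be square")
        if len(self.labels) != self.d.shape[0]:
            raise ValidationError("labels must match matrix size")


def bray_curtis(community: CommunityMatrix, transform: str = "none") -> DissimilarityMatrix:
    """Bray-Curtis dissimilarity between all sample pairs.

    d(i,j) = sum |x_i - x_j| / sum (x_i + x_j) over species, after the
    chosen transform (``"none"`` or ``"ln1p"``).  Pairs of two empty
    samples are defined as 0 (with a warning).
    """
    X = community.values.astype(float)
    if transform == "ln1p":
        X = np.log1p(X)
    elif transform != "none":
        raise ValidationError(f"unknown transform {transform!r}")
    if X.shape[0] < 2:
        raise ValidationError("Bray-Curtis needs >= 2 samples")
    with np.errstate(invalid="ignore", divide="ignore"):
        dv = pdist(X, metric="braycurtis")
    if np.isnan(dv).any():
        log.warning("Bray-Curtis: %d empty-empty pairs set to 0", int(np.isnan(dv).sum()))
        dv = np.nan_to_num(dv, nan=0.0)
    return DissimilarityMatrix(list(community.samples), squareform(dv))


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

@dataclass
class NMDSResult:
    coordinates: pd.DataFrame
    stress: float
    converged: bool
    n_starts: int
    best_start: int
    stress_history: list[float] = field(default_factory=list, repr=False)


def _disparities(dhat: np.ndarray, order: np.ndarray, tie_blocks: np.ndarray) -> np.ndarray:
    """Monotone disparities for embedded distances ``dhat``.

    ``order`` sorts the observed dissimilarities ascending and
    ``tie_blocks`` labels runs of tied observed values; within a tied
    block the embedded distances are sorted ascending before the
    isotonic fit (Kruskal's primary approach to ties).
    """
    y = dhat[order]
    # sort within tie blocks
    for start, stop in tie_blocks:
        if stop - start > 1:
            y[start:stop] = np.sort(y[start:stop])
    fit = isotonic_regression(y).x
    out = np.empty_like(dhat)
    out[order] = fit
    return out


def _classical_scaling(D: np.ndarray, k: int) -> np.ndarray:
    """Torgerson principal-coordinates start configuration."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh(B)
    idx = np.argsort(w)[::-1][:k]
    lam = np.clip(w[idx], 0, None)
    return V[:, idx] * np.sqrt(lam)[None, :]


def nmds(d: DissimilarityMatrix, k: int = 2, n_starts: int = 20,
         max_iter: int = 300, tol: float = 1e-7, seed: int = 0) -> NMDSResult:
    """Non-metric MDS minimising Kruskal stress-1.

    SMACOF (Guttman-transform) iterations alternating with isotonic
    disparities.  Start 0 is the classical-scaling configuration, the
    remaining starts are random Gaussians; the lowest-stress solution is
    returned, centered and rotated to its principal axes.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    dv = d.condensed
    n = d.d.shape[0]
    order = np.argsort(dv, kind="stable")
    sorted_d = dv[order]
    # tie blocks of equal observed dissimilarity
    edges = np.flatnonzero(np.diff(sorted_d) > 0) + 1
    bounds = np.concatenate([[0], edges, [len(dv)]])
    tie_blocks = np.column_stack([bounds[:-1], bounds[1:]])

    rng = np.random.default_rng(seed)
    best = None
    for start in range(max(1, n_starts)):
        if start == 0:
            X = _classical_scaling(d.d, k)
            if not np.all(np.isfinite(X)):
                X = rng.normal(size=(n, k))
        else:
            X = rng.normal(size=(n, k))
        history = []
        converged = False
        prev = np.inf
        for _ in range(max_iter):
            dhat = pdist(X)
            disp = _disparities(dhat, order, tie_blocks)
            denom = float((dhat**2).sum())
            stress = 0.0 if denom == 0 else float(np.sqrt(((dhat - disp) ** 2).sum() / denom))
            history.append(stress)
            if prev - stress < tol:
                converged = True
                break
            prev = stress
            # Guttman transform toward the disparities
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(dhat > 0, disp / np.where(dhat > 0, dhat, 1.0), 0.0)
            Bmat = -squareform(ratio)
            np.fill_diagonal(Bmat, -Bmat.sum(axis=0))
            X = Bmat @ X / n
        final = history[-1] if history else np.inf
        if best is None or final < best[0]:
            best = (final, X, converged, start, history)

    stress, X, converged, start, history = best
    X = X - X.mean(axis=0)
    _, _, Vt = np.linalg.svd(X, full_matrices=False)
    X = X @ Vt.T
    coords = pd.DataFrame(X, index=d.labels,
                          columns=[f"NMDS{i+1}" for i in range(k)])
    return NMDSResult(coords, stress, converged, max(1, n_starts), start, history)


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

@dataclass
class AnosimResult:
    R: float
    p: float
    n_perm: int


def _anosim_r(ranks: np.ndarray, same: np.ndarray) -> float:
    M = len(ranks)
    rw = ranks[same].mean()
    rb = ranks[~same].mean()
    return float((rb - rw) / (M / 2.0))


def anosim(d: DissimilarityMatrix, groups, n_perm: int = 999,
           seed: int = 0) -> AnosimResult:
    """Analysis of similarities on a dissimilarity matrix.

    ``groups`` maps sample id -> group label (mapping or Series).  All
    off-diagonal dissimilarities are ranked once (average ranks on
    ties); the permutation null randomly relabels samples.
    """
    labels = np.asarray([str(groups[s]) for s in d.labels])
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValidationError("ANOSIM needs >= 2 groups")
    if (counts < 2).any():
        bad = uniq[counts < 2][0]
        raise ValidationError(f"group {bad!r} has < 2 samples")
    n = len(labels)
    iu, ju = np.triu_indices(n, k=1)
    ranks = rankdata(d.condensed)
    same = labels[iu] == labels[ju]
    R_obs = _anosim_r(ranks, same)

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(labels) for _ in range(n_perm)])
    same_p = perms[:, iu] == perms[:, ju]            # (n_perm, M)
    n_within = int(same.sum())
    M = len(ranks)
    sums_within = (same_p * ranks[None, :]).sum(axis=1)
    rw = sums_within / n_within
    rb = (ranks.sum() - sums_within) / (M - n_within)
    R_perm = (rb - rw) / (M / 2.0)
    p = (1 + int((R_perm >= R_obs - 1e-12).sum())) / (1 + n_perm)
    return AnosimResult(R_obs, p, n_perm)


# ---------------------------------------------------------------------------
# CCA
# ---------------------------------------------------------------------------

def _ln1p_matrix(community: CommunityMatrix, transform: str) -> pd.DataFrame:
    Y = community.counts.astype(float)
    if transform == "ln1p":
        Y = np.log1p(Y)
    elif transform != "none":
        raise ValidationError(f"unknown transform {transform!r}")
    return Y


def _chi_square_standardize(Y: np.ndarray):
    """Return (Qbar, r, c): the double-standardized residual matrix and
    the row/column weight vectors."""
    tot = Y.sum()
    if tot <= 0:
        raise ValidationError("community matrix has no individuals")
    P = Y / tot
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    expected = np.outer(r, c)
    Qbar = (P - expected) / np.sqrt(expected)
    return Qbar, r, c


def _weighted_center(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    return X - (w[:, None] * X).sum(axis=0) / w.sum()


def _env_df(env) -> pd.DataFrame:
    """Accept an EnvironmentTable or any DataFrame of constraints."""
    return env.table if isinstance(env, EnvironmentTable) else pd.DataFrame(env)


def scale_env(env, columns=None) -> pd.DataFrame:
    """Environment variables standardized to mean 0, unit variance."""
    df = _env_df(env)
    df = df if columns is None else df[list(columns)]
    sd = df.std(axis=0, ddof=1).replace(0.0, 1.0)
    return (df - df.mean(axis=0)) / sd


@dataclass
class CCAResult:
    eigenvalues: np.ndarray
    total_inertia: float
    constrained_inertia: float
    axis_percent: np.ndarray          # % of constrained inertia per axis
    site_scores: pd.DataFrame         # linear-combination (LC) scores
    species_scores: pd.DataFrame
    biplot_scores: pd.DataFrame       # weighted corr of constraints with axes
    vif: pd.Series
    species_axis_corr: pd.DataFrame   # Pearson r of ln1p species vs axes
    constraints: list[str]
    n_samples: int
    rank: int
    dropped_samples: tuple[str, ...] = ()
    p_model: float | None = None
    p_axes: np.ndarray | None = None
    # permutation machinery (weights tied to community rows)
    _Qbar: np.ndarray = field(default=None, repr=False)
    _r: np.ndarray = field(default=None, repr=False)
    _X: np.ndarray = field(default=None, repr=False)

    def highlighted_species(self, r_threshold: float = 0.5) -> list[str]:
        """Species with |Pearson r| >= threshold on any canonical axis."""
        mask = (self.species_axis_corr.abs() >= r_threshold).any(axis=1)
        return list(self.species_axis_corr.index[mask])


def cca_vif(env, constraints=None, weights=None) -> pd.Series:
    """Variance inflation factor per constraint under optional row weights.

    VIF_j = 1/(1 - R^2_j) from the (weighted) regression of constraint j
    on the others; a single constraint has VIF 1, perfectly collinear
    constraints report +inf.
    """
    df = env.table if isinstance(env, EnvironmentTable) else pd.DataFrame(env)
    if constraints is not None:
        df = df[list(constraints)]
    X = df.to_numpy(dtype=float)
    n, q = X.shape
    w = np.full(n, 1.0 / n) if weights is None else np.asarray(weights, float) / np.sum(weights)
    Xc = _weighted_center(X, w)
    Xw = np.sqrt(w)[:, None] * Xc
    if q == 1:
        return pd.Series([1.0], index=df.columns)
    C = Xw.T @ Xw
    dvar = np.sqrt(np.diag(C))
    if np.any(dvar == 0):
        raise ValidationError("constant constraint has no variance")
    R = C / np.outer(dvar, dvar)
    out = np.empty(q)
    for j in range(q):
        others = [i for i in range(q) if i != j]
        sub = R[np.ix_(others, others)]
        rj = R[others, j]
        try:
            r2 = float(rj @ np.linalg.solve(sub, rj))
        except np.linalg.LinAlgError:
            r2 = 1.0
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, index=df.columns)


def cca_fit(community: CommunityMatrix, env: EnvironmentTable,
            constraints=None, transform: str = "ln1p",
            scale: bool = True) -> CCAResult:
    """Constrained correspondence analysis of community on constraints.

    The community matrix is ln(x+1) transformed by default and samples
    that are empty after transform are dropped with a warning (their
    chi-square row weights would be undefined).  Environment columns are
    standardized to zero mean / unit variance when ``scale`` is set.
    """
    envdf0 = _env_df(env)
    constraints = list(constraints) if constraints is not None else list(envdf0.columns)
    if not constraints:
        raise ValidationError("CCA needs at least one constraint")
    Ydf = _ln1p_matrix(community, transform)
    keep = Ydf.sum(axis=1) > 0
    dropped = tuple(Ydf.index[~keep])
    if dropped:
        log.warning("CCA dropped %d all-zero samples", len(dropped))
        Ydf = Ydf.loc[keep]
    zero_sp = Ydf.columns[Ydf.sum(axis=0) == 0]
    if len(zero_sp):
        log.warning("CCA dropped %d all-zero species", len(zero_sp))
        Ydf = Ydf.drop(columns=zero_sp)
    envdf = (scale_env(envdf0, constraints) if scale else envdf0[constraints]).loc[Ydf.index]
    Y = Ydf.to_numpy()
    Qbar, r, c = _chi_square_standardize(Y)
    total_inertia = float((Qbar**2).sum())

    X = envdf.to_numpy(dtype=float)
    Xc = _weighted_center(X, r)
    Xw = np.sqrt(r)[:, None] * Xc
    coef, *_ = np.linalg.lstsq(Xw, Qbar, rcond=None)
    Yhat = Xw @ coef
    U, S, Vt = np.linalg.svd(Yhat, full_matrices=False)
    rank = int((S > 1e-10 * max(1.0, S[0] if len(S) else 0)).sum())
    rank = min(rank, np.linalg.matrix_rank(Xw), Qbar.shape[1])
    U, S, Vt = U[:, :rank], S[:rank], Vt[:rank]
    eig = S**2
    constrained = float(eig.sum())
    pct = 100.0 * eig / constrained if constrained > 0 else np.zeros_like(eig)

    axes = [f"CCA{i+1}" for i in range(rank)]
    site_lc = (U * S[None, :]) / np.sqrt(r)[:, None]
    species = (Vt.T / np.sqrt(c)[:, None])
    site_scores = pd.DataFrame(site_lc, index=Ydf.index, columns=axes)
    species_scores = pd.DataFrame(species, index=Ydf.columns, columns=axes)
    # weighted correlations of constraints with canonical axes
    Xn = Xw / np.sqrt((Xw**2).sum(axis=0))[None, :]
    biplot = pd.DataFrame(Xn.T @ U, index=constraints, columns=axes)

    # Pearson correlation of transformed species vectors with site scores
    corr = np.zeros((Y.shape[1], rank))
    ys = Y - Y.mean(axis=0)
    ss = site_lc - site_lc.mean(axis=0)
    ynorm = np.sqrt((ys**2).sum(axis=0))
    snorm = np.sqrt((ss**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (ys.T @ ss) / np.outer(ynorm, snorm)
    corr = np.nan_to_num(corr)
    species_axis_corr = pd.DataFrame(corr, index=Ydf.columns, columns=axes)

    vif = cca_vif(pd.DataFrame(X, columns=constraints), weights=r) \
        if len(constraints) >= 1 else pd.Series(dtype=float)

    return CCAResult(
        eigenvalues=eig, total_inertia=total_inertia,
        constrained_inertia=constrained, axis_percent=pct,
        site_scores=site_scores, species_scores=species_scores,
        biplot_scores=biplot, vif=vif,
        species_axis_corr=species_axis_corr, constraints=constraints,
        n_samples=Y.shape[0], rank=rank, dropped_samples=dropped,
        _Qbar=Qbar, _r=r, _X=X,
    )


def _constrained_inertia_batch(Xp: np.ndarray, w: np.ndarray, Qbar: np.ndarray) -> np.ndarray:
    """Constrained inertia for a batch of constraint matrices (B, n, q)."""
    wsum = w.sum()
    means = np.einsum("n,bnq->bq", w, Xp) / wsum
    Xc = Xp - means[:, None, :]
    Xw = np.sqrt(w)[None, :, None] * Xc
    G = np.einsum("bnq,bnp->bqp", Xw, Xw)
    Bm = np.einsum("bnq,ns->bqs", Xw, Qbar)
    try:
        coef = np.linalg.solve(G, Bm)
    except np.linalg.LinAlgError:
        coef = np.stack([np.linalg.pinv(g) @ b for g, b in zip(G, Bm)])
    return np.einsum("bqs,bqs->b", Bm, coef)


def cca_permutation_test(result: CCAResult, n_perm: int = 9999, seed: int = 0,
                         which: str = "all", chunk: int = 2000) -> CCAResult:
    """Permutation significance of the CCA model and (optionally) axes.

    The model test permutes sample rows of the constraint matrix against
    the fixed chi-square standardized community (equivalent to random
    re-pairing of environment with samples); pseudo-F is
    (constrained/q) / (residual/(n-q-1)).  Per-axis tests condition on
    the preceding canonical axes by residualizing both sides on them
    before permuting.  Fills ``p_model`` / ``p_axes`` in place and
    returns the result.
    """
    Qbar, r, X = result._Qbar, result._r, result._X
    n, q = X.shape
    rng = np.random.default_rng(seed)
    resid_df = n - q - 1
    resid = result.total_inertia - result.constrained_inertia
    if resid_df <= 0 or resid <= 1e-12:
        # saturated model: significance undefined, p = 1/(1+n_perm) floor
        result.p_model = 1.0
        result.p_axes = np.ones(result.rank)
        return result
    F_obs = (result.constrained_inertia / q) / (resid / resid_df)

    if which in ("all", "model"):
        count = 0
        for lo in range(0, n_perm, chunk):
            B = min(chunk, n_perm - lo)
            perms = np.array([rng.permutation(n) for _ in range(B)])
            ci = _constrained_inertia_batch(X[perms], r, Qbar)
            F_perm = (ci / q) / ((result.total_inertia - ci) / resid_df)
            count += int((F_perm >= F_obs - 1e-12).sum())
        result.p_model = (1 + count) / (1 + n_perm)

    if which in ("all", "axes"):
        Xc = _weighted_center(X, r)
        Xw = np.sqrt(r)[:, None] * Xc
        coef, *_ = np.linalg.lstsq(Xw, Qbar, rcond=None)
        U, S, Vt = np.linalg.svd(Xw @ coef, full_matrices=False)
        U = U[:, :result.rank]
        p_axes = np.empty(result.rank)
        for i in range(result.rank):
            prev = U[:, :i]
            proj = np.eye(n) - prev @ prev.T
            Xres = proj @ Xw
            Qres = proj @ Qbar
            c2, *_ = np.linalg.lstsq(Xres, Qres, rcond=None)
            s = np.linalg.svd(Xres @ c2, compute_uv=False)
            lam_obs = float(s[0] ** 2)
            F_i_obs = lam_obs / (resid / resid_df)
            count = 0
            for lo in range(0, n_perm, chunk):
                B = min(chunk, n_perm - lo)
                idx = np.array([rng.permutation(n) for _ in range(B)])
                lam = np.empty(B)
                for b in range(B):
                    cb, *_ = np.linalg.lstsq(Xres, Qres[idx[b]], rcond=None)
                    sv = np.linalg.svd(Xres @ cb, compute_uv=False)
                    lam[b] = sv[0] ** 2
                F_perm = lam / (resid / resid_df)
                count += int((F_perm >= F_i_obs - 1e-12).sum())
            p_axes[i] = (1 + count) / (1 + n_perm)
        result.p_axes = p_axes
    return result


def cca_forward_select(community: CommunityMatrix, env: EnvironmentTable,
                       candidates=None, alpha_add: float = 0.05,
                       n_perm: int = 999, seed: int = 0,
                       transform: str = "ln1p") -> list[str]:
    """Forward stepwise selection of CCA constraints by permutation p.

    At each step the candidate whose added constrained inertia has the
    lowest permutation p-value (ties broken by pseudo-F) is added,
    stopping when no candidate reaches ``alpha_add``.  The permutation
    scheme permutes the residuals of the current (reduced) model.
    """
    envdf0 = _env_df(env)
    candidates = list(candidates) if candidates is not None else list(envdf0.columns)
    Ydf = _ln1p_matrix(community, transform)
    Ydf = Ydf.loc[Ydf.sum(axis=1) > 0]
    Ydf = Ydf.loc[:, Ydf.sum(axis=0) > 0]
    envdf = scale_env(envdf0, candidates).loc[Ydf.index]
    Qbar, r, c = _chi_square_standardize(Ydf.to_numpy())
    total = float((Qbar**2).sum())
    sqw = np.sqrt(r)[:, None]
    n = len(Ydf)

    rng = np.random.default_rng(seed)
    selected: list[str] = []
    Qres = Qbar.copy()
    Zw = np.zeros((n, 0))
    while True:
        remaining = [v for v in candidates if v not in selected]
        if not remaining:
            break
        best = None
        for var in remaining:
            x = envdf[var].to_numpy(dtype=float)
            xw = sqw[:, 0] * _weighted_center(x[:, None], r)[:, 0]
            if Zw.shape[1]:
                xw = xw - Zw @ (Zw.T @ xw)
            norm = np.linalg.norm(xw)
            if norm < 1e-10:
                continue
            u = xw / norm
            added = float(((u @ Qres) ** 2).sum())
            df_res = n - len(selected) - 2
            resid = float((Qres**2).sum()) - added
            if df_res <= 0 or resid <= 1e-12:
                continue
            F_obs = added / (resid / df_res)
            # permute rows of the reduced-model residual matrix
            perms = np.array([rng.permutation(n) for _ in range(n_perm)])
            Qp = Qres[perms]                      # (B, n, S)
            addp = ((np.einsum("n,bns->bs", u, Qp)) ** 2).sum(axis=1)
            residp = (Qres**2).sum() - addp
            F_perm = addp / (residp / df_res)
            p = (1 + int((F_perm >= F_obs - 1e-12).sum())) / (1 + n_perm)
            if best is None or (p, -F_obs) < (best[0], -best[1]):
                best = (p, F_obs, var, u)
        if best is None or best[0] > alpha_add:
            break
        p, F, var, u = best
        selected.append(var)
        Zw = np.column_stack([Zw, u])
        Qres = Qres - np.outer(u, u @ Qres)
    return selected
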