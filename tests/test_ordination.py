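"""Bray-Curtis, NMDS, ANOSIM and CCA against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from mitecomm import ordination
from mitecomm.datamodel import ValidationError
from mitecomm.ordination import (
    DissimilarityMatrix, bray_curtis, nmds, anosim, cca_fit, cca_vif,
    cca_permutation_test, cca_forward_select,
)
from conftest import make_community
from _specs import veg_effect_spec
from mitecomm.synthetic import generate


# -- Bray-Curtis -------------------------------------------------------------

def test_bray_curtis_hand_values():
    com = make_community([[2, 1], [1, 3], [2, 1], [1, 0], [0, 1]],
                         ["A"] * 5)
    d = bray_curtis(com).d
    assert d[0, 2] == 0.0
    assert d[3, 4] == 1.0                        # disjoint support
    assert d[0, 1] == pytest.approx(3.0 / 7.0)   # (1+2)/(3+4)
    assert np.allclose(d, d.T) and np.all(np.diag(d) == 0)
    assert d.min() >= 0 and d.max() <= 1


def test_bray_curtis_empty_pair_is_zero():
    com = make_community([[0, 0], [0, 0], [1, 2]], ["A"] * 3)
    d = bray_curtis(com).d
    assert d[0, 1] == 0.0


# -- NMDS --------------------------------------------------------------------

def test_nmds_line_is_exact():
    x = np.array([0.0, 1.0, 2.5, 4.0, 7.0])
    d = np.abs(x[:, None] - x[None, :])
    dm = DissimilarityMatrix([f"s{i}" for i in range(5)], d / d.max())
    res = nmds(dm, k=1, n_starts=3, seed=0)
    assert res.stress < 1e-6


def test_nmds_full_dimension_near_zero_stress():
    rng = np.random.default_rng(0)
    pts = rng.normal(size=(6, 3))
    d = squareform(pdist(pts))
    dm = DissimilarityMatrix([f"s{i}" for i in range(6)], d)
    res = nmds(dm, k=5, n_starts=5, seed=0)
    assert res.stress < 1e-4


def test_nmds_stress_monotone_and_deterministic():
    rng = np.random.default_rng(1)
    d = squareform(pdist(rng.random((8, 2))))
    dm = DissimilarityMatrix([f"s{i}" for i in range(8)], d)
    r1 = nmds(dm, seed=42, n_starts=4)
    r2 = nmds(dm, seed=42, n_starts=4)
    pd.testing.assert_frame_equal(r1.coordinates, r2.coordinates)
    h = np.array(r1.stress_history)
    assert np.all(np.diff(h) <= 1e-6)


def test_nmds_multistart_near_exhaustive():
    """Default starts reach the stress an exhaustive 60-start search finds."""
    rng = np.random.default_rng(7)
    d = squareform(pdist(rng.random((6, 4))))
    dm = DissimilarityMatrix([f"s{i}" for i in range(6)], d)
    default = nmds(dm, k=2, n_starts=10, seed=0)
    exhaustive = nmds(dm, k=2, n_starts=60, seed=123)
    assert default.stress <= exhaustive.stress + 1e-3


# -- ANOSIM ------------------------------------------------------------------

def _anosim_oracle_r(d: np.ndarray, labels) -> float:
    """Independent R from an explicit rank table over all pairs."""
    labels = np.asarray(labels)
    n = len(labels)
    pairs = list(itertools.combinations(range(n), 2))
    dists = np.array([d[i, j] for i, j in pairs])
    ranks = rankdata(dists)
    within = [r for (i, j), r in zip(pairs, ranks) if labels[i] == labels[j]]
    between = [r for (i, j), r in zip(pairs, ranks) if labels[i] != labels[j]]
    M = len(pairs)
    return (np.mean(between) - np.mean(within)) / (M / 2.0)


def test_anosim_perfect_separation():
    d = np.array([
        [0.0, 0.1, 0.9, 0.8],
        [0.1, 0.0, 0.85, 0.95],
        [0.9, 0.85, 0.0, 0.2],
        [0.8, 0.95, 0.2, 0.0]])
    dm = DissimilarityMatrix(["a1", "a2", "b1", "b2"], d)
    res = anosim(dm, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
                 n_perm=99, seed=0)
    assert res.R == pytest.approx(1.0)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_anosim_matches_rank_table_oracle(seed):
    rng = np.random.default_rng(seed)
    d = squareform(pdist(rng.random((7, 3))))
    labels = ["A", "A", "A", "B", "B", "C", "C"]
    dm = DissimilarityMatrix([f"s{i}" for i in range(7)], d)
    res = anosim(dm, dict(zip(dm.labels, labels)), n_perm=99, seed=0)
    assert res.R == pytest.approx(_anosim_oracle_r(d, labels), abs=1e-12)


def test_anosim_exact_enumeration_p():
    """Sampled permutation p agrees with exhaustive enumeration (n=6)."""
    rng = np.random.default_rng(3)
    d = squareform(pdist(rng.random((6, 2))))
    labels = np.array(["A", "A", "A", "B", "B", "B"])
    dm = DissimilarityMatrix([f"s{i}" for i in range(6)], d)
    R_obs = _anosim_oracle_r(d, labels)
    exact_ge = sum(_anosim_oracle_r(d, perm) >= R_obs - 1e-12
                   for perm in itertools.permutations(labels))
    p_exact = exact_ge / 720.0
    res = anosim(dm, dict(zip(dm.labels, labels)), n_perm=4999, seed=0)
    # MC standard error ~ sqrt(p(1-p)/n_perm)
    se = np.sqrt(p_exact * (1 - p_exact) / 4999)
    assert abs(res.p - p_exact) < 4 * se + 1e-3


def test_anosim_small_group_errors():
    d = np.zeros((3, 3))
    dm = DissimilarityMatrix(["a", "b", "c"], d)
    with pytest.raises(ValidationError):
        anosim(dm, {"a": "A", "b": "A", "c": "B"}, n_perm=99)


def test_anosim_matches_scikit_bio(preset_data):
    """Cross-check the R statistic against scikit-bio on real-shaped data."""
    skbio_stats = pytest.importorskip("skbio.stats.distance")
    community, _ = preset_data
    sub = community.restrict(community.samples[::10])
    d = bray_curtis(sub, "ln1p")
    ours = anosim(d, sub.plot_of, n_perm=99, seed=0)
    dm = skbio_stats.DistanceMatrix(d.d, ids=d.labels)
    theirs = skbio_stats.anosim(dm, grouping=sub.plot_of.to_numpy(),
                                permutations=0)
    assert ours.R == pytest.approx(theirs["test statistic"], abs=1e-10)


# -- CCA ---------------------------------------------------------------------

def _cca_oracle_eigs(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Dense-eigen oracle: explicit hat matrix, eigh in species space."""
    tot = Y.sum()
    P = Y / tot
    r, c = P.sum(axis=1), P.sum(axis=0)
    Q = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    Xc = X - (r[:, None] * X).sum(axis=0)
    Xw = np.sqrt(r)[:, None] * Xc
    H = Xw @ np.linalg.pinv(Xw.T @ Xw) @ Xw.T
    M = Q.T @ H @ Q
    w = np.linalg.eigvalsh(M)[::-1]
    return np.clip(w, 0, None)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_cca_eigenvalues_match_dense_oracle(seed):
    rng = np.random.default_rng(seed)
    counts = rng.integers(0, 6, size=(8, 6)) + (rng.random((8, 6)) < 0.3)
    counts[counts.sum(axis=1) == 0, 0] = 1
    com = make_community(counts.astype(int), ["A"] * 8)
    env = pd.DataFrame(rng.normal(size=(8, 2)), columns=["u", "v"],
                       index=com.samples)
    fit = cca_fit(com, env, ["u", "v"], transform="none", scale=False)
    oracle = _cca_oracle_eigs(np.asarray(counts, float), env.to_numpy())
    np.testing.assert_allclose(fit.eigenvalues, oracle[:fit.rank],
                               rtol=1e-10, atol=1e-12)


def test_cca_matches_scikit_bio():
    rng = np.random.default_rng(5)
    counts = rng.integers(1, 8, size=(10, 5))
    com = make_community(counts, ["A"] * 10)
    env = pd.DataFrame(rng.normal(size=(10, 2)), columns=["u", "v"],
                       index=com.samples)
    fit = cca_fit(com, env, ["u", "v"], transform="none", scale=False)
    skord = pytest.importorskip("skbio.stats.ordination")
    theirs = skord.cca(pd.DataFrame(counts, index=com.samples), env)
    np.testing.assert_allclose(fit.eigenvalues,
                               theirs.eigvals.to_numpy()[:fit.rank], rtol=1e-8)


def test_cca_saturated_constraints_recover_total_inertia():
    """With n-1 independent indicator constraints the constrained space is
    everything: constrained inertia == total inertia."""
    rng = np.random.default_rng(2)
    counts = rng.integers(1, 5, size=(5, 4))
    com = make_community(counts, ["A"] * 5)
    dummies = pd.DataFrame(np.eye(5)[:, :4], index=com.samples,
                           columns=[f"d{i}" for i in range(4)])
    fit = cca_fit(com, dummies, transform="none", scale=False)
    assert fit.constrained_inertia == pytest.approx(fit.total_inertia, rel=1e-10)
    assert fit.axis_percent.sum() == pytest.approx(100.0)


def test_cca_sample_order_invariance(preset_data):
    community, env = preset_data
    sub = community.restrict(community.samples[::5])
    esub = env.restrict(sub.samples)
    fit1 = cca_fit(sub, esub, ["VegCovr", "Ts"])
    order = sub.samples[::-1]
    fit2 = cca_fit(sub.restrict(order), esub.restrict(order), ["VegCovr", "Ts"])
    np.testing.assert_allclose(fit1.eigenvalues, fit2.eigenvalues, rtol=1e-9)
    np.testing.assert_allclose(
        fit1.site_scores.loc[fit1.site_scores.index].to_numpy(),
        np.sign(np.sum(fit1.site_scores.to_numpy() *
                       fit2.site_scores.loc[fit1.site_scores.index].to_numpy(),
                       axis=0)) *
        fit2.site_scores.loc[fit1.site_scores.index].to_numpy(), atol=1e-8)


def test_cca_nested_inertia_monotone():
    rng = np.random.default_rng(9)
    counts = rng.integers(0, 5, size=(20, 8)) + 1
    com = make_community(counts, ["A"] * 20)
    env = pd.DataFrame(rng.normal(size=(20, 4)),
                       columns=list("wxyz"), index=com.samples)
    ci = [cca_fit(com, env, list("wxyz")[:q], transform="none").constrained_inertia
          for q in range(1, 5)]
    assert np.all(np.diff(ci) >= -1e-12)


def test_cca_vif_closed_form():
    rng = np.random.default_rng(0)
    # orthonormal columns that are also orthogonal to the intercept, so the
    # sample correlation of (z1, 0.6 z1 + 0.8 z2) is exactly 0.6
    Q = np.linalg.qr(np.column_stack([np.ones(40), rng.normal(size=(40, 2))]))[0]
    z1, z2 = Q[:, 1], Q[:, 2]
    df = pd.DataFrame({"a": z1, "b": 0.6 * z1 + 0.8 * z2})
    vif = cca_vif(df)
    assert vif["a"] == pytest.approx(1.0 / (1 - 0.36), rel=1e-9)
    orth = pd.DataFrame({"a": z1, "b": z2})
    assert cca_vif(orth).max() == pytest.approx(1.0, abs=1e-9)
    dup = pd.DataFrame({"a": z1, "b": z1})
    assert np.isinf(cca_vif(dup)).all()
    assert cca_vif(pd.DataFrame({"a": z1}))["a"] == 1.0


def test_cca_permutation_p_floor_and_power():
    com, env = generate(veg_effect_spec(), 0)
    fit = cca_fit(com, env, ["VegCovr"])
    cca_permutation_test(fit, n_perm=199, seed=0, which="model")
    assert fit.p_model >= 1.0 / 200.0
    assert fit.p_model <= 0.01      # planted effect is strong


def test_forward_select_degenerate_threshold():
    rng = np.random.default_rng(4)
    counts = rng.integers(0, 4, size=(30, 6)) + 1
    com = make_community(counts, ["A"] * 30)
    env = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"),
                       index=com.samples)
    sel = cca_forward_select(com, env, alpha_add=1.0, n_perm=99, seed=0)
    assert sorted(sel) == list("abc")


def test_forward_select_recovers_planted_driver():
    com, env = generate(veg_effect_spec(), 11)
    sel = cca_forward_select(com, env, n_perm=199, seed=5)
    assert sel and sel[0] == "VegCovr"
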