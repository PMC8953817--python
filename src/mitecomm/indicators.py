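"""Dufrene-Legendre indicator-value (IndVal) analysis.

For species i and site-group set G, specificity A is the mean abundance
of i inside G over the sum of group mean abundances (G pooled as one
group against each remaining group), fidelity B is the fraction of
samples of G containing i, and IndVal = 100 * A * B.  Candidate sets are
the single groups and, optionally, all unordered pairs of groups (the
site-group-combination extension).  Significance is assessed by randomly
reallocating samples among groups and comparing each species' best
IndVal against its permutation distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .datamodel import CommunityMatrix, ValidationError


@dataclass
class IndValResult:
    """Long table with one row per (species, group set)."""

    table: pd.DataFrame      # species, group_set, A, B, indval, best, p
    groups: tuple[str, ...]
    max_combo_size: int
    n_perm: int | None = None

    def best_table(self) -> pd.DataFrame:
        """One row per species: its best group set, IndVal and p."""
        return (self.table[self.table["best"]]
                .set_index("species")
                .sort_values("indval", ascending=False))


def _group_sets(k: int, max_combo_size: int):
    sets = [(i,) for i in range(k)]
    if max_combo_size >= 2:
        sets += list(combinations(range(k), 2))
    return sets


def _indval_matrix(sum_ab: np.ndarray, sum_occ: np.ndarray, sizes: np.ndarray,
                   sets, denominator: str = "pooled") -> np.ndarray:
    """IndVal (n_sets, S) from per-group abundance/occurrence sums.

    ``sum_ab``/``sum_occ``: (k, S) per-group summed abundance and
    occurrence counts; ``sizes``: (k,) samples per group.  Supports a
    leading batch axis on sum_ab/sum_occ for permutations.
    """
    batched = sum_ab.ndim == 3
    if not batched:
        sum_ab = sum_ab[None]
        sum_occ = sum_occ[None]
    means = sum_ab / sizes[None, :, None]                     # (B, k, S)
    out = np.empty((sum_ab.shape[0], len(sets), sum_ab.shape[2]))
    total_means = means.sum(axis=1)                           # (B, S)
    for si, G in enumerate(sets):
        G = list(G)
        m = sizes[G].sum()
        pooled_mean = sum_ab[:, G].sum(axis=1) / m            # (B, S)
        Bfid = sum_occ[:, G].sum(axis=1) / m
        if denominator == "pooled":
            rest = total_means - means[:, G].sum(axis=1)
            denom = pooled_mean + rest
        elif denominator == "singletons":
            denom = total_means
        else:
            raise ValidationError(f"unknown denominator {denominator!r}")
        with np.errstate(invalid="ignore", divide="ignore"):
            A = np.where(denom > 0, pooled_mean / np.where(denom > 0, denom, 1.0), 0.0)
        out[:, si] = 100.0 * A * Bfid
    return out if batched else out[0]


def _prep(community: CommunityMatrix, groups):
    if groups is None:
        groups = community.plot_of
    labels = np.asarray([str(groups[s]) for s in community.samples])
    uniq = sorted(set(labels))
    gidx = np.array([uniq.index(l) for l in labels])
    sizes = np.bincount(gidx, minlength=len(uniq)).astype(float)
    if (sizes == 0).any():
        raise ValidationError("every group needs at least one sample")
    X = community.values.astype(float)
    ind = np.zeros((len(uniq), len(labels)))
    ind[gidx, np.arange(len(labels))] = 1.0
    return X, ind, sizes, uniq


def _set_name(G, uniq):
    return " + ".join(uniq[i] for i in G)


def indval(community: CommunityMatrix, groups=None, max_combo_size: int = 2,
           denominator: str = "pooled") -> IndValResult:
    """IndVal for every species over singleton and (optionally) pair sets.

    Per species, the maximum over candidate sets is flagged ``best``.
    """
    X, ind, sizes, uniq = _prep(community, groups)
    if len(uniq) < 2:
        raise ValidationError("IndVal needs >= 2 groups")
    sets = _group_sets(len(uniq), max_combo_size)
    sum_ab = ind @ X
    sum_occ = ind @ (X > 0)
    iv = _indval_matrix(sum_ab, sum_occ, sizes, sets, denominator)
    means = sum_ab / sizes[:, None]
    total_means = means.sum(axis=0)

    rows = []
    best_idx = iv.argmax(axis=0)
    for si, G in enumerate(sets):
        m = sizes[list(G)].sum()
        pooled_mean = sum_ab[list(G)].sum(axis=0) / m
        Bfid = sum_occ[list(G)].sum(axis=0) / m
        if denominator == "pooled":
            denom = pooled_mean + (total_means - means[list(G)].sum(axis=0))
        else:
            denom = total_means
        with np.errstate(invalid="ignore", divide="ignore"):
            A = np.where(denom > 0, pooled_mean / np.where(denom > 0, denom, 1.0), 0.0)
        for j, sp in enumerate(community.species):
            rows.append({
                "species": sp, "group_set": _set_name(G, uniq),
                "A": float(A[j]), "B": float(Bfid[j]),
                "indval": float(iv[si, j]), "best": bool(best_idx[j] == si),
            })
    table = pd.DataFrame(rows)
    table["p"] = np.nan
    return IndValResult(table, tuple(uniq), max_combo_size)


def indval_test(community: CommunityMatrix, groups=None, n_perm: int = 999,
                seed: int = 0, max_combo_size: int = 2,
                denominator: str = "pooled", chunk: int = 256) -> IndValResult:
    """Random-reallocation significance test of each species' best IndVal.

    Samples are permuted among groups; the permutation statistic is the
    species' maximum IndVal over the candidate sets (the same statistic
    as observed), p = (1 + #{perm >= obs}) / (1 + n_perm).
    """
    result = indval(community, groups, max_combo_size, denominator)
    X, ind, sizes, uniq = _prep(community, groups)
    sets = _group_sets(len(uniq), max_combo_size)
    best = result.table[result.table["best"]].set_index("species")
    obs = best.loc[list(community.species), "indval"].to_numpy()

    rng = np.random.default_rng(seed)
    n = X.shape[0]
    occ = (X > 0).astype(float)
    count = np.zeros(len(community.species))
    for lo in range(0, n_perm, chunk):
        B = min(chunk, n_perm - lo)
        perms = np.array([rng.permutation(n) for _ in range(B)])
        Xp = X[perms]                                   # (B, n, S)
        sum_ab = np.einsum("kn,bns->bks", ind, Xp)
        sum_occ = np.einsum("kn,bns->bks", ind, occ[perms])
        iv = _indval_matrix(sum_ab, sum_occ, sizes, sets, denominator)
        count += (iv.max(axis=1) >= obs[None, :] - 1e-12).sum(axis=0)
    p = (1 + count) / (1 + n_perm)
    pmap = dict(zip(community.species, p))
    result.table["p"] = np.where(result.table["best"],
                                 result.table["species"].map(pmap), np.nan)
    result.n_perm = n_perm
    return result


def characteristic_species(result: IndValResult, threshold: float = 25.0,
                           alpha: float = 0.05) -> pd.DataFrame:
    """Species characteristic of a group set: IndVal > threshold, p < alpha.

    Returns the qualifying (species, group set) rows sorted by IndVal
    descending.
    """
    best = result.table[result.table["best"]].copy()
    if best["p"].isna().all():
        raise ValidationError("run indval_test before filtering by significance")
    keep = (best["indval"] > threshold) & (best["p"] < alpha)
    return (best[keep]
            .sort_values("indval", ascending=False)
            .reset_index(drop=True)[["species", "group_set", "A", "B", "indval", "p"]])
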