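"""Frequency/constancy classification, DD4 dispersal rate, per-plot
summaries, and Mao Tau sample-based rarefaction.

Frequency of a species within a plot is the percentage of samples in
which it occurs, F = 100 p / P.  Constancy classes band F into
accidental (F1), accessory (F2), subconstant (F3), constant (F4) and
euconstant (F5) species; class boundaries are half-open so the bands
partition [0, 100].

The DD4 dispersal-rate statistic between two plots is

    DD4 = (2W / (A + B)) * ((A - B) / (A + B - W))

where A and B are the plots' summed species frequencies and W is the
summed pairwise-minimum frequency over the rare (accessory + accidental)
species.  Both factors are bounded by 1 in magnitude, so |DD4| <= 1; the
statistic vanishes for identical communities and is antisymmetric in the
plot pair.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import CommunityMatrix, DEFAULT_CLASS_EDGES, ValidationError

log = logging.getLogger(__name__)

CLASS_NAMES = ("F1", "F2", "F3", "F4", "F5")

POOLED = "pooled"


def constancy_class(F, edges: tuple[float, ...] = DEFAULT_CLASS_EDGES):
    """Map frequency percentages to constancy classes F1..F5.

    Bands are F1 [0, e1), F2 [e1, e2], F3 (e2, e3], F4 (e3, e4],
    F5 (e4, 100]; with the default edges (5, 15, 30, 50) this follows
    the conventional accidental/accessory/.../euconstant banding while
    assigning every possible F to exactly one class.
    """
    F = np.asarray(F, dtype=float)
    e1, e2, e3, e4 = edges
    idx = np.select(
        [F < e1, F <= e2, F <= e3, F <= e4], [0, 1, 2, 3], default=4)
    out = np.asarray(CLASS_NAMES)[idx]
    return out if F.ndim else str(out)


def frequency_table(community: CommunityMatrix, plot: str = POOLED,
                    edges: tuple[float, ...] = DEFAULT_CLASS_EDGES) -> pd.DataFrame:
    """Per-species occurrence frequency and constancy class in one plot.

    ``plot`` may be a plot label or ``"pooled"`` for all samples.
    Returns a DataFrame indexed by species with columns ``p`` (samples
    containing the species), ``P`` (samples in scope), ``F`` (percent)
    and ``constancy_class``.  Presence/absence only: count magnitudes do
    not matter.
    """
    if plot == POOLED:
        sub = community.counts
    else:
        if plot not in community.plots:
            raise ValidationError(f"unknown plot label {plot!r}")
        sub = community.counts.loc[community.plot_of == plot]
    P = len(sub)
    if P < 1:
        raise ValidationError(f"plot {plot!r} has no samples")
    p = (sub > 0).sum(axis=0)
    F = 100.0 * p / P
    return pd.DataFrame({
        "p": p, "P": P, "F": F,
        "constancy_class": constancy_class(F.to_numpy(), edges),
    })


@dataclass
class DispersalResult:
    """DD4 between an ordered plot pair (reported as |DD4|, sign kept)."""

    plot_pair: tuple[str, str]
    W: float
    A: float
    B: float
    dd4: float          # |DD4|
    sign: int           # sign of the raw statistic
    rare_species: tuple[str, ...]

    @property
    def signed(self) -> float:
        return self.sign * self.dd4


def dd4_statistic(fa: np.ndarray, fb: np.ndarray, rare: np.ndarray):
    """Vectorised raw DD4 over frequency arrays (percent scale).

    ``fa``/``fb``: (..., S) frequency arrays; ``rare``: boolean (..., S)
    mask of species entering W.  Returns (dd4, W, A, B) broadcast over
    the leading axes.  Degenerate denominators (empty communities, or
    all species rare and fully shared) yield 0.
    """
    fa = np.asarray(fa, dtype=float)
    fb = np.asarray(fb, dtype=float)
    W = np.where(rare, np.minimum(fa, fb), 0.0).sum(axis=-1)
    A = fa.sum(axis=-1)
    B = fb.sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        first = np.where(A + B > 0, 2.0 * W / np.where(A + B > 0, A + B, 1.0), 0.0)
        denom = A + B - W
        second = np.where(denom > 0, (A - B) / np.where(denom > 0, denom, 1.0), 0.0)
    return first * second, W, A, B


def dispersal_rate(fa: pd.DataFrame, fb: pd.DataFrame,
                   rare_rule: tuple[str, ...] = ("F1", "F2"),
                   rare_scope: str = "both",
                   pair: tuple[str, str] = ("a", "b")) -> DispersalResult:
    """DD4 between two frequency tables over the same species universe.

    ``rare_scope`` controls which species enter W: classified rare in
    ``both`` plots (default, conservative), in ``either``, or in the
    ``pooled`` classification (class of the mean frequency).
    """
    if list(fa.index) != list(fb.index):
        raise ValidationError("frequency tables must share the species universe")
    in_a = fa["constancy_class"].isin(rare_rule).to_numpy()
    in_b = fb["constancy_class"].isin(rare_rule).to_numpy()
    if rare_scope == "both":
        rare = in_a & in_b
    elif rare_scope == "either":
        rare = in_a | in_b
    elif rare_scope == "pooled":
        pooled_F = (fa["F"].to_numpy() + fb["F"].to_numpy()) / 2.0
        rare = np.isin(constancy_class(pooled_F), rare_rule)
    else:
        raise ValidationError(f"unknown rare_scope {rare_scope!r}")

    raw, W, A, B = dd4_statistic(fa["F"].to_numpy(), fb["F"].to_numpy(), rare)
    if A + B == 0:
        log.warning("DD4: both communities empty (A + B = 0); defined as 0")
    elif A + B - W == 0:
        log.warning("DD4: A + B - W = 0; defined as 0")
    return DispersalResult(
        plot_pair=tuple(pair), W=float(W), A=float(A), B=float(B),
        dd4=float(abs(raw)), sign=int(np.sign(raw)),
        rare_species=tuple(fa.index[rare]))


def pairwise_dispersal(community: CommunityMatrix,
                       rare_rule: tuple[str, ...] = ("F1", "F2"),
                       rare_scope: str = "both") -> pd.DataFrame:
    """DD4 for every unordered plot pair (first label alphabetical).

    Returns a long DataFrame with one row per pair and columns
    plot_a, plot_b, W, A, B, dd4 (absolute), sign.
    """
    plots = sorted(community.plots)
    if len(plots) < 2:
        raise ValidationError("pairwise dispersal needs >= 2 plots")
    tables = {p: frequency_table(community, p) for p in plots}
    rows = []
    for i, pa in enumerate(plots):
        for pb in plots[i + 1:]:
            r = dispersal_rate(tables[pa], tables[pb], rare_rule, rare_scope,
                               pair=(pa, pb))
            rows.append({"plot_a": pa, "plot_b": pb, "W": r.W, "A": r.A,
                         "B": r.B, "dd4": r.dd4, "sign": r.sign})
    return pd.DataFrame(rows)


def plot_summaries(community: CommunityMatrix) -> pd.DataFrame:
    """Species richness and total individuals per plot plus pooled row."""
    rows = {}
    for plot in community.plots:
        sub = community.counts.loc[community.plot_of == plot]
        rows[plot] = {"richness": int((sub.sum(axis=0) > 0).sum()),
                      "abundance": int(sub.to_numpy().sum())}
    rows[POOLED] = {"richness": int((community.counts.sum(axis=0) > 0).sum()),
                    "abundance": int(community.values.sum())}
    return pd.DataFrame(rows).T


def mao_tau(community: CommunityMatrix, scope: str = POOLED) -> pd.DataFrame:
    """Analytic sample-based rarefaction (Mao Tau accumulation curve).

    tau(n) = S_obs - sum_j C(N - N_j, n) / C(N, n), the expected number
    of species observed in a uniformly random subset of n of the N
    samples (N_j = number of samples containing species j).  Exact
    integer combinatorics; endpoints satisfy tau(1) = mean per-sample
    richness and tau(N) = S_obs.
    """
    if scope == POOLED:
        sub = community.counts
    else:
        if scope not in community.plots:
            raise ValidationError(f"unknown plot label {scope!r}")
        sub = community.counts.loc[community.plot_of == scope]
    N = len(sub)
    if N < 1:
        raise ValidationError("rarefaction needs >= 1 sample")
    Nj = (sub > 0).sum(axis=0).to_numpy()
    Nj = Nj[Nj > 0]
    S_obs = len(Nj)
    taus = np.empty(N)
    for n in range(1, N + 1):
        denom = math.comb(N, n)
        miss = sum(math.comb(N - nj, n) for nj in Nj if N - nj >= n)
        taus[n - 1] = S_obs - miss / denom
    return pd.DataFrame({"n": np.arange(1, N + 1), "tau": taus})
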