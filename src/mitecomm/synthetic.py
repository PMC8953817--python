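"""Synthetic community generator calibrated to the study design.

The generator emulates a five-plot grassland experiment (control CG and
treatments A-D, 50 soil cores each) with a 30-species mite pool:

* per-plot environment values drawn from truncated Gaussians at the
  published per-plot means/SDs (unprinted plot/variable combinations
  interpolated between the printed extremes);
* counts from an occupancy-thinned negative-binomial log-linear model:
  a species is present in a sample with its plot-specific occupancy
  probability, and a present species contributes ``1 + NB`` individuals
  with log-mean ``baseline + plot offset + beta_veg*z(VegCovr) +
  beta_ts*z(Ts)``.  The ``1 +`` shift makes per-sample presence equal the
  occupancy parameter exactly, so the constancy-class structure and the
  expected per-plot totals are analytic;
* presence profiles that reproduce the strongly unequal richness
  (D >> CG, B) and a constancy structure where only plot D carries
  euconstant/constant species.

Plot offsets are calibrated at spec-construction time so expected
per-plot totals match the published abundances (D 584 >> CG 50, B 52,
with the residual 477 split evenly between A and C).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .datamodel import CommunityMatrix, EnvironmentTable, ENV_VARIABLES, ENV_RANGES, ValidationError

PLOTS = ("CG", "A", "B", "C", "D")

#: Published per-plot environment means/SDs (extremes) with interpolated
#: values for the unprinted plot/variable combinations.
ENV_MEANS = pd.DataFrame(
    {
        "VegCovr": {"CG": 66.0, "A": 75.96, "B": 68.0, "C": 57.28, "D": 62.0},
        "H": {"CG": 65.0, "A": 69.0, "B": 63.5, "C": 61.5, "D": 66.0},
        "Ts": {"CG": 15.9, "A": 15.5, "B": 16.3, "C": 17.0, "D": 14.7},
        "pH": {"CG": 4.80, "A": 4.90, "B": 4.55, "C": 5.05, "D": 4.70},
        "RPs": {"CG": 1.34, "A": 1.30, "B": 1.39, "C": 1.36, "D": 1.33},
    }
).loc[list(PLOTS), list(ENV_VARIABLES)]

ENV_SDS = pd.DataFrame(
    {
        "VegCovr": {"CG": 8.6, "A": 8.74, "B": 8.6, "C": 8.59, "D": 8.6},
        "H": {"CG": 6.3, "A": 6.82, "B": 6.3, "C": 5.9, "D": 6.3},
        "Ts": {"CG": 1.70, "A": 1.70, "B": 1.70, "C": 1.62, "D": 1.74},
        "pH": {"CG": 0.80, "A": 0.80, "B": 1.22, "C": 0.42, "D": 0.80},
        "RPs": {"CG": 0.14, "A": 0.13, "B": 0.14, "C": 0.14, "D": 0.14},
    }
).loc[list(PLOTS), list(ENV_VARIABLES)]

#: Per-plot target expected totals (individuals); residual 477 of the
#: 1163 grand total split evenly between A and C.
TARGET_TOTALS = {"CG": 50.0, "A": 238.0, "B": 52.0, "C": 239.0, "D": 584.0}


def _default_occupancy() -> pd.DataFrame:
    """Per-plot occupancy (presence probability per sample); 0 = absent.

    Species sets: CG 5, B 7, A 16, C 18, D 26 species; species sp26/sp28
    occur only in A, sp27/sp29 only in C, sp21-sp25 only in D.  Only plot
    D has occupancies above 0.30 (euconstant sp00, constant sp05).
    """
    S = 30
    occ = pd.DataFrame(0.0, index=list(PLOTS),
                       columns=[f"sp{j:02d}" for j in range(S)])
    occ.loc["CG", ["sp00", "sp01", "sp02", "sp03", "sp04"]] = [0.25, 0.18, 0.12, 0.10, 0.06]
    occ.loc["B", [f"sp{j:02d}" for j in range(7)]] = [0.20, 0.15, 0.10, 0.10, 0.08, 0.06, 0.05]
    a_species = [f"sp{j:02d}" for j in range(14)] + ["sp26", "sp28"]
    occ.loc["A", a_species] = [0.28, 0.22, 0.18, 0.15, 0.12, 0.12, 0.10, 0.15,
                               0.15, 0.12, 0.10, 0.08, 0.08, 0.06, 0.12, 0.05]
    c_species = [f"sp{j:02d}" for j in range(10)] + \
        [f"sp{j:02d}" for j in range(15, 21)] + ["sp27", "sp29"]
    occ.loc["C", c_species] = [0.28, 0.22, 0.18, 0.15, 0.12, 0.12, 0.10, 0.12,
                               0.12, 0.10, 0.15, 0.12, 0.10, 0.08, 0.06, 0.06,
                               0.12, 0.05]
    d_species = [f"sp{j:02d}" for j in range(26)]
    occ.loc["D", d_species] = [0.60, 0.22, 0.18, 0.15, 0.12, 0.40, 0.15, 0.20,
                               0.20, 0.15, 0.12, 0.10, 0.10, 0.08, 0.10, 0.20,
                               0.15, 0.12, 0.10, 0.08, 0.08, 0.15, 0.12, 0.10,
                               0.08, 0.08]
    return occ


@dataclass
class GeneratorSpec:
    """Full parameterisation of the synthetic community generator."""

    plots: tuple[str, ...] = PLOTS
    samples_per_plot: int = 50
    env_means: pd.DataFrame = field(default_factory=lambda: ENV_MEANS.copy())
    env_sds: pd.DataFrame = field(default_factory=lambda: ENV_SDS.copy())
    occupancy: pd.DataFrame = field(default_factory=_default_occupancy)
    baseline: np.ndarray | None = None      # per-species log-abundance
    plot_offsets: dict[str, float] | None = None
    beta_veg: np.ndarray | None = None      # per-species response to z(VegCovr)
    beta_ts: np.ndarray | None = None       # per-species response to z(Ts)
    overdispersion: float = 2.0             # NB size k; math.inf -> Poisson

    def __post_init__(self):
        S = self.occupancy.shape[1]
        if self.baseline is None:
            self.baseline = np.zeros(S)
        self.baseline = np.asarray(self.baseline, dtype=float)
        if self.beta_veg is None:
            self.beta_veg = np.zeros(S)
        if self.beta_ts is None:
            self.beta_ts = np.zeros(S)
        self.beta_veg = np.asarray(self.beta_veg, dtype=float)
        self.beta_ts = np.asarray(self.beta_ts, dtype=float)
        self.validate()
        if self.plot_offsets is None:
            self.plot_offsets = {p: 0.0 for p in self.plots}

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if self.samples_per_plot < 2:
            raise ValidationError("samples_per_plot must be >= 2")
        if self.occupancy.shape[1] < 2:
            raise ValidationError("species pool must have >= 2 species")
        if self.overdispersion <= 0:
            raise ValidationError("overdispersion must be > 0")
        for p in self.plots:
            if p not in self.env_means.index or p not in self.occupancy.index:
                raise ValidationError(f"plot {p!r} missing from spec tables")
        if (self.env_sds.loc[list(self.plots)].to_numpy() <= 0).any():
            raise ValidationError("environment SDs must be > 0")
        occ = self.occupancy.loc[list(self.plots)].to_numpy()
        if (occ < 0).any() or (occ > 1).any():
            raise ValidationError("occupancies must lie in [0, 1]")
        if (occ.sum(axis=1) <= 0).any():
            raise ValidationError("every plot needs at least one species")
        if len(self.baseline) != self.occupancy.shape[1]:
            raise ValidationError("baseline length must equal species pool size")

    # -- analytic moments ------------------------------------------------
    @property
    def species(self) -> list[str]:
        return list(self.occupancy.columns)

    def env_global_moments(self) -> tuple[pd.Series, pd.Series]:
        """Mixture mean/SD across plots (equal samples per plot)."""
        m = self.env_means.loc[list(self.plots)]
        s = self.env_sds.loc[list(self.plots)]
        mu = m.mean(axis=0)
        var = (s**2 + (m - mu) ** 2).mean(axis=0)
        return mu, np.sqrt(var)

    def _plot_z(self, plot: str) -> tuple[float, float]:
        """Plot means of the standardized VegCovr and Ts channels."""
        mu, sd = self.env_global_moments()
        zv = (self.env_means.loc[plot, "VegCovr"] - mu["VegCovr"]) / sd["VegCovr"]
        zt = (self.env_means.loc[plot, "Ts"] - mu["Ts"]) / sd["Ts"]
        return zv, zt

    def expected_plot_species_means(self, plot: str) -> np.ndarray:
        """Expected count per sample for each species in one plot.

        Uses the plot-mean z scores (environmental variation around the
        plot mean is ignored, adequate for small beta).
        """
        zv, zt = self._plot_z(plot)
        mu = np.exp(self.baseline + self.plot_offsets[plot]
                    + self.beta_veg * zv + self.beta_ts * zt)
        occ = self.occupancy.loc[plot].to_numpy()
        return occ * (1.0 + np.maximum(mu - 1.0, 0.05))

    def expected_plot_total(self, plot: str) -> float:
        return self.samples_per_plot * float(self.expected_plot_species_means(plot).sum())


def default_spec() -> GeneratorSpec:
    """The packaged study calibration: 5 plots x 50 samples, 30 species.

    Baselines make a handful of species numerically dominant; plot
    offsets are solved so expected totals hit the published per-plot
    abundances; moderate environmental responses are planted on species
    sp07-sp09 (vegetation cover) and sp15-sp16 (soil temperature).
    """
    S = 30
    baseline = np.zeros(S)
    baseline[0] = math.log(3.0)    # dominant, euconstant in D
    baseline[5] = math.log(2.5)    # constant in D
    baseline[[1, 7, 15]] = math.log(1.5)
    beta_veg = np.zeros(S)
    beta_veg[[7, 8, 9]] = 0.6
    beta_ts = np.zeros(S)
    beta_ts[[15, 16]] = 0.6
    spec = GeneratorSpec(baseline=baseline, beta_veg=beta_veg, beta_ts=beta_ts,
                         plot_offsets=None)
    spec.plot_offsets = {}
    occ = spec.occupancy

    for plot in spec.plots:
        zv, zt = spec._plot_z(plot)
        o = occ.loc[plot].to_numpy()
        eta = baseline + beta_veg * zv + beta_ts * zt

        def expected(offset, o=o, eta=eta):
            mu = np.exp(eta + offset)
            per = o * (1.0 + np.maximum(mu - 1.0, 0.05))
            return spec.samples_per_plot * per.sum()

        target = TARGET_TOTALS[plot]
        spec.plot_offsets[plot] = brentq(
            lambda x: expected(x) - target, -6.0, 6.0, xtol=1e-10)
    return spec


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float | None, hi: float | None, n: int) -> np.ndarray:
    """Gaussian draws truncated to [lo, hi] by resampling."""
    x = rng.normal(mean, sd, size=n)
    lo_ = -np.inf if lo is None else lo
    hi_ = np.inf if hi is None else hi
    bad = (x < lo_) | (x > hi_)
    while bad.any():
        x[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (x < lo_) | (x > hi_)
    return x


def generate(spec: GeneratorSpec, seed: int) -> tuple[CommunityMatrix, EnvironmentTable]:
    """Draw one synthetic survey: (community counts, environment table).

    Deterministic in ``(spec, seed)``; each plot uses an independent
    random stream keyed by the plot's rank in sorted label order, so the
    draws for a plot do not depend on how the plot tuple is ordered.
    """
    spec.validate()
    sorted_plots = sorted(spec.plots)
    mu_g, sd_g = spec.env_global_moments()
    n = spec.samples_per_plot
    env_frames, count_frames, plot_labels = [], [], []
    for plot in spec.plots:
        rng = np.random.default_rng([seed, sorted_plots.index(plot)])
        env = {}
        for var in ENV_VARIABLES:
            lo, hi = ENV_RANGES[var]
            env[var] = _truncnorm(rng, spec.env_means.loc[plot, var],
                                  spec.env_sds.loc[plot, var], lo, hi, n)
        env = pd.DataFrame(env, index=[f"{plot}_{i+1:03d}" for i in range(n)])

        zv = (env["VegCovr"].to_numpy() - mu_g["VegCovr"]) / sd_g["VegCovr"]
        zt = (env["Ts"].to_numpy() - mu_g["Ts"]) / sd_g["Ts"]
        occ = spec.occupancy.loc[plot].to_numpy()
        eta = (spec.baseline[None, :] + spec.plot_offsets[plot]
               + np.outer(zv, spec.beta_veg) + np.outer(zt, spec.beta_ts))
        mu = np.exp(eta)
        present = rng.random((n, len(occ))) < occ[None, :]
        extra_mean = np.maximum(mu - 1.0, 0.05)
        k = spec.overdispersion
        if math.isinf(k):
            extra = rng.poisson(extra_mean)
        else:
            extra = rng.negative_binomial(k, k / (k + extra_mean))
        counts = present * (1 + extra)
        count_frames.append(pd.DataFrame(counts, index=env.index,
                                         columns=spec.species))
        env_frames.append(env)
        plot_labels.extend([plot] * n)

    counts = pd.concat(count_frames)
    env_table = pd.concat(env_frames)
    plot_of = pd.Series(plot_labels, index=counts.index)
    return (CommunityMatrix(counts, plot_of, plots=tuple(spec.plots)),
            EnvironmentTable(env_table))


# ---------------------------------------------------------------------------
# Deterministic bookkeeping fixture
# ---------------------------------------------------------------------------

#: (richness, total individuals) per plot for the bookkeeping fixture;
#: published marginals where available, even A/C split of the residual.
REFERENCE_MARGINALS = {
    "CG": (5, 50), "A": (16, 238), "B": (7, 52), "C": (18, 239), "D": (26, 584),
}


def reference_count_table() -> CommunityMatrix:
    """Synthetic stand-in for the published per-plot species count table.

    A deterministic 250 x 30 count matrix constructed so that pooled and
    per-plot species/individual totals equal the published marginal
    counts exactly (30 species, 1163 individuals; D 26/584, CG 5/50,
    B 7/52).  The within-plot allocation of individuals to species and
    samples is an arbitrary deterministic fill, not field data.
    """
    occ = _default_occupancy()
    species = list(occ.columns)
    n = 50
    rows, labels, index = [], [], []
    for plot in PLOTS:
        sp_here = [s for s in species if occ.loc[plot, s] > 0]
        richness, total = REFERENCE_MARGINALS[plot]
        assert len(sp_here) == richness
        base, rem = divmod(total, richness)
        block = np.zeros((n, len(species)), dtype=int)
        for j, sp in enumerate(sp_here):
            t = base + (1 if j < rem else 0)
            col = species.index(sp)
            full, extra = divmod(t, n)
            block[:, col] = full
            block[:extra, col] += 1
        rows.append(block)
        labels.extend([plot] * n)
        index.extend(f"{plot}_{i+1:03d}" for i in range(n))
    counts = pd.DataFrame(np.vstack(rows), index=index, columns=species)
    return CommunityMatrix(counts, pd.Series(labels, index=index), plots=PLOTS)
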