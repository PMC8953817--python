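"""Shared synthetic-community parameterisations used across the suite."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from mitecomm.datamodel import ENV_VARIABLES
from mitecomm.synthetic import GeneratorSpec

PLOTS = ("CG", "A", "B", "C", "D")

_FLAT_MEANS = [65.0, 65.0, 16.0, 5.0, 1.3]
_FLAT_SDS = [8.0, 6.0, 1.7, 0.6, 0.14]


def flat_env(plots=PLOTS, means=None, sds=None):
    """Environment mean/SD tables identical across plots (pure noise)."""
    means = means or _FLAT_MEANS
    sds = sds or _FLAT_SDS
    em = pd.DataFrame({v: {p: m for p in plots} for v, m in zip(ENV_VARIABLES, means)})
    es = pd.DataFrame({v: {p: s for p in plots} for v, s in zip(ENV_VARIABLES, sds)})
    return em.loc[list(plots)], es.loc[list(plots)]


def null_spec(n_per_plot: int = 10, n_species: int = 12,
              occupancy: float = 0.4) -> GeneratorSpec:
    """Exchangeable plots: identical environment, occupancy and offsets.

    Under this spec the plot labels carry no information, so any test of
    plot effects is a true null.
    """
    em, es = flat_env()
    occ = pd.DataFrame(occupancy, index=list(PLOTS),
                       columns=[f"sp{j:02d}" for j in range(n_species)])
    return GeneratorSpec(plots=PLOTS, samples_per_plot=n_per_plot,
                         env_means=em, env_sds=es, occupancy=occ,
                         baseline=np.full(n_species, np.log(2.0)))


def offset_spec(offsets: dict[str, float], n_per_plot: int = 20,
                n_species: int = 8) -> GeneratorSpec:
    """Known multiplicative plot effects, full occupancy, Poisson counts.

    The treatment coefficient of plot p relative to CG equals exactly
    ``offsets[p] - offsets['CG']`` on the log scale.
    """
    em, es = flat_env()
    occ = pd.DataFrame(1.0, index=list(PLOTS),
                       columns=[f"sp{j}" for j in range(n_species)])
    return GeneratorSpec(plots=PLOTS, samples_per_plot=n_per_plot,
                         env_means=em, env_sds=es, occupancy=occ,
                         baseline=np.full(n_species, np.log(1.5)),
                         plot_offsets=dict(offsets),
                         overdispersion=math.inf)


def veg_effect_spec(beta: float = 1.0, n_per_plot: int = 20,
                    n_species: int = 12) -> GeneratorSpec:
    """Within-plot VegCovr response planted on four species; everything
    else exchangeable, so VegCovr is the only informative constraint."""
    em, es = flat_env()
    occ = pd.DataFrame(0.5, index=list(PLOTS),
                       columns=[f"sp{j:02d}" for j in range(n_species)])
    bv = np.zeros(n_species)
    bv[[0, 1, 2, 3]] = beta
    return GeneratorSpec(plots=PLOTS, samples_per_plot=n_per_plot,
                         env_means=em, env_sds=es, occupancy=occ,
                         baseline=np.full(n_species, np.log(2.0)), beta_veg=bv)


def exclusive_species_spec(n_per_plot: int = 10, n_species: int = 12) -> GeneratorSpec:
    """Species sp00 occurs only in plot D (occupancy 0.6); all other
    species are spread uniformly (occupancy 0.3) across plots."""
    em, es = flat_env()
    occ = pd.DataFrame(0.3, index=list(PLOTS),
                       columns=[f"sp{j:02d}" for j in range(n_species)])
    occ["sp00"] = 0.0
    occ.loc["D", "sp00"] = 0.6
    return GeneratorSpec(plots=PLOTS, samples_per_plot=n_per_plot,
                         env_means=em, env_sds=es, occupancy=occ,
                         baseline=np.full(n_species, np.log(2.0)))
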