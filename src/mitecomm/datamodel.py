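"""Shared data model: community matrix, environment table, analysis config.

Both tables wrap :class:`pandas.DataFrame` objects and are validated on
construction; all downstream modules consume these types rather than raw
frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Canonical environment variable names, in declaration order.
#: VegCovr: vegetation cover (%); H: soil moisture content (%);
#: Ts: soil temperature (degC); pH: soil acidity; RPs: penetration
#: resistance (MPa).
ENV_VARIABLES = ("VegCovr", "H", "Ts", "pH", "RPs")

#: Legal ranges enforced on load; None means unbounded on that side.
ENV_RANGES: dict[str, tuple[float | None, float | None]] = {
    "VegCovr": (0.0, 100.0),
    "H": (0.0, 100.0),
    "Ts": (None, None),
    "pH": (0.0, 14.0),
    "RPs": (0.0, None),
}


class ValidationError(ValueError):
    """Base class for data-model validation failures."""


class MissingColumnError(ValidationError):
    """A required column (plot, sample id, environment variable) is absent."""


class BadCountError(ValidationError):
    """A community count is negative or non-integral."""


class DuplicateSampleError(ValidationError):
    """A sample identifier occurs more than once."""


class RangeError(ValidationError):
    """An environment value falls outside its legal range."""


class AlignmentError(ValidationError):
    """Community and environment tables share no samples."""


class CommunityMatrix:
    """Sample x species matrix of individual counts with plot assignment.

    Parameters
    ----------
    counts
        DataFrame indexed by sample id, one column per species, values
        non-negative integers (individuals per sample).
    plot_of
        Series mapping sample id -> plot label, aligned with ``counts``.
    plots
        Optional declared finite plot set; defaults to the labels observed.
    """

    def __init__(self, counts: pd.DataFrame, plot_of: pd.Series,
                 plots: Sequence[str] | None = None):
        counts = counts.copy()
        if counts.index.duplicated().any():
            dup = counts.index[counts.index.duplicated()][0]
            raise DuplicateSampleError(f"duplicate sample id {dup!r}")
        if counts.columns.duplicated().any():
            dup = counts.columns[counts.columns.duplicated()][0]
            raise ValidationError(f"duplicate species id {dup!r}")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise BadCountError("community counts must be numeric")
        if np.any(~np.isfinite(arr.astype(float))):
            raise BadCountError("community counts must be finite")
        if np.any(arr < 0) or np.any(arr.astype(float) != np.floor(arr.astype(float))):
            bad = np.argwhere((arr < 0) | (arr.astype(float) != np.floor(arr.astype(float))))[0]
            raise BadCountError(
                f"count at sample {counts.index[bad[0]]!r}, species "
                f"{counts.columns[bad[1]]!r} is {arr[bad[0], bad[1]]!r}; "
                "counts must be non-negative integers"
            )
        self.counts = counts.astype(np.int64)
        self.counts.index.name = "sample"
        self.counts.columns.name = None
        plot_of = plot_of.reindex(counts.index)
        if plot_of.isna().any():
            missing = plot_of.index[plot_of.isna()][0]
            raise ValidationError(f"sample {missing!r} has no plot label")
        self.plot_of = plot_of.astype(str)
        declared = tuple(plots) if plots is not None else tuple(
            pd.unique(self.plot_of))
        unknown = set(self.plot_of) - set(declared)
        if unknown:
            raise ValidationError(f"plot labels {sorted(unknown)} outside declared set {declared}")
        self.plots = declared

    # -- convenience accessors -------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def species(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def values(self) -> np.ndarray:
        return self.counts.to_numpy()

    def subset_plot(self, plot: str) -> "CommunityMatrix":
        """Restrict to samples from one plot."""
        if plot not in self.plots:
            raise ValidationError(f"unknown plot label {plot!r}")
        mask = self.plot_of == plot
        return CommunityMatrix(self.counts.loc[mask], self.plot_of.loc[mask],
                               plots=self.plots)

    def restrict(self, samples: Iterable[str]) -> "CommunityMatrix":
        samples = list(samples)
        return CommunityMatrix(self.counts.loc[samples],
                               self.plot_of.loc[samples], plots=self.plots)

    def __eq__(self, other) -> bool:
        return (isinstance(other, CommunityMatrix)
                and self.counts.equals(other.counts)
                and self.plot_of.equals(other.plot_of))

    def __repr__(self) -> str:
        return (f"CommunityMatrix({len(self.samples)} samples x "
                f"{len(self.species)} species, plots={self.plots})")


class EnvironmentTable:
    """Per-sample continuous soil/vegetation variables.

    One row per sample; the five variables of :data:`ENV_VARIABLES` are
    range-checked on construction.
    """

    def __init__(self, table: pd.DataFrame):
        missing = [v for v in ENV_VARIABLES if v not in table.columns]
        if missing:
            raise MissingColumnError(f"environment table lacks columns {missing}")
        table = table.loc[:, list(ENV_VARIABLES)].astype(float).copy()
        if table.index.duplicated().any():
            dup = table.index[table.index.duplicated()][0]
            raise DuplicateSampleError(f"duplicate sample id {dup!r}")
        if not np.all(np.isfinite(table.to_numpy())):
            raise RangeError("environment values must be finite")
        for var, (lo, hi) in ENV_RANGES.items():
            col = table[var]
            if lo is not None and (col < lo).any():
                bad = col.index[col < lo][0]
                raise RangeError(f"{var} = {col[bad]} at sample {bad!r} below {lo}")
            if hi is not None and (col > hi).any():
                bad = col.index[col > hi][0]
                raise RangeError(f"{var} = {col[bad]} at sample {bad!r} above {hi}")
        self.table = table
        self.table.index.name = "sample"

    @property
    def samples(self) -> list[str]:
        return list(self.table.index)

    @property
    def values(self) -> np.ndarray:
        return self.table.to_numpy()

    def restrict(self, samples: Iterable[str]) -> "EnvironmentTable":
        return EnvironmentTable(self.table.loc[list(samples)])

    def __eq__(self, other) -> bool:
        return isinstance(other, EnvironmentTable) and self.table.equals(other.table)

    def __repr__(self) -> str:
        return f"EnvironmentTable({len(self.samples)} samples)"


#: Default constancy class boundaries on the F (%) scale; half-open so
#: every F in [0, 100] maps to exactly one class.  F1 accidental [0, 5),
#: F2 accessory [5, 15], F3 subconstant (15, 30], F4 constant (30, 50],
#: F5 euconstant (50, 100].
DEFAULT_CLASS_EDGES = (5.0, 15.0, 30.0, 50.0)


@dataclass
class AnalysisConfig:
    """Knobs shared by the whole pipeline, mirrored 1:1 in the YAML config."""

    plots: tuple[str, ...] = ("CG", "A", "B", "C", "D")
    control: str = "CG"
    n_perm_cca: int = 9999
    n_perm_anosim: int = 999
    n_perm_indval: int = 999
    seed: int = 1
    class_edges: tuple[float, ...] = DEFAULT_CLASS_EDGES
    indval_threshold: float = 25.0
    indval_alpha: float = 0.05
    vif_ordination: float = 10.0
    vif_models: float = 3.0
    rare_classes: tuple[str, ...] = ("F1", "F2")
    rare_scope: str = "both"          # both | either | pooled
    transform_bray: bool = True       # ln(x+1) before Bray-Curtis path too
    criterion: str = "aic"            # aic | aicc
    candidate_models: list[str] = field(default_factory=lambda: list(DEFAULT_CANDIDATES))

    def __post_init__(self):
        for name in ("n_perm_cca", "n_perm_anosim", "n_perm_indval"):
            if getattr(self, name) < 99:
                raise ValidationError(f"{name} must be >= 99")
        if self.control not in self.plots:
            raise ValidationError(f"control {self.control!r} not in plots {self.plots}")
        if self.indval_threshold <= 0 or self.indval_alpha <= 0:
            raise ValidationError("thresholds must be strictly positive")
        if self.vif_ordination <= 0 or self.vif_models <= 0:
            raise ValidationError("VIF thresholds must be strictly positive")
        edges = tuple(self.class_edges)
        if len(edges) != 4 or any(b <= a for a, b in zip(edges, edges[1:])) \
                or edges[0] <= 0 or edges[-1] >= 100:
            raise ValidationError("class edges must be strictly increasing inside (0, 100)")
        if self.rare_scope not in ("both", "either", "pooled"):
            raise ValidationError(f"unknown rare_scope {self.rare_scope!r}")
        if self.criterion not in ("aic", "aicc"):
            raise ValidationError(f"unknown criterion {self.criterion!r}")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("plots", "class_edges", "rare_classes"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


#: Default 15-model candidate set for abundance/richness model selection:
#: intercept-only, each single predictor, treatment plus each covariate,
#: and the two/three-predictor combinations of interest; "treatment" is
#: the plot factor, other terms are environment covariates.
DEFAULT_CANDIDATES = (
    "1",
    "treatment",
    "VegCovr",
    "H",
    "Ts",
    "pH",
    "RPs",
    "treatment + RPs",
    "treatment + VegCovr",
    "treatment + H",
    "treatment + pH",
    "treatment + Ts",
    "treatment + VegCovr + pH",
    "treatment + VegCovr + Ts",
    "treatment + H + Ts",
)
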