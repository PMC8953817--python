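"""Reading, writing and aligning the community and environment tables.

File layout: CSV/TSV with a header row.  The community file has the
sample id in the first column, one ``plot`` column, and the remaining
columns are species counts.  The environment file has the sample id plus
the five named variable columns.  The delimiter is auto-detected from
the extension (.csv -> comma, .tsv -> tab) unless overridden.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import NamedTuple

import pandas as pd

from .datamodel import (
    CommunityMatrix,
    EnvironmentTable,
    MissingColumnError,
    AlignmentError,
    ENV_VARIABLES,
)

log = logging.getLogger(__name__)


def _sep_for(path, dialect: str | None) -> str:
    if dialect is not None:
        return {"csv": ",", "tsv": "\t"}.get(dialect, dialect)
    return "\t" if str(path).endswith(".tsv") else ","


def read_community(path, dialect: str | None = None,
                   plot_column: str = "plot") -> CommunityMatrix:
    """Read a sample x species count table with a plot column.

    Row and column order of the file are preserved.  Raises
    :class:`MissingColumnError` if the plot column is absent,
    :class:`BadCountError` for negative/non-integer counts, and
    :class:`DuplicateSampleError` for repeated sample ids.
    """
    df = pd.read_csv(path, sep=_sep_for(path, dialect), index_col=0)
    df.index = df.index.astype(str)
    if plot_column not in df.columns:
        raise MissingColumnError(
            f"community file {path} lacks plot column {plot_column!r}")
    plot_of = df[plot_column].astype(str)
    counts = df.drop(columns=[plot_column])
    return CommunityMatrix(counts, plot_of)


def write_community(community: CommunityMatrix, path,
                    dialect: str | None = None, plot_column: str = "plot") -> None:
    out = community.counts.copy()
    out.insert(0, plot_column, community.plot_of)
    out.index.name = "sample"
    out.to_csv(path, sep=_sep_for(path, dialect))


def read_environment(path, dialect: str | None = None) -> EnvironmentTable:
    """Read the per-sample environment table (five named variables)."""
    df = pd.read_csv(path, sep=_sep_for(path, dialect), index_col=0)
    df.index = df.index.astype(str)
    missing = [v for v in ENV_VARIABLES if v not in df.columns]
    if missing:
        raise MissingColumnError(f"environment file {path} lacks columns {missing}")
    return EnvironmentTable(df)


def write_environment(env: EnvironmentTable, path, dialect: str | None = None) -> None:
    out = env.table.copy()
    out.index.name = "sample"
    out.to_csv(path, sep=_sep_for(path, dialect))


class AlignedView(NamedTuple):
    """Community and environment restricted to their common samples."""

    community: CommunityMatrix
    env: EnvironmentTable
    dropped_community: tuple[str, ...]
    dropped_env: tuple[str, ...]


def align(community: CommunityMatrix, env: EnvironmentTable) -> AlignedView:
    """Restrict both tables to common samples in the community's order.

    Samples present in only one table are dropped and reported (and
    logged); an empty intersection raises :class:`AlignmentError`.
    """
    common = [s for s in community.samples if s in set(env.samples)]
    if not common:
        raise AlignmentError("community and environment tables share no samples")
    dropped_c = tuple(s for s in community.samples if s not in set(common))
    dropped_e = tuple(s for s in env.samples if s not in set(common))
    if dropped_c or dropped_e:
        log.warning("align dropped %d community and %d environment samples",
                    len(dropped_c), len(dropped_e))
    return AlignedView(community.restrict(common), env.restrict(common),
                       dropped_c, dropped_e)
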