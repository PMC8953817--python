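"""End-to-end orchestration: run every analysis stage off one config and
master seed, collect a reproducible report.

Per-stage seeds derive from the master seed by a fixed counter scheme
(``SeedSequence([master, stage_index])``), so adding a stage never
perturbs the random streams of earlier stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from importlib.metadata import version as _pkg_version

try:
    _version = _pkg_version("mitecomm")
except Exception:
    _version = "0.0.0"

from .datamodel import AnalysisConfig, CommunityMatrix, EnvironmentTable
from . import structure, ordination, indicators, models
from .io import write_community, write_environment
from .synthetic import default_spec, generate, reference_count_table

log = logging.getLogger(__name__)

#: Fixed stage registry: (name, counter) pairs; counters are permanent.
STAGES = (
    ("summaries", 0),
    ("frequency", 1),
    ("dispersal", 2),
    ("rarefaction", 3),
    ("nmds_anosim", 4),
    ("cca", 5),
    ("indval", 6),
    ("models", 7),
    ("env_anova", 8),
)


def stage_seed(master: int, counter: int) -> int:
    """Deterministic per-stage seed below 2**31."""
    return int(np.random.SeedSequence([master, counter]).generate_state(1)[0] >> 1)


@dataclass
class RunReport:
    config: dict
    seed: int
    version: str
    stages: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)
        return json.dumps({"config": self.config, "seed": self.seed,
                           "version": self.version, "stages": self.stages,
                           "errors": self.errors, "warnings": self.warnings},
                          indent=2, sort_keys=True, default=default)

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()

    @property
    def ok(self) -> bool:
        return not self.errors


def run_all(community: CommunityMatrix, env: EnvironmentTable,
            config: AnalysisConfig | None = None,
            out_dir: str | Path | None = None) -> RunReport:
    """Run the full analysis chain; independent stage failures don't abort.

    Stages: per-plot summaries, frequency/constancy tables, pairwise
    DD4 dispersal, Mao Tau rarefaction, NMDS + ANOSIM, CCA with forward
    selection and permutation tests, IndVal with significance, candidate
    Poisson model ranking with contrasts, and environment ANOVA/Tukey.
    """
    config = config or AnalysisConfig()
    report = RunReport(config=vars(config).copy(), seed=config.seed, version=_version)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def save(name: str, df: pd.DataFrame):
        if out is not None:
            df.to_csv(out / f"{name}.csv")

    def run_stage(name, counter, fn):
        try:
            report.stages[name] = fn(stage_seed(config.seed, counter))
        except Exception as exc:       # record, keep going
            log.exception("stage %s failed", name)
            report.errors[name] = f"{type(exc).__name__}: {exc}"

    def st_summaries(_):
        summ = structure.plot_summaries(community)
        save("plot_summaries", summ)
        return summ.to_dict()

    def st_frequency(_):
        tables = {p: structure.frequency_table(community, p, config.class_edges)
                  for p in list(community.plots) + [structure.POOLED]}
        longf = pd.concat(tables, names=["plot"])
        save("frequency", longf)
        return {p: t["constancy_class"].value_counts().to_dict()
                for p, t in tables.items()}

    def st_dispersal(_):
        dd = structure.pairwise_dispersal(community, config.rare_classes,
                                          config.rare_scope)
        save("dispersal", dd)
        return dd.to_dict(orient="records")

    def st_rarefaction(_):
        curves = {p: structure.mao_tau(community, p) for p in community.plots}
        curves[structure.POOLED] = structure.mao_tau(community)
        longc = pd.concat(curves, names=["scope"])
        save("rarefaction", longc)
        return {p: float(c["tau"].iloc[-1]) for p, c in curves.items()}

    def st_nmds_anosim(seed):
        d = ordination.bray_curtis(
            community, "ln1p" if config.transform_bray else "none")
        nm = ordination.nmds(d, seed=seed)
        an = ordination.anosim(d, community.plot_of,
                               n_perm=config.n_perm_anosim, seed=seed + 1)
        save("nmds_coordinates", nm.coordinates)
        return {"stress": nm.stress, "converged": nm.converged,
                "anosim_R": an.R, "anosim_p": an.p}

    def st_cca(seed):
        selected = ordination.cca_forward_select(
            community, env, n_perm=min(config.n_perm_cca, 999), seed=seed)
        constraints = selected or list(env.table.columns)
        fit = ordination.cca_fit(community, env, constraints)
        ordination.cca_permutation_test(fit, n_perm=config.n_perm_cca,
                                        seed=seed + 1, which="model")
        save("cca_site_scores", fit.site_scores)
        save("cca_species_scores", fit.species_scores)
        save("cca_biplot_scores", fit.biplot_scores)
        return {"selected": selected, "eigenvalues": fit.eigenvalues,
                "axis_percent": fit.axis_percent,
                "constrained_fraction": fit.constrained_inertia / fit.total_inertia,
                "vif": fit.vif.to_dict(), "p_model": fit.p_model,
                "highlighted_species": fit.highlighted_species()}

    def st_indval(seed):
        res = indicators.indval_test(community, n_perm=config.n_perm_indval,
                                     seed=seed)
        chars = indicators.characteristic_species(
            res, config.indval_threshold, config.indval_alpha)
        save("indval", res.table)
        save("characteristic_species", chars)
        return {"characteristic": chars.to_dict(orient="records")}

    def st_models(_):
        outd = {}
        for resp in ("abundance", "richness"):
            fits = models.fit_candidates(community, env, resp,
                                         config.candidate_models,
                                         reference=config.control)
            table = models.rank_models(fits, config.criterion)
            save(f"model_ranking_{resp}", table)
            best_formula = table.iloc[0]["model"]
            entry = {"ranking": table.to_dict(orient="records"),
                     "best": best_formula}
            if "treatment" in best_formula:
                best = next(f for f in fits if f.formula == best_formula)
                contr = models.model_contrasts(best, config.control)
                save(f"model_contrasts_{resp}", contr)
                entry["contrasts"] = contr.to_dict(orient="records")
            outd[resp] = entry
        return outd

    def st_env_anova(_):
        anova, tukey = models.env_anova_tukey(env, community.plot_of)
        save("env_anova", anova)
        save("env_tukey", tukey)
        return {"anova": anova.to_dict(orient="records")}

    fns = {"summaries": st_summaries, "frequency": st_frequency,
           "dispersal": st_dispersal, "rarefaction": st_rarefaction,
           "nmds_anosim": st_nmds_anosim, "cca": st_cca,
           "indval": st_indval, "models": st_models, "env_anova": st_env_anova}
    for name, counter in STAGES:
        run_stage(name, counter, fns[name])

    if out is not None:
        (out / "report.json").write_text(report.to_json())
        (out / "report.md").write_text(render_markdown(report))
    return report


def render_markdown(report: RunReport) -> str:
    lines = [f"# Analysis report (seed {report.seed}, v{report.version})", ""]
    for name, _ in STAGES:
        lines.append(f"## {name}")
        if name in report.errors:
            lines.append(f"FAILED: {report.errors[name]}")
        else:
            lines.append("```json")
            lines.append(json.dumps(report.stages.get(name), indent=2,
                                    sort_keys=True, default=str))
            lines.append("```")
        lines.append("")
    return "\n".join(lines)


def make_fixtures(out_dir: str | Path, seed: int = 1) -> dict[str, Path]:
    """Write the packaged synthetic tables and worked-example fixtures.

    Emits the study-preset community/environment tables (250 x 30, five
    plots of 50), the deterministic bookkeeping stand-in table, a toy
    DD4 worked-example frequency table, and a JSON of its expected
    statistic.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    community, env = generate(default_spec(), seed)
    paths["community"] = out / "synthetic_community.csv"
    paths["environment"] = out / "synthetic_environment.csv"
    write_community(community, paths["community"])
    write_environment(env, paths["environment"])

    ref = reference_count_table()
    paths["reference"] = out / "synthetic_reference_counts.csv"
    write_community(ref, paths["reference"])

    # Worked DD4 example: A=100, B=60, W=20 -> (40/160)*(40/140) = 1/14
    toy = pd.DataFrame({
        "species": ["s1", "s2", "s3"],
        "F_a": [80.0, 10.0, 10.0],
        "F_b": [40.0, 10.0, 10.0],
        "rare": [False, True, True],
    }).set_index("species")
    paths["dd4_toy"] = out / "dd4_worked_example.csv"
    toy.to_csv(paths["dd4_toy"])
    from .structure import dd4_statistic
    raw, W, A, B = dd4_statistic(toy["F_a"].to_numpy(), toy["F_b"].to_numpy(),
                                 toy["rare"].to_numpy())
    paths["expected"] = out / "expected_examples.json"
    paths["expected"].write_text(json.dumps(
        {"dd4_toy": {"W": float(W), "A": float(A), "B": float(B),
                     "dd4": float(raw)}}, indent=2))
    return paths
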