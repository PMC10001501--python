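"""One-command orchestration: data -> screen -> yearly fits -> stability ->
marginal effects -> sign shares, with every artefact written to an output
directory.  All randomness flows from one root seed; each stage derives its
inputs deterministically, so reruns with the same config are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import CrashTable, correlation_screen, descriptive_summary, load_crash_table
from .inference import average_marginal_effect, sample_averaged_sign_share, sign_share
from .mixed_logit import (
    FitResult,
    ModelSpec,
    ParameterVector,
    RandomCoef,
    RandomSpec,
    fit_model,
    normal_draw_matrix,
)
from .simulate import (
    SyntheticScenario,
    YearRegime,
    demo_scenario,
    make_temporal_dataset,
    study_scenario,
)
from .stability import pooled_separation_test, stability_matrix

log = logging.getLogger("crashlogit")

__all__ = [
    "RunConfig",
    "PipelineError",
    "run_analysis",
    "load_run_config",
    "scenario_from_dict",
    "modelspec_from_dict",
    "demo_modelspec",
]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage (and year, if any)."""


# ---------------------------------------------------------------------------
# config parsing


def modelspec_from_dict(d: dict) -> ModelSpec:
    random = tuple(
        RandomSpec(
            name=r["name"],
            z=tuple(r.get("z", ())),
            w=tuple(r.get("w", ())),
            distribution=r.get("distribution", "normal"),
        )
        for r in d.get("random", ())
    )
    return ModelSpec(
        fixed=tuple(d.get("fixed", ())),
        random=random,
        outcome=d.get("outcome", "fatal"),
        include_constant=bool(d.get("include_constant", True)),
        n_draws=int(d.get("n_draws", 500)),
        halton_burn=int(d.get("halton_burn", 50)),
        seed=int(d.get("seed", 0)),
    )


def _params_from_dict(d: dict) -> ParameterVector:
    random = {
        name: RandomCoef(
            beta=float(r.get("beta", 0.0)),
            sigma=float(r.get("sigma", 0.0)),
            theta={k: float(v) for k, v in r.get("theta", {}).items()},
            omega={k: float(v) for k, v in r.get("omega", {}).items()},
        )
        for name, r in d.get("random", {}).items()
    }
    return ParameterVector(
        constant=None if d.get("constant") is None else float(d["constant"]),
        fixed={k: float(v) for k, v in d.get("fixed", {}).items()},
        random=random,
    )


def scenario_from_dict(d: dict) -> SyntheticScenario:
    years = {}
    for year, block in d["years"].items():
        years[int(year)] = YearRegime(
            n=int(block["n"]),
            prevalences={k: float(v) for k, v in block["prevalences"].items()},
            truth=_params_from_dict(block["truth"]),
        )
    return SyntheticScenario(
        years=years,
        seed=int(d.get("seed", 0)),
        outcome_col=d.get("outcome_col", "fatal"),
        year_col=d.get("year_col", "year"),
    )


def demo_modelspec(n_draws: int = 100, seed: int = 0) -> ModelSpec:
    """Candidate specification matching the demo scenario's covariates."""
    return ModelSpec(
        fixed=("gender", "speeding", "darkness"),
        random=(
            RandomSpec("helmet", z=("drunk",), w=("festival",)),
            RandomSpec("festival"),
        ),
        n_draws=n_draws,
        seed=seed,
    )


@dataclass
class RunConfig:
    """Exactly one of ``data_path`` / ``scenario`` selects the input."""

    outdir: str | Path
    data_path: str | Path | None = None
    scenario: SyntheticScenario | str | None = None  # scenario, "demo", "study", or a file path
    spec: ModelSpec | None = None
    retention_t: float = 1.645
    seed: int = 0
    n_draws: int | None = None  # overrides spec.n_draws when given
    verbosity: int = 1

    def __post_init__(self):
        if (self.data_path is None) == (self.scenario is None):
            raise PipelineError("config must name exactly one of data_path or scenario")


def _load_structured(path: Path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith((".yml", ".yaml")):
        return yaml.safe_load(text)
    return json.loads(text)


def load_run_config(path) -> RunConfig:
    d = _load_structured(Path(path))
    scenario = d.get("scenario")
    if isinstance(scenario, dict):
        scenario = scenario_from_dict(scenario)
    spec = d.get("spec")
    if isinstance(spec, dict):
        spec = modelspec_from_dict(spec)
    return RunConfig(
        outdir=d["outdir"],
        data_path=d.get("data_path"),
        scenario=scenario,
        spec=spec,
        retention_t=float(d.get("retention_t", 1.645)),
        seed=int(d.get("seed", 0)),
        n_draws=d.get("n_draws"),
        verbosity=int(d.get("verbosity", 1)),
    )


# ---------------------------------------------------------------------------
# stages


def _resolve_table(config: RunConfig) -> CrashTable:
    if config.data_path is not None:
        return load_crash_table(config.data_path)
    scenario = config.scenario
    if scenario == "demo":
        scenario = demo_scenario(seed=config.seed)
    elif scenario == "study":
        scenario = study_scenario(seed=config.seed)
    elif isinstance(scenario, (str, Path)):
        scenario = scenario_from_dict(_load_structured(Path(scenario)))
    return make_temporal_dataset(scenario)


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_analysis(config: RunConfig) -> dict:
    """Run the full battery and write the report bundle; returns the in-memory
    results keyed by stage."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    def stage(name, fn, *args, **kwargs):
        log.info("stage %s", name)
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    table = stage("data", _resolve_table, config)
    table.to_csv(outdir / "crash_table.csv")
    results["table"] = table

    summary = stage("descriptives", descriptive_summary, table)
    summary.counts.to_csv(outdir / "counts_by_year.csv")
    flat = summary.moments.copy()
    flat.columns = [f"{y}_{s}" for y, s in flat.columns]
    flat.to_csv(outdir / "descriptives.csv")
    results["descriptives"] = summary

    flagged = stage("screen", correlation_screen, table)
    _dump_json(
        {"threshold": 0.7, "flagged": [{"a": a, "b": b, "r": r} for a, b, r in flagged]},
        outdir / "correlation_screen.json",
    )
    results["screen"] = flagged

    spec = config.spec or demo_modelspec(seed=config.seed)
    if config.n_draws is not None:
        spec = ModelSpec(
            fixed=spec.fixed, random=spec.random, outcome=spec.outcome,
            include_constant=spec.include_constant, n_draws=int(config.n_draws),
            halton_burn=spec.halton_burn, seed=spec.seed,
        )

    fits: dict[int, FitResult] = {}
    tables: dict[int, CrashTable] = {}
    for year in table.years:
        tables[year] = table.subset_year(year)
        fits[year] = stage(f"fit[{year}]", fit_model, spec, tables[year])
        fits[year].summary_table().to_csv(outdir / f"coefficients_{year}.csv", index=False)
    pooled = stage("fit[pooled]", fit_model, spec, table)
    pooled.summary_table().to_csv(outdir / "coefficients_pooled.csv", index=False)
    results["fits"] = fits
    results["pooled"] = pooled

    gof = {
        "pooled": pooled.to_json_dict(),
        **{str(y): fits[y].to_json_dict() for y in fits},
    }
    for block in gof.values():
        for key in ("parameters", "estimates", "std_errors", "t_stats"):
            block.pop(key, None)
    _dump_json(gof, outdir / "goodness_of_fit.json")

    report = stage("stability", stability_matrix, fits, tables, config.retention_t)
    report.pooled = stage(
        "stability[pooled]",
        pooled_separation_test,
        pooled.ll_beta,
        [fits[y].ll_beta for y in sorted(fits)],
        pooled.k,
        [fits[y].k for y in sorted(fits)],
    )
    _dump_json(report.to_json_dict(), outdir / "stability.json")
    (outdir / "stability_matrix.txt").write_text(report.render_matrix() + "\n")
    results["stability"] = report

    variables = list(spec.fixed) + list(spec.random_names)
    me_rows = []
    for year in sorted(fits):
        draws = (
            normal_draw_matrix(spec, tables[year].n) if spec.random else None
        )
        for v in variables:
            me_rows.append(
                {
                    "year": year,
                    "variable": v,
                    "marginal_effect": stage(
                        f"me[{year}:{v}]",
                        average_marginal_effect,
                        fits[year], tables[year], v, draws,
                    ),
                }
            )
    me = pd.DataFrame(me_rows)
    me_wide = me.pivot(index="variable", columns="year", values="marginal_effect")
    me_wide = me_wide.reindex(variables)
    me_wide.to_csv(outdir / "marginal_effects.csv")
    results["marginal_effects"] = me_wide

    share_rows = []
    for year in sorted(fits):
        params = fits[year].params
        for name, rc in params.random.items():
            marginal = sign_share(rc.beta, rc.sigma, variable=name)
            averaged = sample_averaged_sign_share(params, tables[year], name)
            share_rows.append(
                {
                    "year": year,
                    "variable": name,
                    "below_zero": marginal.below_zero,
                    "above_zero": marginal.above_zero,
                    "below_zero_sample_avg": averaged.below_zero,
                }
            )
    shares = pd.DataFrame(share_rows)
    shares.to_csv(outdir / "sign_shares.csv", index=False)
    results["sign_shares"] = shares

    _dump_json(
        {
            "seed": config.seed,
            "retention_t": config.retention_t,
            "n_draws": spec.n_draws,
            "years": [int(y) for y in table.years],
            "n_records": int(table.n),
            "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()),
        },
        outdir / "run_manifest.json",
    )
    return results
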