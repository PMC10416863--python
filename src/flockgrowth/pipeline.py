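"""End-to-end analysis pipeline.

Staged flow per sex: clean -> partition into HE/LE by 35-d FCR -> fit the
three growth models per flock and pooled by group -> derive inflection
traits -> compare performance variables and parameter estimates between
groups -> rank models by goodness of fit -> summarize pooled-fit residuals
by age.  All stages are deterministic; randomness lives only in the
synthetic generator, so a config + seed replays bit-identically.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fitting import FitResult, compare_models, fit_model
from .io import clean_flocks, read_flock_table, records_to_frame, write_flock_table
from .models import MODEL_TAGS, PARAM_NAMES
from .records import FlockRecord, SEXES
from .simulate import GeneratorConfig, simulate_dataset
from .stats import compare_groups
from .tree import partition_flocks, render_tree

log = logging.getLogger("flockgrowth")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the run halts rather than emit partial results."""


@dataclass
class PipelineConfig:
    input: str | None = None          # flock table path; None -> simulate
    outdir: str = "results/run"
    sex: str = "both"                 # male | female | both
    models: tuple[str, ...] = MODEL_TAGS
    max_splits: int = 8
    min_leaf: int = 15
    logworth_threshold: float = 1.3
    n_boundaries: int = 1
    alpha: float = 0.05
    max_iter: int = 500
    rss_tol: float = 1e-10
    step_tol: float = 1e-8
    seed: int = 0
    n_flocks_per_group: int = 50      # generator size when input is None
    verbose: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load flat YAML keys; explicit keyword overrides win over the file."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "models" in data:
            data["models"] = tuple(data["models"])
        return cls(**data)

    def validate(self) -> None:
        if self.sex not in ("male", "female", "both"):
            raise PipelineError(f"sex must be male/female/both, got {self.sex!r}")
        unknown = set(self.models) - set(MODEL_TAGS)
        if unknown:
            raise PipelineError(f"unknown model tags: {sorted(unknown)}")


def _fit_row(scope: str, sex: str, group: str, fit: FitResult) -> dict:
    row: dict[str, object] = {
        "scope": scope, "sex": sex, "group": group, "model": fit.model,
    }
    for name, value in zip(PARAM_NAMES[fit.model], fit.params.as_array()):
        row[name] = value
    d = fit.derived
    row["t_i_derived"] = d.t_i if d else np.nan
    row["w_i"] = d.w_i if d else np.nan
    row["w_a_derived"] = d.w_a if d else np.nan
    row["mi"] = d.mi if d and d.mi is not None else np.nan
    g = fit.gof
    row.update(r2=g.r2, rmse=g.rmse, aic=g.aic, aicc=g.aicc, bic=g.bic,
               n_iter=g.n_iter, converged=g.converged,
               warnings="; ".join(fit.warnings))
    return row


def report_residuals(pooled_fits: dict[tuple[str, str, str], FitResult]) -> pd.DataFrame:
    """Mean residual (observed - predicted, g) per model x sex x group x age.

    Positive values mean the model underfits (predicts below) the observed
    body weight at that age.
    """
    rows = []
    for (sex, group, model), fit in sorted(pooled_fits.items()):
        for age in np.unique(fit.ages):
            mask = fit.ages == age
            rows.append({
                "sex": sex, "group": group, "model": model, "age": int(age),
                "mean_residual": float(fit.residuals[mask].mean()),
                "n": int(mask.sum()),
            })
    return pd.DataFrame(rows)


def _compare_performance(
    records: list[FlockRecord], labels: dict[str, str], sex: str, alpha: float
) -> list[dict]:
    """Table-style HE-vs-LE comparison of every weekly performance variable."""
    recs = [r for r in records if r.sex == sex and labels.get(r.flock_id) in ("HE", "LE")]
    by_group: dict[str, list[FlockRecord]] = {"HE": [], "LE": []}
    for r in recs:
        by_group[labels[r.flock_id]].append(r)
    rows = []
    ages = recs[0].series.ages
    specs = [("bw", "bw", False, 0), ("fi", "fi", False, 1), ("fcr", "fcr", False, 1),
             ("week_mort", "week_mort", True, 1), ("cum_mort", "cum_mort", True, 1)]
    for var, fieldname, is_pct, start in specs:
        for j, age in enumerate(ages):
            if j < start:
                continue
            grouped = {
                g: [getattr(r.series, fieldname)[j] for r in members]
                for g, members in by_group.items()
            }
            comp = compare_groups(grouped, variable=var, age=age, alpha=alpha,
                                  percentage=is_pct)
            rows.append({
                "sex": sex, "variable": var, "age": age,
                "mean_HE": comp.means["HE"], "mean_LE": comp.means["LE"],
                "letter_HE": comp.letters["HE"], "letter_LE": comp.letters["LE"],
                "sem": comp.sem, "cv": comp.cv, "p_value": comp.p_value,
            })
    return rows


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute the full analysis; returns the paths of all written artifacts."""
    config.validate()
    t_start = time.time()
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO if config.verbose else logging.WARNING,
        format="%(levelname)s %(name)s: %(message)s",
    )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # ---- load or simulate -------------------------------------------------
    if config.input is not None:
        records, rejects = read_flock_table(config.input)
        log.info("read %d records (%d rejected) from %s",
                 len(records), len(rejects), config.input)
    else:
        gen = GeneratorConfig(
            n_flocks_per_group=config.n_flocks_per_group, seed=config.seed
        )
        records, truth = simulate_dataset(gen)
        truth.to_csv(outdir / "truth.csv", index=False)
        log.info("simulated %d flocks (seed=%d)", len(records), config.seed)

    kept, dropped = clean_flocks(records)
    if config.sex != "both":
        kept = [r for r in kept if r.sex == config.sex]
    if not kept:
        raise PipelineError("no flocks left after cleaning/filtering")
    sexes = [s for s in SEXES if s == config.sex or config.sex == "both"]

    # ---- partition --------------------------------------------------------
    labels: dict[str, str] = {}
    tree_reports: list[str] = []
    tree_stats: dict[str, dict] = {}
    for sex in sexes:
        sex_recs = [r for r in kept if r.sex == sex]
        ids = [r.flock_id for r in sex_recs]
        fcr = [r.fcr35 for r in sex_recs]
        part = partition_flocks(
            ids, fcr,
            max_splits=config.max_splits, min_leaf=config.min_leaf,
            logworth_threshold=config.logworth_threshold,
            n_boundaries=config.n_boundaries,
        )
        labels.update(part.labels)
        tree_reports.append(f"== {sex} ==\n" + render_tree(part, fcr))
        tree_stats[sex] = {
            "n_splits": part.n_splits, "r2": part.r2, "rase": part.rase,
            "group_means": part.group_means,
        }
        log.info("%s tree: %d splits, r2=%.3f, rase=%.4f",
                 sex, part.n_splits, part.r2, part.rase)

    labeled = records_to_frame(kept)
    labeled["efficiency"] = [labels.get(fid, "unassigned") for fid in labeled["flock_id"]]

    # ---- fits -------------------------------------------------------------
    fit_rows: list[dict] = []
    per_flock_fits: dict[tuple[str, str, str], list[FitResult]] = {}
    pooled_fits: dict[tuple[str, str, str], FitResult] = {}
    for sex in sexes:
        for group in ("HE", "LE"):
            members = [r for r in kept
                       if r.sex == sex and labels.get(r.flock_id) == group]
            if not members:
                continue
            for model in config.models:
                fits = []
                for rec in members:
                    fit = fit_model(rec.series.ages, rec.series.bw, model,
                                    max_iter=config.max_iter,
                                    rss_tol=config.rss_tol,
                                    step_tol=config.step_tol)
                    row = _fit_row("flock", sex, group, fit)
                    row["flock_id"] = rec.flock_id
                    fit_rows.append(row)
                    fits.append(fit)
                per_flock_fits[(sex, group, model)] = fits
                pooled_ages = np.concatenate([r.series.ages for r in members])
                pooled_bw = np.concatenate([r.series.bw for r in members])
                pfit = fit_model(pooled_ages, pooled_bw, model,
                                 max_iter=config.max_iter,
                                 rss_tol=config.rss_tol, step_tol=config.step_tol)
                pooled_fits[(sex, group, model)] = pfit
                prow = _fit_row("pooled", sex, group, pfit)
                prow["flock_id"] = ""
                fit_rows.append(prow)
            log.info("fitted %d flocks + pooled for %s/%s", len(members), sex, group)
    fits_df = pd.DataFrame(fit_rows)

    # ---- group comparisons ------------------------------------------------
    comp_rows: list[dict] = []
    for sex in sexes:
        comp_rows += _compare_performance(kept, labels, sex, config.alpha)
        # fitted parameters and derived traits per model
        for model in config.models:
            sub = fits_df[(fits_df.scope == "flock") & (fits_df.sex == sex)
                          & (fits_df.model == model)]
            for col in list(PARAM_NAMES[model]) + ["t_i_derived", "w_i", "mi"]:
                grouped = {
                    g: sub[sub.group == g][col].dropna().to_numpy()
                    for g in ("HE", "LE")
                }
                if any(len(v) < 2 for v in grouped.values()):
                    continue
                if all(np.ptp(v) == 0 for v in grouped.values()):
                    continue
                comp = compare_groups(grouped, variable=f"{model}:{col}",
                                      alpha=config.alpha)
                comp_rows.append({
                    "sex": sex, "variable": f"{model}:{col}", "age": np.nan,
                    "mean_HE": comp.means["HE"], "mean_LE": comp.means["LE"],
                    "letter_HE": comp.letters["HE"], "letter_LE": comp.letters["LE"],
                    "sem": comp.sem, "cv": comp.cv, "p_value": comp.p_value,
                })
    comparison_df = pd.DataFrame(comp_rows)

    # ---- model comparison on pooled fits ----------------------------------
    mc_rows = []
    for sex in sexes:
        for group in ("HE", "LE"):
            cell = [pooled_fits[(sex, group, m)] for m in config.models
                    if (sex, group, m) in pooled_fits]
            if len(cell) < 2:
                continue
            ranked = compare_models(cell)
            ranked.insert(0, "sex", sex)
            ranked.insert(1, "group", group)
            mc_rows.append(ranked)
    model_comparison_df = (
        pd.concat(mc_rows, ignore_index=True) if mc_rows else pd.DataFrame()
    )

    residuals_df = report_residuals(pooled_fits)

    # ---- write artifacts --------------------------------------------------
    paths: dict[str, Path] = {}

    def _write(name: str, df: pd.DataFrame) -> None:
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path

    _write("flocks_labeled", labeled)
    _write("fits", fits_df)
    _write("group_comparison", comparison_df)
    _write("model_comparison", model_comparison_df)
    _write("residuals", residuals_df)
    (outdir / "tree.txt").write_text("\n\n".join(tree_reports) + "\n")
    paths["tree"] = outdir / "tree.txt"

    manifest = {
        "package": "flockgrowth",
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "seed": config.seed,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "counts": {
            "input": len(records),
            "kept": len(kept),
            "dropped": len(dropped),
            "labeled_HE": sum(1 for v in labels.values() if v == "HE"),
            "labeled_LE": sum(1 for v in labels.values() if v == "LE"),
            "unassigned": sum(1 for v in labels.values() if v == "unassigned"),
        },
        "trees": tree_stats,
    }
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    paths["manifest"] = mpath
    log.info("pipeline finished in %.1f s -> %s", time.time() - t_start, outdir)
    return paths
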