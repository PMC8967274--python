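"""Stage orchestration: simulate -> preprocess -> fit -> derive -> contrast -> clines.

Each stage reads its upstream artifacts from the output directory and writes
its own, so any suffix of the pipeline can be re-run. A manifest records the
configuration hash, seeds, and every artifact path; re-running with the same
configuration reproduces all stochastic outputs bit-identically.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .errors import PipelineError
from .inference import cline_analysis, range_contrast
from .io import read_climate_csv, read_experiment_csv, read_json, write_json, write_table
from .preprocess import preprocess, scale_dataset
from .synthetic_data import simulate_experiment
from .tpc_derive import derive_draws, summarize_derived
from .tpc_model import PARAM_NAMES, PosteriorDraws, fit_tpc, posterior_predictive_pvalue

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "fit", "derive", "contrast", "clines")

ARTIFACTS = {
    "simulate": ("experiment.csv", "climate.csv", "truths.csv"),
    "preprocess": ("genotype_means.csv", "scaling.json", "filter_report.json"),
    "fit": ("posterior_draws.csv", "posterior_sigma.csv", "diagnostics.json"),
    "derive": ("derived_draws.csv", "derived_summary.csv"),
    "contrast": ("contrasts.json",),
    "clines": ("clines.csv",),
}

#: which stage produces each artifact a later stage may need
_PRODUCER = {f: s for s, files in ARTIFACTS.items() for f in files}


def _need(outdir: Path, filename: str, for_stage: str) -> Path:
    path = outdir / filename
    if not path.exists():
        raise PipelineError(
            f"stage '{for_stage}' needs {filename}, which does not exist; "
            f"run stage '{_PRODUCER[filename]}' first"
        )
    return path


def _rebuild_scaled(outdir: Path, stage: str):
    means = pd.read_csv(_need(outdir, "genotype_means.csv", stage))
    return scale_dataset(means)


def _rebuild_draws(outdir: Path, stage: str) -> PosteriorDraws:
    long = pd.read_csv(_need(outdir, "posterior_draws.csv", stage))
    sig = pd.read_csv(_need(outdir, "posterior_sigma.csv", stage))
    scaling = read_json(_need(outdir, "scaling.json", stage))
    pops = sorted(long["population_id"].unique())
    labels = (
        long.drop_duplicates("population_id")
        .set_index("population_id")["range_label"]
        .to_dict()
    )
    n_d = int(long["draw"].max()) + 1
    params = np.empty((n_d, len(pops), len(PARAM_NAMES)))
    for k, pop in enumerate(pops):
        sub = long[long["population_id"] == pop]
        for j, name in enumerate(PARAM_NAMES):
            s = sub[sub["parameter"] == name].sort_values("draw")
            params[:, k, j] = s["value"].to_numpy(dtype=float)
    sig = sig.sort_values("draw")
    return PosteriorDraws(
        params=params,
        sigma=sig["sigma"].to_numpy(dtype=float),
        chain=sig["chain"].to_numpy(dtype=int),
        populations=pops,
        range_labels=[labels[p] for p in pops],
        grand_mean_rgr=float(scaling["grand_mean_rgr"]),
        temp_center=float(scaling["temp_center"]),
    )


def _stage_simulate(cfg: RunConfig, outdir: Path):
    climate, truths, records = simulate_experiment(cfg.sim)
    write_table(records, outdir / "experiment.csv")
    write_table(climate, outdir / "climate.csv")
    write_table(truths, outdir / "truths.csv")


def _stage_preprocess(cfg: RunConfig, outdir: Path):
    records = read_experiment_csv(_need(outdir, "experiment.csv", "preprocess"))
    _clean, report, means, scaled = preprocess(records)
    logger.info(
        "filter audit: %d -> %d established -> %d final",
        report.n_total,
        report.n_after_establish,
        report.n_final,
    )
    write_table(means, outdir / "genotype_means.csv")
    write_json(
        {"grand_mean_rgr": scaled.grand_mean_rgr, "temp_center": scaled.temp_center},
        outdir / "scaling.json",
    )
    write_json(report.to_dict(), outdir / "filter_report.json")


def _stage_fit(cfg: RunConfig, outdir: Path):
    scaled = _rebuild_scaled(outdir, "fit")
    draws, diag = fit_tpc(scaled, cfg.mcmc)
    write_table(draws.to_frame(), outdir / "posterior_draws.csv")
    write_table(
        pd.DataFrame(
            {"draw": np.arange(draws.n_draws), "chain": draws.chain, "sigma": draws.sigma}
        ),
        outdir / "posterior_sigma.csv",
    )
    ppc = posterior_predictive_pvalue(draws, scaled, seed=cfg.mcmc.seed)
    write_json(
        {
            "converged": diag.converged,
            "max_rhat": diag.max_rhat,
            "min_ess": diag.min_ess,
            "warnings": diag.warnings,
            "ppc_overall": ppc.overall,
            "ppc_per_population": ppc.per_population,
        },
        outdir / "diagnostics.json",
    )


def _stage_derive(cfg: RunConfig, outdir: Path):
    draws = _rebuild_draws(outdir, "derive")
    per_draw = derive_draws(draws, cfg.derive)
    summary = summarize_derived(draws, cfg.derive, per_draw=per_draw)
    write_table(per_draw, outdir / "derived_draws.csv")
    write_table(summary.table, outdir / "derived_summary.csv")


def _stage_contrast(cfg: RunConfig, outdir: Path):
    per_draw = pd.read_csv(_need(outdir, "derived_draws.csv", "contrast"))
    contrasts = {
        p: range_contrast(per_draw, p).to_dict() for p in ("t_opt", "t_breadth")
    }
    write_json(contrasts, outdir / "contrasts.json")


def _stage_clines(cfg: RunConfig, outdir: Path):
    summary = pd.read_csv(_need(outdir, "derived_summary.csv", "clines"))
    climate = read_climate_csv(_need(outdir, "climate.csv", "clines"))
    means = summary[summary["parameter"].isin(["t_opt", "t_breadth"])].pivot_table(
        index=["population_id", "range_label"], columns="parameter", values="mean"
    ).reset_index()
    report = cline_analysis(means, climate)
    write_table(report.to_frame(), outdir / "clines.csv")


_STAGE_FN = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "fit": _stage_fit,
    "derive": _stage_derive,
    "contrast": _stage_contrast,
    "clines": _stage_clines,
}


def run_pipeline(cfg: RunConfig, outdir, stages=None) -> dict:
    """Execute the requested stages in order and write the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if stages is None:
        stages = STAGES
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in STAGES if s in stages]

    manifest_path = outdir / "manifest.json"
    manifest = read_json(manifest_path) if manifest_path.exists() else {}
    manifest.setdefault("stages", {})
    manifest["config_hash"] = cfg.content_hash()
    manifest["seeds"] = {"sim": cfg.sim.seed, "mcmc": cfg.mcmc.seed}
    manifest["version"] = __version__

    for stage in stages:
        t0 = time.time()
        logger.info("running stage %s", stage)
        _STAGE_FN[stage](cfg, outdir)
        manifest["stages"][stage] = {
            "artifacts": [str(outdir / f) for f in ARTIFACTS[stage]],
            "elapsed_s": round(time.time() - t0, 3),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
    write_json(manifest, manifest_path)
    return manifest
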