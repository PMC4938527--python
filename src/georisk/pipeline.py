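"""End-to-end pipeline driver: simulate -> survey -> explore -> fit ->
predict -> map, persisting every intermediate artifact plus a manifest
recording seeds, versions, per-stage wall times and the config hash."""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .covariates import (bite_model_spec, envenoming_model_spec, fit_glm,
                         standardized_residuals, select_breakpoint)
from .geostat import (MCSettings, ParamSet, empirical_variogram, fit_mcml,
                      initial_params)
from .io import (read_clusters, read_grid, read_strata, write_clusters,
                 write_grid, write_strata)
from .mapping import incidence_surface, krige_conditional, threshold_suite
from .survey import survey_table
from .synthetic import TrueModel, make_domain, sample_clusters, \
    simulate_counts, simulate_field

log = logging.getLogger("georisk")

STAGES = ["simulate", "survey", "explore", "fit", "predict", "map"]


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _model_spec(cfg: PipelineConfig):
    if cfg.model.response == "bites":
        return bite_model_spec(cfg.model.elevation_knot, cfg.model.agri_knot)
    return envenoming_model_spec(cfg.model.elevation_knot)


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run all stages and return the artifact directory.

    Any stage failure halts the run with the stage name; artifacts from
    completed stages are left in place.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": cfg.seed,
        "config_hash": cfg.content_hash(),
        "version": __version__,
        "stages": [],
    }
    log.info("pipeline start: seed=%d config_hash=%s", cfg.seed,
             manifest["config_hash"])
    state: dict = {}
    for stage in STAGES:
        t0 = time.perf_counter()
        log.info("stage %s starting", stage)
        try:
            outputs = _STAGE_FUNCS[stage](cfg, outdir, state)
        except Exception as exc:
            _write_manifest(outdir, manifest)
            raise StageFailure(stage, exc) from exc
        wall = time.perf_counter() - t0
        manifest["stages"].append(
            {"name": stage, "wall_time_s": round(wall, 3),
             "outputs": outputs})
        log.info("stage %s done in %.2fs", stage, wall)
    _write_manifest(outdir, manifest)
    return outdir


def _write_manifest(outdir: Path, manifest: dict) -> None:
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8")


def _stage_simulate(cfg, outdir, state):
    sim = cfg.simulate
    spec = _model_spec(cfg)
    if not sim.enabled:
        state["clusters"] = read_clusters(cfg.clusters_path)
        state["design"] = read_strata(cfg.strata_path)
        state["grid_cells"] = (read_grid(cfg.grid_path)
                               if cfg.grid_path else None)
        return []
    grid = make_domain(sim.extent_km, sim.resolution_km, cfg.seed)
    design, clusters = sample_clusters(
        grid, sim.n_strata, sim.clusters_per_stratum,
        sim.persons_per_cluster_mean, cfg.seed)
    coords = clusters[["x_km", "y_km"]].to_numpy(dtype=float)
    field = simulate_field(coords, sim.sigma2, sim.phi, cfg.seed)
    truth = TrueModel(spec, np.asarray(sim.beta), sim.sigma2, sim.phi,
                      sim.tau2)
    clusters = simulate_counts(clusters, truth, field, cfg.seed)
    if spec.response == "y_bites" and "y_envenoming" not in clusters:
        # envenomings are a thinned subset of bites for schema completeness
        rng = np.random.default_rng(cfg.seed + 17)
        clusters["y_envenoming"] = rng.binomial(clusters["y_bites"], 0.45)
    elif spec.response == "y_envenoming" and "y_bites" not in clusters:
        clusters["y_bites"] = clusters["y_envenoming"]
    write_grid(grid, outdir / "grid.csv")
    write_strata(design, outdir / "strata.csv")
    write_clusters(clusters, outdir / "clusters.csv")
    state.update(clusters=clusters, design=design, grid_cells=grid.cells)
    return ["grid.csv", "strata.csv", "clusters.csv"]


def _stage_survey(cfg, outdir, state):
    spec = _model_spec(cfg)
    table = survey_table(state["clusters"], state["design"],
                         response=spec.response)
    table.to_csv(outdir / "survey_table.csv", index=False)
    state["survey_table"] = table
    return ["survey_table.csv"]


def _stage_explore(cfg, outdir, state):
    spec = _model_spec(cfg)
    clusters = state["clusters"]
    outputs = []
    if cfg.model.scan_breakpoints:
        from .covariates import HingeTerm, LinearTerm
        base = spec.with_terms(
            [t for t in spec.terms if not isinstance(t, HingeTerm)])
        elev = clusters["elevation"]
        step = cfg.model.elevation_scan_step
        knots = np.arange(np.ceil(elev.min() / step) * step,
                          elev.max(), step)
        if len(knots) >= 1:
            pw = select_breakpoint(clusters, base, "elevation", knots)
            pw.profile.to_csv(outdir / "breakpoint_profile_elevation.csv",
                              index=False)
            outputs.append("breakpoint_profile_elevation.csv")
            spec = spec.with_terms([
                HingeTerm("elevation", pw.knot)
                if (isinstance(t, HingeTerm) and t.variable == "elevation")
                else t for t in spec.terms])
    glm = fit_glm(clusters, spec)
    glm.summary_frame().to_csv(outdir / "glm_coefficients.csv")
    resid = standardized_residuals(clusters, glm)
    resid.to_csv(outdir / "residuals.csv", index=False)
    coords = clusters[["x_km", "y_km"]].to_numpy(dtype=float)
    max_d = np.sqrt(((coords.max(0) - coords.min(0)) ** 2).sum())
    vg = empirical_variogram(resid["residual"].to_numpy(), coords,
                             np.linspace(0, max_d / 2, 11))
    vg.to_csv(outdir / "variogram.csv", index=False)
    state["glm"] = glm
    state["spec"] = spec
    return outputs + ["glm_coefficients.csv", "residuals.csv",
                      "variogram.csv"]


def _stage_fit(cfg, outdir, state):
    spec = state["spec"]
    clusters = state["clusters"]
    settings = MCSettings(n_burn=cfg.mc.n_burn, thin=cfg.mc.thin,
                          n_keep=cfg.mc.n_keep,
                          max_reanchor=cfg.mc.max_reanchor,
                          rel_tol=cfg.mc.rel_tol)
    init = initial_params(clusters, spec)
    fit = fit_mcml(clusters, spec, init, settings, seed=cfg.seed)
    fit.summary_frame().to_csv(outdir / "fit_table.csv")
    p = fit.params
    (outdir / "fit.json").write_text(json.dumps({
        "beta": p.beta.tolist(), "sigma2": p.sigma2, "phi": p.phi,
        "tau2": p.tau2, "loglik_ratio": fit.loglik_ratio,
        "std_errors": [None if not np.isfinite(s) else s
                       for s in fit.std_errors],
        "param_names": fit.param_names,
        "diagnostics": {k: (v if np.isfinite(v) else None)
                        if isinstance(v, float) else v
                        for k, v in fit.diagnostics.items()},
    }, indent=2), encoding="utf-8")
    np.savez_compressed(outdir / "latent_draws.npz",
                        draws=fit.samples.draws, coords=fit.samples.coords)
    (outdir / "latent_draws.json").write_text(json.dumps({
        "n_draws": int(fit.samples.draws.shape[0]),
        "n_locations": int(fit.samples.draws.shape[1]),
        "n_burn": fit.samples.n_burn, "thin": fit.samples.thin,
        "acceptance_rate": fit.samples.acceptance_rate,
    }, indent=2), encoding="utf-8")
    state["fit"] = fit
    return ["fit_table.csv", "fit.json", "latent_draws.npz",
            "latent_draws.json"]


def _stage_predict(cfg, outdir, state):
    fit = state["fit"]
    grid_cells = state.get("grid_cells")
    if grid_cells is None:
        raise ValueError("no prediction grid available")
    s_draws = krige_conditional(
        fit.params, fit.samples,
        grid_cells[["x_km", "y_km"]].to_numpy(dtype=float),
        seed=cfg.seed + 7)
    surface, inc_draws = incidence_surface(fit, grid_cells, s_draws)
    surface.to_csv(outdir / "incidence_surface.csv", index=False)
    state["s_draws"] = s_draws
    state["surface"] = surface
    return ["incidence_surface.csv"]


def _stage_map(cfg, outdir, state):
    fit = state["fit"]
    grid_cells = state["grid_cells"]
    maps, summary = threshold_suite(fit, grid_cells, state["s_draws"],
                                    cfg.thresholds)
    wide = grid_cells[["x_km", "y_km"]].copy()
    for pcm in maps:
        tag = f"{pcm.threshold:g}"
        wide[f"p_{tag}"] = pcm.probability
        wide[f"class_{tag}"] = pcm.classes
    wide.insert(2, "estimate", state["surface"]["estimate"].to_numpy())
    wide.to_csv(outdir / "exceedance_maps.csv", index=False)
    summary.to_csv(outdir / "map_summary.csv", index=False)
    return ["exceedance_maps.csv", "map_summary.csv"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "survey": _stage_survey,
    "explore": _stage_explore,
    "fit": _stage_fit,
    "predict": _stage_predict,
    "map": _stage_map,
}
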