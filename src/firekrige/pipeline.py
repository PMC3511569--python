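"""End-to-end plot analysis: simulate or ingest, metrics, kriging, selection.

A run is described by one YAML config (validated with pydantic before any
computation starts; every stochastic stage has an explicit seed).  Outputs
per plot: the observation table, per-core community metrics and their
plot-level summary, the posterior spatial-model summary, the kriged surface,
leave-one-out diagnostics and (when candidates are available) the stepwise
selection table.  A manifest records the config (defaults echoed), its hash,
seeds and per-stage row counts so a rerun with the same config reproduces
the outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, model_validator

from . import datasets, io
from .kriging import BayesianKriging, loo_cross_validate
from .plfa import community_metrics, filter_cores, summarize_metrics
from .stepwise import StepwiseAIC
from .synthetic import SimulationTruth, generate_design, simulate_field, simulate_lipid_table

__all__ = ["RunConfig", "PlotConfig", "load_config", "run_pipeline", "demo_config"]

log = logging.getLogger("firekrige.pipeline")


class DesignConfig(BaseModel):
    spacings: tuple[float, ...] = (2, 2, 4, 4, 8, 8, 4, 2)
    n_rows: int = 9
    row_spacing: float = 2.0
    plot_size: float = 50.0
    reverse_middle: bool = True


class TruthConfig(BaseModel):
    beta: tuple[float, float, float] = (20.0, 0.1, -0.1)
    sigma2: float = Field(1.0, gt=0)
    phi: float = Field(2.0, gt=0)
    tau2_rel: float = Field(0.7, ge=0)


class SimulateConfig(BaseModel):
    truth: TruthConfig = TruthConfig()
    profile_plot: str = "glade_crown"
    total_mean: float = Field(300.0, gt=0)
    total_sd: float = Field(120.0, ge=0)
    n_missing_16_0: int = Field(0, ge=0)


class InputConfig(BaseModel):
    observations: str
    lipids: str | None = None
    value_col: str = "value"


class KrigeConfig(BaseModel):
    n_phi: int = Field(100, ge=2)
    n_tau: int = Field(100, ge=2)
    phi_bounds: tuple[float, float] | None = None
    tau2rel_max: float = Field(4.0, gt=0)
    n_draws: int = Field(100_000, ge=1)
    trend: str = "linear"
    surface_spacing: float = Field(0.5, gt=0)
    run_loo: bool = True
    loo_grid: int = Field(25, ge=2)


class PlotConfig(BaseModel):
    name: str
    design: DesignConfig = DesignConfig()
    simulate: SimulateConfig | None = None
    inputs: InputConfig | None = None

    @model_validator(mode="after")
    def _one_source(self):
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError(f"plot {self.name!r}: give exactly one of simulate/inputs")
        return self


class RunConfig(BaseModel):
    plots: list[PlotConfig]
    krige: KrigeConfig = KrigeConfig()
    seed: int = 0
    run_selection: bool = True
    output_dir: str = "firekrige_out"

    def canonical_json(self) -> str:
        return json.dumps(self.model_dump(mode="json"), sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig.model_validate(raw)


def demo_config(output_dir, seed: int = 0) -> RunConfig:
    """Small self-contained run: one simulated plot, reduced grids."""
    return RunConfig(
        plots=[PlotConfig(name="demo_plot", simulate=SimulateConfig())],
        krige=KrigeConfig(n_phi=20, n_tau=20, n_draws=5000, surface_spacing=2.0,
                          run_loo=False),
        seed=seed,
        output_dir=str(output_dir),
    )


def _stage(report: dict, plot: str, stage: str, t0: float, **counts) -> None:
    entry = {"stage": stage, "seconds": round(time.perf_counter() - t0, 3), **counts}
    report.setdefault(plot, []).append(entry)
    log.info("%s/%s: %s", plot, stage, entry)


def _simulate_plot(pc: PlotConfig, seed: int, outdir: Path, stages: dict):
    t0 = time.perf_counter()
    design = generate_design(**pc.design.model_dump())
    sim = pc.simulate
    truth = SimulationTruth(**sim.truth.model_dump())
    obs = simulate_field(design, truth, seed=seed)
    profiles = datasets.load_lipid_profiles()
    if sim.profile_plot not in profiles.columns:
        raise ValueError(f"unknown profile plot {sim.profile_plot!r}")
    profile = profiles[sim.profile_plot].dropna()
    profile = 100.0 * profile / profile.sum()
    lipids = simulate_lipid_table(
        design, profile, total_mean=sim.total_mean, total_sd=sim.total_sd,
        n_missing_16_0=sim.n_missing_16_0, seed=seed + 1,
    )
    io.write_observations(obs, outdir / "observations.csv")
    io.write_lipids(lipids, outdir / "lipids.csv")
    _stage(stages, pc.name, "simulate", t0, n_cores=design.n_points,
           n_lipids=len(profile))
    return obs, lipids


def _ingest_plot(pc: PlotConfig, stages: dict):
    t0 = time.perf_counter()
    obs = io.read_observations(
        pc.inputs.observations, value_col=pc.inputs.value_col,
        plot_size=pc.design.plot_size,
    )
    lipids = io.read_lipids(pc.inputs.lipids) if pc.inputs.lipids else None
    _stage(stages, pc.name, "ingest", t0, n_obs=obs.n,
           n_lipid_rows=0 if lipids is None else len(lipids))
    return obs, lipids


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage for every configured plot; returns the manifest dict
    (also written to ``output_dir/manifest.json``)."""
    outroot = Path(config.output_dir)
    outroot.mkdir(parents=True, exist_ok=True)
    stages: dict = {}
    for k, pc in enumerate(config.plots):
        outdir = outroot / pc.name
        outdir.mkdir(parents=True, exist_ok=True)
        seed = config.seed + 1000 * k

        try:
            if pc.simulate is not None:
                obs, lipids = _simulate_plot(pc, seed, outdir, stages)
            else:
                obs, lipids = _ingest_plot(pc, stages)

            metrics = None
            if lipids is not None:
                t0 = time.perf_counter()
                filtered, rep = filter_cores(lipids)
                metrics = community_metrics(filtered, filtered=True)
                metrics.to_csv(outdir / "metrics.csv", index=False)
                summarize_metrics(metrics).to_csv(outdir / "metrics_summary.csv")
                with open(outdir / "filter_report.json", "w") as fh:
                    json.dump(rep, fh, indent=2)
                _stage(stages, pc.name, "metrics", t0, n_retained=len(metrics),
                       n_removed=rep["n_removed"])

            t0 = time.perf_counter()
            kc = config.krige
            model = BayesianKriging(
                n_phi=kc.n_phi, n_tau=kc.n_tau, phi_bounds=kc.phi_bounds,
                tau2rel_max=kc.tau2rel_max, trend=kc.trend, n_draws=kc.n_draws,
                random_state=seed + 1,
            ).fit(obs.coords, obs.y)
            model.summary_.to_csv(outdir / "posterior_summary.csv")
            surface = model.predict_surface(spacing=kc.surface_spacing)
            io.write_surface(surface, outdir / "surface.csv")
            _stage(stages, pc.name, "krige", t0, n_obs=obs.n,
                   n_draws=model.draws_.n_draws, n_surface=len(surface))

            if kc.run_loo:
                t0 = time.perf_counter()
                cv, adj_r2 = loo_cross_validate(
                    obs, n_phi=kc.loo_grid, n_tau=kc.loo_grid, seed=seed + 2
                )
                cv.to_csv(outdir / "cv.csv", index=False)
                (outdir / "cv_r2.txt").write_text(f"{adj_r2:.6f}\n")
                _stage(stages, pc.name, "loo", t0, adj_r2=round(adj_r2, 4))

            if config.run_selection and metrics is not None:
                t0 = time.perf_counter()
                cand = metrics[["abundance_nmol", "fb_ratio", "gm_pos", "gm_neg"]]
                # responses and metrics share cores only in simulation mode
                if len(cand) == obs.n:
                    sel = StepwiseAIC().fit(cand, obs.y)
                    table = sel.results_.copy()
                    table["aic"] = sel.aic_
                    table["adj_r2"] = sel.adj_r2_
                    table.to_csv(outdir / "selection.csv")
                    _stage(stages, pc.name, "select", t0,
                           n_terms=len(sel.selected_), aic=round(sel.aic_, 2))
                else:
                    log.info("%s: selection skipped (metrics/obs core mismatch)", pc.name)
        except Exception as err:
            raise RuntimeError(f"pipeline failed at plot {pc.name!r}: {err}") from err

    manifest = {
        "config": json.loads(config.canonical_json()),
        "config_hash": config.config_hash,
        "seed": config.seed,
        "stages": stages,
    }
    with open(outroot / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
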