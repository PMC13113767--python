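"""Configuration-driven orchestration: simulate → render → correlate → fit.

A run is described by a :class:`RunConfig` (loadable from a flat YAML file
with namespaced keys, e.g. ``simulation.D_out`` / ``analysis.k2_max`` /
``io.output_dir``).  ``run_full`` writes the six canonical artifacts of one
analysis — the TIFF stack, the CF table, the per-τ fit table, the confinement
parameter record, the partition (β) statistics and a provenance record — into
an output directory, all stamped with the seed and a config hash so a run can
be reproduced bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .correlation import DEFAULT_MAX_TAU, KICSCorrelation, compute_kics_cf, normalize_cf
from .fitting import (
    ConfinementParameters,
    TwoComponentFit,
    extract_parameters,
    fit_two_component,
)
from .imaging import (
    DEFAULT_PSF_RADIUS,
    ImageSeries,
    add_background_noise,
    crop_center,
    read_tiff,
    render_series,
    write_tiff,
)
from .sim import (
    DomainField,
    PartitionStats,
    SimulationConfig,
    TrajectorySet,
    partition_coefficient,
    simulate,
)

__all__ = [
    "ConfigError",
    "AnalysisConfig",
    "RunConfig",
    "PipelineResult",
    "run_pipeline",
    "analyze_images",
    "run_full",
    "run_sweep",
    "make_fixtures",
    "sweep_seeds",
]

logger = logging.getLogger("ckics")

MODES = ("simulate", "render", "analyze", "full", "sweep", "fixtures")

ARTIFACTS = (
    "images.tif",
    "cf.csv",
    "fits.csv",
    "parameters.json",
    "beta.json",
    "provenance.json",
)


class ConfigError(ValueError):
    """A run configuration is malformed; the message names the field."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis-side knobs of a run."""

    psf_radius: float = DEFAULT_PSF_RADIUS  # μm, e⁻² radius
    peak_intensity: float = 1.0
    noise_param: float = 0.0  # background noise σ as a fraction of I0
    crop_px: int | None = None  # None → central crop with ~7.3% margin a side
    k2_min: float = 0.0  # μm⁻²
    k2_max: float | None = None  # μm⁻²; None → adaptive bound (≤ 200)
    max_tau: int = DEFAULT_MAX_TAU  # frames
    subtract_mean: bool = True
    early_window: tuple[int, int] | None = None
    late_window: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.noise_param < 0:
            raise ConfigError("analysis.noise_param must be non-negative")
        if self.k2_max is not None and self.k2_max <= self.k2_min:
            raise ConfigError("analysis.k2_max must exceed analysis.k2_min")
        if self.max_tau < 2:
            raise ConfigError("analysis.max_tau must be >= 2")

    def resolve_crop(self, region_px: int) -> int:
        if self.crop_px is not None:
            if self.crop_px > region_px:
                raise ConfigError(
                    f"analysis.crop_px ({self.crop_px}) exceeds region_px ({region_px})"
                )
            return self.crop_px
        margin = max(4, int(round(0.0733 * region_px)))
        return region_px - 2 * margin


@dataclass(frozen=True)
class RunConfig:
    """One orchestrated run: mode, simulation, analysis and I/O settings."""

    mode: str = "full"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    input_path: str | None = None  # TIFF stack for analyze mode
    output_dir: str = "ckics_out"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.mode == "analyze" and not self.input_path:
            raise ConfigError("analyze mode requires io.input_path")

    @property
    def seed(self) -> int:
        return self.simulation.seed

    def to_flat_dict(self) -> dict:
        d: dict = {"mode": self.mode, "log_level": self.log_level}
        for k, v in dataclasses.asdict(self.simulation).items():
            d[f"simulation.{k}"] = v
        for k, v in dataclasses.asdict(self.analysis).items():
            d[f"analysis.{k}"] = list(v) if isinstance(v, tuple) else v
        d["io.input_path"] = self.input_path
        d["io.output_dir"] = self.output_dir
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_flat_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_flat_dict(cls, flat: dict) -> "RunConfig":
        sim_fields = {f.name for f in dataclasses.fields(SimulationConfig)}
        ana_fields = {f.name for f in dataclasses.fields(AnalysisConfig)}
        sim_kwargs, ana_kwargs, top = {}, {}, {}
        for key, value in flat.items():
            if key.startswith("simulation."):
                name = key.split(".", 1)[1]
                if name not in sim_fields:
                    raise ConfigError(f"unknown config key: {key!r}")
                sim_kwargs[name] = value
            elif key.startswith("analysis."):
                name = key.split(".", 1)[1]
                if name not in ana_fields:
                    raise ConfigError(f"unknown config key: {key!r}")
                if name in ("early_window", "late_window") and value is not None:
                    value = tuple(value)
                ana_kwargs[name] = value
            elif key == "io.input_path":
                top["input_path"] = value
            elif key == "io.output_dir":
                top["output_dir"] = value
            elif key in ("mode", "log_level"):
                top[key] = value
            else:
                raise ConfigError(f"unknown config key: {key!r}")
        try:
            sim = SimulationConfig(**sim_kwargs)
            ana = AnalysisConfig(**ana_kwargs)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc
        return cls(simulation=sim, analysis=ana, **top)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            flat = yaml.safe_load(fh) or {}
        if not isinstance(flat, dict):
            raise ConfigError(f"{path}: expected a flat key-value mapping")
        return cls.from_flat_dict(flat)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_flat_dict(), fh, sort_keys=True)


@dataclass
class PipelineResult:
    """In-memory results of a full (or partial) pipeline run."""

    config: RunConfig
    trajectories: TrajectorySet | None = None
    domains: DomainField | None = None
    images: ImageSeries | None = None
    cf: KICSCorrelation | None = None
    fit: TwoComponentFit | None = None
    parameters: ConfinementParameters | None = None
    partition: PartitionStats | None = None


def render_images(
    traj: TrajectorySet, config: RunConfig, noise_seed: int
) -> ImageSeries:
    """Render, add background noise and crop per the analysis settings."""
    ana = config.analysis
    series = render_series(
        traj,
        psf_radius=ana.psf_radius,
        pixel_size=config.simulation.pixel_size,
        peak_intensity=ana.peak_intensity,
    )
    if ana.noise_param > 0:
        series = add_background_noise(series, ana.noise_param, noise_seed)
    crop = ana.resolve_crop(series.frame_shape[0])
    if crop < series.frame_shape[0]:
        series = crop_center(series, crop)
    return series


def analyze_images(series: ImageSeries, config: RunConfig) -> tuple[
    KICSCorrelation, TwoComponentFit, ConfinementParameters
]:
    """Correlation + two-component fit + parameter extraction on an image stack."""
    ana = config.analysis
    cf = compute_kics_cf(
        series,
        max_tau=min(ana.max_tau, series.n_frames - 1),
        subtract_mean=ana.subtract_mean,
    )
    ncf = normalize_cf(cf)
    # k2_max=None defers to the fitter's adaptive (data-driven) upper bound
    k2_range = None if ana.k2_max is None else (ana.k2_min, ana.k2_max)
    fit = fit_two_component(ncf, k2_range=k2_range)
    params = extract_parameters(fit, ana.early_window, ana.late_window)
    return ncf, fit, params


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Simulate, render and analyze one run entirely in memory."""
    t0 = time.perf_counter()
    traj, domains = simulate(config.simulation)
    logger.info("stage=simulate seed=%d wall=%.1fs", config.seed, time.perf_counter() - t0)
    stats = partition_coefficient(traj, domains)

    t0 = time.perf_counter()
    series = render_images(traj, config, noise_seed=config.seed + 1)
    logger.info("stage=render seed=%d wall=%.1fs", config.seed, time.perf_counter() - t0)

    t0 = time.perf_counter()
    cf, fit, params = analyze_images(series, config)
    logger.info("stage=analyze seed=%d wall=%.1fs", config.seed, time.perf_counter() - t0)

    return PipelineResult(
        config=config,
        trajectories=traj,
        domains=domains,
        images=series,
        cf=cf,
        fit=fit,
        parameters=params,
        partition=stats,
    )


def _provenance(config: RunConfig) -> dict:
    return {
        "package": "ckics",
        "version": __version__,
        "numpy": np.__version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_flat_dict(),
    }


def run_full(config: RunConfig, plots: bool = False) -> Path:
    """Full pipeline with artifacts written to ``config.output_dir``.

    Writes exactly: images.tif, cf.csv, fits.csv, parameters.json, beta.json,
    provenance.json (plus optional PNG figures with ``plots=True``).  In
    ``analyze`` mode the stack is read from ``input_path`` instead of
    simulated (beta statistics are then empty).
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.mode == "analyze":
        series = read_tiff(
            config.input_path,
            pixel_size=config.simulation.pixel_size,
            frame_time=config.simulation.resolved_frame_time(),
            psf_radius=config.analysis.psf_radius,
        )
        cf, fit, params = analyze_images(series, config)
        result = PipelineResult(
            config=config, images=series, cf=cf, fit=fit, parameters=params
        )
    else:
        result = run_pipeline(config)

    write_tiff(result.images, outdir / "images.tif")
    result.cf.to_frame().to_csv(outdir / "cf.csv", index=False)
    result.fit.to_frame().to_csv(outdir / "fits.csv", index=False)

    params_record = {"seed": config.seed, "config_hash": config.config_hash()}
    params_record.update(result.parameters.to_dict())
    (outdir / "parameters.json").write_text(json.dumps(params_record, indent=2))

    if result.partition is not None:
        beta_record = {
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "beta_mean": result.partition.beta_mean,
            "n_domains": result.partition.n_domains,
            "mean_occupancy": result.partition.mean_occupancy,
        }
    else:
        beta_record = {"seed": config.seed, "config_hash": config.config_hash()}
    (outdir / "beta.json").write_text(json.dumps(beta_record, indent=2))
    (outdir / "provenance.json").write_text(json.dumps(_provenance(config), indent=2))
    if plots:
        make_plots(result, outdir)
    return outdir


def make_plots(result: PipelineResult, outdir: str | Path) -> list[Path]:
    """Optional diagnostic figures: CF heat map and exponent/amplitude trends.

    Numeric tables are the contract; these are visual aids only.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    cf = result.cf
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.pcolormesh(
        cf.k2_grid, cf.tau_grid, cf.values, shading="nearest", cmap="viridis"
    )
    ax.set_xlabel("k² (μm⁻²)")
    ax.set_ylabel("τ (s)")
    ax.set_title("normalized kICS correlation" if cf.normalized else "kICS correlation")
    fig.colorbar(im, ax=ax)
    path = outdir / "cf_heatmap.png"
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(path)

    fit = result.fit
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    ok = fit.converged
    axes[0].plot(fit.tau[ok], fit.g_M[ok], "o-", ms=3, label="g_M")
    axes[0].plot(fit.tau[ok], fit.g_mu[ok], "s-", ms=3, label="g_μ")
    axes[0].set_xlabel("τ (s)")
    axes[0].set_ylabel("exponent (μm²)")
    axes[0].legend()
    axes[1].plot(fit.tau[ok], fit.A_M[ok], "o-", ms=3, label="A_M")
    axes[1].plot(fit.tau[ok], fit.A_mu[ok], "s-", ms=3, label="A_μ")
    axes[1].set_xlabel("τ (s)")
    axes[1].set_ylabel("amplitude")
    axes[1].legend()
    fig.tight_layout()
    path = outdir / "fit_trends.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)
    return written


def sweep_seeds(base_seed: int, n: int) -> list[int]:
    """Deterministic, collision-free child seeds below 2³¹ for sweep runs."""
    state = np.random.SeedSequence(base_seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


def run_sweep(
    base_config: RunConfig,
    parameter: str,
    values: list,
    replicates: int = 1,
    link_p_out: bool = False,
    output_csv: str | Path | None = None,
) -> pd.DataFrame:
    """One full pipeline run per (value, replicate) of a simulation parameter.

    ``link_p_out=True`` ties P_out = 1 − P_in while sweeping P_in (the
    partition-probability scenario).  Per-run failures are recorded in the
    ``error`` column and skipped; the sweep fails only if every run fails.
    """
    if not values:
        raise ConfigError("sweep requires a non-empty list of values")
    sim_fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    if parameter not in sim_fields:
        raise ConfigError(f"{parameter!r} is not a SimulationConfig field")
    seeds = sweep_seeds(base_config.seed, len(values) * replicates)

    rows = []
    idx = 0
    for value in values:
        for rep in range(replicates):
            changes = {parameter: value, "seed": seeds[idx]}
            if link_p_out and parameter == "P_in":
                changes["P_out"] = 1.0 - value
            sim = base_config.simulation.replace(**changes)
            cfg = dataclasses.replace(base_config, simulation=sim)
            idx += 1
            row = {parameter: value, "replicate": rep, "seed": sim.seed}
            try:
                res = run_pipeline(cfg)
            except Exception as exc:  # noqa: BLE001 - per-run isolation
                logger.warning("sweep run %s=%s rep=%d failed: %s", parameter, value, rep, exc)
                row["error"] = str(exc)
                rows.append(row)
                continue
            p = res.parameters
            row.update(
                D_M=p.D_M,
                D_mu=p.D_mu,
                plateau_mu=p.plateau_mu,
                sat_A_M=p.sat_A_M,
                sat_A_mu=p.sat_A_mu,
                effective_radius=p.effective_radius,
                beta_mean=res.partition.beta_mean,
                n_domains=res.partition.n_domains,
                error="",
            )
            rows.append(row)

    df = pd.DataFrame(rows)
    ok = df["error"] == "" if "error" in df else pd.Series(True, index=df.index)
    if not ok.any():
        raise RuntimeError("all sweep runs failed")
    if output_csv is not None:
        df.to_csv(output_csv, index=False)
    return df


TINY_SCALE = {"region_px": 128, "n_frames": 500, "burn_in_frames": 100, "particle_density": 2.0}


def make_fixtures(output_dir: str | Path, scale: str = "tiny", base_seed: int = 1234) -> dict:
    """Write the three reference scenarios with ground-truth sidecars.

    ``tiny`` shrinks the region/frames/density for continuous-integration
    budgets; ``paper`` uses the full default scale.  Scenarios: free
    diffusion, a 50/50 two-free-species mixture, and the default confined
    run.  Each gets a TIFF stack plus a JSON sidecar with the generating
    parameters (and β for the confined case).
    """
    if scale not in ("tiny", "paper"):
        raise ConfigError("scale must be 'tiny' or 'paper'")
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    overrides = TINY_SCALE if scale == "tiny" else {}
    written: dict[str, Path] = {}

    def _write(name: str, series: ImageSeries, truth: dict) -> None:
        tiff = outdir / f"{name}.tif"
        write_tiff(series, tiff)
        sidecar = dict(truth)
        sidecar.update(
            pixel_size=series.pixel_size,
            frame_time=series.frame_time,
            psf_radius=series.psf_radius,
            n_frames=series.n_frames,
        )
        (outdir / f"{name}.json").write_text(json.dumps(sidecar, indent=2))
        written[name] = tiff

    ana = AnalysisConfig()

    # free diffusion at the outside-domain default
    free_sim = SimulationConfig(
        area_fraction=0.0, frame_time=0.1, seed=base_seed, **overrides
    )
    cfg = RunConfig(simulation=free_sim, analysis=ana)
    traj, _ = simulate(free_sim)
    series = render_images(traj, cfg, noise_seed=base_seed + 1)
    _write("free_diffusion", series, {"D": free_sim.D_out, "seed": base_seed})

    # 50/50 mixture of two free species (rendering is linear, so sum stacks)
    fast = free_sim.replace(D_out=0.05, seed=base_seed + 10)
    slow = free_sim.replace(D_out=0.005, seed=base_seed + 11)
    t_fast, _ = simulate(fast)
    t_slow, _ = simulate(slow)
    s_fast = render_images(t_fast, dataclasses.replace(cfg, simulation=fast), base_seed + 12)
    s_slow = render_images(t_slow, dataclasses.replace(cfg, simulation=slow), base_seed + 13)
    mix = dataclasses.replace(s_fast, frames=s_fast.frames + s_slow.frames)
    _write(
        "two_species",
        mix,
        {"D1": fast.D_out, "D2": slow.D_out, "N1_frac": 0.5, "seed": base_seed + 10},
    )

    # default confined scenario
    conf_sim = SimulationConfig(seed=base_seed + 20, **overrides)
    cfg = RunConfig(simulation=conf_sim, analysis=ana)
    traj, domains = simulate(conf_sim)
    stats = partition_coefficient(traj, domains)
    series = render_images(traj, cfg, noise_seed=base_seed + 21)
    _write(
        "confined_default",
        series,
        {
            "D_in": conf_sim.D_in,
            "D_out": conf_sim.D_out,
            "P_in": conf_sim.P_in,
            "P_out": conf_sim.P_out,
            "domain_radius": conf_sim.domain_radius,
            "area_fraction": conf_sim.area_fraction,
            "beta_mean": stats.beta_mean,
            "seed": conf_sim.seed,
        },
    )
    return written
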