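"""Brownian dynamics of membrane particles partitioning into static circular domains.

The simulated system is a 2D membrane patch populated by point particles that
diffuse freely outside circular microdomains (diffusion coefficient ``D_out``)
and more slowly inside them (``D_in``).  A particle whose displacement would
carry it across a domain boundary enters with probability ``P_in`` (from
outside) or escapes with probability ``P_out`` (from inside); otherwise the
crossing is refused and resolved by the configured boundary policy.  Domains
are static, non-overlapping disks; boundaries of the patch are periodic so the
particle number is conserved.

All lengths are in micrometres, times in seconds, diffusion coefficients in
μm²/s.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "PackingError",
    "SimulationConfig",
    "DomainField",
    "TrajectorySet",
    "PartitionStats",
    "place_domains",
    "auto_frame_time",
    "init_particles",
    "step_particles",
    "simulate",
    "partition_coefficient",
    "effective_diffusion",
    "ensemble_msd",
    "estimate_diffusion_from_msd",
]


class PackingError(RuntimeError):
    """Requested domain coverage cannot be packed under the 2r-separation rule."""


@dataclass(frozen=True)
class SimulationConfig:
    """Physical and numerical parameters of one confined-diffusion run.

    ``frame_time`` may be the string ``"auto"``, in which case it is derived
    from the domain radius and ``D_in`` so that a particle diffusing at
    ``D_in`` traverses about a fifth of the domain radius per frame
    (RMS one-axis step of radius/5).
    """

    region_px: int = 300
    pixel_size: float = 0.1
    n_frames: int = 2200
    burn_in_frames: int = 200
    frame_time: float | str = "auto"
    D_in: float = 0.001
    D_out: float = 0.01
    P_in: float = 0.5
    P_out: float = 0.1
    domain_radius: float = 0.2
    area_fraction: float = 0.05
    particle_density: float = 5.0
    substeps_per_frame: int = 1
    boundary_policy: str = "reject_step"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.region_px <= 0:
            raise ValueError("region_px must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not 0.0 <= self.P_in <= 1.0:
            raise ValueError(f"P_in must be in [0, 1], got {self.P_in}")
        if not 0.0 <= self.P_out <= 1.0:
            raise ValueError(f"P_out must be in [0, 1], got {self.P_out}")
        if self.D_in < 0 or self.D_out < 0:
            raise ValueError("diffusion coefficients must be non-negative")
        if not 0.0 <= self.area_fraction < 1.0:
            raise ValueError("area_fraction must be in [0, 1)")
        if self.burn_in_frames < 0 or self.burn_in_frames >= self.n_frames:
            raise ValueError("burn_in_frames must satisfy 0 <= burn_in < n_frames")
        if self.domain_radius <= 0:
            raise ValueError("domain_radius must be positive")
        if self.particle_density < 0:
            raise ValueError("particle_density must be non-negative")
        if self.substeps_per_frame < 1:
            raise ValueError("substeps_per_frame must be >= 1")
        if self.boundary_policy not in ("reject_step", "reflect"):
            raise ValueError("boundary_policy must be 'reject_step' or 'reflect'")
        if isinstance(self.frame_time, str):
            if self.frame_time != "auto":
                raise ValueError("frame_time must be a positive number or 'auto'")
            if self.D_in <= 0:
                raise ValueError("frame_time='auto' requires D_in > 0")
        elif self.frame_time <= 0:
            raise ValueError("frame_time must be positive")

    @property
    def region_extent(self) -> tuple[float, float]:
        side = self.region_px * self.pixel_size
        return (side, side)

    def resolved_frame_time(self) -> float:
        if self.frame_time == "auto":
            return auto_frame_time(self.domain_radius, self.D_in)
        return float(self.frame_time)

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)


def auto_frame_time(domain_radius: float, D_in: float) -> float:
    """Frame time (s) matched to the domain size: (radius/5)² / (4·D_in)."""
    if D_in <= 0:
        raise ValueError("auto frame time requires D_in > 0")
    return (domain_radius / 5.0) ** 2 / (4.0 * D_in)


@dataclass
class DomainField:
    """Static, non-overlapping circular domains inside a rectangular region."""

    centers: np.ndarray  # (n, 2) μm
    radius: float  # μm
    region_extent: tuple[float, float]  # μm
    achieved_fraction: float

    _tree: cKDTree | None = field(default=None, repr=False, compare=False)

    @property
    def n_domains(self) -> int:
        return len(self.centers)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask: is each (x, y) point strictly inside any domain?"""
        points = np.atleast_2d(points)
        if self.n_domains == 0:
            return np.zeros(len(points), dtype=bool)
        if self._tree is None:
            self._tree = cKDTree(self.centers)
        dist, _ = self._tree.query(points, k=1)
        return dist < self.radius

    def nearest_center(self, points: np.ndarray) -> np.ndarray:
        if self._tree is None:
            self._tree = cKDTree(self.centers)
        _, idx = self._tree.query(np.atleast_2d(points), k=1)
        return self.centers[idx]


def place_domains(
    region_extent: tuple[float, float],
    radius: float,
    area_fraction: float,
    seed: int | np.random.Generator,
    max_attempts: int = 10_000,
) -> DomainField:
    """Scatter domain centers uniformly with centers at least 2·radius apart.

    The number of domains is round(area_fraction · region_area / (π·radius²)).
    Centers are sampled so each disk lies entirely within the region (no
    overhang across the periodic boundary).  Placement is bounded rejection
    sampling; an over-dense request that cannot be packed within
    ``max_attempts`` tries per domain raises PackingError.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    width, height = region_extent
    area = width * height
    n = int(round(area_fraction * area / (math.pi * radius**2)))
    if n > 0 and (width < 2 * radius or height < 2 * radius):
        raise PackingError(
            f"domain radius {radius} μm does not fit in region {region_extent}"
        )
    centers: list[np.ndarray] = []
    min_sep2 = (2.0 * radius) ** 2
    for _ in range(n):
        for attempt in range(max_attempts):
            cand = rng.uniform([radius, radius], [width - radius, height - radius])
            if not centers:
                centers.append(cand)
                break
            d2 = np.sum((np.asarray(centers) - cand) ** 2, axis=1)
            if np.all(d2 >= min_sep2):
                centers.append(cand)
                break
        else:
            raise PackingError(
                f"could not place domain {len(centers) + 1}/{n} "
                f"(radius {radius} μm, fraction {area_fraction}) within "
                f"{max_attempts} attempts"
            )
    centers_arr = np.asarray(centers, dtype=float).reshape(n, 2)
    achieved = n * math.pi * radius**2 / area
    return DomainField(centers_arr, radius, (width, height), achieved)


def init_particles(
    density: float,
    region_extent: tuple[float, float],
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Uniform initial positions; n = round(density × area)."""
    if density < 0:
        raise ValueError("particle density must be non-negative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    width, height = region_extent
    n = int(round(density * width * height))
    return rng.uniform([0.0, 0.0], [width, height], size=(n, 2))


@dataclass
class TrajectorySet:
    """Ground-truth particle paths over the retained frames.

    ``positions`` holds periodically wrapped coordinates, shape
    (n_frames, n_particles, 2); ``inside_flags`` the per-frame geometric
    membership of each particle in a domain.
    """

    positions: np.ndarray  # (T, n, 2) μm
    inside_flags: np.ndarray  # (T, n) bool
    frame_time: float  # s
    region_extent: tuple[float, float]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    def to_table(self) -> pd.DataFrame:
        """Tidy long-format table (particle, frame, x_um, y_um, inside)."""
        T, n, _ = self.positions.shape
        frame_idx = np.repeat(np.arange(T), n)
        particle_idx = np.tile(np.arange(n), T)
        flat = self.positions.reshape(T * n, 2)
        return pd.DataFrame(
            {
                "particle": particle_idx,
                "frame": frame_idx,
                "x_um": flat[:, 0],
                "y_um": flat[:, 1],
                "inside": self.inside_flags.reshape(T * n),
            }
        )


@dataclass(frozen=True)
class PartitionStats:
    """Occupancy statistics of the domain field."""

    beta_per_frame: np.ndarray  # fraction of particles inside, per frame
    beta_mean: float
    n_domains: int
    mean_occupancy: float  # average particles per domain


def _substep(
    pos: np.ndarray,
    inside: np.ndarray,
    domains: DomainField,
    config: SimulationConfig,
    dt: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    width, height = config.region_extent
    extent = np.array([width, height])
    D = np.where(inside, config.D_in, config.D_out)
    step = rng.normal(size=pos.shape) * np.sqrt(2.0 * D * dt)[:, None]
    prop = (pos + step) % extent

    if domains.n_domains == 0:
        return prop, np.zeros(len(prop), dtype=bool)

    inside_prop = domains.contains(prop)
    crossing = inside != inside_prop
    # One uniform per particle keeps the draw order independent of geometry.
    u = rng.random(len(pos))
    p_accept = np.where(inside, config.P_out, config.P_in)
    accept = ~crossing | (u < p_accept)

    if config.boundary_policy == "reject_step" or np.all(accept):
        new_pos = np.where(accept[:, None], prop, pos)
    else:
        new_pos = prop.copy()
        rej = ~accept
        # Fold the refused endpoint radially back across the circle of the
        # adjudicating domain: the one left (exit attempt) or entered (entry
        # attempt).  Degenerate folds fall back to cancelling the step.
        centers = domains.nearest_center(np.where(inside[rej, None], pos[rej], prop[rej]))
        vec = prop[rej] - centers
        d = np.linalg.norm(vec, axis=1)
        ok = d > 1e-12
        d_new = 2.0 * domains.radius - d
        ok &= d_new > 1e-12
        folded = centers + vec * np.where(ok, d_new / np.maximum(d, 1e-300), 1.0)[:, None]
        folded = np.where(ok[:, None], folded, pos[rej])
        new_pos[rej] = folded % extent

    return new_pos, domains.contains(new_pos)


def step_particles(
    positions: np.ndarray,
    inside_flags: np.ndarray,
    domains: DomainField,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance all particles by one frame (``substeps_per_frame`` substeps).

    Each substep draws an independent Gaussian displacement per axis with
    standard deviation sqrt(2·D·Δt), D chosen by the particle's region at the
    start of the substep; a substep whose endpoint changes region is accepted
    with the corresponding partition probability, otherwise resolved by the
    boundary policy.  Positions are wrapped periodically.
    """
    dt = config.resolved_frame_time() / config.substeps_per_frame
    pos, inside = positions, inside_flags
    for _ in range(config.substeps_per_frame):
        pos, inside = _substep(pos, inside, domains, config, dt, rng)
    return pos, inside


def simulate(config: SimulationConfig) -> tuple[TrajectorySet, DomainField]:
    """Run a full confined-diffusion simulation.

    A single seeded generator drives, in order: domain placement, particle
    initialization, then every displacement/crossing draw.  The first
    ``burn_in_frames`` frames are discarded so the occupancy reaches its
    partitioning steady state; only the retained frames are returned.
    """
    rng = np.random.default_rng(config.seed)
    domains = place_domains(
        config.region_extent, config.domain_radius, config.area_fraction, rng
    )
    pos = init_particles(config.particle_density, config.region_extent, rng)
    inside = domains.contains(pos)

    n_keep = config.n_frames - config.burn_in_frames
    n = len(pos)
    positions = np.empty((n_keep, n, 2), dtype=float)
    flags = np.empty((n_keep, n), dtype=bool)

    for frame in range(config.n_frames):
        pos, inside = step_particles(pos, inside, domains, config, rng)
        k = frame - config.burn_in_frames
        if k >= 0:
            positions[k] = pos
            flags[k] = inside

    traj = TrajectorySet(positions, flags, config.resolved_frame_time(), config.region_extent)
    return traj, domains


def partition_coefficient(traj: TrajectorySet, domains: DomainField) -> PartitionStats:
    """Fraction of particles inside domains, per frame and time-averaged (β)."""
    if traj.n_particles == 0:
        beta = np.zeros(traj.n_frames)
    else:
        beta = traj.inside_flags.mean(axis=1)
    occupancy = (
        traj.inside_flags.sum(axis=1).mean() / domains.n_domains
        if domains.n_domains
        else 0.0
    )
    return PartitionStats(
        beta_per_frame=beta,
        beta_mean=float(beta.mean()),
        n_domains=domains.n_domains,
        mean_occupancy=float(occupancy),
    )


def effective_diffusion(D_free: float, beta: float) -> float:
    """Effective long-range diffusion coefficient D_eff = D_free·(1 − β)."""
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must be in [0, 1], got {beta}")
    return D_free * (1.0 - beta)


def ensemble_msd(traj: TrajectorySet, max_lag: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Ensemble/time-averaged mean squared displacement from the trajectories.

    Periodic wrapping is undone with the minimum-image convention applied to
    per-frame increments (exact as long as no particle moves more than half
    the region in one frame).  Returns (lag times in s, MSD in μm²) for lags
    1..max_lag.
    """
    if max_lag is None:
        max_lag = traj.n_frames // 4
    extent = np.asarray(traj.region_extent)
    delta = np.diff(traj.positions, axis=0)
    delta -= extent * np.round(delta / extent)
    unwrapped = np.concatenate(
        [traj.positions[:1], traj.positions[0] + np.cumsum(delta, axis=0)], axis=0
    )
    lags = np.arange(1, max_lag + 1)
    msd = np.empty(max_lag)
    for i, lag in enumerate(lags):
        disp = unwrapped[lag:] - unwrapped[:-lag]
        msd[i] = np.mean(np.sum(disp**2, axis=-1))
    return lags * traj.frame_time, msd


def estimate_diffusion_from_msd(traj: TrajectorySet, max_lag: int | None = None) -> float:
    """Diffusion coefficient from a linear fit of MSD(τ) = 4·D·τ."""
    t, msd = ensemble_msd(traj, max_lag)
    slope, _ = np.polyfit(t, msd, 1)
    return float(slope / 4.0)
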