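"""Shared fixtures: scaled-down simulation runs reused across test modules.

The confined-diffusion study conditions are desk-scaled: a 12.8 μm (128 px)
region analyzed over the central 112 px, 600 retained frames, particle
density 5/μm², two seeds averaged per condition.  These sizes keep the whole
suite within a workstation budget while leaving every extracted parameter
statistically resolvable.
"""

import numpy as np
import pytest

from ckics import (
    AnalysisConfig,
    RunConfig,
    SimulationConfig,
    compute_kics_cf,
    run_pipeline,
    simulate,
)
from ckics.pipeline import render_images

SEEDS = (5, 17)

BASE_SIM = dict(region_px=128, n_frames=720, burn_in_frames=120, particle_density=5.0)
BASE_ANALYSIS = AnalysisConfig(crop_px=112, max_tau=60)


def run_confined(seed: int, **overrides):
    """One confined pipeline run at the desk-scale study conditions."""
    sim = SimulationConfig(seed=seed, **{**BASE_SIM, **overrides})
    res = run_pipeline(RunConfig(simulation=sim, analysis=BASE_ANALYSIS))
    return res


def seed_averaged(values_by_seed):
    return {
        key: float(np.mean([v[key] for v in values_by_seed]))
        for key in values_by_seed[0]
    }


def sweep(param_values, **fixed):
    """Seed-averaged confinement parameters along one simulation parameter."""
    rows = []
    for overrides in param_values:
        per_seed = []
        for seed in SEEDS:
            res = run_confined(seed, **{**fixed, **overrides})
            p = res.parameters
            per_seed.append(
                dict(
                    D_M=p.D_M,
                    D_mu=p.D_mu,
                    plateau_mu=p.plateau_mu,
                    effective_radius=p.effective_radius,
                    sat_A_M=p.sat_A_M,
                    sat_A_mu=p.sat_A_mu,
                    beta=res.partition.beta_mean,
                )
            )
        rows.append(seed_averaged(per_seed))
    return rows


@pytest.fixture(scope="session")
def free_run():
    """Free diffusion at the default outside-domain D, rendered noiselessly.

    Returns the trajectories plus the *unnormalized* CF, as consumed by the
    single-species analysis.
    """
    sim = SimulationConfig(
        seed=101,
        area_fraction=0.0,
        frame_time=0.1,
        **{**BASE_SIM, "n_frames": 1100, "burn_in_frames": 100},
    )
    traj, _ = simulate(sim)
    cfg = RunConfig(simulation=sim, analysis=BASE_ANALYSIS)
    series = render_images(traj, cfg, noise_seed=sim.seed + 1)
    cf = compute_kics_cf(series, max_tau=30)
    return {"trajectories": traj, "series": series, "cf": cf}


@pytest.fixture(scope="session")
def dratio_sweep():
    """D_out/D_in ∈ {1, 2, 5, 10} with D_out fixed at 0.01 μm²/s."""
    values = [{"D_in": d} for d in (0.01, 0.005, 0.002, 0.001)]
    return {"D_in": [v["D_in"] for v in values], "rows": sweep(values)}


@pytest.fixture(scope="session")
def area_sweep():
    """Domain area coverage from 0.5% to 5%."""
    values = [{"area_fraction": a} for a in (0.005, 0.02, 0.035, 0.05)]
    return {"area_fraction": [v["area_fraction"] for v in values], "rows": sweep(values)}


@pytest.fixture(scope="session")
def pin_sweep():
    """P_in/P_out swept with P_out = 1 − P_in."""
    values = [{"P_in": p, "P_out": 1.0 - p} for p in (0.3, 0.5, 0.7, 0.9)]
    return {"P_in": [v["P_in"] for v in values], "rows": sweep(values)}


@pytest.fixture(scope="session")
def radius_sweep():
    """Domain radii from sub-resolution (0.05 μm) to 0.5 μm at 5% coverage."""
    radii = (0.05, 0.1, 0.2, 0.3, 0.4, 0.5)
    values = [{"domain_radius": r} for r in radii]
    return {"radius": list(radii), "rows": sweep(values)}
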