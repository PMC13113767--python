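"""Simulation engine: domain packing, stepping, partitioning, MSD oracle."""

import numpy as np
import pytest

from ckics import (
    DomainField,
    PackingError,
    SimulationConfig,
    TrajectorySet,
    auto_frame_time,
    effective_diffusion,
    ensemble_msd,
    estimate_diffusion_from_msd,
    init_particles,
    partition_coefficient,
    place_domains,
    simulate,
    step_particles,
)

REGION = (30.0, 30.0)


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"P_in": 1.5},
            {"P_out": -0.1},
            {"D_in": -1e-3},
            {"area_fraction": 1.0},
            {"burn_in_frames": 2200},
            {"frame_time": 0.0},
            {"frame_time": "auto", "D_in": 0.0},
            {"boundary_policy": "bounce"},
            {"substeps_per_frame": 0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)

    def test_auto_frame_time_resolution(self):
        # (radius/5)² / (4·D_in) at the default radius and D_in
        assert SimulationConfig().resolved_frame_time() == pytest.approx(0.4)

    @pytest.mark.parametrize(
        "radius,D_in,expected",
        [(0.2, 0.001, 0.4), (0.5, 0.001, 2.5), (0.2, 0.01, 0.04)],
    )
    def test_auto_frame_time_values(self, radius, D_in, expected):
        assert auto_frame_time(radius, D_in) == pytest.approx(expected)

    def test_auto_frame_time_rejects_zero_D(self):
        with pytest.raises(ValueError):
            auto_frame_time(0.2, 0.0)


class TestPlaceDomains:
    def test_zero_coverage_gives_empty_field(self):
        field = place_domains(REGION, 0.2, 0.0, seed=0)
        assert field.n_domains == 0
        assert field.achieved_fraction == 0.0

    def test_default_coverage_domain_count(self):
        # n = round(0.05 · 900 / (π · 0.04)) = 358
        field = place_domains(REGION, 0.2, 0.05, seed=0)
        assert field.n_domains == 358

    def test_separation_and_bounds(self):
        field = place_domains(REGION, 0.2, 0.05, seed=1)
        c = field.centers
        d2 = np.sum((c[:, None, :] - c[None, :, :]) ** 2, axis=-1)
        np.fill_diagonal(d2, np.inf)
        assert np.sqrt(d2.min()) >= 2 * field.radius
        assert np.all((c >= 0) & (c <= 30.0))
        assert abs(field.achieved_fraction - 0.05) <= np.pi * 0.2**2 / 900

    def test_overdense_request_raises(self):
        with pytest.raises(PackingError):
            place_domains((3.0, 3.0), 1.0, 0.9, seed=0, max_attempts=2000)

    def test_reproducible(self):
        a = place_domains(REGION, 0.2, 0.02, seed=42)
        b = place_domains(REGION, 0.2, 0.02, seed=42)
        np.testing.assert_array_equal(a.centers, b.centers)


class TestInitParticles:
    def test_counts(self):
        assert len(init_particles(0.0, REGION, seed=0)) == 0
        assert len(init_particles(5.0, REGION, seed=0)) == 4500

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            init_particles(-1.0, REGION, seed=0)

    def test_deterministic(self):
        np.testing.assert_array_equal(
            init_particles(2.0, REGION, seed=7), init_particles(2.0, REGION, seed=7)
        )


class TestStepping:
    def test_zero_diffusion_is_static(self):
        cfg = SimulationConfig(D_in=0.0, D_out=0.0, frame_time=0.4)
        field = place_domains(cfg.region_extent, 0.2, 0.05, seed=0)
        pos = init_particles(1.0, cfg.region_extent, seed=1)
        inside = field.contains(pos)
        rng = np.random.default_rng(2)
        new_pos, _ = step_particles(pos, inside, field, cfg, rng)
        np.testing.assert_array_equal(new_pos, pos)

    def test_zero_escape_probability_traps_forever(self):
        cfg = SimulationConfig(
            region_px=64,
            n_frames=60,
            burn_in_frames=0,
            P_out=0.0,
            P_in=1.0,
            frame_time=0.4,
            particle_density=2.0,
            seed=3,
        )
        traj, domains = simulate(cfg)
        started_inside = traj.inside_flags[0]
        # every particle inside at the first retained frame stays inside
        assert np.all(traj.inside_flags[:, started_inside])

    def test_free_msd_slope_matches_set_D(self):
        # domains present but dynamically invisible (P=1 both ways, equal D)
        cfg = SimulationConfig(
            region_px=150,
            n_frames=400,
            burn_in_frames=0,
            D_in=0.01,
            D_out=0.01,
            P_in=1.0,
            P_out=1.0,
            frame_time=0.4,
            particle_density=1.0,
            seed=4,
        )
        traj, _ = simulate(cfg)
        D = estimate_diffusion_from_msd(traj, max_lag=40)
        assert D == pytest.approx(0.01, rel=0.05)

    def test_particle_count_and_bounds_conserved(self):
        cfg = SimulationConfig(
            region_px=64, n_frames=50, burn_in_frames=10, frame_time=0.4,
            particle_density=2.0, seed=5,
        )
        traj, _ = simulate(cfg)
        assert traj.positions.shape == (40, round(2.0 * 6.4**2), 2)
        assert np.all(traj.positions >= 0)
        assert np.all(traj.positions <= 6.4)

    def test_reflect_policy_also_conserves(self):
        cfg = SimulationConfig(
            region_px=64, n_frames=40, burn_in_frames=0, frame_time=0.4,
            particle_density=2.0, boundary_policy="reflect", seed=6,
        )
        traj, domains = simulate(cfg)
        assert np.all(np.isfinite(traj.positions))
        # flags stay consistent with geometry
        np.testing.assert_array_equal(
            traj.inside_flags[-1], domains.contains(traj.positions[-1])
        )


class TestSimulate:
    def test_retained_frames_default_counts(self):
        cfg = SimulationConfig(
            region_px=32, n_frames=30, burn_in_frames=5, frame_time=0.4,
            particle_density=1.0, seed=0,
        )
        traj, _ = simulate(cfg)
        assert traj.n_frames == 25

    def test_no_domains_no_inside_flags(self):
        cfg = SimulationConfig(
            region_px=32, n_frames=20, burn_in_frames=0, area_fraction=0.0,
            frame_time=0.1, particle_density=1.0, seed=0,
        )
        traj, domains = simulate(cfg)
        assert domains.n_domains == 0
        assert not traj.inside_flags.any()

    def test_same_seed_bit_identical(self):
        cfg = SimulationConfig(
            region_px=48, n_frames=30, burn_in_frames=5, frame_time=0.4,
            particle_density=1.0, seed=11,
        )
        t1, _ = simulate(cfg)
        t2, _ = simulate(cfg)
        np.testing.assert_array_equal(t1.positions, t2.positions)
        np.testing.assert_array_equal(t1.inside_flags, t2.inside_flags)

    def test_flags_consistent_with_geometry(self):
        cfg = SimulationConfig(
            region_px=64, n_frames=30, burn_in_frames=0, frame_time=0.4,
            particle_density=1.0, seed=12,
        )
        traj, domains = simulate(cfg)
        for t in (0, traj.n_frames - 1):
            np.testing.assert_array_equal(
                traj.inside_flags[t], domains.contains(traj.positions[t])
            )

    def test_table_export_shape(self):
        cfg = SimulationConfig(
            region_px=32, n_frames=12, burn_in_frames=2, frame_time=0.4,
            particle_density=0.5, seed=0,
        )
        traj, _ = simulate(cfg)
        df = traj.to_table()
        assert list(df.columns) == ["particle", "frame", "x_um", "y_um", "inside"]
        assert len(df) == traj.n_frames * traj.n_particles


class TestPartition:
    def test_no_domains_beta_zero(self):
        cfg = SimulationConfig(
            region_px=32, n_frames=12, burn_in_frames=0, area_fraction=0.0,
            frame_time=0.1, particle_density=1.0, seed=0,
        )
        traj, domains = simulate(cfg)
        stats = partition_coefficient(traj, domains)
        assert stats.beta_mean == 0.0
        assert stats.n_domains == 0

    def test_absorbing_domains_fill_up(self):
        # P_out = 0, P_in = 1: domains only gain particles, so the occupied
        # fraction climbs from its initial value toward 1
        cfg = SimulationConfig(
            region_px=64, n_frames=600, burn_in_frames=0, P_out=0.0, P_in=1.0,
            frame_time=0.4, particle_density=2.0, seed=13,
        )
        traj, domains = simulate(cfg)
        stats = partition_coefficient(traj, domains)
        beta = stats.beta_per_frame
        # absorbing domains: the inside population never loses a member
        assert np.all(np.diff(beta) >= -1e-12)
        assert beta[-1] > beta[0] + 0.2

    def test_beta_bounds(self):
        cfg = SimulationConfig(
            region_px=64, n_frames=60, burn_in_frames=10, frame_time=0.4,
            particle_density=2.0, seed=14,
        )
        traj, domains = simulate(cfg)
        stats = partition_coefficient(traj, domains)
        assert np.all((stats.beta_per_frame >= 0) & (stats.beta_per_frame <= 1))
        assert stats.beta_mean == pytest.approx(stats.beta_per_frame.mean())


class TestEffectiveDiffusion:
    @pytest.mark.parametrize(
        "D,beta,expected", [(0.01, 0.0, 0.01), (0.01, 1.0, 0.0), (0.01, 0.3, 0.007)]
    )
    def test_values(self, D, beta, expected):
        assert effective_diffusion(D, beta) == pytest.approx(expected)

    @pytest.mark.parametrize("beta", [-0.1, 1.1])
    def test_invalid_beta(self, beta):
        with pytest.raises(ValueError):
            effective_diffusion(0.01, beta)


def test_msd_unwraps_periodic_boundaries():
    # a ballistic walker crossing the boundary must not reset its MSD
    pos = np.zeros((30, 1, 2))
    pos[:, 0, 0] = (0.5 + 0.4 * np.arange(30)) % 6.4
    pos[:, 0, 1] = 3.0
    traj = TrajectorySet(pos, np.zeros((30, 1), bool), 1.0, (6.4, 6.4))
    lags, msd = ensemble_msd(traj, max_lag=5)
    np.testing.assert_allclose(msd, (0.4 * np.arange(1, 6)) ** 2, rtol=1e-10)
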