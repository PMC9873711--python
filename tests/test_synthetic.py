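"""Generator properties: scaffold geometry, telegraph gate, Langevin ions, waters."""

import numpy as np
import pytest

from permeoscope.geometry import align_to_reference, pore_geometry_per_frame
from permeoscope.ions import extract_ion_traces
from permeoscope.synthetic import (
    GateRates,
    GaussianWell,
    SyntheticConfig,
    build_scaffold,
    generate,
    mfpt_reflecting,
    potential,
    simulate_gate,
    simulate_ions,
    simulate_waters,
)


class TestScaffold:
    def test_zero_drift_gives_static_helix_ends(self):
        cfg = SyntheticConfig.field_on()
        cfg.n_frames = 20
        cfg.scaffold.drift = {}
        topo, traj = build_scaffold(cfg)
        assert np.ptp(traj.coords, axis=0).max() == 0.0

    def test_origin_residue_defines_z_zero(self):
        cfg = SyntheticConfig.field_on()
        cfg.n_frames = 5
        topo, traj = build_scaffold(cfg)
        z = traj.coords[:, topo.origin_ca_index(), 2]
        np.testing.assert_allclose(z, 0.0, atol=1e-12)

    def test_programmed_drift_moves_anchor_distance(self):
        cfg = SyntheticConfig.field_on()
        cfg.n_frames = 700
        cfg.scaffold.drift = {"TM1": 5.0}
        topo, traj = build_scaffold(cfg)
        i106 = np.flatnonzero((topo.resids == 106) & topo.ca_mask())[0]
        i1131 = np.flatnonzero((topo.resids == 1131) & topo.ca_mask())[0]
        d = np.linalg.norm(traj.coords[:, i106] - traj.coords[:, i1131], axis=1)
        assert d.max() - d.min() >= 4.0

    def test_role_tags_resolve(self):
        cfg = SyntheticConfig.field_on()
        cfg.n_frames = 2
        topo, _ = build_scaffold(cfg)
        for role in ("origin", "gate", "site1", "site2", "basic"):
            for resid in topo.role_tags[role]:
                assert topo.atom_indices(resid).size > 0


class TestGate:
    def test_stationary_wet_fraction(self):
        cfg = SyntheticConfig.field_on()
        cfg.n_frames = 100_000
        cfg.gate = GateRates(k_wet=0.01, k_dry=0.01)
        cfg.seed = 4
        states, _ = simulate_gate(cfg)
        assert states.mean() == pytest.approx(0.5, abs=0.02)

    def test_absorbing_limit_stays_wet_after_first_transition(self):
        cfg = SyntheticConfig.field_on()
        cfg.n_frames = 5000
        cfg.gate = GateRates(k_wet=0.05, k_dry=0.0)
        cfg.seed = 1
        states, transitions = simulate_gate(cfg)
        first_wet = np.argmax(states == 1)
        assert states[first_wet:].all()

    def test_fixed_seed_bit_identical(self):
        cfg = SyntheticConfig.field_on()
        cfg.n_frames = 2000
        a, _ = simulate_gate(cfg, seed=33)
        b, _ = simulate_gate(cfg, seed=33)
        np.testing.assert_array_equal(a, b)


class TestIons:
    def test_impenetrable_dry_barrier_blocks_all_crossings(self):
        cfg = SyntheticConfig.field_on()
        cfg.n_frames = 300
        cfg.barrier.impenetrable_dry = True
        cfg.gate_fixed = "dry"
        cfg.seed = 6
        states, _ = simulate_gate(cfg)
        _, _, truth = simulate_ions(cfg, states)
        assert truth.crossing_count() == 0
        assert truth.n_absorptions == 0

    def test_free_diffusion_has_no_net_flux(self):
        # closed box, no potential: signed crossings must balance
        cfg = SyntheticConfig.field_on()
        cfg.n_frames = 1500
        cfg.n_ions = 40
        cfg.wells = []
        cfg.barrier.height_dry = cfg.barrier.height_wet = 0.0
        cfg.voltage_tilt = 0.0
        cfg.boundary = "reflect"
        cfg.gate_fixed = "wet"
        cfg.seed = 8
        states, _ = simulate_gate(cfg)
        _, _, truth = simulate_ions(cfg, states)
        total = truth.crossing_count()
        assert total > 50  # enough traffic for the sign test to mean something
        # net/total should be within a 99% binomial band around 0
        assert abs(truth.net_count) <= 2.6 * np.sqrt(total)

    @pytest.mark.parametrize("seed", range(5))
    def test_tilt_monotonicity_paired_seeds(self, seed):
        def count(tilt):
            cfg = SyntheticConfig.field_on()
            cfg.n_frames = 400
            cfg.n_ions = 6
            cfg.gate_fixed = "wet"
            cfg.voltage_tilt = tilt
            cfg.seed = seed
            states, _ = simulate_gate(cfg)
            _, _, truth = simulate_ions(cfg, states)
            return truth.n_absorptions

        assert count(-0.08) >= count(0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_barrier_monotonicity_paired_seeds(self, seed):
        def count(height):
            cfg = SyntheticConfig.field_on()
            cfg.n_frames = 400
            cfg.n_ions = 6
            cfg.gate_fixed = "wet"
            cfg.barrier.height_wet = height
            cfg.seed = seed
            states, _ = simulate_gate(cfg)
            _, _, truth = simulate_ions(cfg, states)
            return truth.n_absorptions

        assert count(1.0) >= count(6.0)

    def test_instability_guard(self):
        cfg = SyntheticConfig.field_on()
        cfg.n_frames = 5
        cfg.wells = [GaussianWell(-20.0, 5000.0, 0.5)]
        cfg.seed = 0
        states, _ = simulate_gate(cfg)
        from permeoscope.synthetic import SimulationUnstableError

        with pytest.raises(SimulationUnstableError):
            simulate_ions(cfg, states)

    def test_reproducible_bit_for_bit(self):
        cfg = SyntheticConfig.field_on()
        cfg.n_frames = 60
        cfg.seed = 12
        a = generate(cfg)
        b = generate(cfg)
        np.testing.assert_array_equal(a.trajectory.coords, b.trajectory.coords)
        assert a.truth.crossings == b.truth.crossings


class TestWaters:
    def test_dry_lambda_zero_empties_bottleneck(self):
        cfg = SyntheticConfig.field_on()
        cfg.n_frames = 50
        cfg.n_ions = 0
        cfg.gate_fixed = "dry"
        cfg.water.lambda_dry = 0.0
        cfg.seed = 2
        states, _ = simulate_gate(cfg)
        coords, layout = simulate_waters(cfg, states, np.zeros((50, 0)), np.zeros((50, 0, 2)))
        pool = coords[:, : layout["n_bottleneck_pool"]]
        in_bottleneck = (np.abs(pool[:, :, 2]) < 5.0) & (np.linalg.norm(pool[:, :, :2], axis=2) < 10)
        assert in_bottleneck.sum() == 0

    def test_wet_poisson_mean(self):
        cfg = SyntheticConfig.field_on()
        cfg.n_frames = 10_000
        cfg.n_ions = 0
        cfg.gate_fixed = "wet"
        cfg.seed = 3
        states, _ = simulate_gate(cfg)
        coords, layout = simulate_waters(cfg, states, np.zeros((10_000, 0)), np.zeros((10_000, 0, 2)))
        pool = coords[:, : layout["n_bottleneck_pool"]]
        counts = ((np.abs(pool[:, :, 2]) < 5.0) & (np.linalg.norm(pool[:, :, :2], axis=2) < 10)).sum(axis=1)
        assert counts.mean() == pytest.approx(30.0, abs=0.2)


class TestStationarity:
    def test_boltzmann_binned_density_small_sample(self):
        """Ion marginal tracks exp(-U) (chi-square on a 10^5-sample ensemble)."""
        from scipy.stats import chisquare

        from permeoscope.synthetic import boltzmann_profile

        cfg = SyntheticConfig.equilibrium(n_ions=50_000, n_frames=2)
        cfg.seed = 13
        states, _ = simulate_gate(cfg)
        z, _, _ = simulate_ions(cfg, states)
        edges = np.arange(-40, 20.1, 2.0)
        obs, _ = np.histogram(z.ravel(), bins=edges)
        expected = boltzmann_profile(cfg, edges, gate_wet=True) * obs.sum()
        _, p = chisquare(obs, f_exp=expected)
        assert p > 0.01

    def test_first_passage_matches_quadrature_oracle(self):
        """Mean escape time from the binding well recovers the MFPT integral."""
        cfg = SyntheticConfig.single_well(n_frames=1500)
        cfg.seed = 21
        z0 = np.linspace(
            cfg.pore.z_min + cfg.reinject_window[0], cfg.pore.z_min + cfg.reinject_window[1], 101
        )
        tau = mfpt_reflecting(cfg, z0, cfg.pore.z_min, cfg.pore.z_max)
        states, _ = simulate_gate(cfg)
        z, _, truth = simulate_ions(cfg, states)
        # direct passage statistics from the truth ledger's binding intervals
        durations = [(b - a + 1) * cfg.dt for _, a, b in truth.binding_intervals["site1"]]
        assert len(durations) >= 200
        assert np.mean(durations) == pytest.approx(tau, rel=0.15)


def test_potential_shape_wells_and_barrier():
    cfg = SyntheticConfig.field_on()
    u = potential(cfg, np.array([-28.0, -12.0, 0.0]), gate_wet=False)
    assert u[0] < 0 and u[1] < 0 and u[2] > 5
    u_wet = potential(cfg, np.array([0.0]), gate_wet=True)
    assert u_wet[0] < u[2]
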