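"""The generators must honor their declared ground truth exactly."""

import numpy as np
import pytest

from cycloplex import build_toy_complex
from cycloplex.assay import four_pl
from cycloplex.synthetic import (
    DoseResponseSimSpec,
    ScenarioSpec,
    SolubilitySimSpec,
    ToyHostSpec,
    al_slope,
    simulate_dose_response,
    simulate_inclusion_trajectory,
    simulate_phase_solubility,
)


class TestToyBuilder:
    def test_unit_bookkeeping(self, toy):
        system, _ = toy
        assert system.n_units == 7
        for kind in ("O2", "O3", "O4"):
            ids = [system.rim_oxygen(kind, k) for k in range(1, 8)]
            assert len(set(ids)) == 7

    def test_symmetric_build_has_equal_glycosidic_distances(self, toy):
        system, xyz = toy
        o4 = np.array([xyz[system.rim_oxygen("O4", k)] for k in range(1, 8)])
        d = np.linalg.norm(o4 - np.roll(o4, -1, axis=0), axis=1)
        assert np.ptp(d) < 1e-9

    @pytest.mark.parametrize("net", [0.0, -1.0])
    def test_charges_sum_to_declared_net(self, net):
        system, _ = build_toy_complex(host_net_charge=net)
        host_q = system.charges[system.group("host")].sum()
        guest_q = system.charges[system.group("guest")].sum()
        assert abs(host_q - net) < 1e-12
        assert abs(guest_q) < 1e-12

    def test_guest_rings_share_fused_edge(self, toy):
        system, _ = toy
        a = set(system.group("guest_ring_A").tolist())
        q = set(system.group("guest_ring_Q").tolist())
        assert len(a) == len(q) == 6
        assert len(a & q) == 2

    def test_too_few_units_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            ToyHostSpec(n_units=2)


class TestTrajectoryGenerator:
    def test_zero_noise_guest_sits_at_the_mean(self, toy):
        system, xyz = toy
        spec = ScenarioSpec(scenario="stable_wide", n_frames=20,
                            noise_sigma=0.0, ou_mean=2.0, seed=5)
        traj = simulate_inclusion_trajectory(system, xyz, spec)
        guest = system.group("guest")
        m = system.masses[guest]
        z = (traj.coords[:, guest, 2] * m).sum(axis=1) / m.sum()
        assert np.allclose(z, 2.0, atol=1e-9)

    def test_same_seed_bit_identical(self, toy):
        system, xyz = toy
        spec = ScenarioSpec(n_frames=50, seed=9)
        a = simulate_inclusion_trajectory(system, xyz, spec)
        b = simulate_inclusion_trajectory(system, xyz, spec)
        assert np.array_equal(a.coords, b.coords)

    def test_ou_time_average_matches_stationary_mean(self, toy):
        system, xyz = toy
        spec = ScenarioSpec(scenario="stable_wide", n_frames=9000,
                            ou_mean=2.0, noise_sigma=0.6,
                            ou_relaxation=50.0, seed=1)
        traj = simulate_inclusion_trajectory(system, xyz, spec)
        guest = system.group("guest")
        m = system.masses[guest]
        z = (traj.coords[:, guest, 2] * m).sum(axis=1) / m.sum()
        # standard error of an OU time average: sigma * sqrt(2 tau / n)
        se = 0.6 * np.sqrt(2 * 50.0 / 9000)
        assert abs(z.mean() - 2.0) < 3 * se

    def test_ou_stationary_variance_matches_analytic(self, toy):
        system, xyz = toy
        spec = ScenarioSpec(scenario="stable_wide", n_frames=50_000,
                            ou_mean=0.0, noise_sigma=0.6,
                            ou_relaxation=5.0, seed=0)
        traj = simulate_inclusion_trajectory(system, xyz, spec)
        guest = system.group("guest")
        m = system.masses[guest]
        z = (traj.coords[:, guest, 2] * m).sum(axis=1) / m.sum()
        assert abs(z.var() - 0.36) / 0.36 < 0.05

    def test_dissociating_scenario_ends_beyond_threshold(self, toy):
        system, xyz = toy
        spec = ScenarioSpec(scenario="dissociating", n_frames=400,
                            ou_mean=0.0, seed=2)
        traj = simulate_inclusion_trajectory(system, xyz, spec)
        guest = system.group("guest")
        m = system.masses[guest]
        z_end = (traj.coords[-1, guest, 2] * m).sum() / m.sum()
        assert abs(z_end) > 8.0

    def test_rim_pairs_follow_requested_targets(self, toy):
        # every unit pair carries the same per-frame target by construction
        from cycloplex.geometry import rim_distances

        system, xyz = toy
        traj = simulate_inclusion_trajectory(
            system, xyz, ScenarioSpec(n_frames=30, seed=3))
        rim = rim_distances(system, traj)
        assert np.ptp(rim.d32, axis=1).max() < 1e-9
        assert np.ptp(rim.d44, axis=1).max() < 1e-9


class TestSolubilitySimulator:
    def test_exactly_linear_at_zero_noise(self):
        spec = SolubilitySimSpec(S0_true=1e-3, Kc_true=500.0, noise_cv=0.0)
        series = simulate_phase_solubility(spec)
        slope = al_slope(500.0, 1e-3)
        expected = 1e-3 + slope * series.cd_conc
        assert np.allclose(series.guest_conc, expected, rtol=1e-14)

    def test_zero_affinity_series_is_flat(self):
        spec = SolubilitySimSpec(S0_true=1e-3, Kc_true=0.0, noise_cv=0.0)
        series = simulate_phase_solubility(spec)
        assert np.allclose(series.guest_conc, 1e-3)

    def test_slope_algebra_at_unit_kc_s0(self):
        # Kc*S0 = 1 puts the isotherm slope exactly at 1/2
        assert al_slope(1000.0, 1e-3) == pytest.approx(0.5, abs=1e-15)


class TestDoseResponseSimulator:
    def test_midpoint_viability_at_ic50(self):
        spec = DoseResponseSimSpec(ic50_true=10.0, doses=(10.0, 1.0, 100.0, 3.0),
                                   noise_sd=0.0)
        series = simulate_dose_response(spec)
        at_ic50 = series.viability[series.dose == 10.0][0]
        assert at_ic50 == pytest.approx(50.0, abs=1e-12)

    def test_noise_free_curve_matches_model(self):
        spec = DoseResponseSimSpec(ic50_true=7.0, hill=1.5, top=95.0,
                                   bottom=5.0, noise_sd=0.0)
        series = simulate_dose_response(spec)
        assert np.allclose(series.viability,
                           four_pl(series.dose, 7.0, 1.5, 95.0, 5.0))
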