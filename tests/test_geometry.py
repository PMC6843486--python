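"""Geometric observables against hand-computed and analytic references."""

import numpy as np
import pytest

from cycloplex.core import Trajectory
from cycloplex.geometry import (
    GeometryError,
    ParameterError,
    classify_binding_mode,
    guest_sasa,
    hbond_fraction,
    host_axis,
    native_contacts,
    rim_distances,
    shrake_rupley,
    signed_ring_distance,
)
from cycloplex.synthetic import ScenarioSpec, simulate_inclusion_trajectory


def brute_force_contacts(frame, host_idx, guest_idx, cutoff):
    """Independent O(N^2) contact count."""
    count = 0
    for g in guest_idx:
        for h in host_idx:
            if np.linalg.norm(frame[g] - frame[h]) <= cutoff:
                count += 1
    return count


class TestSignedDistance:
    def test_guest_at_host_center_reads_zero(self, toy):
        system, xyz = toy
        frame = xyz.copy()
        guest = system.group("guest")
        # place the whole guest's mass center exactly at the host center
        m = system.masses[guest]
        com = (frame[guest] * m[:, None]).sum(axis=0) / m.sum()
        frame[guest] -= com
        traj = Trajectory(frame[None], 0.05)
        trace = signed_ring_distance(system, traj, "guest")
        assert trace.values[0] == pytest.approx(0.0, abs=1e-9)

    def test_axis_translation_reads_back_exactly(self, toy):
        system, xyz = toy
        frame = xyz.copy()
        guest = system.group("guest")
        frame[guest, 2] += 2.0
        trace = signed_ring_distance(system, Trajectory(frame[None], 0.05),
                                     "guest")
        assert trace.values[0] == pytest.approx(2.0, abs=1e-9)

    def test_sign_flips_with_rim_convention(self, toy, short_traj):
        system, _ = toy
        d = signed_ring_distance(system, short_traj, "guest")
        dflip = signed_ring_distance(system, short_traj, "guest",
                                     wide_rim_positive=False)
        assert np.allclose(dflip.values, -d.values, atol=1e-12)

    def test_mirroring_the_structure_is_convention_invariant(self, toy):
        # reflecting everything through the O4 plane swaps rims and guest
        # together, so the signed distance must not change
        system, xyz = toy
        frame = xyz.copy()
        guest = system.group("guest")
        frame[guest, 2] += 2.0
        mirrored = frame.copy()
        mirrored[:, 2] *= -1.0
        d = signed_ring_distance(system, Trajectory(frame[None], 0.05), "guest")
        dm = signed_ring_distance(system, Trajectory(mirrored[None], 0.05),
                                  "guest")
        assert dm.values[0] == pytest.approx(d.values[0], abs=1e-9)

    def test_rings_report_separate_coordinates(self, toy):
        system, xyz = toy
        traj = Trajectory(xyz[None], 0.05)
        da = signed_ring_distance(system, traj, "A").values[0]
        dq = signed_ring_distance(system, traj, "Q").values[0]
        assert dq > da  # quinone ring sits on the wide-rim side

    def test_collinear_o4_ring_is_degenerate(self, toy):
        system, xyz = toy
        frame = xyz.copy()
        for k in range(1, 8):
            i = system.rim_oxygen("O4", k)
            frame[i] = [float(k), 0.0, 0.0]
        with pytest.raises(GeometryError):
            host_axis(system, frame)


class TestBindingModeClassifier:
    @pytest.mark.parametrize(
        "mean,expected",
        [
            (0.0, "inside"),
            (1.0, "inside"),
            (3.0, "wide_rim"),
            (-3.0, "narrow_rim"),
            (9.5, "dissociated"),
            (-9.5, "dissociated"),
        ],
    )
    def test_rule_table(self, mean, expected):
        from cycloplex.geometry import DistanceTrace

        trace = DistanceTrace(values=np.full(10, mean), label="d")
        assert classify_binding_mode(trace) == expected

    def test_dissociating_scenario_classified_dissociated(self, toy):
        system, xyz = toy
        spec = ScenarioSpec(scenario="dissociating", n_frames=300,
                            timestep_label=0.05, seed=4)
        traj = simulate_inclusion_trajectory(system, xyz, spec)
        trace = signed_ring_distance(system, traj, "guest")
        mode = classify_binding_mode(trace, traj.last_window(1.0))
        assert mode == "dissociated"


class TestRimDistances:
    def test_hand_computed_two_frame_case(self, toy):
        system, xyz = toy
        frames = np.stack([xyz, xyz + [0.0, 0.0, 1.0]])  # rigid shift
        rim = rim_distances(system, Trajectory(frames, 0.05))
        # manual recomputation straight from the coordinates
        for t in range(2):
            for k in range(7):
                o3 = frames[t][system.rim_oxygen("O3", k + 1)]
                o2n = frames[t][system.rim_oxygen("O2", (k % 7) + 2 if k < 6 else 1)]
                assert rim.d32[t, k] == pytest.approx(
                    np.linalg.norm(o3 - o2n), abs=1e-9)

    def test_symmetric_host_has_equal_d44(self, toy):
        system, xyz = toy
        rim = rim_distances(system, Trajectory(xyz[None], 0.05))
        assert np.ptp(rim.d44[0]) < 1e-9

    @pytest.mark.parametrize("value,expected", [(10.0, 0.0), (2.8, 1.0)])
    def test_hbond_fraction_extremes(self, value, expected):
        from cycloplex.geometry import RimGeometryTrace

        trace = RimGeometryTrace(d32=np.full((5, 7), value),
                                 d44=np.full((5, 7), 4.5))
        _, overall = hbond_fraction(trace)
        assert overall == expected

    def test_hbond_fraction_counts_pairs(self):
        from cycloplex.geometry import RimGeometryTrace

        d32 = np.full((4, 7), 5.0)
        d32[:, :3] = 3.4  # 3 of 7 pairs under the cutoff in every frame
        trace = RimGeometryTrace(d32=d32, d44=np.full((4, 7), 4.5))
        per_pair, overall = hbond_fraction(trace, cutoff=3.5)
        assert overall == pytest.approx(3 / 7)
        assert np.allclose(per_pair, [1, 1, 1, 0, 0, 0, 0])


class TestNativeContacts:
    def test_distant_guest_has_no_contacts(self, toy):
        system, xyz = toy
        frame = xyz.copy()
        frame[system.group("guest")] += [50.0, 0.0, 0.0]
        traj = Trajectory(frame[None], 20.0)
        cs = native_contacts(system, traj, window_ns=20.0)
        assert cs.mean_total == 0.0

    def test_constructed_pair_count(self, ad_hoc_system):
        # 5 cross pairs at 2.9 A, everything else beyond 3.2 A
        host_xy = [(0.0, 0.0), (10.0, 0.0), (20.0, 0.0), (30.0, 0.0),
                   (40.0, 0.0), (50.0, 50.0)]
        coords = [(x, y, 0.0) for x, y in host_xy]
        coords += [(x, 2.9, 0.0) for x, _ in host_xy[:5]]  # 5 guest atoms
        groups = {"host": range(6), "guest": range(6, 11),
                  "guest_ring_A": [6], "guest_ring_Q": [7],
                  "unit_1": range(6), "O2_1": [0], "O3_1": [1], "O4_1": [2]}
        system = ad_hoc_system(np.array(coords), groups=groups)
        traj = Trajectory(np.array(coords)[None], 1.0)
        cs = native_contacts(system, traj, cutoff=3.0, window_ns=1.0)
        assert cs.mean_total == 5.0

    def test_matches_brute_force_on_random_frames(self, toy):
        system, xyz = toy
        rng = np.random.default_rng(7)
        host_idx = system.group("host")
        guest_idx = system.group("guest")
        frames = xyz[None] + rng.uniform(-6, 6, size=(25, system.n_atoms, 3))
        traj = Trajectory(frames, 1.0)
        cs = native_contacts(system, traj, window_ns=1e9)
        expected = [brute_force_contacts(f, host_idx, guest_idx, 3.0)
                    for f in frames]
        assert cs.per_frame["MD1"].tolist() == expected

    def test_invariant_under_rigid_motion(self, toy):
        system, xyz = toy
        traj = Trajectory(xyz[None], 1.0)
        base = native_contacts(system, traj, window_ns=1.0).mean_total
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        moved = xyz @ rot.T + np.array([5.0, -3.0, 11.0])
        same = native_contacts(system, Trajectory(moved[None], 1.0),
                               window_ns=1.0).mean_total
        assert same == base

    def test_sem_across_replicates(self, toy):
        system, xyz = toy
        traj = Trajectory(xyz[None], 1.0)
        cs = native_contacts(system, [traj, traj, traj], window_ns=1.0)
        assert cs.sem_total == 0.0


class TestSasa:
    def test_isolated_sphere_matches_analytic_area(self):
        areas = shrake_rupley(np.zeros((1, 3)), np.array([1.7]),
                              probe_radius=1.4, n_points=960)
        exact = 4 * np.pi * (1.7 + 1.4) ** 2
        assert abs(areas[0] - exact) / exact < 0.01

    def test_two_sphere_overlap_matches_lens_formula(self):
        r, p, d = 1.7, 1.4, 2.5
        R = r + p
        h = R - d / 2.0  # equal spheres: symmetric cap height
        exact = 4 * np.pi * R * R - 2 * np.pi * R * h
        areas = shrake_rupley(np.array([[0, 0, 0], [d, 0, 0.0]]),
                              np.array([r, r]), probe_radius=p, n_points=960)
        assert abs(areas[0] - exact) / exact < 0.02
        assert abs(areas[1] - exact) / exact < 0.02

    def test_fully_enclosed_guest_has_zero_area(self, toy):
        system, xyz = toy
        frame = xyz.copy()
        guest = system.group("guest")
        center = frame[guest].mean(axis=0)
        frame[guest] = center + 0.3 * (frame[guest] - center)  # shrink guest
        # occluding shell: big host spheres all around the shrunken guest
        host = system.group("host")
        shell = center + 4.0 * np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1],
             [0, 0, -1]] * 7)
        frame[host] = shell
        sys2 = system
        radii = sys2.radii.copy()
        radii[host] = 6.0
        sys2 = type(sys2)(names=sys2.names, elements=sys2.elements,
                          radii=radii, charges=sys2.charges,
                          lj_eps=sys2.lj_eps, lj_rmin_half=sys2.lj_rmin_half,
                          groups=sys2.groups)
        trace = guest_sasa(sys2, Trajectory(frame[None], 1.0))
        assert trace.values[0] == 0.0

    def test_occlusion_is_monotone(self):
        # adding atoms can only reduce the accessible area of atom 0
        rng = np.random.default_rng(3)
        coords = [np.zeros(3)]
        prev = np.inf
        for _ in range(6):
            coords.append(rng.uniform(-2.5, 2.5, 3))
            c = np.array(coords)
            a0 = shrake_rupley(c, np.full(len(c), 1.7), n_points=480,
                               subset=[0])[0]
            assert a0 <= prev + 1e-9
            prev = a0

    def test_missing_radius_is_reported(self):
        with pytest.raises(ParameterError, match="atom 1"):
            shrake_rupley(np.zeros((2, 3)) + [[0, 0, 0], [5, 0, 0]],
                          np.array([1.7, np.nan]))

    def test_complex_context_occludes(self, toy, short_traj):
        system, _ = toy
        sub = Trajectory(short_traj.coords[:3], 0.05)
        bound = guest_sasa(system, sub).values
        free = guest_sasa(system, sub, context="guest").values
        assert np.all(bound <= free + 1e-9)
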