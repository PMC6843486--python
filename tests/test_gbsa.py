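"""MM/GBSA components against closed forms and brute-force oracles."""

import numpy as np
import pytest

from cycloplex.core import Trajectory
from cycloplex.gbsa import (
    COULOMB_CONSTANT,
    GBParams,
    SamplingError,
    SingularityError,
    effective_born_radii,
    gb_polar_energy,
    mmgbsa_single_trajectory,
    pair_energies,
    verify_ledger,
)
from cycloplex.synthetic import ScenarioSpec, simulate_replicates

# the published component table this module's ledger mirrors (kcal/mol)
TABLE_COLUMNS = {
    "beta": {"dE_vdw": -27.61, "dE_ele": -11.79, "dE_MM": -39.40,
             "dG_solv_polar": 22.14, "dG_solv_nonpolar": -2.83,
             "dG_solv": 19.31, "dG_polar_plus_ele": 10.35,
             "dG_nonpolar_plus_vdw": -30.44, "TdS": -17.74,
             "dG_bind": -2.34},
    "dimethyl": {"dE_vdw": -29.19, "dE_ele": -4.43, "dE_MM": -33.62,
                 "dG_solv_polar": 12.72, "dG_solv_nonpolar": -2.98,
                 "dG_solv": 9.73, "dG_polar_plus_ele": 8.29,
                 "dG_nonpolar_plus_vdw": -32.18, "TdS": -18.16,
                 "dG_bind": -5.73},
    "hydroxypropyl": {"dE_vdw": -28.59, "dE_ele": -6.40, "dE_MM": -34.99,
                      "dG_solv_polar": 17.17, "dG_solv_nonpolar": -3.10,
                      "dG_solv": 14.06, "dG_polar_plus_ele": 10.77,
                      "dG_nonpolar_plus_vdw": -31.69, "TdS": -17.57,
                      "dG_bind": -3.35},
}


class TestPairEnergies:
    def test_lj_minimum_depth(self, ad_hoc_system):
        s = ad_hoc_system(np.zeros((2, 3)), eps=[0.1, 0.1],
                          rmin_half=[1.9, 1.9])
        frame = np.array([[0, 0, 0], [3.8, 0, 0.0]])
        e_vdw, _ = pair_energies(s, frame, [0], [1])
        assert e_vdw == pytest.approx(-0.1, abs=1e-12)

    def test_coulomb_constant_at_one_angstrom(self, ad_hoc_system):
        s = ad_hoc_system(np.zeros((2, 3)), charges=[1.0, 1.0])
        _, e_ele = pair_energies(s, np.array([[0, 0, 0], [1.0, 0, 0]]),
                                 [0], [1])
        assert e_ele == pytest.approx(332.0636, abs=1e-10)

    def test_matches_brute_force_double_loop(self, ad_hoc_system):
        rng = np.random.default_rng(17)
        n = 10
        coords = rng.uniform(-5, 5, (n, 3))
        s = ad_hoc_system(coords, charges=rng.uniform(-0.5, 0.5, n),
                          eps=rng.uniform(0.05, 0.3, n),
                          rmin_half=rng.uniform(1.2, 2.0, n))
        g1, g2 = np.arange(4), np.arange(4, n)
        e_vdw, e_ele = pair_energies(s, coords, g1, g2)
        bf_vdw = bf_ele = 0.0
        for i in g1:
            for j in g2:
                r = np.linalg.norm(coords[i] - coords[j])
                rm = s.lj_rmin_half[i] + s.lj_rmin_half[j]
                eps = np.sqrt(s.lj_eps[i] * s.lj_eps[j])
                bf_vdw += eps * ((rm / r) ** 12 - 2 * (rm / r) ** 6)
                bf_ele += COULOMB_CONSTANT * s.charges[i] * s.charges[j] / r
        assert e_vdw == pytest.approx(bf_vdw, abs=1e-10)
        assert e_ele == pytest.approx(bf_ele, abs=1e-10)

    def test_coincident_atoms_reported(self, ad_hoc_system):
        s = ad_hoc_system(np.zeros((2, 3)))
        with pytest.raises(SingularityError):
            pair_energies(s, np.zeros((2, 3)), [0], [1])


class TestGeneralizedBorn:
    def test_single_ion_born_limit(self, ad_hoc_system):
        a, q = 1.5, 1.0
        s = ad_hoc_system(np.zeros((1, 3)), radii=[a], charges=[q],
                          elements=["O"])
        e = gb_polar_energy(s, np.zeros((1, 3)))
        born = -0.5 * (1 - 1 / 78.5) * COULOMB_CONSTANT * q * q / a
        assert abs(e - born) / abs(born) < 1e-9

    def test_invariant_under_charge_sign_flip(self, ad_hoc_system):
        rng = np.random.default_rng(2)
        coords = rng.uniform(-3, 3, (5, 3))
        q = rng.uniform(-0.5, 0.5, 5)
        s1 = ad_hoc_system(coords, radii=np.full(5, 1.6), charges=q,
                           elements=["O"] * 5)
        s2 = ad_hoc_system(coords, radii=np.full(5, 1.6), charges=-q,
                           elements=["O"] * 5)
        assert gb_polar_energy(s1, coords) == pytest.approx(
            gb_polar_energy(s2, coords), abs=1e-12)

    def test_two_atom_pairwise_formula_by_hand(self, ad_hoc_system):
        r12 = 3.0
        coords = np.array([[0, 0, 0], [r12, 0, 0.0]])
        radii = np.array([1.5, 1.8])
        q = np.array([0.4, -0.3])
        s = ad_hoc_system(coords, radii=radii, charges=q, elements=["O", "O"])
        params = GBParams()
        alpha = effective_born_radii(coords, radii, ["O", "O"], params)
        pref = -0.5 * COULOMB_CONSTANT * (1 - 1 / 78.5)
        expected = 0.0
        for i in range(2):
            for j in range(2):
                r2 = 0.0 if i == j else r12 * r12
                aa = alpha[i] * alpha[j]
                f = np.sqrt(r2 + aa * np.exp(-r2 / (4 * aa)))
                expected += pref * q[i] * q[j] / f
        assert gb_polar_energy(s, coords, params) == pytest.approx(
            expected, abs=1e-9)

    def test_matched_dielectrics_remove_polar_term(self, ad_hoc_system):
        rng = np.random.default_rng(4)
        coords = rng.uniform(-3, 3, (6, 3))
        s = ad_hoc_system(coords, radii=np.full(6, 1.6),
                          charges=rng.uniform(-0.4, 0.4, 6),
                          elements=["O"] * 6)
        params = GBParams(eps_in=1.0, eps_out=1.0 + 1e-12)
        assert abs(gb_polar_energy(s, coords, params)) < 1e-9

    def test_descreening_shrinks_effective_radius_of_buried_atom(self):
        coords = np.array([[0, 0, 0], [2.8, 0, 0.0]])
        radii = np.array([1.6, 1.6])
        alpha = effective_born_radii(coords, radii, ["O", "O"])
        iso = effective_born_radii(coords[:1], radii[:1], ["O"])
        assert alpha[0] > iso[0]  # neighbor descreens: radius grows toward bulk


class TestSingleTrajectoryEstimator:
    def test_null_binding_gives_zero_components(self, toy):
        system, xyz = toy
        # ghost guest: no charge, no dispersion, parked 100 A away
        s = type(system)(
            names=system.names, elements=system.elements, radii=system.radii,
            charges=system.charges.copy(), lj_eps=system.lj_eps.copy(),
            lj_rmin_half=system.lj_rmin_half, groups=system.groups,
        )
        guest = s.group("guest")
        s.charges[guest] = 0.0
        s.lj_eps[guest] = 0.0
        frame = xyz.copy()
        frame[guest] += [100.0, 0.0, 0.0]
        traj = Trajectory(np.repeat(frame[None], 4, axis=0), 10.0)
        ledger = mmgbsa_single_trajectory(s, traj, TdS=0.0, window_ns=40.0,
                                          n_snapshots=4, sasa_points=240)
        for key in ("dE_vdw", "dE_ele", "dG_solv_polar", "dG_solv_nonpolar",
                    "dG_bind"):
            assert abs(ledger.mean[key]) < 1e-6, key

    def test_delta_terms_reduce_to_cross_interactions(self, toy, short_traj):
        system, _ = toy
        traj = Trajectory(short_traj.coords[:3], 10.0)
        ledger = mmgbsa_single_trajectory(system, traj, TdS=0.0,
                                          window_ns=30.0, n_snapshots=3,
                                          sasa_points=120)
        direct_vdw = direct_ele = 0.0
        for t in range(3):
            ev, ee = pair_energies(system, traj.coords[t], "host", "guest")
            direct_vdw += ev / 3
            direct_ele += ee / 3
        assert ledger.mean["dE_vdw"] == pytest.approx(direct_vdw, abs=1e-8)
        assert ledger.mean["dE_ele"] == pytest.approx(direct_ele, abs=1e-8)

    def test_identical_replicates_have_zero_sem(self, toy, short_traj):
        system, _ = toy
        traj = Trajectory(short_traj.coords[:3], 10.0)
        ledger = mmgbsa_single_trajectory(system, [traj, traj, traj],
                                          TdS=-5.0, window_ns=30.0,
                                          n_snapshots=3, sasa_points=120)
        assert all(abs(v) < 1e-12 for v in ledger.sem.values())

    def test_window_shorter_than_snapshots_rejected(self, toy, short_traj):
        system, _ = toy
        with pytest.raises(SamplingError):
            mmgbsa_single_trajectory(system, short_traj, TdS=0.0,
                                     window_ns=0.1, n_snapshots=300)

    def test_replicate_aggregation_keeps_identities_exact(self, toy):
        system, xyz = toy
        reps = simulate_replicates(system, xyz,
                                   ScenarioSpec(n_frames=60, timestep_label=1.0,
                                                seed=8), 3)
        ledger = mmgbsa_single_trajectory(system, reps, TdS=-17.7,
                                          window_ns=10.0, n_snapshots=5,
                                          sasa_points=120)
        report = verify_ledger(ledger, tol=1e-9)
        assert not report["flagged"].any()


class TestLedgerVerification:
    @pytest.mark.parametrize("column", sorted(TABLE_COLUMNS))
    def test_published_columns_are_additive_to_print_precision(self, column):
        report = verify_ledger(TABLE_COLUMNS[column], tol=0.01)
        assert len(report) == 5
        assert not report["flagged"].any()
        assert report["residual_kcal_mol"].max() <= 0.01 + 1e-9

    def test_corrupted_solvation_row_is_flagged(self):
        bad = dict(TABLE_COLUMNS["beta"])
        bad["dG_solv"] += 0.5
        report = verify_ledger(bad, tol=0.01)
        assert report.set_index("identity").loc[
            "dG_solv = dG_solv_polar + dG_solv_nonpolar", "flagged"]

    def test_exact_ledger_has_zero_residuals(self):
        exact = {"dE_vdw": -27.0, "dE_ele": -12.0, "dE_MM": -39.0,
                 "dG_solv_polar": 22.0, "dG_solv_nonpolar": -3.0,
                 "dG_solv": 19.0, "TdS": -17.0, "dG_bind": -3.0}
        report = verify_ledger(exact, tol=1e-12)
        assert not report["flagged"].any()
        assert report["residual_kcal_mol"].max() == 0.0
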