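import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fomotor.constants import KB, LN10, pn_nm_to_kcal_mol
from fomotor.topology_energy import (
    MembraneGeometry, ProtonationState, make_topology, net_torque_z,
    pka_energy, restraint_and_torque_forces, structure_forces, total_energy,
    total_forces, v_mem_switch,
)
from dataclasses import replace


def all_protonated(top):
    return ProtonationState(np.ones(top.n_sites, dtype=np.int8))


class TestEnergyBreakdown:
    def test_all_protonated_sites_carry_no_charge(self, fixture_structure,
                                                  fixture_topology):
        """With every site protonated (q_i = h_i - 1 = 0) the membrane term
        vanishes and the Coulomb term involves only the gate arginine."""
        top = fixture_topology
        H = all_protonated(top)
        e = total_energy(fixture_structure.coords, H, top)
        assert e["membrane"] == 0.0
        assert e["coulomb"] == 0.0  # only one charged bead left (aR176)

    def test_deep_lipid_deprotonated_carrier_costs_eps_mem(
            self, fixture_structure, fixture_topology):
        top = fixture_topology
        H = all_protonated(top)
        # rotate the ring so carrier c1 sits deep in the lipid phase
        occ = H.occupancy.copy()
        occ[0] = 0
        H = ProtonationState(occ)
        R = fixture_structure.coords.copy()
        ring = top.ring_beads
        a = np.deg2rad(150.0)
        rot = np.array([[np.cos(a), -np.sin(a), 0],
                        [np.sin(a), np.cos(a), 0], [0, 0, 1.0]])
        R[ring] = R[ring] @ rot.T
        e = total_energy(R, H, top)
        assert e["membrane"] == pytest.approx(10.0)

    def test_coulomb_pair_value(self, fixture_structure, fixture_topology):
        """Two unit charges at 1.0 nm in dielectric 10:
        -332.0637/(10*10) = -3.3206 kcal/mol."""
        top = fixture_topology
        H = all_protonated(top)
        base = total_energy(fixture_structure.coords, H, top)["coulomb"]
        occ = H.occupancy.copy()
        occ[0] = 0  # c1 now -1; only partner is aR176 (+1)
        H2 = ProtonationState(occ)
        R = fixture_structure.coords.copy()
        b_c1 = int(top.site_beads[0])
        b_arg = top.r176_bead
        # place the pair at exactly 1.0 nm, far from the membrane wedge
        R[b_c1] = [50.0, 0.0, 0.0]
        R[b_arg] = [51.0, 0.0, 0.0]
        e = total_energy(R, H2, top)["coulomb"]
        assert e - base == pytest.approx(-332.0637 / (10.0 * 10.0), abs=1e-4)

    def test_overlapping_charges_error(self, fixture_structure, fixture_topology):
        top = fixture_topology
        occ = np.ones(top.n_sites, dtype=np.int8)
        occ[0] = 0
        R = fixture_structure.coords.copy()
        R[int(top.site_beads[0])] = R[top.r176_bead]
        with pytest.raises(ValueError, match="overlap"):
            total_energy(R, ProtonationState(occ), top)


class TestMembraneSwitch:
    def test_branches(self):
        assert v_mem_switch(-0.1, 0.4) == 0.0
        assert v_mem_switch(0.4, 0.4) == 1.0
        assert v_mem_switch(0.2, 0.4) == pytest.approx(0.5)
        assert v_mem_switch(0.2, 0.4) == pytest.approx(
            0.5 * (1 - np.cos(np.pi / 2)))

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(-1.0, 1.0))
    def test_bounded_and_monotone(self, x):
        d = 0.4
        v = v_mem_switch(x, d)
        assert 0.0 <= v <= 1.0
        assert v_mem_switch(x + 0.01, d) >= v

    def test_printed_form_retained_for_comparison(self):
        # the legacy form does not reach 1 continuously at x = d
        assert v_mem_switch(0.39999, 0.4, printed_form=True) != pytest.approx(
            1.0, abs=0.1)


class TestPkaEnergy:
    def test_values(self):
        H0 = ProtonationState(np.zeros(3, dtype=np.int8))
        assert pka_energy(H0, np.array([8.0, 6.0, 9.0]), 323.0) == 0.0
        H1 = ProtonationState(np.array([1, 0, 0]))
        expected = -LN10 * KB * 323.0 * 8.0
        assert pka_energy(H1, np.array([8.0, 6.0, 9.0]), 323.0) == \
            pytest.approx(expected)
        assert expected == pytest.approx(-11.822, abs=2e-3)

    def test_larger_pka_lowers_energy_more(self):
        pka = np.array([8.0, 9.0])
        e8 = pka_energy(ProtonationState(np.array([1, 0])), pka, 323.0)
        e9 = pka_energy(ProtonationState(np.array([0, 1])), pka, 323.0)
        assert e9 < e8 < 0


class TestStructureForces:
    def test_zero_at_reference(self, fixture_structure, fixture_topology):
        f = structure_forces(fixture_structure.coords, fixture_topology,
                             include_ev=False)
        assert np.abs(f).max() < 1e-6

    def test_stretched_bond_restoring_force(self, fixture_structure,
                                            fixture_topology):
        # isolate the bond term: all other interactions stripped
        top = replace(
            fixture_topology,
            angles=np.zeros((0, 3), dtype=np.int64), angle_k=np.zeros(0),
            angle_t0=np.zeros(0),
            dihedrals=np.zeros((0, 4), dtype=np.int64),
            dihedral_k1=np.zeros(0), dihedral_k3=np.zeros(0),
            dihedral_p0=np.zeros(0),
            contacts=np.zeros((0, 2), dtype=np.int64),
            contact_eps=np.zeros(0), contact_r0=np.zeros(0),
            bonds=fixture_topology.bonds[:1],
            bond_k=fixture_topology.bond_k[:1],
            bond_r0=fixture_topology.bond_r0[:1])
        i, j = top.bonds[0]
        R = fixture_structure.coords.copy()
        u = (R[j] - R[i]) / np.linalg.norm(R[j] - R[i])
        delta = 0.01
        R[j] = R[j] + u * delta
        f = structure_forces(R, top, include_ev=False)
        # V = k dr^2 -> |F| = 2 k dr along the bond
        expect = 2.0 * top.bond_k[0] * delta
        assert np.dot(f[j], -u) == pytest.approx(expect, rel=1e-3)

    def test_forces_match_finite_difference(self, fixture_structure,
                                            fixture_topology, rng):
        top = fixture_topology
        H = top.initial_protonation()
        R = fixture_structure.coords + 0.01 * rng.standard_normal(
            fixture_structure.coords.shape)
        f = total_forces(R, H, top)
        eps = 1e-6
        for i in rng.integers(0, top.n_beads, 6):
            for d in range(3):
                Rp, Rm = R.copy(), R.copy()
                Rp[i, d] += eps
                Rm[i, d] -= eps
                ep = total_energy(Rp, H, top)
                em = total_energy(Rm, H, top)
                num = -((ep["total"] - ep["pka"])
                        - (em["total"] - em["pka"])) / (2 * eps)
                denom = max(abs(num), abs(f[i, d]), 1e-8)
                assert abs(f[i, d] - num) / denom < 1e-5

    def test_nan_coordinates_rejected(self, fixture_structure, fixture_topology):
        R = fixture_structure.coords.copy()
        R[0, 0] = np.nan
        with pytest.raises(ValueError):
            total_energy(R, all_protonated(fixture_topology), fixture_topology)


class TestRestraintsAndTorque:
    def test_zero_torque_zero_force(self, fixture_structure, fixture_topology):
        f = restraint_and_torque_forces(fixture_structure.coords,
                                        fixture_topology)
        tb = fixture_topology.torque_beads
        assert np.abs(f[tb]).max() < 1e-9  # reference circle, no torque

    def test_net_torque_equals_configured_value(self, fixture_structure,
                                                fixture_topology, rng):
        top = replace(fixture_topology, torque_pn_nm=86.2)
        top._ref_coords = fixture_topology._ref_coords
        # arbitrary ring conformation: net torque must still be -86.2 pN nm
        R = fixture_structure.coords + 0.05 * rng.standard_normal(
            fixture_structure.coords.shape)
        f = restraint_and_torque_forces(R, top)
        f_restr = restraint_and_torque_forces(R, replace(
            top, torque_pn_nm=0.0))
        tau = net_torque_z(R, f - f_restr, top.torque_beads)
        assert tau == pytest.approx(-pn_nm_to_kcal_mol(86.2), rel=1e-9)

    def test_per_bead_torque_force_magnitude(self):
        # 86.2 pN nm over 10 beads at rho = 3 nm -> 2.873 pN each
        assert 86.2 / (10 * 3.0) == pytest.approx(2.873, abs=1e-3)

    def test_torque_near_axis_rejected(self, fixture_structure,
                                       fixture_topology):
        top = replace(fixture_topology, torque_pn_nm=10.0)
        top._ref_coords = fixture_topology._ref_coords
        R = fixture_structure.coords.copy()
        R[top.torque_beads[0], :2] = [0.01, 0.0]
        with pytest.raises(ValueError, match="tangent"):
            restraint_and_torque_forces(R, top)


class TestSymmetry:
    def test_tenfold_rotation_with_state_shift_preserves_energy(
            self, fixture_structure, fixture_topology):
        top = fixture_topology
        occ = top.initial_protonation().occupancy
        R = fixture_structure.coords.copy()
        e0 = total_energy(R, ProtonationState(occ), top)["total"]
        a = np.deg2rad(36.0)
        rot = np.array([[np.cos(a), -np.sin(a), 0],
                        [np.sin(a), np.cos(a), 0], [0, 0, 1.0]])
        R2 = R.copy()
        R2[top.ring_beads] = R[top.ring_beads] @ rot.T
        # CCW rotation by one subunit spacing: c2 moves into c1's old
        # position (numbering is clockwise), so the occupancy pattern over
        # positions is preserved by occ2[s] = occ[s-1]
        occ2 = occ.copy()
        occ2[:10] = np.roll(occ[:10], 1)
        e1 = total_energy(R2, ProtonationState(occ2), top)["total"]
        assert e1 == pytest.approx(e0, abs=1e-6)


class TestProtonationState:
    def test_entries_validated(self):
        with pytest.raises(ValueError):
            ProtonationState(np.array([0, 2, 1]))

    def test_charges(self):
        H = ProtonationState(np.array([1, 0]))
        np.testing.assert_allclose(H.charges(), [0.0, -1.0])

    def test_registry_size_mismatch_rejected(self, fixture_topology):
        with pytest.raises(ValueError, match="11"):
            fixture_topology.charges(ProtonationState(np.ones(11)))
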