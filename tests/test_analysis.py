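import numpy as np
import pytest

from fomotor import analysis
from fomotor.constants import kbt, pn_nm_to_kcal_mol
from fomotor.proton_mc import ProtonEvent
from fomotor.synthetic_validation import make_synthetic_logs


class TestRotationAngle:
    def test_initial_frame_is_zero(self, fixture_structure, fixture_topology):
        b = fixture_topology.angle_bead
        az0 = np.degrees(np.arctan2(fixture_structure.coords[b, 1],
                                    fixture_structure.coords[b, 0]))
        assert analysis.rotation_angle(fixture_structure.coords, b, az0) == 0.0

    def test_rigid_rotation_by_36(self, fixture_structure, fixture_topology):
        b = fixture_topology.angle_bead
        az0 = np.degrees(np.arctan2(fixture_structure.coords[b, 1],
                                    fixture_structure.coords[b, 0]))
        a = np.deg2rad(36.0)
        rot = np.array([[np.cos(a), -np.sin(a), 0],
                        [np.sin(a), np.cos(a), 0], [0, 0, 1.0]])
        R = fixture_structure.coords @ rot.T
        assert analysis.rotation_angle(R, b, az0) == pytest.approx(36.0)

    def test_bead_on_axis_rejected(self):
        with pytest.raises(ValueError):
            analysis.rotation_angle(np.zeros((1, 3)), 0, 0.0)

    def test_incremental_unwrap_of_minus_350(self):
        """-350 deg applied in small increments unwraps to -350, not +10."""
        steps = np.linspace(0.0, -350.0, 200)
        wrapped = (steps + 180.0) % 360.0 - 180.0
        cum = analysis.unwrap_cumulative(wrapped)
        assert cum[-1] == pytest.approx(-350.0, abs=1e-9)


class TestUnwrap:
    def test_constant_series(self):
        np.testing.assert_allclose(
            analysis.unwrap_cumulative([10.0] * 5), [10.0] * 5)

    def test_sawtooth_becomes_line(self):
        truth = np.arange(0.0, 1500.0, 20.0)
        wrapped = (truth + 180.0) % 360.0 - 180.0
        cum = analysis.unwrap_cumulative(wrapped)
        np.testing.assert_allclose(np.diff(cum), 20.0, atol=1e-9)

    def test_white_noise_has_no_drift(self, rng):
        a = rng.uniform(-30, 30, size=4000)
        cum = analysis.unwrap_cumulative(a)
        assert abs(cum.mean()) < 3 * 30.0 / np.sqrt(len(a)) + 5

    def test_undersampling_warns(self):
        with pytest.warns(UserWarning, match="undersampled"):
            analysis.unwrap_cumulative([0.0, 179.999, 0.0])

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            analysis.unwrap_cumulative([])


def _linear_angles(n_stages, total):
    return np.linspace(0.0, total, n_stages + 1)


class TestClassifyItineraries:
    def test_transport_ride_288(self):
        angles = _linear_angles(100, 360.0)
        spec = {"angles": angles, "protons": [
            dict(side_in="IMS", stage_in=2, carrier="c1E59", board_stage=3,
                 unboard_stage=83, side_out="matrix", stage_out=84),
        ]}
        _, events = make_synthetic_logs(spec)
        out = analysis.classify_itineraries(events, angles)
        assert out["counts"]["transport_ims_to_matrix"] == 1

    def test_leak_ride_minus_72(self):
        angles = _linear_angles(100, -360.0)
        spec = {"angles": angles, "protons": [
            dict(side_in="IMS", stage_in=2, carrier="c1E59", board_stage=3,
                 unboard_stage=23, side_out="matrix", stage_out=24),
        ]}
        _, events = make_synthetic_logs(spec)
        out = analysis.classify_itineraries(events, angles)
        assert out["counts"]["leak_ims_to_matrix"] == 1

    def test_idle_full_turn_same_side(self):
        angles = _linear_angles(100, 360.0)
        spec = {"angles": angles, "protons": [
            dict(side_in="IMS", stage_in=1, carrier="c1E59", board_stage=2,
                 unboard_stage=99, side_out="IMS", stage_out=100),
        ]}
        _, events = make_synthetic_logs(spec)
        out = analysis.classify_itineraries(events, angles)
        assert out["counts"]["idle"] == 1

    def test_ten_transports_per_revolution_is_ten(self):
        """Tightly coupled stream: one IMS->matrix transport per 36 degrees
        gives exactly 10 per revolution."""
        angles = _linear_angles(1000, 360.0)
        # each proton rides 520 stages x 0.36 deg/stage ~ 187 deg (> 180)
        spec = {"angles": angles, "protons": [
            dict(side_in="IMS", stage_in=2 + 50 * k, carrier=f"c{k + 1}E59",
                 board_stage=3 + 50 * k, unboard_stage=3 + 50 * k + 520,
                 side_out="matrix", stage_out=4 + 50 * k + 520)
            for k in range(10)]}
        _, events = make_synthetic_logs(spec)
        out = analysis.classify_itineraries(events, angles)
        assert out["counts"]["transport_ims_to_matrix"] == 10
        assert out["per_revolution"]["transport_ims_to_matrix"] == \
            pytest.approx(10.0)

    def test_classification_is_exhaustive_and_exclusive(self):
        angles = _linear_angles(200, 720.0)
        spec = {"angles": angles, "protons": [
            dict(side_in="IMS", stage_in=2, carrier="c1E59", board_stage=3,
                 unboard_stage=103, side_out="matrix", stage_out=104),
            dict(side_in="matrix", stage_in=5, carrier="c5E59", board_stage=6,
                 unboard_stage=16, side_out="IMS", stage_out=17),
            dict(side_in="IMS", stage_in=110, carrier="c2E59",
                 board_stage=111, unboard_stage=195, side_out="IMS",
                 stage_out=196),
        ]}
        _, events = make_synthetic_logs(spec)
        out = analysis.classify_itineraries(events, angles)
        n_classified = sum(v for k, v in out["counts"].items()
                           if k != "flicker")
        assert n_classified == 3
        assert len(out["itineraries"]) == 3

    def test_contradictory_spec_rejected(self):
        with pytest.raises(ValueError, match="exit before entry"):
            make_synthetic_logs({"angles": [0, 1], "protons": [
                dict(side_in="IMS", stage_in=5, carrier="c1E59",
                     side_out="matrix", stage_out=2)]})


class TestStepCensus:
    def test_ten_well_density_yields_ten_minima(self, rng):
        # sample from a 10-fold cosine-modulated density by rejection
        n = 40000
        out = []
        while len(out) < n:
            x = rng.uniform(0, 360, 20000)
            keep = rng.uniform(0, 1, 20000) < (1 + 0.9 * np.cos(
                np.radians(10 * x - 180))) / 1.9
            out.extend(x[keep].tolist())
        census = analysis.step_census(np.array(out[:n]))
        assert census["n_minima"] == 10
        assert census["mean_spacing_deg"] == pytest.approx(36.0, abs=2.0)

    def test_uniform_density_has_no_significant_minima(self, rng):
        census = analysis.step_census(rng.uniform(0, 360, 40000))
        assert census["n_minima"] == 0

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            analysis.step_census([])


class TestPathwayCensus:
    def _angles_one_step(self):
        # window k=0 (theta in [-18, 18)), then step to k=1
        return np.array([-17.0, -10.0, -2.0, -2.0, 3.0, 3.0, 10.0, 19.0,
                         25.0, 30.0])

    def test_path1_deprotonation_before_protonation(self):
        angles = self._angles_one_step()
        events = [
            ProtonEvent(3, "hop", "c3E59", "aE162", True),   # deprot at -2
            ProtonEvent(5, "hop", "aE223", "c1E59", True),   # prot at 3
        ]
        counts = analysis.pathway_census(events, angles)
        assert counts[1] == 1 and counts[2] == 0

    def test_path2_protonation_first(self):
        angles = self._angles_one_step()
        events = [
            ProtonEvent(3, "hop", "aE223", "c1E59", True),
            ProtonEvent(5, "hop", "c3E59", "aE162", True),
        ]
        counts = analysis.pathway_census(events, angles)
        assert counts[2] == 1 and counts[1] == 0

    def test_empty_window_not_counted(self):
        angles = self._angles_one_step()
        counts = analysis.pathway_census([], angles)
        assert sum(counts.values()) == 0

    def test_rolling_frame_relabels_after_one_step(self):
        # same physical sequence one step later: molecular c4 plays slot c3
        angles = np.concatenate([self._angles_one_step(),
                                 self._angles_one_step() + 36.0])
        events = [
            ProtonEvent(13, "hop", "c4E59", "aE162", True),
            ProtonEvent(15, "hop", "aE223", "c2E59", True),
        ]
        counts = analysis.pathway_census(events, angles)
        assert counts[1] == 1


class TestFes:
    def test_flat_density_flat_curve(self, rng):
        out = analysis.state_conditioned_fes(rng.uniform(0, 36, 100000),
                                             bins=18, angle_range=(0, 36))
        F = out["free_energy_kcal_mol"]
        assert np.nanmax(F) - np.nanmin(F) < 0.05

    def test_double_well_barrier_recovered(self, rng):
        """Samples from exp(-U/kBT) with a known double well: the estimated
        barrier matches the analytic one within sampling error."""
        T = 323.0
        barrier = 1.2

        def U(x):
            return barrier * 0.5 * (1 - np.cos(2 * np.pi * x / 18.0))

        xs = []
        while len(xs) < 60000:
            x = rng.uniform(0, 36, 30000)
            keep = rng.uniform(0, 1, 30000) < np.exp(-U(x) / kbt(T))
            xs.extend(x[keep].tolist())
        out = analysis.state_conditioned_fes(np.array(xs[:60000]), bins=36,
                                             angle_range=(0, 36),
                                             temperature=T)
        F = out["free_energy_kcal_mol"]
        est = np.nanmax(F) - np.nanmin(F)
        assert est == pytest.approx(barrier, abs=0.12)

    def test_torque_tilt_shifts_quadratic_minimum(self, rng):
        """Adding -tau*theta to F = 0.5 k theta^2 moves the minimum to
        tau/k (analytic)."""
        T = 323.0
        k = 0.005   # kcal/mol/deg^2
        xs = rng.normal(0.0, np.sqrt(kbt(T) / k), 200000)
        xs = xs[np.abs(xs) < 60]
        tau = 86.2
        out = analysis.state_conditioned_fes(xs, bins=60,
                                             angle_range=(-60, 60),
                                             temperature=T,
                                             torque_pn_nm=tau)
        F = out["free_energy_kcal_mol"]
        th = out["angle_deg"]
        tau_kcal_per_deg = pn_nm_to_kcal_mol(tau) * np.pi / 180.0
        expect = tau_kcal_per_deg / k
        assert th[np.nanargmin(F)] == pytest.approx(expect, abs=4.0)

    def test_empty_bins_masked(self):
        out = analysis.state_conditioned_fes([1.0, 1.1, 30.0], bins=36,
                                             angle_range=(0, 36))
        assert np.isnan(out["free_energy_kcal_mol"]).any()


class TestStallAndEfficiency:
    def test_symmetric_pair_midpoint(self):
        out = analysis.stall_torque_scan([40.0, 60.0], [1.0, -1.0])
        assert out["stall_pn_nm"] == pytest.approx(50.0)
        assert out["kind"] == "interpolated"

    def test_all_positive_gives_lower_bound(self):
        out = analysis.stall_torque_scan([10.0, 40.0], [2.0, 1.0])
        assert out["kind"] == "lower_bound"
        assert out["bound_pn_nm"] == 40.0

    def test_paper_bracket_interpolates_near_fifty(self):
        out = analysis.stall_torque_scan([43.0, 51.6], [0.5, -0.4])
        assert 43.0 < out["stall_pn_nm"] < 51.6

    def test_energy_accounting_identities(self):
        """tau_stall = 50 pN nm: work/H+ = 50*2pi/10 = 31.4 pN nm =
        4.52 kcal/mol; pH term 1.48; dPsi term 3.46; total ~4.94; eta ~0.9."""
        out = analysis.efficiency(50.0, 7.0, 8.0, 150.0, 323.0)
        assert out["work_per_proton_pn_nm"] == pytest.approx(31.4, abs=0.1)
        assert out["pmf_ph_kcal_mol"] == pytest.approx(1.48, abs=0.01)
        assert out["pmf_psi_kcal_mol"] == pytest.approx(3.46, abs=0.01)
        assert out["pmf_total_kcal_mol"] == pytest.approx(4.94, abs=0.01)
        assert out["eta"] == pytest.approx(0.89, abs=0.04)

    def test_zero_psi_ph_term_only(self):
        out = analysis.efficiency(50.0, 7.0, 8.0, 0.0, 323.0)
        assert out["pmf_total_kcal_mol"] == pytest.approx(1.48, abs=0.01)

    def test_zero_stall_zero_eta(self):
        assert analysis.efficiency(0.0, 7.0, 8.0, 150.0)["eta"] == 0.0

    def test_zero_pmf_rejected(self):
        with pytest.raises(ValueError):
            analysis.efficiency(50.0, 7.0, 7.0, 0.0)


class TestNetFlux:
    def test_counts_reservoir_exchanges(self):
        events = [
            ProtonEvent(1, "reservoir", "IMS", "aE223", True),
            ProtonEvent(2, "hop", "aE223", "c1E59", True),
            ProtonEvent(3, "hop", "c1E59", "aE162", True),
            ProtonEvent(4, "reservoir", "aE162", "matrix", True),
        ]
        out = analysis.net_flux(events)
        assert out == {"net_to_matrix": 1, "net_from_ims": 1}
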