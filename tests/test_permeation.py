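import numpy as np
import pytest

from ionflux import permeation, reference, synthdata
from ionflux.io_core import ChannelGeometry, IonTrajectory, KB_KCAL
from ionflux.permeation import (CurrentEstimate, IVDataset, PermeationEvent,
                                classify_events, detect_events,
                                estimate_current, fit_conductance,
                                number_density_profile,
                                pore_crossing_count_timeseries,
                                pore_water_count, rectification_ratio,
                                vestibule_return_events)

from conftest import events_equal, random_walk_trajectory


def _scripted(paths, geom, dt=0.1):
    return synthdata.scripted_trajectory(paths, dt=dt, geometry=geom)


class TestDetectEvents:
    def test_single_inward(self, geom):
        traj, _ = _scripted([(np.array([0.0, 10.0]),
                              np.array([[0.5, 0, 35.0], [0.5, 0, -35.0]]))],
                            geom)
        ev = detect_events(traj, geom)
        assert len(ev) == 1 and ev[0].direction == "inward"
        assert ev[0].entry_ns < ev[0].exit_ns

    def test_enter_and_return(self, geom):
        mid = 0.5 * (geom.z_lower + geom.z_upper)
        traj, _ = _scripted([(np.array([0.0, 5.0, 10.0]),
                              np.array([[0, 0, -30.0], [0, 0, mid],
                                        [0, 0, -30.0]]))], geom)
        assert detect_events(traj, geom) == []

    def test_off_axis_transit_rejected(self, geom):
        # crosses both planes but outside the pore cylinder: not an event
        r = geom.r_pore + 3.0
        traj, _ = _scripted([(np.array([0.0, 10.0]),
                              np.array([[r, 0, 35.0], [r, 0, -35.0]]))], geom)
        assert detect_events(traj, geom) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_oracle(self, geom, seed):
        traj = random_walk_trajectory(seed)
        assert events_equal(detect_events(traj, geom),
                            reference.oracle_events(traj, geom))

    def test_buffer_margin_suppresses_jitter(self, geom):
        # ion hovering across z_upper: strict detection sees nothing (it
        # never reaches the far plane); jitter must not create events either
        z = geom.z_upper
        t = np.arange(8, dtype=float)
        wig = np.array([[0, 0, z + 1], [0, 0, z - 1]] * 4)
        traj, _ = _scripted([(t, wig)], geom)
        assert detect_events(traj, geom, buffer=2.0) == []

    def test_time_reversal_swaps_directions(self, geom):
        traj = random_walk_trajectory(99)
        fwd = detect_events(traj, geom)
        rev = IonTrajectory(times=traj.times,
                            box=traj.box[::-1].copy(),
                            positions=traj.positions[:, ::-1].copy(),
                            ion_ids=traj.ion_ids)
        bwd = detect_events(rev, geom)
        assert len(fwd) == len(bwd)
        assert (sum(e.direction == "outward" for e in fwd)
                == sum(e.direction == "inward" for e in bwd))
        i_f = estimate_current(fwd, traj.duration).current
        i_b = estimate_current(bwd, traj.duration).current
        assert i_f == pytest.approx(-i_b)

    def test_geometry_outside_box_rejected(self, geom):
        traj = random_walk_trajectory(0, box=(30.0, 30.0, 30.0))
        with pytest.raises(ValueError, match="primary box"):
            detect_events(traj, geom)


class TestPathwayClassification:
    def test_scripted_routes_match_construction(self, geom):
        paths, labels = synthdata.mixed_route_paths(200, seed=11,
                                                    geometry=geom)
        traj, _ = _scripted(paths, geom, dt=0.05)
        ev = classify_events(detect_events(traj, geom), traj, geom)
        by_ion = {e.ion_id: e for e in ev}
        assert len(ev) == 200
        for i, (d, p, s) in enumerate(labels):
            e = by_ion[i]
            assert (e.direction, e.pathway) == (d, p)
            if p == "lateral":
                assert e.sector == s

    def test_counts_conserved_under_classification(self, geom):
        paths, _ = synthdata.mixed_route_paths(100, seed=13, geometry=geom)
        traj, _ = _scripted(paths, geom, dt=0.05)
        ev = classify_events(detect_events(traj, geom), traj, geom)
        n_ap = sum(e.pathway == "apical" for e in ev)
        n_lat = sum(e.pathway == "lateral" for e in ev)
        n_un = sum(e.pathway == "unassigned" for e in ev)
        assert n_ap + n_lat + n_un == len(ev)
        assert n_un == 0

    def test_sector_counts_sum_to_lateral_total(self, geom):
        paths, _ = synthdata.mixed_route_paths(150, seed=17, geometry=geom)
        traj, _ = _scripted(paths, geom, dt=0.05)
        ev = classify_events(detect_events(traj, geom), traj, geom)
        lat = [e for e in ev if e.pathway == "lateral"]
        per_sector = [sum(e.sector == s for e in lat)
                      for s in range(geom.n_sectors)]
        assert sum(per_sector) == len(lat)

    @pytest.mark.parametrize("azimuth_deg, expected", [(10.0, 0), (350.0, 4)])
    def test_sector_binning(self, geom, azimuth_deg, expected):
        th = np.radians(azimuth_deg)
        zf = 0.5 * (geom.z_fen_lo + geom.z_fen_hi)
        wp = np.array([
            [20 * np.cos(th), 20 * np.sin(th), zf],
            [6 * np.cos(th), 6 * np.sin(th), zf],
            [0.3, 0.0, geom.z_upper + 1.5],
            [0.3, 0.0, geom.z_lower - 6.0]])
        traj, _ = _scripted([(np.linspace(0, 9, 4), wp)], geom, dt=0.05)
        ev = classify_events(detect_events(traj, geom), traj, geom)
        assert len(ev) == 1
        assert ev[0].pathway == "lateral"
        assert ev[0].sector == expected

    def test_fenestration_requires_lateral(self, geom):
        ev = PermeationEvent(ion_id=0, entry_ns=0.0, exit_ns=1.0,
                             direction="inward", pathway="apical")
        traj = random_walk_trajectory(0)
        with pytest.raises(ValueError, match="lateral"):
            permeation.assign_fenestration(ev, traj, geom)


class TestCurrents:
    def test_one_sodium_per_ns(self):
        ev = [PermeationEvent(ion_id=0, entry_ns=0.0, exit_ns=0.5,
                              direction="outward")]
        cur = estimate_current(ev, time_ns=1.0, z_ion=1)
        assert cur.current == pytest.approx(160.2176634, abs=1e-4)

    def test_balanced_flux_is_zero(self):
        ev = [PermeationEvent(0, 0.0, 0.5, "outward"),
              PermeationEvent(1, 0.1, 0.6, "inward")]
        assert estimate_current(ev, 10.0).current == 0.0
        assert estimate_current(ev, 10.0, gross=True).current != 0.0

    def test_chloride_sign(self):
        ev = [PermeationEvent(i, 0.0, 0.5, "outward") for i in range(15)]
        cur = estimate_current(ev, time_ns=150.0, z_ion=-1)
        assert cur.current == pytest.approx(-16.02, abs=0.01)

    def test_zero_time_rejected(self):
        with pytest.raises(ValueError):
            estimate_current([], time_ns=0.0)


class TestConductanceFit:
    @staticmethod
    def _iv(voltages, slope_pa_per_mv):
        pts = [CurrentEstimate(dv_m=v, current=slope_pa_per_mv * v, n_out=0,
                               n_in=0, time_ns=1.0) for v in voltages]
        return IVDataset(points=pts)

    def test_exact_ohmic_line(self):
        iv = self._iv([-250, -100, 0, 100, 250], 0.1)
        fit = fit_conductance(iv)
        assert fit.gamma_o == pytest.approx(100.0)
        assert fit.gamma_i == pytest.approx(100.0)
        assert fit.ratio == pytest.approx(1.0)
        assert fit.se_o == pytest.approx(0.0, abs=1e-9)

    def test_insufficient_polarity_rejected(self):
        iv = self._iv([0, 100, 250], 0.1)
        with pytest.raises(ValueError, match="polarity|voltages"):
            fit_conductance(iv)

    def test_noisy_ohmic_within_2_se(self):
        rng = np.random.default_rng(4)
        pts = []
        for v in (-250, -100, 0, 100, 250):
            for rep in range(3):
                pts.append(CurrentEstimate(
                    dv_m=v, current=0.1 * v + rng.normal(0, 2.0),
                    n_out=0, n_in=0, time_ns=1.0, replicate=rep))
        fit = fit_conductance(IVDataset(points=pts))
        assert abs(fit.gamma_o - 100.0) < 2 * fit.se_o
        assert abs(fit.gamma_i - 100.0) < 2 * fit.se_i


class TestRectificationRatio:
    @pytest.mark.parametrize("go, gi, expected", [
        (85.5, 21.0, 4.07),     # strongly outward-rectifying
        (70.29, 20.54, 3.42),   # lateral-pathway double mutant
        (50.0, 50.0, 1.00),     # Ohmic
    ])
    def test_printed_pairs(self, go, gi, expected):
        assert round(rectification_ratio(go, gi), 2) == expected

    def test_zero_inward_rejected(self):
        with pytest.raises(ZeroDivisionError):
            rectification_ratio(10.0, 0.0)


class TestVestibuleReturn:
    def test_trapped_ion_counted(self, geom):
        # up through the gate, lingers in the vestibule, back down: 1 return
        t = np.linspace(0, 12, 5)
        wp = np.array([[0.2, 0, -26.0], [0.2, 0, 8.0], [0.4, 0, 10.0],
                       [0.2, 0, 8.0], [0.2, 0, -26.0]])
        traj, _ = _scripted([(t, wp)], geom)
        assert vestibule_return_events(traj, geom) == 1

    def test_bulk_visit_breaks_pair(self, geom):
        t = np.linspace(0, 16, 6)
        wp = np.array([[0.2, 0, -26.0], [0.2, 0, 8.0], [0.3, 0, 26.0],
                       [0.2, 0, 35.0], [0.2, 0, 8.0], [0.2, 0, -26.0]])
        traj, _ = _scripted([(t, wp)], geom)
        assert vestibule_return_events(traj, geom) == 0

    def test_matches_oracle_count_on_ensemble(self, geom):
        spec = synthdata.SimSpec(mode="channel", duration=15.0, n_ions=30,
                                 e_z=250 / 80.0, seed=31, save_every=2)
        traj, _ = synthdata.langevin_channel_sim(spec)
        events = reference.oracle_events(traj, geom)
        # brute-force recount from the oracle events and bulk occupancy
        bulk, _, _ = permeation._ecd_region_masks(traj, geom)
        expected = 0
        by_ion = {}
        for e in sorted(events, key=lambda x: x.exit_ns):
            by_ion.setdefault(e.ion_id, []).append(e)
        for ion, evs in by_ion.items():
            idx = int(np.flatnonzero(traj.ion_ids == ion)[0])
            for e1, e2 in zip(evs[:-1], evs[1:]):
                if e1.direction == "outward" and e2.direction == "inward":
                    if not bulk[idx, e1.exit_frame:e2.entry_frame + 1].any():
                        expected += 1
        assert vestibule_return_events(traj, geom) == expected


class TestDensityProfile:
    def test_uniform_ions_ratio_one(self, geom):
        rng = np.random.default_rng(7)
        n_frames, n_ions = 200, 50
        pos = rng.uniform(-20, 20, (n_ions, n_frames, 3))
        pos[:, :, 2] = rng.uniform(-40, 40, (n_ions, n_frames))
        traj = IonTrajectory(times=np.arange(n_frames, dtype=float),
                             box=np.tile((40, 40, 80.0), (n_frames, 1)),
                             positions=pos, ion_ids=np.arange(n_ions))
        centers, mean, sd = number_density_profile(
            traj, geom, bin_width=4.0, bulk_band=(24.0, 38.0))
        assert np.all(np.abs(mean - 1.0) < 0.25)

    def test_excluded_band_is_zero(self, geom):
        rng = np.random.default_rng(8)
        pos = rng.uniform(-10, 10, (20, 100, 3))
        pos[:, :, 2] = np.where(pos[:, :, 2] > 0,
                                pos[:, :, 2] + 20, pos[:, :, 2] - 10)
        traj = IonTrajectory(times=np.arange(100.0),
                             box=np.tile((40, 40, 80.0), (100, 1)),
                             positions=pos, ion_ids=np.arange(20))
        centers, mean, _ = number_density_profile(
            traj, geom, bin_width=2.0, bulk_band=(22.0, 28.0))
        gap = (centers > 2.0) & (centers < 8.0)
        assert np.all(mean[gap] == 0.0)

    def test_boltzmann_weights_recovered(self, geom):
        # tube ions in U(z) = ½kz²: density ratio must follow exp(-U/kT)
        k_spring = 0.1
        zk = np.linspace(-38, 38, 153)
        spec = synthdata.SimSpec(duration=300.0, n_ions=12, seed=44,
                                 save_every=10,
                                 u_profile=(zk, 0.5 * k_spring * zk ** 2))
        traj, _ = synthdata.langevin_channel_sim(spec)
        kt = KB_KCAL * spec.temperature
        centers, mean, _ = number_density_profile(
            traj, geom, bin_width=2.0, bulk_band=(-1.0, 1.0))
        inner = np.abs(centers) < 8
        expect = np.exp(-0.5 * k_spring * centers[inner] ** 2 / kt)
        assert np.allclose(mean[inner], expect, atol=0.15)

    def test_empty_bulk_band_rejected(self, geom):
        traj = random_walk_trajectory(1)
        with pytest.raises(ValueError):
            number_density_profile(traj, geom, bulk_band=(10.0, 10.0))


class TestOccupancyTimeseries:
    def test_cumulative_reaches_three(self, geom):
        paths = [(np.array([3.0 * i, 3.0 * i + 3.0]),
                  np.array([[0.3, 0, 35.0], [0.3, 0, -35.0]]))
                 for i in range(3)]
        traj, _ = _scripted(paths, geom)
        times, cum = pore_crossing_count_timeseries(traj, geom)
        assert cum[-1] == 3
        assert np.all(np.diff(cum) >= 0)

    def test_empty_pore_occupancy_zero(self, geom):
        pos = np.full((2, 10, 3), 30.0)
        traj = IonTrajectory(times=np.arange(10.0),
                             box=np.tile((80, 80, 80.0), (10, 1)),
                             positions=pos, ion_ids=[0, 1])
        assert np.all(pore_water_count(traj, geom) == 0)

    def test_cumulative_matches_oracle(self, geom):
        traj = random_walk_trajectory(23)
        _, cum = pore_crossing_count_timeseries(traj, geom)
        assert np.array_equal(cum,
                              reference.oracle_cumulative_crossings(traj, geom))
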