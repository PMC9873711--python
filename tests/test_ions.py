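"""Ion traces, occupancy/density, permeation events, bursts, pathways, residence."""

import numpy as np
import pandas as pd
import pytest

from permeoscope import ions as I
from permeoscope.geometry import PoreGeometry
from permeoscope.io import Topology

from conftest import make_trajectory


def _traces_from_z(z_series, box_z=70.0, dt=1.0, radius=10.0):
    """Build an IonTraces object directly from per-ion z arrays (on-axis ions)."""
    z = np.asarray(z_series, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    f, n = z.shape
    return I.IonTraces(
        ids=np.arange(n) + 2001,
        z=z,
        z_unwrapped=_unwrap(z, box_z),
        xy=np.zeros((f, n, 2)),
        inside=(z > -40) & (z < 20),
        times=np.arange(f, dtype=float) * dt,
        box_z=np.full(f, box_z),
    )


def _unwrap(z, box_z):
    dz = np.diff(z, axis=0)
    dz -= box_z * np.round(dz / box_z)
    return np.vstack([z[:1], z[:1] + np.cumsum(dz, axis=0)])


class TestTraces:
    def test_inside_pore_flags(self, wet_analysis):
        traces = wet_analysis["traces"]
        geo = wet_analysis["geometry"]
        # brute-force recount of in-pore ions frame by frame
        topo, traj = wet_analysis["topology"], wet_analysis["trajectory"]
        ion_idx = np.flatnonzero(topo.ion_mask())
        for f in [0, traces.n_frames // 2, traces.n_frames - 1]:
            pos = traj.coords[f, ion_idx]
            z = pos[:, 2] - geo.z_origin[f]
            r = np.linalg.norm(pos[:, :2] - geo.center_xy[f], axis=1)
            expected = ((r < geo.radius[f]) & (z > -40) & (z < 20)).sum()
            assert traces.inside[f].sum() == expected

    def test_radial_exclusion(self):
        # an ion at 1.5x the cylinder radius is never inside
        geo = PoreGeometry(np.zeros(3), np.zeros((3, 2)), np.full(3, 10.0))
        topo = Topology(
            names=np.array(["CLA"]),
            elements=np.array(["CL"]),
            resnames=np.array(["CLA"]),
            resids=np.array([2001]),
            chains=np.array(["I"]),
            radii=np.array([1.75]),
        )
        coords = np.tile(np.array([[15.0, 0.0, -10.0]]), (3, 1, 1))
        traces = I.extract_ion_traces(make_trajectory(coords), topo, geo)
        assert not traces.inside.any()

    def test_unwrapped_continuity(self, wet_analysis):
        traces = wet_analysis["traces"]
        du = np.abs(np.diff(traces.z_unwrapped, axis=0))
        assert (du < traces.box_z[1:, None] / 2).all()


class TestOccupancyAndDensity:
    def test_constant_occupancy(self):
        traces = _traces_from_z(np.full((50, 2), -10.0))
        occ = I.occupancy_distribution(traces, region=(-40, -5))
        assert occ.probabilities[2] == 1.0
        assert occ.mean == 2.0

    def test_histogram_mean_identity(self, wet_analysis):
        occ = I.occupancy_distribution(wet_analysis["traces"], region=(-40, -5))
        mean_from_hist = sum(k * p for k, p in occ.probabilities.items())
        assert mean_from_hist == pytest.approx(occ.mean, abs=1e-12)

    def test_empty_region_rejected(self, wet_analysis):
        with pytest.raises(ValueError, match="empty"):
            I.occupancy_distribution(wet_analysis["traces"], region=(-5, -5))

    def test_single_pinned_ion_density(self):
        traces = _traces_from_z(np.full(30, -0.5))
        prof = I.axial_density(traces, bin_width=1.0)
        occupied = np.flatnonzero(prof.rho > 0)
        assert len(occupied) == 1
        assert prof.rho[occupied[0]] == pytest.approx(1.0)
        assert prof.cumulative[-1] == pytest.approx(1.0)

    def test_density_integral_equals_mean_occupancy(self, wet_analysis):
        traces = wet_analysis["traces"]
        prof = I.axial_density(traces, bin_width=1.0)
        mean_occ = traces.region_counts((-40, 20)).mean()
        assert np.sum(prof.rho) * 1.0 == pytest.approx(mean_occ, abs=1e-9)
        assert (np.diff(prof.cumulative) >= -1e-12).all()


class TestEventDetection:
    def test_monotone_outward_trace(self):
        traces = _traces_from_z(np.linspace(-30, 15, 40))
        events = I.detect_permeation_events(traces)
        assert len(events) == 1
        assert events[0].direction == +1
        assert events[0].frame_enter < events[0].frame_exit

    def test_recrossing_rejected(self):
        z = -19.0 + 11.0 * np.sin(np.linspace(0, 8 * np.pi, 200))  # oscillates -30..-8
        events = I.detect_permeation_events(_traces_from_z(z))
        assert events == []

    def test_inward_event_direction(self):
        traces = _traces_from_z(np.linspace(15, -30, 40))
        events = I.detect_permeation_events(traces)
        assert len(events) == 1 and events[0].direction == -1

    def test_time_reversal_antisymmetry(self, wet_analysis):
        traces = wet_analysis["traces"]
        fwd = I.detect_permeation_events(traces)
        rev = I.detect_permeation_events(
            I.IonTraces(
                ids=traces.ids,
                z=traces.z[::-1],
                z_unwrapped=traces.z_unwrapped[::-1],
                xy=traces.xy[::-1],
                inside=traces.inside[::-1],
                times=traces.times,
                box_z=traces.box_z,
            )
        )
        assert len(fwd) == len(rev)
        assert sum(e.direction for e in fwd) == -sum(e.direction for e in rev)

    def test_matches_generator_truth(self, wet_analysis):
        events = I.detect_permeation_events(wet_analysis["traces"])
        assert len(events) == wet_analysis["truth"].crossing_count()
        assert len(events) > 0

    def test_net_flux_equals_boundary_wrap_count(self, wet_analysis):
        """Winding oracle: net events equal the net periodic wraps per trace."""
        traces = wet_analysis["traces"]
        events = I.detect_permeation_events(traces)
        net = sum(e.direction for e in events)
        wraps = np.round(
            ((traces.z_unwrapped[-1] - traces.z_unwrapped[0]) - (traces.z[-1] - traces.z[0]))
            / traces.box_z[0]
        ).astype(int)
        assert net == wraps.sum()

    def test_planes_must_be_inside_pore(self, wet_analysis):
        with pytest.raises(ValueError, match="inside the pore"):
            I.detect_permeation_events(wet_analysis["traces"], z_low=-50.0, z_high=10.0)


class TestBursts:
    def test_gap_clustering(self):
        traces = _traces_from_z(np.linspace(-30, 15, 40))
        ev = I.detect_permeation_events(traces)

        def fake(frame):
            return I.PermeationEvent(ion_id=1, ion_column=0, frame_enter=frame - 1, frame_exit=frame, direction=1)

        times = np.arange(1000, dtype=float)
        events = [fake(10), fake(50), fake(900)]
        bursts = I.detect_bursts(events, times, gap=100.0)
        assert [b.size for b in bursts] == [2, 1]

    def test_no_events(self):
        assert I.detect_bursts([], np.arange(10.0), gap=100.0) == []

    def test_chain_rule_single_burst(self):
        def fake(frame):
            return I.PermeationEvent(ion_id=1, ion_column=0, frame_enter=frame - 1, frame_exit=frame, direction=1)

        times = np.arange(1000, dtype=float)
        events = [fake(10), fake(90), fake(170), fake(240)]
        bursts = I.detect_bursts(events, times, gap=100.0)
        assert len(bursts) == 1 and bursts[0].size == 4

    def test_order_permutation_invariance(self):
        def fake(frame):
            return I.PermeationEvent(ion_id=1, ion_column=0, frame_enter=frame - 1, frame_exit=frame, direction=1)

        times = np.arange(1000, dtype=float)
        events = [fake(f) for f in (10, 900, 50, 400)]
        a = I.detect_bursts(events, times, gap=100.0)
        b = I.detect_bursts(events[::-1], times, gap=100.0)
        assert sorted(bb.t_start for bb in a) == sorted(bb.t_start for bb in b)


class TestPathways:
    @staticmethod
    def _constructed_event(system, angle_deg):
        """Place an exit trace along a chosen xy bearing; return its label."""
        from permeoscope.geometry import pore_geometry_per_frame

        topo, traj = system.topology, system.trajectory
        geo = pore_geometry_per_frame(traj, topo)
        n = 20
        z = np.concatenate([np.linspace(-30, 2, n // 2), np.linspace(3, 15, n - n // 2)])
        th = np.deg2rad(angle_deg)
        xy = np.tile(geo.center_xy[0] + 6.0 * np.array([np.cos(th), np.sin(th)]), (n, 1))
        traces = I.IonTraces(
            ids=np.array([2001]),
            z=z[:, None],
            z_unwrapped=z[:, None],
            xy=xy[:, None, :],
            inside=np.ones((n, 1), bool),
            times=np.arange(n, dtype=float),
            box_z=np.full(n, 70.0),
        )
        events = I.detect_permeation_events(traces)
        assert len(events) == 1
        return I.classify_pathway(events[0], traces, traj, topo, geo)

    def test_constructed_exit_bearings_recovered(self, wet_system):
        # anchors sit at TM1=90, TM6=30, TM8=-90, TM12=150 degrees
        assert self._constructed_event(wet_system, 60.0) == "1-6"
        assert self._constructed_event(wet_system, 120.0) == "1-12"
        assert self._constructed_event(wet_system, -90.0) == "intermediate"

    def test_thirty_random_labelled_exits(self, wet_system):
        rng = np.random.default_rng(0)
        sectors = {"1-6": (40.0, 80.0), "1-12": (100.0, 140.0), "intermediate": (-120.0, -60.0)}
        hits = 0
        for k in range(30):
            label = list(sectors)[k % 3]
            lo, hi = sectors[label]
            ang = rng.uniform(lo, hi)
            hits += self._constructed_event(wet_system, ang) == label
        assert hits == 30


class TestResidence:
    @staticmethod
    def _contacts_from_pattern(pattern, site_resid=190):
        class FakeContacts:
            def __init__(self, pattern):
                self.protein_contacts = [[(site_resid,) if p else ()] for p in pattern]

        return FakeContacts(pattern)

    def _topo(self):
        return Topology(
            names=np.array(["CA"]),
            elements=np.array(["C"]),
            resnames=np.array(["LYS"]),
            resids=np.array([190]),
            chains=np.array(["A"]),
            radii=np.array([1.7]),
            role_tags={"site1": (190,)},
        )

    def test_gap_bridging(self):
        traces = _traces_from_z(np.full(5, -28.0))
        res = I.binding_residence(traces, self._contacts_from_pattern([1, 1, 0, 1, 1]), self._topo(), "site1", 1.0)
        assert len(res.durations) == 1
        assert res.durations[0] == pytest.approx(5.0)

    def test_zero_tolerance_splits(self):
        traces = _traces_from_z(np.full(5, -28.0))
        res = I.binding_residence(traces, self._contacts_from_pattern([1, 1, 0, 1, 1]), self._topo(), "site1", 0.0)
        assert sorted(res.durations) == [2.0, 2.0]

    def test_unknown_site_rejected(self):
        traces = _traces_from_z(np.full(5, -28.0))
        with pytest.raises(ValueError, match="unknown site"):
            I.binding_residence(traces, self._contacts_from_pattern([1]), self._topo(), "siteX")

    def test_occupancy_fraction(self):
        traces = _traces_from_z(np.full(4, -28.0))
        res = I.binding_residence(traces, self._contacts_from_pattern([1, 0, 0, 1]), self._topo(), "site1", 0.0)
        assert res.occupancy == pytest.approx(0.5)


def test_events_to_dataframe_ledger(wet_analysis):
    events = I.detect_permeation_events(wet_analysis["traces"])
    df = I.events_to_dataframe(events, wet_analysis["traces"].times)
    assert list(df.columns) == ["ion_id", "t_enter_ns", "t_exit_ns", "direction", "pathway"]
    if len(df):
        assert (df.t_enter_ns < df.t_exit_ns).all()
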