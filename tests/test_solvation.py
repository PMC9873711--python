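"""First-shell contacts, radial distribution functions, solvation profiles."""

import numpy as np
import pytest

from permeoscope.io import Topology
from permeoscope.ions import IonTraces
from permeoscope.solvation import first_shell_contacts, radial_distribution, solvation_profile
from permeoscope.stats import minimum_image

from conftest import make_trajectory


def _mini_system(water_positions, protein_positions=(), ion_z=-10.0):
    """One ion on the axis plus point waters/protein atoms at given positions."""
    n_w, n_p = len(water_positions), len(protein_positions)
    names = ["CLA"] + ["OW"] * n_w + ["CB"] * n_p
    resnames = ["CLA"] + ["SOL"] * n_w + ["ALA"] * n_p
    resids = [2001] + [3001 + i for i in range(n_w)] + [101 + i for i in range(n_p)]
    elements = ["CL"] + ["O"] * n_w + ["C"] * n_p
    topo = Topology(
        names=np.array(names, "U6"),
        elements=np.array(elements, "U2"),
        resnames=np.array(resnames, "U6"),
        resids=np.array(resids),
        chains=np.full(len(names), "A", "U1"),
        radii=np.full(len(names), 1.6),
    )
    coords = np.concatenate(
        [
            np.array([[0.0, 0.0, ion_z]]),
            np.asarray(water_positions, float).reshape(-1, 3),
            np.asarray(protein_positions, float).reshape(-1, 3),
        ]
    )[None]
    traces = IonTraces(
        ids=np.array([2001]),
        z=np.array([[ion_z]]),
        z_unwrapped=np.array([[ion_z]]),
        xy=np.zeros((1, 1, 2)),
        inside=np.ones((1, 1), bool),
        times=np.array([0.0]),
        box_z=np.array([70.0]),
    )
    return topo, make_trajectory(coords), traces


class TestContacts:
    def test_cutoff_boundary(self):
        topo, traj, traces = _mini_system([[0, 0, -10 + 2.9], [0, 0, -10 - 3.1]])
        contacts = first_shell_contacts(traj, topo, traces, cutoff=3.0)
        assert contacts.water_counts[0, 0] == 1

    def test_residue_counted_once_with_two_atoms_inside(self):
        # two atoms of the same protein residue inside the cutoff -> one contact
        topo, traj, traces = _mini_system([], protein_positions=[[0, 0, -8.5], [1.0, 0, -9.0]])
        topo.resids[-1] = topo.resids[-2]  # same residue
        contacts = first_shell_contacts(traj, topo, traces, cutoff=3.0)
        assert contacts.protein_contacts[0][0] == (101,)

    def test_brute_force_oracle_on_synthetic_frame(self, wet_analysis):
        topo, traj, traces = wet_analysis["topology"], wet_analysis["trajectory"], wet_analysis["traces"]
        contacts = wet_analysis["contacts"]
        ion_idx = np.flatnonzero(topo.ion_mask())
        water = topo.water_mask()
        protein = ~water & ~topo.ion_mask()
        f = traces.n_frames // 2
        for i in range(traces.n_ions):
            if not traces.inside[f, i]:
                continue
            delta = minimum_image(traj.coords[f] - traj.coords[f, ion_idx[i]], traj.box[f])
            d = np.linalg.norm(delta, axis=1)
            hit = d < contacts.cutoff
            w_expected = len(np.unique(topo.resids[hit & water]))
            p_expected = tuple(np.unique(topo.resids[hit & protein]))
            assert contacts.water_counts[f, i] == w_expected
            assert contacts.protein_contacts[f][i] == p_expected

    def test_rigid_motion_invariance(self):
        topo, traj, traces = _mini_system([[0, 0, -7.4], [2.0, 0, -10.0]])
        base = first_shell_contacts(traj, topo, traces, cutoff=3.0)
        th = 0.9
        rot = np.array([[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        moved = make_trajectory((traj.coords[0] @ rot.T + np.array([3.0, -2.0, 1.0]))[None])
        # traces describe the same ion after the same rigid motion
        traces2 = IonTraces(
            ids=traces.ids,
            z=traces.z + 1.0,
            z_unwrapped=traces.z_unwrapped + 1.0,
            xy=traces.xy,
            inside=traces.inside,
            times=traces.times,
            box_z=traces.box_z,
        )
        res = first_shell_contacts(moved, topo, traces2, cutoff=3.0)
        assert res.water_counts[0, 0] == base.water_counts[0, 0]


class TestRDF:
    def test_uniform_ideal_gas_is_flat(self):
        rng = np.random.default_rng(5)
        n_c, n_p = 50, 6000
        box = 40.0
        n = n_c + n_p
        coords = rng.uniform(0, box, size=(20, n, 3))
        topo = Topology(
            names=np.array(["CLA"] * n_c + ["OW"] * n_p),
            elements=np.array(["CL"] * n_c + ["O"] * n_p),
            resnames=np.array(["CLA"] * n_c + ["SOL"] * n_p),
            resids=np.arange(n) + 1,
            chains=np.full(n, "A"),
            radii=np.full(n, 1.5),
        )
        traj = make_trajectory(coords, box=(box, box, box))
        rdf = radial_distribution(traj, topo, topo.ion_mask(), topo.water_mask(), r_max=10.0, dr=0.5)
        tail = rdf.g[rdf.r > 1.0]
        assert np.all(np.abs(tail - 1.0) < 0.05)

    def test_fixed_pair_peak(self):
        topo = Topology(
            names=np.array(["CLA", "OW"]),
            elements=np.array(["CL", "O"]),
            resnames=np.array(["CLA", "SOL"]),
            resids=np.array([1, 2]),
            chains=np.array(["A", "A"]),
            radii=np.array([1.75, 1.52]),
        )
        coords = np.array([[[0, 0, 0], [2.95, 0, 0]]], dtype=float)
        traj = make_trajectory(coords, box=(50, 50, 50))
        rdf = radial_distribution(traj, topo, topo.ion_mask(), topo.water_mask(), r_max=6.0, dr=0.2)
        assert rdf.counts.sum() == 1
        peak_bin = np.argmax(rdf.counts)
        assert rdf.r[peak_bin] == pytest.approx(2.95, abs=0.1)

    def test_shell_peak_location_on_synthetic_run(self, wet_analysis):
        topo, traj = wet_analysis["topology"], wet_analysis["trajectory"]
        sub = make_trajectory(traj.coords[:40], box=traj.box[0])
        rdf = radial_distribution(sub, topo, topo.ion_mask(), topo.water_mask(), r_max=6.0, dr=0.2)
        peak = rdf.r[np.argmax(rdf.g)]
        assert 2.4 <= peak <= 2.8

    def test_r_max_beyond_half_box_rejected(self, wet_analysis):
        topo, traj = wet_analysis["topology"], wet_analysis["trajectory"]
        with pytest.raises(ValueError, match="half the smallest box"):
            radial_distribution(traj, topo, topo.ion_mask(), topo.water_mask(), r_max=60.0)

    def test_coordination_integral_recovers_pair_count(self):
        # closed box of uniform partners: integrating g recovers the partner count
        rng = np.random.default_rng(6)
        n = 2000
        box = 30.0
        coords = rng.uniform(0, box, size=(30, n + 1, 3))
        topo = Topology(
            names=np.array(["CLA"] + ["OW"] * n),
            elements=np.array(["CL"] + ["O"] * n),
            resnames=np.array(["CLA"] + ["SOL"] * n),
            resids=np.arange(n + 1) + 1,
            chains=np.full(n + 1, "A"),
            radii=np.full(n + 1, 1.5),
        )
        traj = make_trajectory(coords, box=(box, box, box))
        rdf = radial_distribution(traj, topo, topo.ion_mask(), topo.water_mask(), r_max=10.0, dr=0.25)
        expected = n * (4 / 3 * np.pi * 10.0**3) / box**3
        integral = np.sum(rdf.g * 4 * np.pi * rdf.r**2 * 0.25) * rdf.rho_partner
        assert integral == pytest.approx(expected, rel=0.02)


class TestProfile:
    def test_flat_water_curve(self):
        # ion contacting exactly 6 waters and no residues in every frame
        waters = [[0, 0, -10 + d] for d in (2.0, -2.0)] + [[2.0, 0, -10], [-2.0, 0, -10], [0, 2.0, -10], [0, -2.0, -10]]
        topo, traj, traces = _mini_system(waters)
        contacts = first_shell_contacts(traj, topo, traces, cutoff=3.0)
        prof = solvation_profile(contacts, traces, bin_width=1.0)
        occupied = np.isfinite(prof.water)
        assert prof.water[occupied] == pytest.approx(6.0)
        assert prof.protein[occupied] == pytest.approx(0.0)
        assert prof.total[occupied] == pytest.approx(6.0)

    def test_decomposition_identity(self, wet_analysis):
        prof = solvation_profile(wet_analysis["contacts"], wet_analysis["traces"], bin_width=1.0)
        ok = np.isfinite(prof.total)
        np.testing.assert_allclose(prof.total[ok], prof.water[ok] + prof.protein[ok], atol=1e-12)

    def test_profile_means_match_independent_reducer(self, wet_analysis):
        contacts, traces = wet_analysis["contacts"], wet_analysis["traces"]
        prof = solvation_profile(contacts, traces, bin_width=1.0)
        # one-pass recomputation of a populated bin
        b = int(np.nanargmax(prof.n_samples))
        lo, hi = prof.edges[b], prof.edges[b + 1]
        vals = []
        for f in range(traces.n_frames):
            for i in range(traces.n_ions):
                if contacts.water_counts[f, i] >= 0 and lo < traces.z[f, i] < hi:
                    vals.append(contacts.water_counts[f, i])
        assert prof.water[b] == pytest.approx(np.mean(vals), abs=1e-9)

    def test_bottleneck_deficit_recovered(self, wet_analysis):
        prof = solvation_profile(
            wet_analysis["contacts"], wet_analysis["traces"], bin_width=1.0, seed=3
        )
        lo, hi = prof.water_deficit_ci
        assert lo <= 1.2 <= hi
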