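"""Shared fixtures: small synthetic systems reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from permeoscope import ions as ion_mod
from permeoscope.geometry import align_to_reference, pore_geometry_per_frame
from permeoscope.io import Topology, Trajectory
from permeoscope.solvation import first_shell_contacts
from permeoscope.synthetic import SYNTHETIC_CONTACT_CUTOFF, SyntheticConfig, generate


@pytest.fixture(scope="session")
def wet_system():
    """Conductive synthetic run: gate pinned wet so permeation occurs quickly."""
    cfg = SyntheticConfig.field_on()
    cfg.n_frames = 800
    cfg.n_ions = 8
    cfg.gate_fixed = "wet"
    cfg.seed = 5
    return generate(cfg)


@pytest.fixture(scope="session")
def wet_analysis(wet_system):
    traj, rmsd = align_to_reference(wet_system.trajectory, wet_system.topology)
    geometry = pore_geometry_per_frame(traj, wet_system.topology)
    traces = ion_mod.extract_ion_traces(traj, wet_system.topology, geometry)
    contacts = first_shell_contacts(traj, wet_system.topology, traces, SYNTHETIC_CONTACT_CUTOFF)
    return {
        "topology": wet_system.topology,
        "trajectory": traj,
        "rmsd": rmsd,
        "geometry": geometry,
        "traces": traces,
        "contacts": contacts,
        "truth": wet_system.truth,
        "config": wet_system.config,
    }


@pytest.fixture()
def toy_topology():
    """Three-residue linear chain with annotated helices and roles."""
    names = np.array(["CA", "CA", "CA", "CA", "CA", "CA", "CA", "CA"], dtype="U6")
    return Topology(
        names=names,
        elements=np.full(8, "C", "U2"),
        resnames=np.full(8, "ALA", "U6"),
        resids=np.arange(1, 9),
        chains=np.full(8, "A", "U1"),
        radii=np.full(8, 1.70),
        helix_map={"TM1": [(1, 4)], "TM6": [(5, 8)]},
        pore_helices=("TM1", "TM6"),
        role_tags={"origin": (1,), "gate": (2,), "site1": (3,), "site2": (4,)},
        anchors={"TM1": 4, "TM6": 8},
    )


def make_trajectory(coords, dt=1.0, box=(100.0, 100.0, 70.0)):
    coords = np.asarray(coords, dtype=float)
    f = coords.shape[0]
    return Trajectory(
        coords=coords,
        times=np.arange(f, dtype=float) * dt,
        box=np.tile(np.asarray(box, dtype=float), (f, 1)),
    )
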