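"""Pore-helix movements and charged-sidechain geometry.

Tracks the interhelical distances d_1-6, d_1-8, d_1-12 between the
extracellular anchor residues, the xy dispersion of the helix ends, and the
joint distribution of the tracking sidechain's charge centre with the
nearest ion below it (the "dunking" analysis).
"""

import numpy as np

import permeoscope as ps
from permeoscope import ions
from permeoscope.helices import (
    helix_end_xy_distribution,
    interhelical_distances,
    r334_dunking_joint,
)

cfg = ps.SyntheticConfig.field_on()
cfg.n_frames = 800
cfg.gate_fixed = "wet"
cfg.seed = 5
system = ps.generate(cfg)
traj, _ = ps.align_to_reference(system.trajectory, system.topology)
geometry = ps.pore_geometry_per_frame(traj, system.topology)
traces = ions.extract_ion_traces(traj, system.topology, geometry)

dists = interhelical_distances(traj, system.topology)
for col in dists.columns:
    print(f"{col}: mean {dists[col].mean():.1f} A, range "
          f"{dists[col].min():.1f}..{dists[col].max():.1f} A")

xy = helix_end_xy_distribution(traj, system.topology)
for h, rec in xy.items():
    print(f"{h} end dispersion: {rec['dispersion']:.2f} A")

joint = r334_dunking_joint(traj, system.topology, traces)
print(f"dunked-state fraction (z_R < +2 A): {joint.dunked_fraction:.2f}")
print(f"frames with an ion below the sidechain: {len(joint.pairs)} "
      f"(skipped {joint.n_skipped})")
# The drifting helix (TM1) shows the largest end dispersion; the tracking
# sidechain dips towards approaching anions, producing the dunked shoulder
# in its axial distribution.
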