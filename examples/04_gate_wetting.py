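"""Hydrophobic-gate wetting: bottleneck water counts, SASA, wet/dry dwells,
and the temporal association between wetting and permeation.

Uses the natural (telegraph) gate so the run alternates between dry and wet
episodes; permeation should be confined to the wet ones.
"""

import numpy as np

import permeoscope as ps
from permeoscope import ions
from permeoscope.gating import (
    classify_gate_state,
    count_bottleneck_waters,
    sasa_series,
    wetting_event_association,
)

cfg = ps.SyntheticConfig.field_on()
cfg.n_frames = 1500
cfg.seed = 2  # a seed whose gate wets repeatedly
system = ps.generate(cfg)
traj, _ = ps.align_to_reference(system.trajectory, system.topology)
geometry = ps.pore_geometry_per_frame(traj, system.topology)
traces = ions.extract_ion_traces(traj, system.topology, geometry)

n_water = count_bottleneck_waters(traj, system.topology, geometry)
cls = classify_gate_state(n_water, dt=traces.dt)
print(f"wet fraction                  : {cls.labels.mean():.2f} (threshold {cls.threshold:.1f} waters)")
print(f"mean N_water wet / dry        : {n_water[cls.labels == 1].mean():.1f} / "
      f"{n_water[cls.labels == 0].mean():.1f}")
print(f"mean wet dwell                : {cls.dwell_wet.mean():.0f} ns ({len(cls.dwell_wet)} episodes)")

events = ions.detect_permeation_events(traces)
assoc = wetting_event_association(cls.labels, [e.frame_exit for e in events], seed=0)
print(f"permeation events             : {len(events)}")
if assoc.defined:
    print(f"fraction of events in wet gate: {assoc.event_wet_fraction:.2f}")
    print(f"circular-permutation p-value  : {assoc.p_value:.4f}")

sasa = sasa_series(traj, system.topology, [99, 102, 106])
wet, dry = cls.labels == 1, cls.labels == 0
for resid in (99, 102, 106):
    print(f"SASA residue {resid}: wet {sasa[resid][wet].mean():.1f} A^2, "
          f"dry {sasa[resid][dry].mean():.1f} A^2")
# Permeation clusters inside wetting episodes (p << 0.05); gate-residue SASA
# tracks the hydration state of the bottleneck.
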