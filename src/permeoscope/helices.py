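"""Pore-lining helix movements and charged-sidechain geometry.

Interhelical distances are tracked between anchor Cα pairs at the
extracellular helix ends (d_1-6, d_1-8, d_1-12 for a CFTR-like pore);
sidechain charge centres use the conventional representative points (Lys: NZ;
Arg: unweighted centroid of the guanidinium group NE/CZ/NH1/NH2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Topology, Trajectory
from .ions import IonTraces

__all__ = [
    "interhelical_distances",
    "helix_end_xy_distribution",
    "sidechain_charge_center",
    "charge_center_series",
    "r334_dunking_joint",
    "DunkingJoint",
]

_DEFAULT_PAIRS = {"d_1-6": ("TM1", "TM6"), "d_1-8": ("TM1", "TM8"), "d_1-12": ("TM1", "TM12")}

_ARG_GROUP = ("NE", "CZ", "NH1", "NH2")


def _anchor_ca_index(topo: Topology, helix: str) -> int:
    resid = topo.anchors.get(helix)
    if resid is None:
        raise ValueError(f"no anchor residue annotated for helix {helix}")
    idx = np.flatnonzero((topo.resids == resid) & topo.ca_mask())
    if idx.size == 0:
        raise ValueError(f"anchor residue {resid} ({helix}) has no CA atom")
    return int(idx[0])


def interhelical_distances(
    traj: Trajectory,
    topo: Topology,
    pairs: dict | None = None,
) -> pd.DataFrame:
    """Per-frame Cα-Cα distances between anchor residues of helix pairs."""
    pairs = pairs or _DEFAULT_PAIRS
    cols = {}
    for label, (ha, hb) in pairs.items():
        ia, ib = _anchor_ca_index(topo, ha), _anchor_ca_index(topo, hb)
        cols[label] = np.linalg.norm(traj.coords[:, ia] - traj.coords[:, ib], axis=1)
    return pd.DataFrame(cols, index=traj.times)


def helix_end_xy_distribution(
    traj: Trajectory,
    topo: Topology,
    helices=("TM1", "TM6", "TM8", "TM12"),
    bins: int = 40,
    extent: float | None = None,
) -> dict:
    """2-D occupancy histograms of anchor-Cα xy positions per helix end.

    Returns a dict per helix with the histogram, bin edges, the mean xy
    position and the RMS radial fluctuation about it (dispersion).
    """
    out = {}
    for h in helices:
        idx = _anchor_ca_index(topo, h)
        xy = traj.coords[:, idx, :2]
        mean = xy.mean(axis=0)
        disp = float(np.sqrt(np.mean(np.sum((xy - mean) ** 2, axis=1))))
        if extent is None:
            lo = xy.min(axis=0) - 1.0
            hi = xy.max(axis=0) + 1.0
            rng = [[lo[0], hi[0]], [lo[1], hi[1]]]
        else:
            rng = [[mean[0] - extent, mean[0] + extent], [mean[1] - extent, mean[1] + extent]]
        hist, xe, ye = np.histogram2d(xy[:, 0], xy[:, 1], bins=bins, range=rng)
        out[h] = {"hist": hist, "x_edges": xe, "y_edges": ye, "mean_xy": mean, "dispersion": disp}
    return out


def sidechain_charge_center(coords_frame: np.ndarray, topo: Topology, resid: int) -> np.ndarray:
    """Representative charge point of a basic sidechain in one frame.

    Lysine: the terminal amine nitrogen NZ.  Arginine: the unweighted mean of
    the guanidinium-group atoms NE, CZ, NH1, NH2.
    """
    idx = topo.atom_indices(resid)
    if idx.size == 0:
        raise ValueError(f"residue {resid} not in topology")
    resname = str(topo.resnames[idx[0]]).upper()
    names = topo.names[idx]
    if resname.startswith("LYS") or resname == "LYS":
        pick = idx[names == "NZ"]
        if pick.size == 0:
            raise ValueError(f"Lys {resid}: NZ atom missing")
        return coords_frame[pick[0]].astype(float)
    if resname.startswith("ARG") or resname == "ARG":
        pick = idx[np.isin(names, _ARG_GROUP)]
        if pick.size != len(_ARG_GROUP):
            raise ValueError(f"Arg {resid}: guanidinium atoms {_ARG_GROUP} incomplete")
        return coords_frame[pick].mean(axis=0)
    raise ValueError(f"residue {resid} ({resname}) is not Lys or Arg")


def charge_center_series(traj: Trajectory, topo: Topology, resids) -> dict:
    """Per-frame charge-centre xyz for each requested Lys/Arg residue."""
    out = {}
    for r in resids:
        pts = np.stack([sidechain_charge_center(traj.coords[f], topo, r) for f in range(traj.n_frames)])
        out[int(r)] = pts
    return out


@dataclass
class DunkingJoint:
    z_r_edges: np.ndarray
    z_ion_edges: np.ndarray
    joint: np.ndarray  # 2-D histogram counts (z_R x z_ion)
    z_r_marginal: np.ndarray  # histogram of z_R over all frames
    n_skipped: int  # frames with no ion below the charge centre
    dunked_fraction: float
    dunk_threshold: float
    pairs: np.ndarray  # (n_kept, 2): per-frame (z_R, z_ion)


def r334_dunking_joint(
    traj: Trajectory,
    topo: Topology,
    traces: IonTraces,
    resid: int = 334,
    dunk_threshold: float = 2.0,
    bins: int = 40,
    z_range: tuple[float, float] = (-15.0, 15.0),
) -> DunkingJoint:
    """Joint distribution of the sidechain charge-centre z and the nearest
    ion "below" it (further into the pore).

    Per frame, z_R is the charge-centre axial position and z_ion the largest
    z among in-pore ions with z < z_R; frames with no such ion contribute
    only to the z_R marginal.  The dunked-state fraction is the fraction of
    frames with z_R below ``dunk_threshold``.
    """
    centers = charge_center_series(traj, topo, [resid])[resid]
    z_r = centers[:, 2]
    pairs = []
    n_skip = 0
    for f in range(traj.n_frames):
        cand = traces.z[f][traces.inside[f] & (traces.z[f] < z_r[f])]
        if cand.size == 0:
            n_skip += 1
            continue
        pairs.append((z_r[f], float(cand.max())))
    pairs = np.asarray(pairs) if pairs else np.empty((0, 2))
    edges = np.linspace(z_range[0], z_range[1], bins + 1)
    if len(pairs):
        joint, _, _ = np.histogram2d(pairs[:, 0], pairs[:, 1], bins=[edges, edges])
    else:
        joint = np.zeros((bins, bins))
    marg, _ = np.histogram(z_r, bins=edges)
    return DunkingJoint(
        z_r_edges=edges,
        z_ion_edges=edges,
        joint=joint,
        z_r_marginal=marg,
        n_skipped=n_skip,
        dunked_fraction=float(np.mean(z_r < dunk_threshold)),
        dunk_threshold=dunk_threshold,
        pairs=pairs,
    )
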