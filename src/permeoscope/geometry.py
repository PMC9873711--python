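"""Frame alignment (Kabsch superposition) and the cylindrical pore frame.

The pore coordinate system follows the convention used for CFTR-like
channels: z is the membrane normal with the extracellular side at +z and the
axial origin is the Cα of a designated origin residue (T338 for CFTR),
re-evaluated every frame so the origin tracks protein drift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Topology, Trajectory

__all__ = [
    "kabsch",
    "align_to_reference",
    "PoreFrameGeometry",
    "PoreGeometry",
    "pore_geometry_per_frame",
]


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t minimising ``|R @ x + t - ref|``.

    Standard SVD solution with the determinant correction that excludes
    reflections.  Both inputs are (N, 3) with N >= 3.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.shape[0] < 3:
        raise ValueError("kabsch requires matching point sets with at least 3 points")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = rc - rot @ mc
    return rot, trans


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def align_to_reference(
    traj: Trajectory,
    topo: Topology,
    selection: np.ndarray | None = None,
) -> tuple[Trajectory, np.ndarray]:
    """Rigidly superpose every frame onto frame 0 on a Cα selection.

    ``selection`` is a boolean mask or index array over atoms; by default the
    Cα atoms of all annotated helices (the transmembrane scaffold) are used.
    Returns the aligned trajectory (a copy; ``aligned`` flag set) and the
    per-frame post-alignment RMSD of the selection.
    """
    if selection is None:
        idx = topo.helix_ca_indices(list(topo.helix_map))
    else:
        selection = np.asarray(selection)
        idx = np.flatnonzero(selection) if selection.dtype == bool else selection
    if idx.size < 3:
        raise ValueError(f"alignment selection resolves to {idx.size} atoms; need >= 3 (rotation underdetermined)")

    coords = traj.coords.copy()
    ref = coords[0, idx]
    rmsd = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        rot, trans = kabsch(coords[f, idx], ref)
        coords[f] = coords[f] @ rot.T + trans
        rmsd[f] = _rmsd(coords[f, idx], ref)
    out = Trajectory(coords=coords, times=traj.times.copy(), box=traj.box.copy(), aligned=True)
    return out, rmsd


@dataclass
class PoreFrameGeometry:
    """Cylindrical pore frame for one trajectory frame."""

    frame_index: int
    z_origin: float
    cylinder_center_xy: tuple[float, float]
    cylinder_radius: float

    def __post_init__(self) -> None:
        if self.cylinder_radius <= 0:
            raise ValueError("cylinder radius must be positive")


class PoreGeometry:
    """Per-frame pore frames stored as arrays; indexable to PoreFrameGeometry."""

    def __init__(self, z_origin: np.ndarray, center_xy: np.ndarray, radius: np.ndarray):
        self.z_origin = np.asarray(z_origin, dtype=float)
        self.center_xy = np.asarray(center_xy, dtype=float)
        self.radius = np.asarray(radius, dtype=float)

    def __len__(self) -> int:
        return len(self.z_origin)

    def __getitem__(self, f: int) -> PoreFrameGeometry:
        return PoreFrameGeometry(
            frame_index=f,
            z_origin=float(self.z_origin[f]),
            cylinder_center_xy=(float(self.center_xy[f, 0]), float(self.center_xy[f, 1])),
            cylinder_radius=float(self.radius[f]),
        )


def pore_geometry_per_frame(
    traj: Trajectory,
    topo: Topology,
    z_window: tuple[float, float] = (-40.0, 20.0),
    freeze_at_frame0: bool = False,
) -> PoreGeometry:
    """Cylindrical pore definition recomputed for every frame.

    Per frame: the axial origin is the z of the origin-residue Cα; pore-helix
    Cα atoms with origin-relative z inside ``z_window`` are selected; the
    cylinder centre is their unweighted xy mean and the radius the mean xy
    distance from that centre.  With ``freeze_at_frame0`` the frame-0 centre
    and radius are reused for all frames (the z-origin still tracks).
    """
    helices = topo.pore_helices or tuple(topo.helix_map)
    ca_idx = topo.helix_ca_indices(helices)
    if ca_idx.size == 0:
        raise ValueError("no pore-helix CA atoms found")
    origin_idx = topo.origin_ca_index()

    n = traj.n_frames
    z_origin = traj.coords[:, origin_idx, 2].astype(float)
    centers = np.empty((n, 2))
    radii = np.empty(n)
    for f in range(n):
        pts = traj.coords[f, ca_idx]
        zrel = pts[:, 2] - z_origin[f]
        sel = (zrel > z_window[0]) & (zrel < z_window[1])
        if not np.any(sel):
            raise ValueError(f"pore-helix CA selection empty in frame {f}")
        xy = pts[sel, :2]
        c = xy.mean(axis=0)
        centers[f] = c
        radii[f] = np.mean(np.linalg.norm(xy - c, axis=1))
    if freeze_at_frame0:
        centers[:] = centers[0]
        radii[:] = radii[0]
    return PoreGeometry(z_origin=z_origin, center_xy=centers, radius=radii)
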