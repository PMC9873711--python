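"""Ion traces, axial densities, permeation events, bursts and exit pathways.

Permeation is counted with a two-plane (committor) hysteresis rule: an event
is a passage from below the lower plane to above the upper plane (or the
reverse) without touching the far side in between.  The planes default to
(-20, +10) A, bracketing the hydrophobic bottleneck (-5 < z < 5 A) widely
enough that ions which merely reach the bottleneck entrance and retreat are
not counted.  The rule is wrap-aware: a jump larger than half the box height
between consecutive frames is treated as a passage through the periodic (or
re-injection) boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import PoreGeometry
from .io import Topology, Trajectory
from .stats import BootstrapCI, bootstrap_ci

__all__ = [
    "IonTraces",
    "PermeationEvent",
    "Burst",
    "AxialDensityProfile",
    "OccupancyDistribution",
    "extract_ion_traces",
    "occupancy_distribution",
    "axial_density",
    "detect_permeation_events",
    "detect_bursts",
    "classify_pathway",
    "classify_pathways",
    "binding_residence",
    "events_to_dataframe",
]


@dataclass
class IonTraces:
    """Per-ion time series in the pore coordinate frame.

    ``z`` is origin-relative (wrapped into the box); ``z_unwrapped`` is the
    continuous axial coordinate obtained by minimum-image accumulation of
    frame-to-frame displacements.
    """

    ids: np.ndarray  # ion residue numbers, one per column
    z: np.ndarray  # (F, N)
    z_unwrapped: np.ndarray  # (F, N)
    xy: np.ndarray  # (F, N, 2)
    inside: np.ndarray  # (F, N) bool
    times: np.ndarray  # (F,) ns
    box_z: np.ndarray  # (F,)

    @property
    def n_frames(self) -> int:
        return self.z.shape[0]

    @property
    def n_ions(self) -> int:
        return self.z.shape[1]

    @property
    def dt(self) -> float:
        return float(np.mean(np.diff(self.times))) if self.n_frames > 1 else 0.0

    def region_counts(self, region: tuple[float, float]) -> np.ndarray:
        """Per-frame number of in-pore ions with z inside ``region``."""
        lo, hi = region
        if not lo < hi:
            raise ValueError("empty z region")
        mask = self.inside & (self.z > lo) & (self.z < hi)
        return mask.sum(axis=1)


def extract_ion_traces(
    traj: Trajectory,
    topo: Topology,
    geometry: PoreGeometry,
    z_window: tuple[float, float] = (-40.0, 20.0),
) -> IonTraces:
    """Build one trace per chloride-typed atom, with the in-pore flag.

    An ion is inside the pore when its xy distance to the cylinder centre is
    below the cylinder radius and its origin-relative z lies in ``z_window``.
    """
    ion_idx = np.flatnonzero(topo.ion_mask())
    if ion_idx.size == 0:
        raise ValueError("no chloride ion atoms in topology")
    pos = traj.coords[:, ion_idx, :]  # (F, N, 3)
    z = pos[:, :, 2] - geometry.z_origin[:, None]
    xy = pos[:, :, :2]
    box_z = traj.box[:, 2]

    dz = np.diff(z, axis=0)
    dz -= box_z[1:, None] * np.round(dz / box_z[1:, None])
    z_unwrapped = np.vstack([z[0], z[0] + np.cumsum(dz, axis=0)])

    dxy = xy - geometry.center_xy[:, None, :]
    radial = np.linalg.norm(dxy, axis=2)
    inside = (radial < geometry.radius[:, None]) & (z > z_window[0]) & (z < z_window[1])

    return IonTraces(
        ids=topo.resids[ion_idx],
        z=z,
        z_unwrapped=z_unwrapped,
        xy=xy,
        inside=inside,
        times=traj.times.copy(),
        box_z=box_z.copy(),
    )


# --------------------------------------------------------------------------
# occupancy and density


@dataclass
class OccupancyDistribution:
    region: tuple[float, float]
    counts: np.ndarray  # per-frame occupancy
    probabilities: dict  # N -> probability
    ci: dict  # N -> BootstrapCI
    mean: float
    mean_ci: BootstrapCI


def occupancy_distribution(
    traces: IonTraces,
    region: tuple[float, float] = (-40.0, -5.0),
    level: float = 0.99,
    n_resamples: int = 1000,
    seed: int = 0,
) -> OccupancyDistribution:
    """Distribution of the number of ions occupying an axial region.

    The default region is the inner vestibule, from the pore bottom to the
    bottleneck floor.  Per-bar confidence intervals are percentile bootstrap
    over frames.
    """
    counts = traces.region_counts(region)
    if counts.size == 0:
        raise ValueError("no frames")
    values = np.arange(counts.max() + 1)
    probs, cis = {}, {}
    for v in values:
        ind = (counts == v).astype(float)
        probs[int(v)] = float(ind.mean())
        cis[int(v)] = bootstrap_ci(ind, "mean", level, n_resamples, seed=seed + int(v))
    mean_ci = bootstrap_ci(counts.astype(float), "mean", level, n_resamples, seed=seed + 10_007)
    return OccupancyDistribution(
        region=region,
        counts=counts,
        probabilities=probs,
        ci=cis,
        mean=float(counts.mean()),
        mean_ci=mean_ci,
    )


@dataclass
class AxialDensityProfile:
    edges: np.ndarray  # bin edges, A
    rho: np.ndarray  # mean ion count per A per frame
    cumulative: np.ndarray  # n(z): integral of rho from the pore bottom
    ci_low: np.ndarray
    ci_high: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def axial_density(
    traces: IonTraces,
    bin_width: float = 1.0,
    z_range: tuple[float, float] = (-40.0, 20.0),
    block_size: int = 50,
    level: float = 0.99,
    n_resamples: int = 200,
    seed: int = 0,
) -> AxialDensityProfile:
    """Axial number density rho(z) of in-pore ions and its cumulative integral.

    rho integrates exactly to the mean in-pore occupancy of the range; the
    per-bin CIs come from a block bootstrap over frame blocks (autocorrelated
    frames are resampled in contiguous blocks of ``block_size``).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    edges = np.arange(z_range[0], z_range[1] + bin_width / 2, bin_width)
    n_bins = len(edges) - 1
    f_all, i_all = np.nonzero(traces.inside & (traces.z > edges[0]) & (traces.z < edges[-1]))
    zs = traces.z[f_all, i_all]
    b = np.clip(((zs - edges[0]) / bin_width).astype(int), 0, n_bins - 1)
    per_frame = np.zeros((traces.n_frames, n_bins))
    np.add.at(per_frame, (f_all, b), 1.0)

    rho = per_frame.mean(axis=0) / bin_width
    cum = np.concatenate([[0.0], np.cumsum(rho * bin_width)])

    # block bootstrap over frames
    rng = np.random.default_rng(seed)
    n_blocks = max(1, traces.n_frames // block_size)
    blocks = np.array_split(np.arange(traces.n_frames), n_blocks)
    block_sums = np.stack([per_frame[blk].sum(axis=0) for blk in blocks])
    block_lens = np.array([len(blk) for blk in blocks], dtype=float)
    est = np.empty((n_resamples, n_bins))
    for r in range(n_resamples):
        pick = rng.integers(0, n_blocks, size=n_blocks)
        est[r] = block_sums[pick].sum(axis=0) / block_lens[pick].sum() / bin_width
    alpha = (1 - level) / 2
    lo, hi = np.quantile(est, [alpha, 1 - alpha], axis=0)
    return AxialDensityProfile(edges=edges, rho=rho, cumulative=cum, ci_low=lo, ci_high=hi)


# --------------------------------------------------------------------------
# permeation events


@dataclass
class PermeationEvent:
    ion_id: int
    ion_column: int
    frame_enter: int
    frame_exit: int
    direction: int  # +1 towards the extracellular side
    pathway: str = "unassigned"

    def __post_init__(self) -> None:
        if self.frame_enter >= self.frame_exit:
            raise ValueError("frame_enter must precede frame_exit")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")


def detect_permeation_events(
    traces: IonTraces,
    z_low: float = -20.0,
    z_high: float = 10.0,
    z_window: tuple[float, float] = (-40.0, 20.0),
) -> list[PermeationEvent]:
    """Two-plane hysteresis detection of full bottleneck translocations."""
    if not z_low < z_high:
        raise ValueError("need z_low < z_high")
    if z_low <= z_window[0] or z_high >= z_window[1]:
        raise ValueError("committor planes must lie strictly inside the pore z-range")
    events: list[PermeationEvent] = []
    z = traces.z
    box_half = traces.box_z / 2.0
    for col in range(traces.n_ions):
        state = None
        last_below = None
        last_above = None
        for f in range(traces.n_frames):
            zi = z[f, col]
            if f > 0:
                d = zi - z[f - 1, col]
                if d < -box_half[f]:
                    # passage out through the top boundary, re-entry at the bottom
                    state = "below"
                    last_below = f
                elif d > box_half[f]:
                    state = "above"
                    last_above = f
            if zi < z_low:
                if state == "above" and last_above is not None:
                    events.append(
                        PermeationEvent(
                            ion_id=int(traces.ids[col]),
                            ion_column=col,
                            frame_enter=min(last_above, f - 1),
                            frame_exit=f,
                            direction=-1,
                        )
                    )
                state = "below"
                last_below = f
            elif zi > z_high:
                if state == "below" and last_below is not None:
                    events.append(
                        PermeationEvent(
                            ion_id=int(traces.ids[col]),
                            ion_column=col,
                            frame_enter=min(last_below, f - 1),
                            frame_exit=f,
                            direction=+1,
                        )
                    )
                state = "above"
                last_above = f
    events.sort(key=lambda e: (e.frame_exit, e.ion_column))
    return events


def events_to_dataframe(events: list[PermeationEvent], times: np.ndarray) -> pd.DataFrame:
    """Event ledger: one row per translocation."""
    rows = [
        {
            "ion_id": e.ion_id,
            "t_enter_ns": float(times[e.frame_enter]),
            "t_exit_ns": float(times[e.frame_exit]),
            "direction": e.direction,
            "pathway": e.pathway,
        }
        for e in events
    ]
    return pd.DataFrame(rows, columns=["ion_id", "t_enter_ns", "t_exit_ns", "direction", "pathway"])


@dataclass
class Burst:
    event_indices: list
    t_start: float
    t_end: float

    @property
    def size(self) -> int:
        return len(self.event_indices)


def detect_bursts(events: list[PermeationEvent], times: np.ndarray, gap: float = 100.0) -> list[Burst]:
    """Single-linkage clustering of event times with a gap threshold (ns)."""
    if gap <= 0:
        raise ValueError("gap must be positive")
    if not events:
        return []
    order = np.argsort([times[e.frame_exit] for e in events])
    ts = np.array([times[events[i].frame_exit] for i in order])
    bursts: list[Burst] = []
    start = 0
    for k in range(1, len(ts) + 1):
        if k == len(ts) or ts[k] - ts[k - 1] > gap:
            members = [int(order[j]) for j in range(start, k)]
            bursts.append(Burst(event_indices=members, t_start=float(ts[start]), t_end=float(ts[k - 1])))
            start = k
    return bursts


# --------------------------------------------------------------------------
# pathway classification


def _angdist(a: np.ndarray | float, b: np.ndarray | float) -> np.ndarray:
    return np.abs(np.angle(np.exp(1j * (np.asarray(a) - np.asarray(b)))))


def classify_pathway(
    event: PermeationEvent,
    traces: IonTraces,
    traj: Trajectory,
    topo: Topology,
    geometry: PoreGeometry,
    z_cross: float = 2.5,
    ambiguity_deg: float = 10.0,
) -> str:
    """Assign an exit route by the ion's angular sector at the upper bottleneck.

    At the first (last, for inward events) frame of the event with ion
    z > ``z_cross``, the ion's xy bearing about the cylinder centre is
    compared with the bearings of the four anchor Cα atoms.  The two nearest
    anchors name the gap: {TM1, TM6} -> "1-6", {TM1, TM12} -> "1-12"; a
    nearest anchor on TM8, or a sector call ambiguous within
    ``ambiguity_deg``, gives "intermediate".
    """
    needed = ("TM1", "TM6", "TM8", "TM12")
    if any(h not in topo.anchors for h in needed):
        raise ValueError(f"pathway anchors require helices {needed} in the anchor map")
    window = range(event.frame_enter, event.frame_exit + 1)
    frames = [f for f in window if traces.z[f, event.ion_column] > z_cross]
    if not frames:
        return "unassigned"
    f = frames[0] if event.direction > 0 else frames[-1]

    center = geometry.center_xy[f]
    ion_xy = traces.xy[f, event.ion_column]
    theta_ion = np.arctan2(ion_xy[1] - center[1], ion_xy[0] - center[0])

    anchor_resid = {h: topo.anchors[h] for h in needed}
    theta = {}
    for h, resid in anchor_resid.items():
        idx = np.flatnonzero((topo.resids == resid) & topo.ca_mask())
        if idx.size == 0:
            raise ValueError(f"anchor residue {resid} ({h}) has no CA atom")
        xy = traj.coords[f, idx[0], :2]
        theta[h] = np.arctan2(xy[1] - center[1], xy[0] - center[0])

    helices = list(needed)
    dists = np.array([_angdist(theta_ion, theta[h]) for h in helices])
    order = np.argsort(dists)
    nearest = helices[order[0]]
    pair = {helices[order[0]], helices[order[1]]}
    margin_rad = dists[order[2]] - dists[order[1]]
    ambiguous = margin_rad < np.deg2rad(ambiguity_deg)
    if pair == {"TM1", "TM6"} and not ambiguous:
        return "1-6"
    if pair == {"TM1", "TM12"} and not ambiguous:
        return "1-12"
    if nearest == "TM8" or ambiguous:
        return "intermediate"
    return "unassigned"


def classify_pathways(events, traces, traj, topo, geometry, **kwargs) -> list[PermeationEvent]:
    for e in events:
        e.pathway = classify_pathway(e, traces, traj, topo, geometry, **kwargs)
    return events


# --------------------------------------------------------------------------
# binding residence


@dataclass
class ResidenceResult:
    site: str
    intervals: list  # (ion_column, frame_start, frame_stop) after gap bridging
    durations: np.ndarray  # ns
    mean: float
    max: float
    occupancy: float  # fraction of frames with >= 1 bound ion
    gap_tolerance: float


def binding_residence(
    traces: IonTraces,
    contacts,
    topo: Topology,
    site: str,
    gap_tolerance: float = 1.0,
) -> ResidenceResult:
    """Residence-time statistics for a named binding site.

    A binding interval is a maximal run of frames in which the ion contacts
    at least one site residue (first-shell rule), bridging interruptions of
    at most ``gap_tolerance`` ns.  Occupancy is the fraction of frames with
    at least one bound ion.
    """
    if site not in topo.role_tags:
        raise ValueError(f"unknown site {site!r}; available: {sorted(topo.role_tags)}")
    if gap_tolerance < 0:
        raise ValueError("gap_tolerance must be >= 0")
    site_resids = set(topo.role_tags[site])
    dt = traces.dt or 1.0
    gap_frames = int(round(gap_tolerance / dt))

    n_f, n_i = traces.n_frames, traces.n_ions
    bound = np.zeros((n_f, n_i), dtype=bool)
    for f in range(n_f):
        for i in range(n_i):
            res = contacts.protein_contacts[f][i]
            if res and not site_resids.isdisjoint(res):
                bound[f, i] = True

    intervals = []
    for i in range(n_i):
        col = bound[:, i].astype(np.int8)
        edges = np.flatnonzero(np.diff(np.concatenate([[0], col, [0]])))
        runs = [(int(a), int(b - 1)) for a, b in zip(edges[::2], edges[1::2])]
        merged: list[list[int]] = []
        for a, b in runs:
            if merged and a - merged[-1][1] - 1 <= gap_frames:
                merged[-1][1] = b
            else:
                merged.append([a, b])
        intervals.extend((i, a, b) for a, b in merged)

    durations = np.array([(b - a + 1) * dt for _, a, b in intervals])
    any_bound = bound.any(axis=1)
    return ResidenceResult(
        site=site,
        intervals=intervals,
        durations=durations,
        mean=float(durations.mean()) if durations.size else float("nan"),
        max=float(durations.max()) if durations.size else float("nan"),
        occupancy=float(any_bound.mean()),
        gap_tolerance=gap_tolerance,
    )
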