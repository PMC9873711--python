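"""Topology / trajectory containers and readers.

The channel coordinate system used throughout the package is membrane-normal
z with the extracellular side at +z.  All coordinates are in Angstrom and all
times in nanoseconds.  Standard structure formats (PDB, GRO) and binary
trajectories (DCD, XTC, TRR) are read through MDAnalysis; a documented
plain-text multi-frame format is provided for portable, binary-free fixtures.

Plain-text trajectory format::

    n_atoms                      # header, one integer
    <time ns>                    # per frame: timestamp line
    <bx> <by> <bz>               #            box lengths, Angstrom
    <x> <y> <z>                  #            n_atoms coordinate lines
    ...
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "Topology",
    "Trajectory",
    "VDW_RADII",
    "load_system",
    "load_annotation",
    "read_plaintext_trajectory",
    "write_plaintext_trajectory",
    "write_pdb",
]

#: Bondi van der Waals radii by element symbol (Angstrom).
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "CL": 1.75,
    "NA": 2.27,
    "K": 2.75,
    "MG": 1.73,
    "F": 1.47,
    "BR": 1.85,
    "I": 1.98,
}

#: Residue names recognised as water.
WATER_RESNAMES = frozenset({"HOH", "TIP3", "SOL", "WAT", "SPC", "W"})

#: Residue names recognised as chloride ions.
CHLORIDE_RESNAMES = frozenset({"CLA", "CL", "CL-"})


@dataclass
class Topology:
    """Static atom table with residue identity and pore annotations.

    ``helix_map`` maps helix names (e.g. ``"TM6"``) to inclusive residue
    ranges; ``pore_helices`` names the subset lining the pore.  ``role_tags``
    holds named residue sets used by the analyses (``origin``, ``gate``,
    ``site1``, ``site2``, ``basic``) and ``anchors`` maps helix names to the
    single residue tracking each helix end.
    """

    names: np.ndarray
    elements: np.ndarray
    resnames: np.ndarray
    resids: np.ndarray
    chains: np.ndarray
    radii: np.ndarray
    helix_map: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    pore_helices: tuple[str, ...] = ()
    role_tags: dict[str, tuple[int, ...]] = field(default_factory=dict)
    anchors: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.names)
        for arr, label in [
            (self.elements, "elements"),
            (self.resnames, "resnames"),
            (self.resids, "resids"),
            (self.chains, "chains"),
            (self.radii, "radii"),
        ]:
            if len(arr) != n:
                raise ValueError(f"topology field {label!r} has length {len(arr)}, expected {n}")
        if np.any(self.radii <= 0):
            bad = np.flatnonzero(self.radii <= 0)[0]
            raise ValueError(f"non-positive vdW radius for atom {bad} ({self.names[bad]})")
        self._validate_helix_map()

    def _validate_helix_map(self) -> None:
        seen: list[tuple[int, int]] = []
        for name, ranges in self.helix_map.items():
            for lo, hi in ranges:
                if lo > hi:
                    raise ValueError(f"helix {name}: bad residue range {lo}-{hi}")
                for plo, phi in seen:
                    if lo <= phi and plo <= hi:
                        raise ValueError(f"helix residue ranges overlap at {name} {lo}-{hi}")
                seen.append((lo, hi))

    # ------------------------------------------------------------------ util

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def atom_indices(self, resids) -> np.ndarray:
        """Indices of all atoms belonging to any of the given residue numbers."""
        resids = np.atleast_1d(np.asarray(resids, dtype=int))
        return np.flatnonzero(np.isin(self.resids, resids))

    def ca_mask(self) -> np.ndarray:
        return self.names == "CA"

    def helix_resids(self, helix: str) -> np.ndarray:
        ranges = self.helix_map[helix]
        out = np.concatenate([np.arange(lo, hi + 1) for lo, hi in ranges])
        return out

    def helix_ca_indices(self, helices) -> np.ndarray:
        ca = self.ca_mask()
        resids = np.concatenate([self.helix_resids(h) for h in helices])
        return np.flatnonzero(ca & np.isin(self.resids, resids))

    def water_mask(self) -> np.ndarray:
        return np.isin(self.resnames, sorted(WATER_RESNAMES))

    def ion_mask(self) -> np.ndarray:
        return np.isin(self.resnames, sorted(CHLORIDE_RESNAMES))

    def origin_ca_index(self) -> int:
        """Atom index of the Cα of the z-origin residue."""
        origin = self.role_tags["origin"][0]
        idx = np.flatnonzero((self.resids == origin) & self.ca_mask())
        if idx.size == 0:
            raise ValueError(f"origin residue {origin} has no CA atom")
        return int(idx[0])


@dataclass
class Trajectory:
    """Time-ordered Cartesian frames with per-frame orthorhombic box lengths."""

    coords: np.ndarray  # (n_frames, n_atoms, 3), Angstrom
    times: np.ndarray  # (n_frames,), ns, strictly increasing
    box: np.ndarray  # (n_frames, 3), Angstrom
    aligned: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(f"coords must have shape (F, A, 3), got {self.coords.shape}")
        f = self.coords.shape[0]
        if self.times.shape != (f,):
            raise ValueError("times length does not match number of frames")
        if self.box.shape != (f, 3):
            raise ValueError("box array must have shape (F, 3)")
        if np.any(self.box <= 0):
            raise ValueError("box lengths must be positive")
        if f > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def dt(self) -> float:
        """Mean frame spacing in ns."""
        if self.n_frames < 2:
            return 0.0
        return float(np.mean(np.diff(self.times)))


# --------------------------------------------------------------------------
# plain-text trajectory format


def write_plaintext_trajectory(path, traj: Trajectory, fmt: str = "%.6f") -> None:
    with open(path, "w") as fh:
        fh.write(f"{traj.n_atoms}\n")
        for f in range(traj.n_frames):
            fh.write(fmt % traj.times[f] + "\n")
            fh.write(" ".join(fmt % v for v in traj.box[f]) + "\n")
            np.savetxt(fh, traj.coords[f], fmt=fmt)


def read_plaintext_trajectory(path) -> Trajectory:
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 1:
            raise ValueError(f"{path}: expected single-integer atom-count header")
        n_atoms = int(header[0])
        flat = np.array(fh.read().split(), dtype=float)
    per_frame = 4 + 3 * n_atoms  # 1 time + 3 box + 3N coords
    if flat.size % per_frame != 0:
        raise ValueError(f"{path}: truncated trajectory (got {flat.size} numbers, frame stride {per_frame})")
    n_frames = flat.size // per_frame
    frames = flat.reshape(n_frames, per_frame)
    times = frames[:, 0]
    box = frames[:, 1:4]
    coords = frames[:, 4:].reshape(n_frames, n_atoms, 3)
    return Trajectory(coords=coords, times=times, box=box)


# --------------------------------------------------------------------------
# PDB output (topology + frame 0)

_PDB_ATOM = (
    "ATOM  {serial:>5d} {name:<4s}{resname:>4s} {chain:1s}{resid:>4d}    "
    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {element:>2s}\n"
)


def write_pdb(path, topo: Topology, coords: np.ndarray, box=None) -> None:
    """Write a single-model PDB (ATOM records only)."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (topo.n_atoms, 3):
        raise ValueError("coords shape does not match topology")
    with open(path, "w") as fh:
        if box is not None:
            fh.write(
                "CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{al:7.2f}{be:7.2f}{ga:7.2f} P 1           1\n".format(
                    a=box[0], b=box[1], c=box[2], al=90.0, be=90.0, ga=90.0
                )
            )
        for i in range(topo.n_atoms):
            name = topo.names[i]
            # PDB convention: 1-3 char names start in column 14
            name_fmt = f" {name:<3s}" if len(name) < 4 else name
            fh.write(
                _PDB_ATOM.format(
                    serial=(i % 99999) + 1,
                    name=name_fmt,
                    resname=topo.resnames[i],
                    chain=topo.chains[i] or "A",
                    resid=int(topo.resids[i]) % 10000,
                    x=coords[i, 0],
                    y=coords[i, 1],
                    z=coords[i, 2],
                    occ=1.0,
                    b=0.0,
                    element=topo.elements[i],
                )
            )
        fh.write("END\n")


# --------------------------------------------------------------------------
# annotation files

_REQUIRED_ROLES = ("origin", "gate", "site1", "site2")


def load_annotation(path) -> dict:
    """Parse a YAML annotation file mapping residue ranges to helices and roles."""
    with open(path) as fh:
        ann = yaml.safe_load(fh)
    return normalise_annotation(ann)


def normalise_annotation(ann: dict) -> dict:
    if "helices" not in ann:
        raise ValueError("annotation missing 'helices' section")
    helices: dict[str, list[tuple[int, int]]] = {}
    for name, ranges in ann["helices"].items():
        if isinstance(ranges[0], (int, float)):
            ranges = [ranges]
        helices[name] = [(int(lo), int(hi)) for lo, hi in ranges]
    roles = ann.get("roles", {})
    missing = [r for r in _REQUIRED_ROLES if r not in roles]
    if missing:
        raise ValueError(f"annotation missing required role tags: {missing}")
    tags = {}
    anchors = {}
    for key, val in roles.items():
        if key == "anchors":
            anchors = {h: int(r) for h, r in val.items()}
            continue
        if isinstance(val, (int, float)):
            val = [val]
        tags[key] = tuple(int(v) for v in val)
    out = {
        "helices": helices,
        "pore_helices": tuple(ann.get("pore_helices", list(helices))),
        "role_tags": tags,
        "anchors": anchors,
    }
    return out


# --------------------------------------------------------------------------
# system loading


def _guess_elements(names: np.ndarray, mda_elements=None) -> np.ndarray:
    if mda_elements is not None and all(e for e in mda_elements):
        return np.array([str(e).upper() for e in mda_elements], dtype="U2")
    out = []
    for name in names:
        stripped = "".join(c for c in str(name) if c.isalpha()).upper()
        if stripped[:2] in VDW_RADII and stripped[:2] not in ("CA",):
            out.append(stripped[:2])
        elif stripped[:1] in VDW_RADII:
            out.append(stripped[:1])
        else:
            raise ValueError(f"cannot infer element for atom named {name!r}")
    return np.array(out, dtype="U2")


def _radii_for(elements: np.ndarray) -> np.ndarray:
    radii = np.empty(len(elements))
    for i, el in enumerate(elements):
        key = str(el).upper()
        if key not in VDW_RADII:
            raise ValueError(f"unknown element {el!r} for atom index {i}; extend VDW_RADII")
        radii[i] = VDW_RADII[key]
    return radii


def load_system(topology_path, trajectory_path, annotation_path) -> tuple[Topology, Trajectory]:
    """Read topology + trajectory + annotation into package containers.

    The topology may be PDB or GRO; the trajectory DCD/XTC/TRR (read through
    MDAnalysis, times converted ps -> ns) or the plain-text fallback format.
    Raises on atom-count mismatch between topology and trajectory, unknown
    elements, or missing required role tags.
    """
    topology_path = Path(topology_path)
    trajectory_path = Path(trajectory_path)
    ann = load_annotation(annotation_path)

    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(topology_path))
    names = np.array([a.name for a in u.atoms], dtype="U6")
    resnames = np.array([a.resname for a in u.atoms], dtype="U6")
    resids = np.array([a.resid for a in u.atoms], dtype=int)
    try:
        chains = np.array([a.segid[:1] or "A" for a in u.atoms], dtype="U1")
    except Exception:
        chains = np.full(len(names), "A", dtype="U1")
    mda_elements = None
    if hasattr(u.atoms, "elements"):
        mda_elements = list(u.atoms.elements)
    elements = _guess_elements(names, mda_elements)
    radii = _radii_for(elements)

    topo = Topology(
        names=names,
        elements=elements,
        resnames=resnames,
        resids=resids,
        chains=chains,
        radii=radii,
        helix_map=ann["helices"],
        pore_helices=ann["pore_helices"],
        role_tags=ann["role_tags"],
        anchors=ann["anchors"],
    )

    suffix = trajectory_path.suffix.lower()
    if suffix in (".txt", ".traj", ".dat"):
        traj = read_plaintext_trajectory(trajectory_path)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u2 = mda.Universe(str(topology_path), str(trajectory_path))
        frames, times, boxes = [], [], []
        for ts in u2.trajectory:
            frames.append(ts.positions.astype(float).copy())
            times.append(ts.time / 1000.0)  # ps -> ns
            boxes.append(ts.dimensions[:3].astype(float).copy())
        times = np.asarray(times)
        if len(times) > 1 and np.any(np.diff(times) <= 0):
            times = np.arange(len(times), dtype=float)
        traj = Trajectory(coords=np.asarray(frames), times=times, box=np.asarray(boxes))

    if traj.n_atoms != topo.n_atoms:
        raise ValueError(
            f"atom-count mismatch: trajectory has {traj.n_atoms} atoms, topology has {topo.n_atoms}"
        )
    _check_roles(topo)
    return topo, traj


def _check_roles(topo: Topology) -> None:
    for role, resids in topo.role_tags.items():
        for r in resids:
            if topo.atom_indices(r).size == 0:
                raise ValueError(f"role tag {role!r}: residue {r} resolves to no atoms")
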