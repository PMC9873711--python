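"""Synthetic gated-pore trajectory generator with a ground-truth ledger.

The generator emulates the statistical structure of microsecond MD
trajectories of an anion channel sampled at nanosecond resolution:

* a pseudo-protein scaffold of six ideal transmembrane helices on a hexagon,
  with tagged binding-site, gate and anchor residues at channel-consistent
  axial positions, and optional slow lateral drift of helix ends;
* chloride ions moving by overdamped (Euler-Maruyama) Langevin dynamics on a
  1-D axial potential built from Gaussian binding wells, a central barrier
  whose height switches with a two-state wet/dry gate, and a linear voltage
  tilt; a reflecting wall at the intracellular end and an absorbing,
  re-injecting boundary at the extracellular end make the permeation flux
  countable;
* a two-state continuous-time Markov ("telegraph") gate standing in for
  wetting/dewetting transitions of the hydrophobic bottleneck;
* point pseudo-waters: Poisson-distributed bottleneck waters whose mean
  jumps between the dry and wet hydration levels, a uniform bath outside the
  bottleneck, and first-solvation-shell waters placed around each in-pore
  ion with a smaller mean count inside the bottleneck than in the vestibule
  (partial dehydration of the permeating anion).

Energies are expressed in units of kT (kT = 1); the voltage enters only as
a linear tilt of the synthetic potential.  Every stage is reproducible
bit-for-bit from (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import yaml

from .io import Topology, Trajectory, VDW_RADII, write_pdb, write_plaintext_trajectory

__all__ = [
    "GaussianWell",
    "Barrier",
    "GateRates",
    "WaterModel",
    "PoreRegion",
    "ScaffoldSpec",
    "SyntheticConfig",
    "TruthRecord",
    "SyntheticSystem",
    "build_scaffold",
    "simulate_gate",
    "simulate_ions",
    "simulate_waters",
    "generate",
    "write_system",
    "potential",
    "boltzmann_profile",
    "mean_first_passage_time",
]

HELIX_RISE = 1.5  # Angstrom per residue, ideal alpha helix


# --------------------------------------------------------------------------
# configuration


@dataclass
class GaussianWell:
    z_center: float
    depth: float  # kT, > 0 (well is attractive)
    width: float  # Angstrom (Gaussian sigma)


@dataclass
class Barrier:
    z_center: float = 0.0
    height_dry: float = 12.0  # kT
    height_wet: float = 3.0  # kT
    width: float = 3.0
    impenetrable_dry: bool = False  # hard wall at z_center while the gate is dry


@dataclass
class GateRates:
    k_wet: float = 0.004  # /ns, dry -> wet
    k_dry: float = 0.010  # /ns, wet -> dry


@dataclass
class WaterModel:
    lambda_dry: float = 5.0  # mean bottleneck water count, dry gate
    lambda_wet: float = 30.0  # mean bottleneck water count, wet gate
    n_bath: int = 240  # fixed background waters outside the bottleneck
    shell_mean_vestibule: float = 6.0  # mean first-shell waters, |z| > 5
    shell_mean_bottleneck: float = 4.8  # mean first-shell waters, -5 < z < 5
    shell_r_mean: float = 2.6  # Angstrom, ion-water distance
    shell_r_sigma: float = 0.25
    exclusion: float = 4.5  # bath/bottleneck waters keep this far from ions


@dataclass
class PoreRegion:
    radius: float = 8.0  # ion/water sampling disc, < scaffold hexagon radius
    z_min: float = -40.0
    z_max: float = 20.0


@dataclass
class ScaffoldSpec:
    hex_radius: float = 10.0
    drift: dict = field(default_factory=lambda: {"TM1": 2.5, "TM6": 1.0})  # amplitudes, Angstrom
    drift_period: float = 600.0  # ns
    dunk: bool = True  # R334-analogue sidechain tracks approaching ions
    dunk_jitter: float = 0.2
    grid_spacing: float = 1.2  # binding-site capture grid (see methods note)


@dataclass
class SyntheticConfig:
    n_frames: int = 1500
    dt: float = 1.0  # ns per emitted frame
    n_ions: int = 8
    kT: float = 1.0
    wells: list = field(
        default_factory=lambda: [GaussianWell(-28.0, 4.0, 3.0), GaussianWell(-12.0, 3.0, 3.0)]
    )
    barrier: Barrier = field(default_factory=Barrier)
    voltage_tilt: float = -0.08  # kT/Angstrom; negative drives anions to +z
    gate: GateRates = field(default_factory=GateRates)
    gate_fixed: str | None = None  # None | "wet" | "dry"
    diffusion_D: float = 10.0  # Angstrom^2/ns
    substep_disp: float = 0.5  # max diffusive displacement per substep, Angstrom
    pore: PoreRegion = field(default_factory=PoreRegion)
    water: WaterModel = field(default_factory=WaterModel)
    scaffold: ScaffoldSpec = field(default_factory=ScaffoldSpec)
    boundary: str = "reinject"  # "reinject" (flux-countable) or "reflect" (equilibrium)
    reinject_window: tuple = (2.0, 7.0)  # re-entry band, offsets above z_min (Angstrom)
    reinject_delay_frames: int = 0  # frames an absorbed ion stays parked before re-entry
    init: str = "uniform"  # initial ion placement: "uniform" or "boltzmann"
    seed: int = 0

    def validate(self) -> None:
        if self.n_frames < 1 or self.n_ions < 0:
            raise ValueError("n_frames must be >= 1 and n_ions >= 0")
        if self.dt <= 0 or self.diffusion_D <= 0:
            raise ValueError("dt and diffusion_D must be positive")
        for w in self.wells:
            if w.width <= 0 or w.depth < 0:
                raise ValueError("well widths must be positive and depths non-negative")
        if self.barrier.width <= 0:
            raise ValueError("barrier width must be positive")
        if self.barrier.height_dry < self.barrier.height_wet:
            raise ValueError("height_dry must be >= height_wet")
        if self.gate_fixed not in (None, "wet", "dry"):
            raise ValueError("gate_fixed must be None, 'wet' or 'dry'")
        if self.gate_fixed is None and (self.gate.k_wet < 0 or self.gate.k_dry < 0):
            raise ValueError("gate rates must be non-negative")
        if self.water.lambda_wet < self.water.lambda_dry or self.water.lambda_dry < 0:
            raise ValueError("need lambda_wet >= lambda_dry >= 0")
        if self.pore.z_min >= self.pore.z_max or self.pore.radius <= 0:
            raise ValueError("invalid pore region")
        if self.boundary not in ("reinject", "reflect"):
            raise ValueError("boundary must be 'reinject' or 'reflect'")

    # ------------------------------------------------------------- presets

    @classmethod
    def field_on(cls, **overrides) -> "SyntheticConfig":
        """Hyperpolarised condition: voltage tilt plus field-induced wetting."""
        return cls(**overrides)

    @classmethod
    def field_off(cls, **overrides) -> "SyntheticConfig":
        """No applied field: no tilt and a gate that essentially never wets."""
        cfg = cls(**overrides)
        cfg.voltage_tilt = 0.0
        cfg.gate = GateRates(k_wet=1e-4, k_dry=0.05)
        return cfg

    @classmethod
    def equilibrium(cls, n_frames: int = 1, n_ions: int = 1_000_000, **overrides) -> "SyntheticConfig":
        """Unbiased, closed (reflect-both) ensemble for stationarity checks.

        Designed so the emitted ion-frames are strictly independent draws
        from the stationary law: a wide ensemble of independent walkers
        initialised from the exact Boltzmann distribution and emitted after
        one 10 ns evolution interval (one frame per walker, so count
        variances carry no autocorrelation inflation), with wells shallow
        and wide enough that the Euler-Maruyama stationary-density bias
        stays below the resolution of a million-sample histogram test.
        Intended for direct ion-marginal simulation (simulate_ions); do not
        feed an ensemble this wide through the full system assembly.
        """
        cfg = cls(n_frames=n_frames, n_ions=n_ions, dt=10.0, **overrides)
        cfg.voltage_tilt = 0.0
        cfg.boundary = "reflect"
        cfg.gate_fixed = "wet"
        cfg.barrier = Barrier(height_dry=1.2, height_wet=1.2)
        cfg.wells = [GaussianWell(-28.0, 2.0, 4.0), GaussianWell(-12.0, 1.5, 3.5)]
        cfg.init = "boltzmann"
        cfg.substep_disp = 0.3
        cfg.scaffold = ScaffoldSpec(drift={})
        return cfg

    @classmethod
    def single_well(
        cls,
        depth: float = 5.9,
        width: float = 2.0,
        n_frames: int = 4000,
        n_ions: int = 16,
        **overrides,
    ) -> "SyntheticConfig":
        """One binding well set up as a clean first-passage experiment.

        The domain is a sliver around the well: a reflecting wall just below
        it and the absorbing boundary just above the contact capture band, so
        a binding interval measured by the contact rule coincides with the
        first-passage time from the re-injection point (near the well bottom)
        to the absorbing boundary.  Absorbed ions stay parked for a few
        frames before re-entering, so consecutive intervals can never be
        bridged together.  The default depth gives a mean escape time of
        roughly 30 ns at D = 10 A^2/ns (cf. mean_first_passage_time with a
        reflecting lower boundary).
        """
        cfg = cls(n_frames=n_frames, n_ions=n_ions, dt=0.5, **overrides)
        cfg.wells = [GaussianWell(-28.0, depth, width)]
        cfg.barrier = Barrier(height_dry=0.0, height_wet=0.0)
        cfg.voltage_tilt = 0.0
        cfg.boundary = "reinject"
        cfg.reinject_window = (1.0, 3.5)  # z in (-29.5, -27.0), around the well bottom
        cfg.reinject_delay_frames = 4
        cfg.substep_disp = 0.25  # keep first-passage discretisation bias ~1%
        cfg.gate_fixed = "wet"
        cfg.pore = PoreRegion(z_min=-30.5, z_max=-24.0)
        cfg.init = "uniform"
        cfg.scaffold = ScaffoldSpec(drift={})
        # background waters are irrelevant here and cannot be placed outside
        # the crowded ion exclusion zones of this sliver domain
        cfg.water = WaterModel(lambda_dry=0.0, lambda_wet=0.0, n_bath=0)
        return cfg


# --------------------------------------------------------------------------
# potential


def _gaussian_terms(cfg: SyntheticConfig, gate_wet: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    centers = [w.z_center for w in cfg.wells]
    coefs = [-w.depth for w in cfg.wells]
    inv_w2 = [1.0 / w.width**2 for w in cfg.wells]
    height = cfg.barrier.height_wet if gate_wet else cfg.barrier.height_dry
    centers.append(cfg.barrier.z_center)
    coefs.append(height)
    inv_w2.append(1.0 / cfg.barrier.width**2)
    return np.asarray(centers), np.asarray(coefs), np.asarray(inv_w2)


def potential(cfg: SyntheticConfig, z, gate_wet: bool = True) -> np.ndarray:
    """Axial potential U(z) in kT for the given gate state."""
    z = np.asarray(z, dtype=float)
    centers, coefs, inv_w2 = _gaussian_terms(cfg, gate_wet)
    dz = z[..., None] - centers
    u = np.sum(coefs * np.exp(-0.5 * dz**2 * inv_w2), axis=-1)
    return u + cfg.voltage_tilt * z


def boltzmann_profile(cfg: SyntheticConfig, edges: np.ndarray, gate_wet: bool = True) -> np.ndarray:
    """Expected stationary bin probabilities proportional to integral exp(-U)."""
    edges = np.asarray(edges, dtype=float)
    zfine = np.linspace(edges[0], edges[-1], 20001)
    w = np.exp(-potential(cfg, zfine, gate_wet))
    cum = np.concatenate([[0.0], np.cumsum((w[1:] + w[:-1]) / 2 * np.diff(zfine))])
    binmass = np.interp(edges, zfine, cum)
    p = np.diff(binmass)
    return p / p.sum()


def mean_first_passage_time(
    cfg: SyntheticConfig,
    z_start: float,
    a: float,
    b: float,
    gate_wet: bool = True,
    n_grid: int = 8001,
) -> float:
    """Mean first-passage time (ns) from ``z_start`` to absorption at a or b.

    Numerical solution of D d/dz [exp(-U) d tau/dz] = -exp(-U) with
    tau(a) = tau(b) = 0 by trapezoidal quadrature; serves as the independent
    oracle for binding residence times.
    """
    if not a < z_start < b:
        raise ValueError("need a < z_start < b")
    z = np.linspace(a, b, n_grid)
    u = potential(cfg, z, gate_wet)
    u = u - u.min()  # overflow guard; MFPT is invariant to potential offset
    em = np.exp(-u)
    ep = np.exp(u)
    dz = z[1] - z[0]
    g = np.concatenate([[0.0], np.cumsum((em[1:] + em[:-1]) / 2 * dz)])  # int_a^z e^-U
    integrand = ep * g
    h = np.concatenate([[0.0], np.cumsum((integrand[1:] + integrand[:-1]) / 2 * dz)])
    ep_int = np.concatenate([[0.0], np.cumsum((ep[1:] + ep[:-1]) / 2 * dz)])
    d = cfg.diffusion_D
    c = h[-1] / ep_int[-1] / d
    tau = c * ep_int - h / d
    return float(np.interp(z_start, z, tau))


def mfpt_reflecting(
    cfg: SyntheticConfig,
    z_start,
    a: float,
    b: float,
    gate_wet: bool = True,
    n_grid: int = 8001,
) -> float:
    """Mean first-passage time (ns) to ``b`` with a reflecting wall at ``a``.

    tau(x) = (1/D) int_x^b exp(U(y)) int_a^y exp(-U(s)) ds dy.  ``z_start``
    may be a scalar or an array (the result is averaged), so a distributed
    re-entry point can be handled exactly.
    """
    z = np.linspace(a, b, n_grid)
    u = potential(cfg, z, gate_wet)
    u = u - u.min()
    em = np.exp(-u)
    ep = np.exp(u)
    dz = z[1] - z[0]
    g = np.concatenate([[0.0], np.cumsum((em[1:] + em[:-1]) / 2 * dz)])
    integrand = ep * g
    h = np.concatenate([[0.0], np.cumsum((integrand[1:] + integrand[:-1]) / 2 * dz)])
    tau = (h[-1] - h) / cfg.diffusion_D
    z0 = np.atleast_1d(np.asarray(z_start, dtype=float))
    return float(np.mean(np.interp(z0, z, tau)))


# --------------------------------------------------------------------------
# scaffold

# name, hexagon angle (deg), resid range, True if resid increases with +z
_HELIX_LAYOUT = [
    ("TM1", 90.0, (76, 116), True),
    ("TM2", -150.0, (118, 158), True),
    ("TM6", 30.0, (324, 364), False),
    ("TM8", -90.0, (874, 914), True),
    ("TM11", -30.0, (1018, 1058), True),
    ("TM12", 150.0, (1121, 1161), False),
]

_ANCHORS = {"TM1": 106, "TM6": 334, "TM8": 914, "TM12": 1131}

# charged/tagged sidechains carried by helix residues: resid -> (resname, atoms)
_LYS_ATOMS = ("NZ",)
_ARG_ATOMS = ("NE", "CZ", "NH1", "NH2")
_SIDECHAINS = {
    95: ("LYS", _LYS_ATOMS),
    98: ("GLN", ("OE1",)),
    134: ("ARG", _ARG_ATOMS),
    334: ("ARG", _ARG_ATOMS),
}
# standalone portal-site residues (z set to the first well centre): angle deg
_SITE1_RESIDUES = {190: ("LYS", _LYS_ATOMS, 210.0), 248: ("ARG", _ARG_ATOMS, 270.0), 303: ("ARG", _ARG_ATOMS, 330.0)}
_SITE2_RESIDUES = (95, 98, 134)

SYNTHETIC_ANNOTATION = {
    "helices": {name: list(rng) for name, _, rng, _ in _HELIX_LAYOUT},
    "pore_helices": ["TM1", "TM2", "TM6", "TM8", "TM11", "TM12"],
    "roles": {
        "origin": 338,
        "gate": [99, 102, 106, 337, 1137, 338, 1134],
        "site1": [190, 248, 303],
        "site2": [95, 98, 134],
        "basic": [95, 134, 190, 248, 303, 334],
        "anchors": dict(_ANCHORS),
    },
}

#: Contact cutoff (Angstrom) appropriate for the hydrogen-free pseudo-waters.
SYNTHETIC_CONTACT_CUTOFF = 3.5


def _helix_z(resid: int, rng: tuple[int, int], ascending: bool) -> float:
    lo, hi = rng
    if ascending:
        return -40.0 + (resid - lo) * HELIX_RISE
    return 21.0 - (resid - lo) * HELIX_RISE


def _site_grid(spacing: float, r_max: float) -> np.ndarray:
    """Hexagonal xy grid covering the pore disc (binding-site capture patch)."""
    pts = []
    dy = spacing * np.sqrt(3) / 2
    j = 0
    y = -r_max
    while y <= r_max:
        x0 = -r_max + (spacing / 2 if j % 2 else 0.0)
        x = x0
        while x <= r_max:
            if x * x + y * y <= r_max * r_max:
                pts.append((x, y))
            x += spacing
        y += dy
        j += 1
    return np.asarray(pts)


def _ramp(z: np.ndarray) -> np.ndarray:
    # lateral drift grows towards the extracellular helix ends, pivot below
    return np.clip((z + 10.0) / 15.0, 0.0, 1.0)


@dataclass
class _ScaffoldAtoms:
    names: list
    elements: list
    resnames: list
    resids: list
    base_xyz: list  # (x, y, z) at rest
    helix_of: list  # helix name or None
    radial_unit: list  # unit xy vector for drift, or (0, 0)


def _build_scaffold_atoms(cfg: SyntheticConfig) -> _ScaffoldAtoms:
    sc = _ScaffoldAtoms([], [], [], [], [], [], [])
    R = cfg.scaffold.hex_radius

    def add(name, element, resname, resid, xyz, helix, unit):
        sc.names.append(name)
        sc.elements.append(element)
        sc.resnames.append(resname)
        sc.resids.append(resid)
        sc.base_xyz.append(xyz)
        sc.helix_of.append(helix)
        sc.radial_unit.append(unit)

    for hname, ang, rng, asc in _HELIX_LAYOUT:
        th = np.deg2rad(ang)
        ux, uy = np.cos(th), np.sin(th)
        for resid in range(rng[0], rng[1] + 1):
            z = _helix_z(resid, rng, asc)
            resname, side = _SIDECHAINS.get(resid, ("ALA", ()))
            add("CA", "C", resname, resid, (R * ux, R * uy, z), hname, (ux, uy))
            for k, aname in enumerate(side):
                # sidechain points inward; guanidinium atoms form a small square
                r_in = 5.5 if resid == 334 else 5.0
                off = 0.6 * np.array([np.cos(k * np.pi / 2), np.sin(k * np.pi / 2)]) if len(side) > 1 else np.zeros(2)
                el = "N" if aname.startswith("N") else "O" if aname.startswith("O") else "C"
                if aname == "CZ":
                    el = "C"
                add(aname, el, resname, resid, (r_in * ux + off[0], r_in * uy + off[1], z), hname, (ux, uy))

    # standalone portal-site residues at the first well centre
    z_site1 = cfg.wells[0].z_center if cfg.wells else -28.0
    for resid, (resname, side, ang) in _SITE1_RESIDUES.items():
        th = np.deg2rad(ang)
        ux, uy = np.cos(th), np.sin(th)
        add("CA", "C", resname, resid, (R * ux, R * uy, z_site1), None, (0.0, 0.0))
        for k, aname in enumerate(side):
            off = 0.6 * np.array([np.cos(k * np.pi / 2), np.sin(k * np.pi / 2)]) if len(side) > 1 else np.zeros(2)
            el = "N" if aname.startswith("N") else "C"
            add(aname, el, resname, resid, (4.0 * ux + off[0], 4.0 * uy + off[1], z_site1), None, (0.0, 0.0))

    # capture grids: flat patches of pseudo-atoms spanning the pore disc at
    # each binding-site plane, so that the 3 A-scale contact rule reduces to a
    # clean axial capture band for ions anywhere in the sampling disc
    grid = _site_grid(cfg.scaffold.grid_spacing, cfg.pore.radius + 0.3)
    ang_site1 = {190: 210.0, 248: 270.0, 303: 330.0}

    def add_grid(z_plane, members, angles):
        th = np.array([np.deg2rad(angles[m]) for m in members])
        for gx, gy in grid:
            a = np.arctan2(gy, gx)
            pick = int(np.argmin(np.abs(np.angle(np.exp(1j * (a - th))))))
            resid = members[pick]
            resname = sc.resnames[sc.resids.index(resid)]
            add("GC", "C", resname, resid, (gx, gy, z_plane), None, (0.0, 0.0))

    add_grid(z_site1, list(_SITE1_RESIDUES), ang_site1)
    if len(cfg.wells) > 1:
        ang_site2 = {95: 90.0, 98: 90.0, 134: -150.0}
        add_grid(cfg.wells[1].z_center, list(_SITE2_RESIDUES), ang_site2)
    return sc


def build_scaffold(cfg: SyntheticConfig) -> tuple[Topology, Trajectory]:
    """Pseudo-protein scaffold: six ideal helices plus tagged pseudo-residues.

    Helix Cα atoms sit on vertical lines through a hexagon of circumradius
    ``scaffold.hex_radius``; per-frame lateral drift (radial sinusoid ramping
    towards the extracellular ends) is applied to helices listed in
    ``scaffold.drift``.  The origin residue's Cα defines z = 0 in every frame.
    """
    cfg.validate()
    sc = _build_scaffold_atoms(cfg)
    n_atoms = len(sc.names)
    base = np.asarray(sc.base_xyz, dtype=float)
    units = np.asarray(sc.radial_unit, dtype=float)
    helices = np.asarray(sc.helix_of, dtype=object)

    times = np.arange(cfg.n_frames, dtype=float) * cfg.dt
    coords = np.broadcast_to(base, (cfg.n_frames, n_atoms, 3)).copy()
    phases = {"TM1": 0.0, "TM2": 1.0, "TM6": np.pi / 2, "TM8": 2.0, "TM11": 3.0, "TM12": 4.0}
    for hname, amp in cfg.scaffold.drift.items():
        if amp == 0:
            continue
        mask = helices == hname
        ramp = _ramp(base[mask, 2])
        disp = amp * np.sin(2 * np.pi * times / cfg.scaffold.drift_period + phases.get(hname, 0.0))
        coords[:, mask, 0] += disp[:, None] * ramp * units[mask, 0]
        coords[:, mask, 1] += disp[:, None] * ramp * units[mask, 1]

    # box z exceeds the 60 A scaffold span so that no two scaffold atoms alias
    # across the periodic boundary; re-injection jumps still exceed box_z/2
    box_z = max(70.0, (cfg.pore.z_max - cfg.pore.z_min) + 10.0)
    box = np.tile(np.array([100.0, 100.0, box_z]), (cfg.n_frames, 1))
    ann = SYNTHETIC_ANNOTATION
    topo = Topology(
        names=np.asarray(sc.names, dtype="U6"),
        elements=np.asarray(sc.elements, dtype="U2"),
        resnames=np.asarray(sc.resnames, dtype="U6"),
        resids=np.asarray(sc.resids, dtype=int),
        chains=np.full(n_atoms, "A", dtype="U1"),
        radii=np.asarray([VDW_RADII[e] for e in sc.elements]),
        helix_map={k: [tuple(v)] for k, v in ann["helices"].items()},
        pore_helices=tuple(ann["pore_helices"]),
        role_tags={
            "origin": (338,),
            "gate": tuple(ann["roles"]["gate"]),
            "site1": tuple(ann["roles"]["site1"]),
            "site2": tuple(ann["roles"]["site2"]),
            "basic": tuple(ann["roles"]["basic"]),
        },
        anchors=dict(_ANCHORS),
    )
    traj = Trajectory(coords=coords, times=times, box=box)
    return topo, traj


# --------------------------------------------------------------------------
# gate


def simulate_gate(cfg: SyntheticConfig, seed: int | None = None) -> tuple[np.ndarray, list]:
    """Two-state telegraph gate sampled at the frame cadence.

    Continuous-time Markov chain with exact exponential waiting times; state
    0 is dry, 1 is wet; the chain starts dry (the de-wetted resting state).
    Returns (per-frame states, list of (time, new_state) transitions).
    """
    cfg.validate()
    n = cfg.n_frames
    if cfg.gate_fixed is not None:
        s = 1 if cfg.gate_fixed == "wet" else 0
        return np.full(n, s, dtype=np.int8), []
    rng = np.random.default_rng(cfg.seed * 3 + 1 if seed is None else seed)
    t_end = n * cfg.dt
    t, state = 0.0, 0
    transitions: list[tuple[float, int]] = []
    times: list[float] = [0.0]
    states: list[int] = [0]
    while t < t_end:
        rate = cfg.gate.k_wet if state == 0 else cfg.gate.k_dry
        if rate <= 0:
            break
        t += rng.exponential(1.0 / rate)
        if t >= t_end:
            break
        state = 1 - state
        transitions.append((t, state))
        times.append(t)
        states.append(state)
    frame_t = np.arange(n) * cfg.dt
    idx = np.searchsorted(np.asarray(times), frame_t, side="right") - 1
    return np.asarray(states, dtype=np.int8)[idx], transitions


# --------------------------------------------------------------------------
# ions


class SimulationUnstableError(RuntimeError):
    pass


@dataclass
class TruthRecord:
    """Ground truth emitted alongside a synthetic trajectory."""

    gate_states: np.ndarray
    gate_transitions: list
    crossings: list  # dicts: ion, frame, time, direction (frame-resolution ledger)
    n_absorptions: int  # full boundary absorptions counted during substepping
    committor_planes: tuple
    binding_intervals: dict  # site -> list of (ion, frame_start, frame_stop)
    mean_residence: dict  # site -> mean interval duration, ns
    capture_half_width: float

    @property
    def net_count(self) -> int:
        return sum(c["direction"] for c in self.crossings)

    def crossing_count(self) -> int:
        return len(self.crossings)


def _sample_boltzmann(cfg: SyntheticConfig, n: int, gate_wet: bool, rng) -> np.ndarray:
    z = np.linspace(cfg.pore.z_min, cfg.pore.z_max, 4001)
    w = np.exp(-potential(cfg, z, gate_wet))
    w /= w.sum()
    return rng.choice(z, size=n, p=w) + rng.uniform(-0.0075, 0.0075, size=n)


def _frame_crossings(z_frames: np.ndarray, z_low: float, z_high: float, box_z: float) -> list:
    """Wrap-aware two-plane hysteresis ledger for one ion (frame resolution)."""
    events = []
    state = None
    prev = None
    for i, zi in enumerate(z_frames):
        if prev is not None:
            d = zi - prev
            if d < -box_z / 2:
                state = "below"  # re-entered through the periodic/reinjection boundary
            elif d > box_z / 2:
                state = "above"
        if zi < z_low:
            if state == "above":
                events.append((i, -1))
            state = "below"
        elif zi > z_high:
            if state == "below":
                events.append((i, +1))
            state = "above"
        prev = zi
    return events


def simulate_ions(
    cfg: SyntheticConfig,
    gate_states: np.ndarray,
    seed: int | None = None,
    committor_planes: tuple[float, float] = (-20.0, 10.0),
) -> tuple[np.ndarray, np.ndarray, TruthRecord]:
    """Overdamped Langevin ion dynamics on the gated axial potential.

    Euler-Maruyama with substeps chosen so the diffusive substep displacement
    sqrt(2 D dt_sub) <= 0.5 A.  Reflecting wall at ``pore.z_min``; with the
    ``reinject`` boundary an ion reaching ``pore.z_max`` is absorbed (logged),
    held at the boundary until the end of the frame interval (so the crossing
    is visible at frame resolution) and re-injected near the intracellular
    entrance at the start of the next frame.  Returns per-frame ion z (F, N),
    xy (F, N, 2) sampled uniformly in the pore disc, and the TruthRecord.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed * 3 + 2 if seed is None else seed)
    n_f, n_i = cfg.n_frames, cfg.n_ions
    d = cfg.diffusion_D
    dt_sub_max = cfg.substep_disp**2 / (2 * d)
    n_sub = max(1, int(np.ceil(cfg.dt / dt_sub_max)))
    dt_sub = cfg.dt / n_sub
    noise_scale = np.sqrt(2 * d * dt_sub)
    # Mannella boundary-shift correction for discrete-time absorption: the
    # effective absorbing plane sits 0.5826 * sqrt(2 D dt_sub) inside the
    # nominal one, compensating sub-step crossings the sampler cannot see
    z_absorb = cfg.pore.z_max - 0.5826 * noise_scale

    z_lo, z_hi = cfg.pore.z_min, cfg.pore.z_max
    box_z = z_hi - z_lo
    reinject = cfg.boundary == "reinject"
    bc = cfg.barrier.z_center

    terms = {
        True: _gaussian_terms(cfg, True),
        False: _gaussian_terms(cfg, False),
    }

    if cfg.init == "boltzmann":
        z = _sample_boltzmann(cfg, n_i, bool(gate_states[0]), rng)
    else:
        z = rng.uniform(z_lo + 1.0, min(-10.0, z_hi - 1.0), size=n_i)
    parked = np.zeros(n_i, dtype=bool)
    parked_age = np.zeros(n_i, dtype=int)

    z_out = np.empty((n_f, n_i))
    n_absorb = 0
    tilt = cfg.voltage_tilt
    for f in range(n_f):
        wet = bool(gate_states[f])
        centers, coefs, inv_w2 = terms[wet]
        hard_wall = cfg.barrier.impenetrable_dry and not wet
        # re-inject absorbed ions once their parking delay has elapsed
        if reinject and parked.any():
            ready = parked & (parked_age >= cfg.reinject_delay_frames)
            if ready.any():
                k = int(ready.sum())
                z[ready] = rng.uniform(
                    z_lo + cfg.reinject_window[0], z_lo + cfg.reinject_window[1], size=k
                )
                parked[ready] = False
            parked_age[parked] += 1
        for s in range(n_sub):
            dzc = z[:, None] - centers
            force = np.sum(coefs * inv_w2 * dzc * np.exp(-0.5 * dzc**2 * inv_w2), axis=1) - tilt
            step = d * force * dt_sub + noise_scale * rng.standard_normal(n_i)
            if np.any(np.abs(step) > 5.0):
                raise SimulationUnstableError(
                    "ion displacement exceeded 5 A in one substep; reduce dt or diffusion_D"
                )
            z_new = z + step
            if hard_wall:
                crossed = (z - bc) * (z_new - bc) < 0
                z_new[crossed] = 2 * bc - z_new[crossed]
            # reflecting bottom wall
            low = z_new < z_lo
            z_new[low] = 2 * z_lo - z_new[low]
            if reinject:
                hit = (z_new >= z_absorb) & ~parked
                if hit.any():
                    n_absorb += int(hit.sum())
                    parked |= hit
                    parked_age[hit] = 0
                z_new[parked] = z_hi
            else:
                high = z_new > z_hi
                z_new[high] = 2 * z_hi - z_new[high]
            z = z_new
        z_out[f] = z

    # xy positions: uniform in the sampling disc, resampled every frame
    r = cfg.pore.radius * np.sqrt(rng.uniform(size=(n_f, n_i)))
    th = rng.uniform(0, 2 * np.pi, size=(n_f, n_i))
    xy = np.stack([r * np.cos(th), r * np.sin(th)], axis=-1)

    # frame-resolution crossing ledger
    crossings = []
    for i in range(n_i):
        for frame, direction in _frame_crossings(z_out[:, i], *committor_planes, box_z):
            crossings.append(
                {"ion": i, "frame": frame, "time": frame * cfg.dt, "direction": direction}
            )
    crossings.sort(key=lambda c: (c["time"], c["ion"]))

    # binding-interval ledger: axial capture bands around the well centres
    half_width = _capture_half_width(cfg)
    sites = {"site1": cfg.wells[0].z_center} if cfg.wells else {}
    if len(cfg.wells) > 1:
        sites["site2"] = cfg.wells[1].z_center
    intervals: dict[str, list] = {s: [] for s in sites}
    for sname, zc in sites.items():
        inband = np.abs(z_out - zc) <= half_width
        padded = np.zeros((n_i, n_f + 2), dtype=np.int8)
        padded[:, 1:-1] = inband.T
        d = np.diff(padded, axis=1)
        starts = np.argwhere(d == 1)
        stops = np.argwhere(d == -1)
        intervals[sname] = [
            (int(i), int(a), int(b - 1)) for (i, a), (_, b) in zip(starts, stops)
        ]
    mean_res = {
        s: (float(np.mean([(b - a + 1) * cfg.dt for _, a, b in v])) if v else float("nan"))
        for s, v in intervals.items()
    }

    truth = TruthRecord(
        gate_states=np.asarray(gate_states),
        gate_transitions=[],
        crossings=crossings,
        n_absorptions=n_absorb,
        committor_planes=committor_planes,
        binding_intervals=intervals,
        mean_residence=mean_res,
        capture_half_width=half_width,
    )
    return z_out, xy, truth


def _capture_half_width(cfg: SyntheticConfig) -> float:
    """Mean axial half-width of the 3.5 A contact band over the capture grid."""
    s = cfg.scaffold.grid_spacing
    # mean squared xy offset to the nearest hexagonal grid point
    mean_off2 = (s / 2) ** 2 * 0.5
    return float(np.sqrt(SYNTHETIC_CONTACT_CUTOFF**2 - mean_off2))


# --------------------------------------------------------------------------
# waters


def simulate_waters(
    cfg: SyntheticConfig,
    gate_states: np.ndarray,
    ion_z: np.ndarray,
    ion_xy: np.ndarray,
    seed: int | None = None,
) -> tuple[np.ndarray, dict]:
    """Pseudo-water positions per frame (bottleneck pool, bath, ion shells).

    Bottleneck waters are Poisson with the state-dependent mean; bath waters
    fill the pore outside the bottleneck; first-shell waters are placed on a
    2.6 A shell around each in-pore ion with a lower mean inside the
    bottleneck than in the vestibule.  Bath and bottleneck waters keep an
    exclusion distance from every ion so they never leak into measured
    first-shell counts.  Waters are point pseudo-atoms without identity
    across frames; unused pool slots are parked far outside the pore.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed * 3 + 3 if seed is None else seed)
    n_f = cfg.n_frames
    n_i = ion_z.shape[1] if ion_z.size else 0
    w = cfg.water
    rad = cfg.pore.radius
    box = np.array([100.0, 100.0, cfg.pore.z_max - cfg.pore.z_min])
    ghost = np.array([45.0, 45.0, 0.0])

    n_pool_b = int(np.ceil(w.lambda_wet + 6 * np.sqrt(max(w.lambda_wet, 1.0))))
    n_shell_per_ion = 20
    n_total = n_pool_b + w.n_bath + n_shell_per_ion * n_i
    coords = np.tile(ghost, (n_f, n_total, 1))

    lam = np.where(np.asarray(gate_states, dtype=bool), w.lambda_wet, w.lambda_dry)

    def far_from_ions(pts, f):
        if n_i == 0 or len(pts) == 0:
            return np.ones(len(pts), dtype=bool)
        ions = np.column_stack([ion_xy[f], ion_z[f]])
        delta = pts[:, None, :] - ions[None, :, :]
        delta -= box * np.round(delta / box)
        d2 = np.sum(delta**2, axis=-1)
        return np.all(d2 > w.exclusion**2, axis=1)

    def disc(n):
        r = rad * np.sqrt(rng.uniform(size=n))
        t = rng.uniform(0, 2 * np.pi, size=n)
        return r * np.cos(t), r * np.sin(t)

    bottleneck_lo = max(-5.0, cfg.pore.z_min)
    bottleneck_hi = min(5.0, cfg.pore.z_max)
    has_bottleneck = bottleneck_hi > bottleneck_lo
    bath_regions = [
        (lo, hi)
        for lo, hi in [(cfg.pore.z_min, min(-5.0, cfg.pore.z_max)), (max(5.0, cfg.pore.z_min), cfg.pore.z_max)]
        if hi > lo
    ]
    bath_lens = np.array([hi - lo for lo, hi in bath_regions])

    for f in range(n_f):
        # bottleneck pool
        n_b = min(int(rng.poisson(lam[f])), n_pool_b) if has_bottleneck else 0
        placed = 0
        for _ in range(30):
            if placed >= n_b:
                break
            need = n_b - placed
            x, y = disc(need)
            z = rng.uniform(bottleneck_lo, bottleneck_hi, size=need)
            pts = np.column_stack([x, y, z])
            ok = far_from_ions(pts, f)
            k = int(ok.sum())
            coords[f, placed : placed + k] = pts[ok]
            placed += k
        # bath (outside the bottleneck)
        placed = 0
        off = n_pool_b
        if bath_regions:
            for _ in range(30):
                if placed >= w.n_bath:
                    break
                need = w.n_bath - placed
                x, y = disc(need)
                pick = rng.choice(len(bath_regions), size=need, p=bath_lens / bath_lens.sum())
                lo = np.array([bath_regions[j][0] for j in pick])
                hi = np.array([bath_regions[j][1] for j in pick])
                z = rng.uniform(lo, hi)
                pts = np.column_stack([x, y, z])
                ok = far_from_ions(pts, f)
                k = int(ok.sum())
                coords[f, off + placed : off + placed + k] = pts[ok]
                placed += k
        # first-solvation shells; a shell water of ion i is kept away from all
        # other ions so each measured count equals the count drawn for its ion
        off = n_pool_b + w.n_bath
        if n_i:
            ions_f = np.column_stack([ion_xy[f], ion_z[f]])
        for i in range(n_i):
            zi = ion_z[f, i]
            if not (cfg.pore.z_min < zi < cfg.pore.z_max):
                continue
            mean = w.shell_mean_bottleneck if -5.0 < zi < 5.0 else w.shell_mean_vestibule
            n_s = min(int(rng.poisson(mean)), n_shell_per_ion)
            if n_s == 0:
                continue
            center = ions_f[i]
            others = np.delete(ions_f, i, axis=0)
            placed_pts = np.empty((n_s, 3))
            got = 0
            for _ in range(40):
                if got >= n_s:
                    break
                need = n_s - got
                v = rng.standard_normal((need, 3))
                v /= np.linalg.norm(v, axis=1, keepdims=True)
                r = np.clip(rng.normal(w.shell_r_mean, w.shell_r_sigma, size=need), 2.0, 3.4)
                pts = center + v * r[:, None]
                if len(others):
                    delta = pts[:, None, :] - others[None, :, :]
                    delta -= box * np.round(delta / box)
                    ok = np.all(np.sum(delta**2, axis=-1) > 3.6**2, axis=1)
                else:
                    ok = np.ones(need, dtype=bool)
                k = int(ok.sum())
                placed_pts[got : got + k] = pts[ok]
                got += k
            coords[f, off + i * n_shell_per_ion : off + i * n_shell_per_ion + got] = placed_pts[:got]

    layout = {"n_bottleneck_pool": n_pool_b, "n_bath": w.n_bath, "n_shell_per_ion": n_shell_per_ion}
    return coords, layout


# --------------------------------------------------------------------------
# assembly


@dataclass
class SyntheticSystem:
    topology: Topology
    trajectory: Trajectory
    truth: TruthRecord
    annotation: dict
    config: SyntheticConfig


def _apply_dunking(cfg, topo, coords, ion_z, rng) -> None:
    """R334-analogue guanidinium tracks ions approaching the bottleneck."""
    side_idx = np.flatnonzero((topo.resids == 334) & (topo.names != "CA") & (topo.names != "GC"))
    if side_idx.size == 0 or ion_z.size == 0:
        return
    base_z = coords[0, side_idx, 2].copy()
    base_center = float(base_z.mean())
    for f in range(coords.shape[0]):
        zi = ion_z[f]
        near = zi[(zi > -8.0) & (zi < 4.0) & (zi < cfg.pore.z_max)]
        if near.size:
            target = min(base_center, float(near.max()) + 2.5)
        else:
            target = base_center
        target += rng.normal(0.0, cfg.scaffold.dunk_jitter)
        coords[f, side_idx, 2] = base_z + (target - base_center)


def generate(cfg: SyntheticConfig, seed: int | None = None) -> SyntheticSystem:
    """Build the full synthetic system: scaffold + ions + waters + truth."""
    cfg = dataclasses.replace(cfg, seed=cfg.seed if seed is None else seed)
    cfg.validate()
    topo_p, traj_p = build_scaffold(cfg)
    gate_states, transitions = simulate_gate(cfg)
    ion_z, ion_xy, truth = simulate_ions(cfg, gate_states)
    truth.gate_transitions = transitions
    if cfg.scaffold.dunk:
        rng = np.random.default_rng(cfg.seed * 3 + 5)
        _apply_dunking(cfg, topo_p, traj_p.coords, ion_z, rng)
    water_coords, layout = simulate_waters(cfg, gate_states, ion_z, ion_xy)

    n_i = cfg.n_ions
    n_w = water_coords.shape[1]
    names = np.concatenate([topo_p.names, np.full(n_i, "CLA", "U6"), np.full(n_w, "OW", "U6")])
    elements = np.concatenate([topo_p.elements, np.full(n_i, "CL", "U2"), np.full(n_w, "O", "U2")])
    resnames = np.concatenate([topo_p.resnames, np.full(n_i, "CLA", "U6"), np.full(n_w, "SOL", "U6")])
    resids = np.concatenate(
        [topo_p.resids, 2001 + np.arange(n_i), 3001 + np.arange(n_w)]
    )
    chains = np.concatenate([topo_p.chains, np.full(n_i, "I", "U1"), np.full(n_w, "W", "U1")])
    radii = np.concatenate([topo_p.radii, np.full(n_i, VDW_RADII["CL"]), np.full(n_w, VDW_RADII["O"])])

    topo = Topology(
        names=names,
        elements=elements,
        resnames=resnames,
        resids=resids,
        chains=chains,
        radii=radii,
        helix_map=topo_p.helix_map,
        pore_helices=topo_p.pore_helices,
        role_tags=topo_p.role_tags,
        anchors=topo_p.anchors,
    )
    coords = np.concatenate(
        [
            traj_p.coords,
            np.concatenate([ion_xy, ion_z[:, :, None]], axis=2),
            water_coords,
        ],
        axis=1,
    )
    traj = Trajectory(coords=coords, times=traj_p.times, box=traj_p.box)
    ann = {k: (dict(v) if isinstance(v, dict) else v) for k, v in SYNTHETIC_ANNOTATION.items()}
    return SyntheticSystem(topology=topo, trajectory=traj, truth=truth, annotation=ann, config=cfg)


def write_system(system: SyntheticSystem, prefix) -> dict:
    """Write PDB topology, plain-text trajectory, annotation YAML and truth JSON."""
    prefix = str(prefix)
    paths = {
        "topology": prefix + ".pdb",
        "trajectory": prefix + ".traj.txt",
        "annotation": prefix + ".annotation.yaml",
        "truth": prefix + ".truth.json",
    }
    write_pdb(paths["topology"], system.topology, system.trajectory.coords[0], system.trajectory.box[0])
    write_plaintext_trajectory(paths["trajectory"], system.trajectory)
    with open(paths["annotation"], "w") as fh:
        yaml.safe_dump(system.annotation, fh, sort_keys=False)
    truth = system.truth
    payload = {
        "gate_states": truth.gate_states.astype(int).tolist(),
        "crossings": truth.crossings,
        "n_absorptions": truth.n_absorptions,
        "committor_planes": list(truth.committor_planes),
        "binding_intervals": {k: [list(t) for t in v] for k, v in truth.binding_intervals.items()},
        "mean_residence": truth.mean_residence,
        "capture_half_width": truth.capture_half_width,
        "net_count": truth.net_count,
    }
    with open(paths["truth"], "w") as fh:
        json.dump(payload, fh, indent=1)
    return paths
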