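"""First-solvation-shell analysis of pore ions.

A molecule or residue is in direct contact with an ion when any of its atoms
lies within the contact cutoff of the ion (3.0 A for all-atom systems where
the closest contacting atoms are hydrogens; 3.5 A is the documented
equivalent for hydrogen-free pseudo-waters).  Waters are identified by
residue name and counted once per molecule; everything else polymeric counts
as protein; ion-ion contacts are tallied separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Topology, Trajectory
from .ions import IonTraces
from .stats import minimum_image

__all__ = [
    "ContactSeries",
    "SolvationProfile",
    "RadialDistribution",
    "radial_distribution",
    "first_shell_contacts",
    "solvation_profile",
]


@dataclass
class ContactSeries:
    """Per ion-frame first-shell contacts (water counts and protein residues)."""

    cutoff: float
    ion_ids: np.ndarray
    water_counts: np.ndarray  # (F, N) int; -1 marks frames where the ion is outside the pore
    protein_contacts: list  # [frame][ion] -> tuple of residue numbers (empty if outside)
    ion_ion_counts: np.ndarray  # (F, N) int

    @property
    def n_frames(self) -> int:
        return self.water_counts.shape[0]


def first_shell_contacts(
    traj: Trajectory,
    topo: Topology,
    traces: IonTraces,
    cutoff: float = 3.0,
) -> ContactSeries:
    """Contacting residues and water-molecule counts for every in-pore ion frame.

    Distances use the minimum-image convention with the per-frame box.  A
    water molecule counts once however many of its atoms fall inside the
    cutoff; protein contacts are reported as the set of residue numbers.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ion_idx = np.flatnonzero(topo.ion_mask())
    water = topo.water_mask()
    ion_atoms = topo.ion_mask()
    protein = ~water & ~ion_atoms

    n_f, n_i = traces.n_frames, traces.n_ions
    water_counts = np.full((n_f, n_i), -1, dtype=int)
    ion_ion = np.zeros((n_f, n_i), dtype=int)
    protein_contacts: list[list[tuple]] = []
    cut2 = cutoff * cutoff

    w_idx = np.flatnonzero(water)
    p_idx = np.flatnonzero(protein)
    w_resids = topo.resids[w_idx]
    p_resids = topo.resids[p_idx]

    for f in range(n_f):
        row: list[tuple] = []
        box = traj.box[f]
        frame = traj.coords[f]
        for i in range(n_i):
            if not traces.inside[f, i]:
                row.append(())
                continue
            ion_pos = frame[ion_idx[i]]
            delta = minimum_image(frame - ion_pos, box)
            d2 = np.einsum("ij,ij->i", delta, delta)
            hit = d2 < cut2
            water_counts[f, i] = len(np.unique(w_resids[hit[w_idx]]))
            res = np.unique(p_resids[hit[p_idx]])
            row.append(tuple(int(r) for r in res))
            other = hit[ion_idx]
            other[i] = False
            ion_ion[f, i] = int(other.sum())
        protein_contacts.append(row)

    return ContactSeries(
        cutoff=cutoff,
        ion_ids=traces.ids.copy(),
        water_counts=water_counts,
        protein_contacts=protein_contacts,
        ion_ion_counts=ion_ion,
    )


# --------------------------------------------------------------------------
# radial distribution function


@dataclass
class RadialDistribution:
    r: np.ndarray  # bin centres, A
    g: np.ndarray
    counts: np.ndarray  # raw pair counts per bin
    n_centers: int
    n_partners: int
    rho_partner: float  # mean partner density, A^-3

    def coordination_number(self, r_cut: float) -> float:
        """Mean partners within ``r_cut`` of a centre (integral of 4 pi rho g r^2)."""
        sel = self.r <= r_cut
        return float(self.counts[sel].sum()) / self._norm_pairs

    _norm_pairs: float = 1.0


def radial_distribution(
    traj: Trajectory,
    topo: Topology,
    center_mask: np.ndarray,
    partner_mask: np.ndarray,
    r_max: float = 8.0,
    dr: float = 0.1,
) -> RadialDistribution:
    """Radial pair distribution g(r) between two atom selections.

    Shell-volume and mean-density normalisation under minimum image; self
    pairs are excluded when the selections overlap.  ``r_max`` must not
    exceed half the smallest box length.
    """
    if dr <= 0:
        raise ValueError("dr must be positive")
    c_idx = np.flatnonzero(np.asarray(center_mask))
    p_idx = np.flatnonzero(np.asarray(partner_mask))
    if c_idx.size == 0 or p_idx.size == 0:
        raise ValueError("empty atom selection")
    if r_max > traj.box.min() / 2:
        raise ValueError("r_max exceeds half the smallest box length")

    edges = np.arange(0.0, r_max + dr / 2, dr)
    counts = np.zeros(len(edges) - 1)
    overlap = np.isin(p_idx, c_idx).sum() > 0
    vol = 0.0
    for f in range(traj.n_frames):
        box = traj.box[f]
        vol += np.prod(box)
        delta = traj.coords[f, c_idx][:, None, :] - traj.coords[f, p_idx][None, :, :]
        delta = minimum_image(delta, box)
        d = np.sqrt(np.einsum("ijk,ijk->ij", delta, delta))
        if overlap:
            same = c_idx[:, None] == p_idx[None, :]
            d = d[~same]
        h, _ = np.histogram(d.ravel(), bins=edges)
        counts += h
    vol /= traj.n_frames

    n_c, n_p = len(c_idx), len(p_idx)
    eff_partners = n_p - 1 if overlap else n_p
    rho = eff_partners / vol
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    norm = traj.n_frames * n_c * rho * shell
    g = counts / norm
    out = RadialDistribution(
        r=0.5 * (edges[:-1] + edges[1:]),
        g=g,
        counts=counts,
        n_centers=n_c,
        n_partners=n_p,
        rho_partner=rho,
    )
    out._norm_pairs = traj.n_frames * n_c
    return out


# --------------------------------------------------------------------------
# solvation profile


@dataclass
class SolvationProfile:
    edges: np.ndarray
    n_samples: np.ndarray  # ion-frames per bin
    water: np.ndarray  # mean first-shell waters per bin (NaN where empty)
    protein: np.ndarray  # mean contacting protein residues per bin
    total: np.ndarray
    water_ci: np.ndarray  # (n_bins, 2)
    per_residue: dict  # resid -> mean contribution per bin
    water_deficit: float  # vestibule minus bottleneck mean water count
    water_deficit_ci: tuple

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def solvation_profile(
    contacts: ContactSeries,
    traces: IonTraces,
    bin_width: float = 1.0,
    z_range: tuple[float, float] = (-40.0, 20.0),
    tagged_resids=(),
    bottleneck: tuple[float, float] = (-5.0, 5.0),
    vestibule: tuple[float, float] = (-40.0, -5.0),
    block_size: int = 50,
    level: float = 0.99,
    n_resamples: int = 500,
    seed: int = 0,
) -> SolvationProfile:
    """Axially binned first-shell composition of in-pore ions.

    Reports per-bin mean water and protein coordination (their sum is the
    total by construction), mean per-residue contributions for tagged
    residues, and the bottleneck hydration deficit: the difference between
    the mean first-shell water count in the vestibule and in the bottleneck,
    with a block-bootstrap CI.  Bins with no ion visits are NaN.
    """
    edges = np.arange(z_range[0], z_range[1] + bin_width / 2, bin_width)
    n_bins = len(edges) - 1
    f_all, i_all = np.nonzero(contacts.water_counts >= 0)
    zs = traces.z[f_all, i_all]
    keep = (zs > edges[0]) & (zs < edges[-1])
    f_all, i_all, zs = f_all[keep], i_all[keep], zs[keep]
    b = np.clip(((zs - edges[0]) / bin_width).astype(int), 0, n_bins - 1)
    w = contacts.water_counts[f_all, i_all].astype(float)
    p = np.array([len(contacts.protein_contacts[f][i]) for f, i in zip(f_all, i_all)], dtype=float)

    def bin_mean(values):
        s = np.zeros(n_bins)
        c = np.zeros(n_bins)
        np.add.at(s, b, values)
        np.add.at(c, b, 1.0)
        with np.errstate(invalid="ignore"):
            return np.where(c > 0, s / np.maximum(c, 1), np.nan), c

    water_mean, n_samp = bin_mean(w)
    protein_mean, _ = bin_mean(p)
    total = water_mean + protein_mean

    per_residue = {}
    for resid in tagged_resids:
        ind = np.array(
            [1.0 if resid in contacts.protein_contacts[f][i] else 0.0 for f, i in zip(f_all, i_all)]
        )
        per_residue[int(resid)], _ = bin_mean(ind)

    # block bootstrap over frames for the water curve and the deficit
    rng = np.random.default_rng(seed)
    n_frames = contacts.n_frames
    n_blocks = max(1, n_frames // block_size)
    block_of_frame = np.minimum(f_all // block_size, n_blocks - 1)
    in_bottle = (zs > bottleneck[0]) & (zs < bottleneck[1])
    in_vest = (zs > vestibule[0]) & (zs < vestibule[1])

    sum_w_bin = np.zeros((n_blocks, n_bins))
    cnt_bin = np.zeros((n_blocks, n_bins))
    np.add.at(sum_w_bin, (block_of_frame, b), w)
    np.add.at(cnt_bin, (block_of_frame, b), 1.0)
    sum_reg = np.zeros((n_blocks, 2))
    cnt_reg = np.zeros((n_blocks, 2))
    np.add.at(sum_reg[:, 0], block_of_frame[in_vest], w[in_vest])
    np.add.at(cnt_reg[:, 0], block_of_frame[in_vest], 1.0)
    np.add.at(sum_reg[:, 1], block_of_frame[in_bottle], w[in_bottle])
    np.add.at(cnt_reg[:, 1], block_of_frame[in_bottle], 1.0)

    est_bins = np.full((n_resamples, n_bins), np.nan)
    est_def = np.full(n_resamples, np.nan)
    for r in range(n_resamples):
        pick = rng.integers(0, n_blocks, size=n_blocks)
        sw, cw = sum_w_bin[pick].sum(axis=0), cnt_bin[pick].sum(axis=0)
        with np.errstate(invalid="ignore"):
            est_bins[r] = np.where(cw > 0, sw / np.maximum(cw, 1), np.nan)
        sr, cr = sum_reg[pick].sum(axis=0), cnt_reg[pick].sum(axis=0)
        if cr[0] > 0 and cr[1] > 0:
            est_def[r] = sr[0] / cr[0] - sr[1] / cr[1]
    alpha = (1 - level) / 2
    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        water_ci = np.nanquantile(est_bins, [alpha, 1 - alpha], axis=0).T

    if in_vest.sum() and in_bottle.sum():
        deficit = float(w[in_vest].mean() - w[in_bottle].mean())
        ok = np.isfinite(est_def)
        dci = tuple(np.quantile(est_def[ok], [alpha, 1 - alpha])) if ok.sum() else (np.nan, np.nan)
    else:
        deficit, dci = float("nan"), (float("nan"), float("nan"))

    return SolvationProfile(
        edges=edges,
        n_samples=n_samp,
        water=water_mean,
        protein=protein_mean,
        total=total,
        water_ci=water_ci,
        per_residue=per_residue,
        water_deficit=deficit,
        water_deficit_ci=dci,
    )
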