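"""End-to-end orchestration: simulate/load -> align -> analyse -> report.

A run is described by a :class:`RunConfig` carrying either a synthetic
generator configuration or paths to topology/trajectory/annotation files,
plus the analysis parameters.  Every artifact is written as plain CSV/JSON;
figures are optional conveniences.  For a fixed (config, seed) all artifacts
are byte-identical between runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import gating, helices, ions, solvation
from .geometry import align_to_reference, pore_geometry_per_frame
from .io import load_system
from .stats import bootstrap_ci
from .synthetic import SYNTHETIC_CONTACT_CUTOFF, SyntheticConfig, generate

__all__ = ["RunConfig", "Report", "PipelineStageError", "run_pipeline", "compare_conditions"]


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    condition: str = "field_on"
    synthetic: SyntheticConfig | None = None
    topology: str | None = None
    trajectory: str | None = None
    annotation: str | None = None
    outdir: str | None = None
    seed: int = 0
    contact_cutoff: float | None = None  # None: 3.5 for synthetic pseudo-waters, 3.0 otherwise
    committor_planes: tuple = (-20.0, 10.0)
    vestibule: tuple = (-40.0, -5.0)
    bottleneck: tuple = (-5.0, 5.0)
    burst_gap: float = 100.0
    bin_width: float = 1.0
    gap_tolerance: float = 1.0
    sasa_resids: tuple = (99, 102, 106)
    make_plots: bool = False

    def resolved_cutoff(self) -> float:
        if self.contact_cutoff is not None:
            return self.contact_cutoff
        return SYNTHETIC_CONTACT_CUTOFF if self.synthetic is not None else 3.0

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("outdir", None)  # scientific parameters only, not artifact placement
        payload.pop("make_plots", None)
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


@dataclass
class Report:
    condition: str
    config: RunConfig
    summary: dict
    events: pd.DataFrame
    bursts: list
    occupancy: ions.OccupancyDistribution
    density: ions.AxialDensityProfile
    solvation: solvation.SolvationProfile
    gate_counts: np.ndarray
    gate_classification: gating.GateClassification
    association: gating.AssociationResult
    sasa: pd.DataFrame
    distances: pd.DataFrame
    helix_xy: dict
    rdf: solvation.RadialDistribution
    charge_centers: dict
    dunking: helices.DunkingJoint
    residence: dict
    rmsd: np.ndarray
    truth: object | None = None


def run_pipeline(cfg: RunConfig) -> Report:
    """Execute every analysis stage in dependency order and write artifacts."""

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise PipelineStageError(name, exc) from exc

    truth = None
    if cfg.synthetic is not None:
        syn = dataclasses.replace(cfg.synthetic, seed=cfg.seed)
        system = stage("simulate", generate, syn)
        topo, traj, truth = system.topology, system.trajectory, system.truth
    elif cfg.topology and cfg.trajectory and cfg.annotation:
        topo, traj = stage("load", load_system, cfg.topology, cfg.trajectory, cfg.annotation)
    else:
        raise PipelineStageError("config", ValueError("need either a synthetic config or input paths"))

    traj, rmsd = stage("align", align_to_reference, traj, topo)
    geometry = stage("geometry", pore_geometry_per_frame, traj, topo)
    traces = stage("traces", ions.extract_ion_traces, traj, topo, geometry)

    events = stage(
        "events", ions.detect_permeation_events, traces, *cfg.committor_planes
    )
    stage("pathways", ions.classify_pathways, events, traces, traj, topo, geometry)
    bursts = stage("bursts", ions.detect_bursts, events, traces.times, cfg.burst_gap)
    occupancy = stage("occupancy", ions.occupancy_distribution, traces, cfg.vestibule, seed=cfg.seed)
    density = stage("density", ions.axial_density, traces, cfg.bin_width, seed=cfg.seed)

    cutoff = cfg.resolved_cutoff()
    contacts = stage("contacts", solvation.first_shell_contacts, traj, topo, traces, cutoff)
    tagged = tuple(
        sorted(set(topo.role_tags.get("site1", ()) + topo.role_tags.get("site2", ()) + topo.role_tags.get("gate", ())))
    )
    solv = stage(
        "solvation",
        solvation.solvation_profile,
        contacts,
        traces,
        cfg.bin_width,
        tagged_resids=tagged,
        bottleneck=cfg.bottleneck,
        vestibule=cfg.vestibule,
        seed=cfg.seed,
    )
    residence = {}
    for site in ("site1", "site2"):
        if site in topo.role_tags:
            residence[site] = stage(
                f"residence:{site}", ions.binding_residence, traces, contacts, topo, site, cfg.gap_tolerance
            )

    gate_counts = stage("gate_counts", gating.count_bottleneck_waters, traj, topo, geometry, *cfg.bottleneck)
    gate_cls = stage("gate_classify", gating.classify_gate_state, gate_counts, traces.dt or 1.0)
    event_frames = [e.frame_exit for e in events]
    association = stage(
        "association", gating.wetting_event_association, gate_cls.labels, event_frames, seed=cfg.seed
    )
    sasa = stage("sasa", gating.sasa_series, traj, topo, list(cfg.sasa_resids))

    # ion-water g(r) on a subsample of frames (the cutoff justification curve)
    def _rdf():
        step = max(1, traj.n_frames // 200)
        from .io import Trajectory as _T

        sub = _T(traj.coords[::step], traj.times[::step], traj.box[::step], aligned=True)
        return solvation.radial_distribution(sub, topo, topo.ion_mask(), topo.water_mask(), r_max=8.0, dr=0.2)

    rdf = stage("rdf", _rdf)

    distances = stage("distances", helices.interhelical_distances, traj, topo)
    helix_xy = stage("helix_xy", helices.helix_end_xy_distribution, traj, topo)
    basic = [
        r
        for r in topo.role_tags.get("basic", ())
        if str(topo.resnames[topo.atom_indices(r)[0]]).upper() in ("LYS", "ARG")
    ]
    charge_centers = stage("charge_centers", helices.charge_center_series, traj, topo, basic)
    dunking = stage("dunking", helices.r334_dunking_joint, traj, topo, traces)

    summary = {
        "condition": cfg.condition,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_frames": traj.n_frames,
        "n_events": len(events),
        "n_events_outward": int(sum(e.direction > 0 for e in events)),
        "n_bursts": len(bursts),
        "mean_occupancy_vestibule": occupancy.mean,
        "mean_occupancy_near_gate": float(traces.region_counts((-20.0, -5.0)).mean()),
        "site_occupancy": {s: residence[s].occupancy for s in residence},
        "mean_residence_ns": {s: residence[s].mean for s in residence},
        "water_deficit": solv.water_deficit,
        "water_deficit_ci": list(solv.water_deficit_ci),
        "wet_fraction": float(np.mean(gate_cls.labels)),
        "gate_threshold": gate_cls.threshold,
        "event_wet_fraction": association.event_wet_fraction,
        "odds_ratio": None
        if association.odds_ratio is None
        else (association.odds_ratio if np.isfinite(association.odds_ratio) else "inf"),
        "association_p": association.p_value,
        "pathway_counts": dict(pd.Series([e.pathway for e in events]).value_counts()) if events else {},
        "mean_rmsd": float(np.mean(rmsd)),
    }

    report = Report(
        condition=cfg.condition,
        config=cfg,
        summary=summary,
        events=ions.events_to_dataframe(events, traces.times),
        bursts=bursts,
        occupancy=occupancy,
        density=density,
        solvation=solv,
        gate_counts=gate_counts,
        gate_classification=gate_cls,
        association=association,
        sasa=sasa,
        distances=distances,
        helix_xy=helix_xy,
        rdf=rdf,
        charge_centers=charge_centers,
        dunking=dunking,
        residence=residence,
        rmsd=rmsd,
        truth=truth,
    )
    if cfg.outdir:
        _write_report(report, Path(cfg.outdir))
    return report


def _write_report(report: Report, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    report.events.to_csv(outdir / "events.csv", index=False)
    pd.DataFrame(
        [
            {"burst": k, "n_events": b.size, "t_start_ns": b.t_start, "t_end_ns": b.t_end}
            for k, b in enumerate(report.bursts)
        ]
    ).to_csv(outdir / "bursts.csv", index=False)

    dens = report.density
    pd.DataFrame(
        {
            "z_center": dens.centers,
            "rho_per_A": dens.rho,
            "cumulative": dens.cumulative[1:],
            "ci_low": dens.ci_low,
            "ci_high": dens.ci_high,
        }
    ).to_csv(outdir / "density.csv", index=False)

    occ = report.occupancy
    with open(outdir / "occupancy.json", "w") as fh:
        json.dump(
            {
                "region": list(occ.region),
                "mean": occ.mean,
                "mean_ci": [occ.mean_ci.lower, occ.mean_ci.upper],
                "probabilities": occ.probabilities,
                "ci": {k: [v.lower, v.upper] for k, v in occ.ci.items()},
            },
            fh,
            indent=1,
        )

    solv = report.solvation
    df = pd.DataFrame(
        {
            "z_center": solv.centers,
            "n_samples": solv.n_samples,
            "water": solv.water,
            "protein": solv.protein,
            "total": solv.total,
            "water_ci_low": solv.water_ci[:, 0],
            "water_ci_high": solv.water_ci[:, 1],
        }
    )
    for resid, contrib in solv.per_residue.items():
        df[f"res_{resid}"] = contrib
    df.to_csv(outdir / "solvation_profile.csv", index=False)

    gc = report.gate_classification
    pd.DataFrame(
        {
            "time_ns": report.distances.index,
            "n_water": report.gate_counts,
            "wet": gc.labels,
            "wet_smoothed": gc.smoothed,
        }
    ).to_csv(outdir / "gate_series.csv", index=False)
    report.sasa.rename(columns=lambda c: f"sasa_{c}").to_csv(outdir / "sasa.csv", index_label="time_ns")

    assoc = report.association
    with open(outdir / "association.json", "w") as fh:
        json.dump(
            {
                "defined": assoc.defined,
                "n_events": assoc.n_events,
                "wet_fraction_frames": assoc.wet_fraction_frames,
                "event_wet_fraction": assoc.event_wet_fraction,
                "odds_ratio": None
                if assoc.odds_ratio is None
                else (assoc.odds_ratio if np.isfinite(assoc.odds_ratio) else "inf"),
                "p_value": assoc.p_value,
                "n_shifts": assoc.n_shifts,
            },
            fh,
            indent=1,
        )

    report.distances.to_csv(outdir / "distances.csv", index_label="time_ns")
    pd.DataFrame({"r_A": report.rdf.r, "g": report.rdf.g, "counts": report.rdf.counts}).to_csv(
        outdir / "rdf.csv", index=False
    )
    pd.DataFrame(
        [
            {
                "helix": h,
                "mean_x": rec["mean_xy"][0],
                "mean_y": rec["mean_xy"][1],
                "dispersion_A": rec["dispersion"],
            }
            for h, rec in report.helix_xy.items()
        ]
    ).to_csv(outdir / "helix_xy.csv", index=False)
    cc_rows = []
    for resid, pts in report.charge_centers.items():
        for f, (x, y, z) in enumerate(pts):
            cc_rows.append({"resid": resid, "frame": f, "x": x, "y": y, "z": z})
    pd.DataFrame(cc_rows, columns=["resid", "frame", "x", "y", "z"]).to_csv(
        outdir / "charge_centers.csv", index=False
    )
    joint = report.dunking
    np.savetxt(outdir / "r334_joint.csv", joint.joint, delimiter=",", fmt="%d")
    with open(outdir / "report.json", "w") as fh:
        json.dump(report.summary, fh, indent=1, default=str)

    if report.config.make_plots:
        _make_plots(report, outdir)


def _make_plots(report: Report, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(1, 2, figsize=(9, 3.2))
    d = report.density
    ax[0].plot(d.centers, d.rho)
    ax[0].fill_between(d.centers, d.ci_low, d.ci_high, alpha=0.3)
    ax[0].set(xlabel="z (A)", ylabel="rho(Cl-) per A")
    ax[1].plot(report.distances.index, report.gate_counts)
    ax[1].set(xlabel="t (ns)", ylabel="N_water(bottleneck)")
    fig.tight_layout()
    fig.savefig(outdir / "overview.png", dpi=110)
    plt.close(fig)


# --------------------------------------------------------------------------
# condition contrasts


def compare_conditions(report_a: Report, report_b: Report, seed: int = 0) -> dict:
    """Side-by-side contrast of two conditions (e.g. field on vs off).

    Returns the per-bin density difference, the occupancy mean difference
    with a bootstrap CI on the difference, and summary deltas.  Differences
    are a - b; swapping the arguments flips every sign.
    """
    da, db = report_a.density, report_b.density
    if len(da.edges) != len(db.edges) or not np.allclose(da.edges, db.edges):
        raise ValueError("density binning differs between reports")
    if report_a.occupancy.region != report_b.occupancy.region:
        raise ValueError("occupancy regions differ between reports")

    density_diff = pd.DataFrame(
        {"z_center": da.centers, "delta_rho": da.rho - db.rho}
    )

    ca = report_a.occupancy.counts.astype(float)
    cb = report_b.occupancy.counts.astype(float)
    rng_seed = seed
    boot_a = bootstrap_ci(ca, "mean", 0.99, 1000, seed=rng_seed)
    boot_b = bootstrap_ci(cb, "mean", 0.99, 1000, seed=rng_seed + 1)
    # CI of the difference of means via independent resampling
    rng = np.random.default_rng(rng_seed + 2)
    diffs = (
        ca[rng.integers(0, ca.size, size=(1000, ca.size))].mean(axis=1)
        - cb[rng.integers(0, cb.size, size=(1000, cb.size))].mean(axis=1)
    )
    dlo, dhi = np.quantile(diffs, [0.005, 0.995])

    return {
        "density_diff": density_diff,
        "occupancy_diff": float(ca.mean() - cb.mean()),
        "occupancy_diff_ci": (float(dlo), float(dhi)),
        "occupancy_a": boot_a,
        "occupancy_b": boot_b,
        "event_count_diff": int(report_a.summary["n_events"] - report_b.summary["n_events"]),
        "distance_mean_diff": (report_a.distances.mean() - report_b.distances.mean()).to_dict(),
    }
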