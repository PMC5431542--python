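"""Config-driven orchestration of the full trajectory analysis.

``run_analysis`` loads topology and frames once, runs every configured
metric, and writes one CSV per metric table plus a ``report.json``
summary.  A failing metric is recorded in the report and does not stop
the others.  CSV output is deterministic (6 significant digits, config
hash in the header) so identical inputs give byte-identical tables.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .config import AnalysisConfig, Finding, validate_config
from .geometry import (
    ScalarSeries,
    distribution,
    min_group_distance_series,
    pocket_size_series,
    rmsd_series,
    rmsf,
)
from .hydration import (
    HydrationSiteSpec,
    residence_time,
    site_occupancy,
)
from .interactions import (
    contact_count_series,
    find_halogen_bonds,
    find_hbonds,
    infer_donor_hydrogens,
    infer_halogen_carbons,
    saltbridge_occupancy,
)
from .io import FrameSeries, Topology, read_frames, read_topology
from .selection import resolve_selection

logger = logging.getLogger(__name__)

__all__ = ["AnalysisReport", "run_analysis", "ValidationError"]


class ValidationError(ValueError):
    """The configuration cannot be run; carries the findings."""

    def __init__(self, findings):
        self.findings = findings
        super().__init__(
            "; ".join(str(f) for f in findings if f.severity == "error")
        )


@dataclass
class AnalysisReport:
    """Machine-readable result of one analysis run."""

    config_hash: str
    summary: dict = field(default_factory=dict)
    tables: dict[str, Path] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    wall_time_s: float = 0.0

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "package_version": __version__,
            "summary": self.summary,
            "tables": {k: str(v) for k, v in self.tables.items()},
            "failures": self.failures,
            "warnings": self.warnings,
            "wall_time_s": round(self.wall_time_s, 3),
        }


def _records_to_csv(path, records, header_lines):
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("frame,kind,donor,hydrogen,acceptor,distance_A,angle_deg\n")
        for r in records:
            h = "" if r.hydrogen_index is None else r.hydrogen_index
            a = "" if r.angle is None else f"{r.angle:.6g}"
            fh.write(
                f"{r.frame_index},{r.kind},{r.donor_index},{h},"
                f"{r.acceptor_index},{r.distance:.6g},{a}\n"
            )


def run_analysis(config: AnalysisConfig, out_dir=None) -> AnalysisReport:
    """Run every configured metric over the trajectory.

    Raises :class:`ValidationError` (before reading any frame) if the
    configuration has error-level findings; per-metric runtime failures
    are collected in ``report.failures`` while other metrics complete.
    """
    t_start = time.monotonic()
    out = Path(out_dir if out_dir is not None else config.out_dir)

    topology = read_topology(config.topology)
    findings = validate_config(config, topology)
    errors = [f for f in findings if f.severity == "error"]
    if errors:
        raise ValidationError(errors)
    report = AnalysisReport(config_hash=config.config_hash())
    report.warnings = [str(f) for f in findings if f.severity == "warning"]
    for w in report.warnings:
        logger.warning("%s", w)

    traj = read_frames(config.trajectory, topology, dt=config.dt)
    out.mkdir(parents=True, exist_ok=True)
    header = (
        f"config_hash: {report.config_hash}",
        f"n_frames: {traj.n_frames}  dt_ps: {config.dt:.6g}",
    )

    def sel(ref, label=None):
        return resolve_selection(topology, config.expression(ref),
                                 label=label or ref)

    def run_metric(name, fn):
        t0 = time.monotonic()
        try:
            fn()
            logger.info("metric %-24s %.2f s", name, time.monotonic() - t0)
        except Exception as exc:  # all-or-nothing per metric
            logger.error("metric %s failed: %s", name, exc)
            report.failures[name] = str(exc)

    m = config.metrics

    if "pocket" in m:
        def _pocket():
            series = pocket_size_series(
                traj, sel(m["pocket"]["helix"]), sel(m["pocket"]["hinge"]),
                topology.masses,
            )
            p = out / "pocket_size.csv"
            series.to_csv(p, header + ("pocket size: |COM(helix)-COM(hinge)| in A",))
            report.tables["pocket_size"] = p
            dist = distribution(series, config.bin_width)
            pd = out / "pocket_size_distribution.csv"
            dist.to_csv(pd, header)
            report.tables["pocket_size_distribution"] = pd
            report.summary["pocket_size_mean_A"] = float(series.values.mean())
        run_metric("pocket", _pocket)

    for entry in m.get("saltbridge", []):
        label = entry.get("label", "saltbridge")

        def _saltbridge(entry=entry, label=label):
            series = min_group_distance_series(
                traj, sel(entry["group_a"]), sel(entry["group_b"]), label=label
            )
            p = out / f"saltbridge_{label}.csv"
            series.to_csv(p, header + ("min side-chain heavy-atom distance in A",))
            report.tables[f"saltbridge_{label}"] = p
            dist = distribution(series, config.bin_width)
            pd = out / f"saltbridge_{label}_distribution.csv"
            dist.to_csv(pd, header)
            report.tables[f"saltbridge_{label}_distribution"] = pd
            report.summary[f"saltbridge_{label}_occupancy"] = saltbridge_occupancy(
                series, config.criteria
            )
        run_metric(f"saltbridge:{label}", _saltbridge)

    for entry in m.get("contacts", []):
        label = entry.get("label", "contacts")

        def _contacts(entry=entry, label=label):
            series = contact_count_series(
                traj, topology, sel(entry["group_a"]), sel(entry["group_b"]),
                config.criteria, label=label,
            )
            p = out / f"contacts_{label}.csv"
            series.to_csv(p, header + (
                f"heavy-atom pairs within {config.criteria.contact_cut:g} A",
            ))
            report.tables[f"contacts_{label}"] = p
            report.summary[f"contacts_{label}_mean"] = float(series.values.mean())
        run_metric(f"contacts:{label}", _contacts)

    for entry in m.get("hbonds", []):
        label = entry.get("label", "hbonds")

        def _hbonds(entry=entry, label=label):
            donors = sel(entry["donors"])
            acceptors = sel(entry["acceptors"])
            donor_map = None
            if topology.has_hydrogens():
                donor_map = infer_donor_hydrogens(
                    topology, traj[0], donors.indices
                )
            records = []
            for i in range(traj.n_frames):
                records.extend(find_hbonds(
                    traj[i], topology, donors, acceptors, config.criteria,
                    frame_index=i, donor_h_map=donor_map,
                    warn_missing_h=(i == 0),
                ))
            mode = () if topology.has_hydrogens() else ("distance_only: true",)
            p = out / f"hbonds_{label}.csv"
            _records_to_csv(p, records, header + mode)
            report.tables[f"hbonds_{label}"] = p
            report.summary[f"hbonds_{label}_per_frame"] = (
                len(records) / traj.n_frames
            )
        run_metric(f"hbonds:{label}", _hbonds)

    for entry in m.get("xbonds", []):
        label = entry.get("label", "xbonds")

        def _xbonds(entry=entry, label=label):
            halogens = sel(entry["halogens"])
            acceptors = sel(entry["acceptors"])
            carbon_map = infer_halogen_carbons(
                topology, traj[0], halogens.indices
            )
            records = []
            for i in range(traj.n_frames):
                records.extend(find_halogen_bonds(
                    traj[i], topology, halogens, acceptors, config.criteria,
                    frame_index=i, carbon_map=carbon_map,
                ))
            p = out / f"xbonds_{label}.csv"
            _records_to_csv(p, records, header)
            report.tables[f"xbonds_{label}"] = p
            report.summary[f"xbonds_{label}_per_frame"] = (
                len(records) / traj.n_frames
            )
            if records:
                report.summary[f"xbonds_{label}_mean_length_A"] = float(
                    np.mean([r.distance for r in records])
                )
        run_metric(f"xbonds:{label}", _xbonds)

    if "rmsd" in m:
        def _rmsd():
            fit = sel(m["rmsd"]["fit"])
            measure = sel(m["rmsd"]["measure"]) if "measure" in m["rmsd"] else None
            series = rmsd_series(traj, fit, measure)
            p = out / "rmsd.csv"
            series.to_csv(p, header + ("RMSD vs frame 0 in A",))
            report.tables["rmsd"] = p
            report.summary["rmsd_mean_A"] = float(series.values.mean())
        run_metric("rmsd", _rmsd)

    if "rmsf" in m:
        def _rmsf():
            fit = sel(m["rmsf"]["fit"])
            measure = sel(m["rmsf"]["measure"]) if "measure" in m["rmsf"] else None
            profile = rmsf(traj, fit, measure)
            p = out / "rmsf.csv"
            with open(p, "w") as fh:
                for line in header + ("per-atom RMSF in A",):
                    fh.write(f"# {line}\n")
                fh.write("atom_index,atom_name,res_id,rmsf_A\n")
                for idx, val in zip(profile.atom_indices, profile.values):
                    fh.write(
                        f"{idx},{topology.atom_names[idx]},"
                        f"{topology.res_ids[idx]},{val:.6g}\n"
                    )
            report.tables["rmsf"] = p
            report.summary["rmsf_mean_A"] = profile.mean()
        run_metric("rmsf", _rmsf)

    for entry in m.get("hydration", []):
        label = entry.get("label", "site")

        def _hydration(entry=entry, label=label):
            site = HydrationSiteSpec(
                ligand_anchor=sel(entry["ligand_anchor"]),
                protein_anchor=sel(entry["protein_anchor"]),
                water_probe=sel(entry["waters"]),
                proximity_cut=entry.get("proximity_cut", 3.5),
                label=label,
            )
            occ = site_occupancy(traj, topology, site)
            res = residence_time(occ, entry.get("gap_tolerance", 0))
            p = out / f"hydration_{label}_occupancy.csv"
            with open(p, "w") as fh:
                for line in header + (
                    f"bridging waters within {site.proximity_cut:g} A of both anchors",
                ):
                    fh.write(f"# {line}\n")
                fh.write("frame_index,time_ps,occupied,water_ids\n")
                for i, (t, o, ids) in enumerate(
                    zip(occ.times, occ.occupied, occ.water_ids)
                ):
                    idstr = ";".join(str(w) for w in sorted(ids))
                    fh.write(f"{i},{t:.6g},{int(o)},{idstr}\n")
            report.tables[f"hydration_{label}_occupancy"] = p
            report.summary[f"hydration_{label}"] = {
                "occupancy_fraction": occ.occupancy_fraction(),
                "total_residence_ps": res.total_time,
                "longest_interval_ps": res.longest_interval,
                "n_intervals": len(res.intervals),
                "n_exchange_events": res.n_exchange_events,
            }
        run_metric(f"hydration:{label}", _hydration)

    report.wall_time_s = time.monotonic() - t_start
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
    return report
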