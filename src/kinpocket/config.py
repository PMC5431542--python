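"""Analysis configuration: YAML-backed, validated before any frame is read.

All geometric cutoffs default to the standard analysis values (hydrogen
bond < 3.0 Å / > 120°, contacts within 6.5 Å, salt bridge < 3.5 Å,
bridging water within 3.5 Å of both partners) and every one of them is
configuration, not a code constant.  Selections are named expressions in
the package's selection language; metric entries may reference a named
selection or carry an inline expression.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import yaml

from .interactions import InteractionCriteria
from .io import Topology, read_topology
from .selection import SelectionSyntaxError, resolve_selection

__all__ = ["AnalysisConfig", "Finding", "validate_config"]


@dataclass(frozen=True)
class Finding:
    """One validation finding; severity is "error" or "warning"."""

    severity: str
    path: str  # config path, e.g. "metrics.pocket.helix"
    message: str

    def __str__(self) -> str:
        return f"[{self.severity}] {self.path}: {self.message}"


@dataclass
class AnalysisConfig:
    """Everything one analysis run needs; see examples/ for a full YAML."""

    topology: str
    trajectory: str
    dt: float = 10.0
    out_dir: str = "out"
    bin_width: float = 0.1
    selections: dict[str, str] = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)
    criteria: InteractionCriteria = field(default_factory=InteractionCriteria)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        crit = d.pop("criteria", None) or {}
        known = {f.name for f in dc_fields(cls)} - {"criteria"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(criteria=InteractionCriteria(**crit), **d)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        crit = {f.name: getattr(self.criteria, f.name)
                for f in dc_fields(InteractionCriteria)}
        return {
            "topology": str(self.topology),
            "trajectory": str(self.trajectory),
            "dt": self.dt,
            "out_dir": str(self.out_dir),
            "bin_width": self.bin_width,
            "selections": dict(self.selections),
            "metrics": self.metrics,
            "criteria": crit,
        }

    def config_hash(self) -> str:
        """SHA-256 of the canonical JSON form; recorded in every output."""
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def expression(self, ref: str) -> str:
        """A metric selection entry: a named selection or an inline expression."""
        return self.selections.get(ref, ref)


def _check_selection(cfg, topology, ref, path, findings, *, allow_empty=False):
    expr = cfg.expression(ref)
    try:
        sel = resolve_selection(topology, expr, label=ref)
    except SelectionSyntaxError as exc:
        findings.append(Finding("error", path, f"invalid selection: {exc}"))
        return None
    if sel.is_empty and not allow_empty:
        findings.append(Finding(
            "error", path, f"selection {expr!r} matches no atoms"
        ))
    return sel


def validate_config(
    config: AnalysisConfig, topology: Topology | None = None
) -> list[Finding]:
    """Validate a config; returns an empty list iff the analysis can run.

    Findings carry a severity and the config path they refer to; warnings
    (e.g. hydrogen-bond analysis on a hydrogen-free topology, which will
    run in distance-only mode) do not block execution.
    """
    findings: list[Finding] = []
    if not config.dt > 0:
        findings.append(Finding("error", "dt", "frame time step must be > 0"))
    if not config.bin_width > 0:
        findings.append(Finding("error", "bin_width", "must be > 0"))
    for key in ("topology", "trajectory"):
        p = Path(getattr(config, key))
        if not p.exists():
            findings.append(Finding("error", key, f"file not found: {p}"))

    if topology is None:
        try:
            topology = read_topology(config.topology)
        except Exception as exc:
            findings.append(Finding("error", "topology", f"unreadable: {exc}"))
            return findings

    m = config.metrics
    if "pocket" in m:
        for role in ("helix", "hinge"):
            ref = m["pocket"].get(role)
            if ref is None:
                findings.append(Finding(
                    "error", f"metrics.pocket.{role}",
                    f"pocket metric requires a '{role}' selection",
                ))
            else:
                _check_selection(config, topology, ref,
                                 f"metrics.pocket.{role}", findings)
    for i, entry in enumerate(m.get("saltbridge", [])):
        for role in ("group_a", "group_b"):
            if role not in entry:
                findings.append(Finding(
                    "error", f"metrics.saltbridge[{i}]", f"missing '{role}'"
                ))
            else:
                _check_selection(config, topology, entry[role],
                                 f"metrics.saltbridge[{i}].{role}", findings)
    for i, entry in enumerate(m.get("contacts", [])):
        for role in ("group_a", "group_b"):
            if role not in entry:
                findings.append(Finding(
                    "error", f"metrics.contacts[{i}]", f"missing '{role}'"
                ))
            else:
                _check_selection(config, topology, entry[role],
                                 f"metrics.contacts[{i}].{role}", findings)
    for i, entry in enumerate(m.get("hbonds", [])):
        for role in ("donors", "acceptors"):
            if role not in entry:
                findings.append(Finding(
                    "error", f"metrics.hbonds[{i}]", f"missing '{role}'"
                ))
            else:
                _check_selection(config, topology, entry[role],
                                 f"metrics.hbonds[{i}].{role}", findings)
        if not topology.has_hydrogens():
            findings.append(Finding(
                "warning", f"metrics.hbonds[{i}]",
                "topology has no hydrogens; hydrogen bonds will be "
                "detected in distance-only mode",
            ))
    for i, entry in enumerate(m.get("xbonds", [])):
        for role in ("halogens", "acceptors"):
            if role not in entry:
                findings.append(Finding(
                    "error", f"metrics.xbonds[{i}]", f"missing '{role}'"
                ))
            else:
                _check_selection(config, topology, entry[role],
                                 f"metrics.xbonds[{i}].{role}", findings)
    for key in ("rmsd", "rmsf"):
        if key in m:
            if "fit" not in m[key]:
                findings.append(Finding(
                    "error", f"metrics.{key}", "missing 'fit' selection"
                ))
            else:
                sel = _check_selection(config, topology, m[key]["fit"],
                                       f"metrics.{key}.fit", findings)
                if sel is not None and 0 < len(sel) < 3:
                    findings.append(Finding(
                        "error", f"metrics.{key}.fit",
                        "superposition needs at least 3 fit atoms",
                    ))
            if "measure" in m[key]:
                _check_selection(config, topology, m[key]["measure"],
                                 f"metrics.{key}.measure", findings)
    for i, entry in enumerate(m.get("hydration", [])):
        for role in ("ligand_anchor", "protein_anchor", "waters"):
            if role not in entry:
                findings.append(Finding(
                    "error", f"metrics.hydration[{i}]", f"missing '{role}'"
                ))
            else:
                _check_selection(config, topology, entry[role],
                                 f"metrics.hydration[{i}].{role}", findings)
    return findings
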