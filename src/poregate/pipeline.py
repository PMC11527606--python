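"""End-to-end orchestration: one config file, many systems, a report bundle.

The bundle directory contains one subdirectory per system with gating,
permeation, occupancy, dwell, contact-fraction, correlation, torsion and
rmsd/rmsf tables, one subdirectory per comparison with the difference
tables, a summary.json with headline counts, and a run log. Failures are
isolated per analysis: one failing table is logged and skipped without
aborting the bundle.
"""
from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import dynamics, gating, networks, permeation
from .traj_io import (
    FrameWindow,
    Selection,
    Trajectory,
    read_topology,
    read_trajectory,
    select,
    write_json,
    write_tsv,
)

log = logging.getLogger("poregate")

_DEFAULT_CUTOFFS = {
    "gate_open": gating.DEFAULT_OPEN_CUTOFF,
    "radial": permeation.DEFAULT_RADIAL_CUTOFF,
    "hysteresis": permeation.DEFAULT_HYSTERESIS,
    "salt_bridge": 4.0,
    "hbond_distance": 3.5,
    "hbond_angle": 135.0,
    "hydrophobic": 4.5,
    "ligand_contact": 4.5,
    "dwell_assign": 5.0,
}


@dataclass
class SystemConfig:
    label: str
    topology: str
    trajectory: str
    window: FrameWindow | None = None


@dataclass
class AnalysisConfig:
    systems: list[SystemConfig]
    selections: dict
    output_dir: str
    cutoffs: dict = field(default_factory=dict)
    comparisons: list[tuple[str, str]] = field(default_factory=list)
    seed: int = 0

    def cutoff(self, name: str) -> float:
        return float(self.cutoffs.get(name, _DEFAULT_CUTOFFS[name]))


def validate_config(raw: dict, base_dir: str = ".", check_files: bool = True) -> AnalysisConfig:
    """Validate a parsed config mapping; collects every problem before
    raising so the user sees the full list."""
    problems: list[str] = []
    systems: list[SystemConfig] = []
    labels: set[str] = set()
    for i, entry in enumerate(raw.get("systems") or []):
        label = entry.get("label")
        if not label:
            problems.append(f"systems[{i}]: missing label")
            continue
        if label in labels:
            problems.append(f"systems[{i}]: duplicate label {label!r}")
        labels.add(label)
        window = None
        if "window" in entry:
            w = entry["window"]
            try:
                window = FrameWindow(int(w.get("start", 0)), int(w["end"]), int(w.get("stride", 1)))
            except (KeyError, TypeError, ValueError) as exc:
                problems.append(f"systems[{i}]: bad window ({exc})")
        paths = {}
        for key in ("topology", "trajectory"):
            p = entry.get(key)
            if not p:
                problems.append(f"systems[{i}]: missing {key} path")
                continue
            p = p if os.path.isabs(p) else os.path.join(base_dir, p)
            if check_files and not os.path.exists(p):
                problems.append(f"systems[{i}]: {key} file not found: {p}")
            paths[key] = p
        if len(paths) == 2:
            systems.append(SystemConfig(label, paths["topology"], paths["trajectory"], window))
    if not systems and not problems:
        problems.append("no systems defined")
    selections = raw.get("selections") or {}
    for key in ("sf", "hbc", "gloop", "ions"):
        if key not in selections:
            problems.append(f"selections: missing {key!r} expression")
    gates = selections.get("gates") or {}
    if not isinstance(gates, dict):
        problems.append("selections.gates must be a mapping gate_name -> settings")
        gates = {}
    for name, g in gates.items():
        if not isinstance(g, dict) or "resid" not in g:
            problems.append(f"selections.gates[{name}]: needs a resid")
    comparisons = []
    for j, cmp_entry in enumerate(raw.get("comparisons") or []):
        apo, holo = cmp_entry.get("apo"), cmp_entry.get("holo")
        if apo not in labels or holo not in labels:
            problems.append(f"comparisons[{j}]: labels {apo!r}/{holo!r} not all defined")
        else:
            comparisons.append((apo, holo))
    if "output_dir" not in raw:
        problems.append("missing output_dir")
    if problems:
        raise ValueError("invalid config:\n  " + "\n  ".join(problems))
    out_dir = raw["output_dir"]
    if not os.path.isabs(out_dir):
        out_dir = os.path.join(base_dir, out_dir)
    return AnalysisConfig(
        systems=systems,
        selections=selections,
        output_dir=out_dir,
        cutoffs=raw.get("cutoffs") or {},
        comparisons=comparisons,
        seed=int(raw.get("seed", 0)),
    )


def load_config(path: str, check_files: bool = True) -> AnalysisConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} is not a mapping")
    return validate_config(raw, base_dir=os.path.dirname(os.path.abspath(path)), check_files=check_files)


@dataclass
class ReportBundle:
    output_dir: str
    tables: dict[str, str]  # table id -> path
    errors: dict[str, str]  # table id -> reason
    summary: dict


class _SystemRun:
    """Per-system analysis state: loaded trajectory plus cached results."""

    def __init__(self, cfg: AnalysisConfig, sys_cfg: SystemConfig):
        self.cfg = cfg
        self.sys = sys_cfg
        topo = read_topology(sys_cfg.topology)
        self.traj: Trajectory = read_trajectory(topo, sys_cfg.trajectory)
        self.window = sys_cfg.window or FrameWindow.full(self.traj)
        self.window.validate(self.traj.n_frames)
        self.fractions: dict[str, networks.PairFractionTable] = {}
        self.corr: dynamics.CorrelationMatrix | None = None

    def sel(self, key: str, granularity: str = "atom") -> Selection:
        return select(self.traj.topology, self.cfg.selections[key], granularity)


def _table(bundle: ReportBundle, run_label: str, name: str, fn):
    """Run one analysis, record its table or its failure."""
    table_id = f"{run_label}/{name}"
    t0 = time.monotonic()
    try:
        path, rows = fn()
        bundle.tables[table_id] = path
        log.info("%s: %d rows in %.2fs", table_id, rows, time.monotonic() - t0)
    except Exception as exc:  # isolation contract: keep going
        bundle.errors[table_id] = f"{type(exc).__name__}: {exc}"
        log.error("%s failed: %s", table_id, exc)


def _analyze_system(cfg: AnalysisConfig, run: _SystemRun, out: str, bundle: ReportBundle) -> None:
    label = run.sys.label
    os.makedirs(out, exist_ok=True)
    traj, window = run.traj, run.window
    cut = cfg.cutoff

    def gates_fn():
        rows = 0
        summaries = {}
        for name, g in (cfg.selections.get("gates") or {}).items():
            gate = gating.GateDefinition(name, int(g["resid"]), g.get("atom_scope", "sidechain_heavy"))
            trace = gating.gate_distance_trace(traj, gate, window, g.get("pairing", "diagonal"))
            path = os.path.join(out, f"gate_{name}.tsv")
            rows += gating.write_gate_trace_tsv(path, trace, cutoff=cut("gate_open"))
            summaries[name] = gating.open_fraction(trace, cut("gate_open")).to_dict()
        write_json(os.path.join(out, "gates.json"), summaries)
        bundle.summary.setdefault("open_fraction", {})[label] = {
            k: v["open_fraction"] for k, v in summaries.items()
        }
        return os.path.join(out, "gates.json"), rows

    _table(bundle, label, "gating", gates_fn)

    model = None

    def perm_fn():
        nonlocal model
        model = permeation.build_compartments(
            traj, run.sel("sf"), run.sel("hbc"), run.sel("gloop"),
            radial_cutoff=cut("radial"), hysteresis=cut("hysteresis"),
        )
        events = permeation.detect_permeation_events(traj, run.sel("ions"), model, "ext_to_int", window)
        path = os.path.join(out, "events.tsv")
        n = write_tsv(
            path,
            ["ion", "frame_enter_sf", "frame_cross_hbc", "frame_exit_gloop", "direction"],
            ((e.ion, e.frame_enter_sf, e.frame_cross_hbc, e.frame_exit_gloop, e.direction) for e in events),
        )
        bundle.summary.setdefault("permeation_events", {})[label] = n
        return path, n

    _table(bundle, label, "permeation", perm_fn)

    def occupancy_fn():
        if model is None:
            raise RuntimeError("compartment model unavailable (permeation step failed)")
        rows = []
        for region in permeation.REGIONS:
            dist = permeation.occupancy_distribution(traj, run.sel("ions"), model, region, window)
            rows.extend((region, k, pct) for k, pct in sorted(dist.percent_of_frames.items()))
        path = os.path.join(out, "occupancy.tsv")
        return path, write_tsv(path, ["region", "n_ions", "percent"], rows)

    _table(bundle, label, "occupancy", occupancy_fn)

    def dwell_fn():
        if model is None:
            raise RuntimeError("compartment model unavailable (permeation step failed)")
        prof = permeation.dwell_profile(
            traj, run.sel("ions"), model, run.sel("protein", "residue") if "protein" in cfg.selections else select(traj.topology, "protein", "residue"),
            scope="all_channel_ions", assign_cutoff=cut("dwell_assign"), window=window,
        )
        path = os.path.join(out, "dwell.tsv")
        rows = [("region:" + k, v) for k, v in prof.per_region_percent.items()]
        rows += [
            (f"{k[0]}:{k[1]}" if isinstance(k, tuple) else str(k), v)
            for k, v in prof.per_residue_percent.items()
        ]
        return path, write_tsv(path, ["where", "percent"], rows)

    _table(bundle, label, "dwell", dwell_fn)

    criteria = {
        "salt_bridge": networks.ContactCriteria.salt_bridge(cut("salt_bridge")),
        "hbond": networks.ContactCriteria.hbond(cut("hbond_distance"), cut("hbond_angle")),
        "hydrophobic": networks.ContactCriteria.hydrophobic(cut("hydrophobic")),
    }
    for ctype, crit in criteria.items():
        def frac_fn(ctype=ctype, crit=crit):
            table = networks.pair_fractions(traj, crit, window, system_label=label)
            run.fractions[ctype] = table
            path = os.path.join(out, f"fractions_{ctype}.tsv")
            return path, networks.write_fraction_tsv(path, table)

        _table(bundle, label, f"fractions_{ctype}", frac_fn)

    if "ligand" in cfg.selections:
        def ligand_fn():
            profile = networks.ligand_contact_profile(
                traj, run.sel("ligand"), select(traj.topology, "protein", "residue"),
                cutoff=cut("ligand_contact"), window=window,
            )
            path = os.path.join(out, "ligand_contacts.tsv")
            rows = ((k[0], k[1], k[2], v) for k, v in profile.per_residue_percent.items())
            return path, write_tsv(path, ["chain", "resid", "resname", "percent"], rows)

        _table(bundle, label, "ligand_contacts", ligand_fn)

    def rmsd_fn():
        ca = select(traj.topology, "name CA and protein")
        trace = dynamics.rmsd_trace(traj, traj.coordinates[0], ca, window)
        path = os.path.join(out, "rmsd.tsv")
        n = write_tsv(path, ["frame", "rmsd_A"], zip(window.indices(), trace))
        prof = dynamics.rmsf_profile(traj, ca, window)
        write_tsv(
            os.path.join(out, "rmsf.tsv"),
            ["chain", "resid", "rmsf_A"],
            ((k[0], k[1], v) for k, v in zip(prof.residue_keys, prof.values)),
        )
        return path, n

    _table(bundle, label, "rmsd_rmsf", rmsd_fn)

    def corr_fn():
        run.corr = dynamics.correlation_matrix(traj, window=window)
        path = os.path.join(out, "correlation_matrix.tsv")
        keys = run.corr.residue_keys
        header = ["residue"] + [f"{c}{r}" for c, r in keys]
        rows = (
            [f"{keys[i][0]}{keys[i][1]}"] + [f"{v:.6f}" for v in run.corr.matrix[i]]
            for i in range(len(keys))
        )
        return path, write_tsv(path, header, rows)

    _table(bundle, label, "correlation", corr_fn)

    def torsion_fn():
        summ = dynamics.torsion_summary(traj, window)
        path = os.path.join(out, "torsions.tsv")
        keys = sorted(set(summ.phi_mean) | set(summ.psi_mean))
        rows = (
            (
                k[0], k[1],
                summ.phi_mean.get(k, float("nan")), summ.psi_mean.get(k, float("nan")),
                summ.phi_sd.get(k, float("nan")), summ.psi_sd.get(k, float("nan")),
            )
            for k in keys
        )
        return path, write_tsv(
            path, ["chain", "resid", "phi_mean", "psi_mean", "phi_circ_sd", "psi_circ_sd"], rows
        )

    _table(bundle, label, "torsions", torsion_fn)


def _compare(cfg: AnalysisConfig, runs: dict[str, _SystemRun], apo: str, holo: str, bundle: ReportBundle) -> None:
    out = os.path.join(cfg.output_dir, f"compare_{apo}_vs_{holo}")
    os.makedirs(out, exist_ok=True)
    for ctype in ("salt_bridge", "hbond", "hydrophobic"):
        def diff_fn(ctype=ctype):
            ta = runs[apo].fractions.get(ctype)
            th = runs[holo].fractions.get(ctype)
            if ta is None or th is None:
                raise RuntimeError(f"{ctype} fractions unavailable for {apo!r}/{holo!r}")
            diff = networks.difference_table(ta, th)
            path = os.path.join(out, f"diff_{ctype}.tsv")
            return path, networks.write_difference_tsv(path, diff)

        _table(bundle, f"{apo}_vs_{holo}", f"diff_{ctype}", diff_fn)

    def corr_diff_fn():
        ca, ch = runs[apo].corr, runs[holo].corr
        if ca is None or ch is None:
            raise RuntimeError("correlation matrices unavailable")
        rows = dynamics.correlation_difference(ca, ch)
        rows.sort(key=lambda r: -abs(r[3]))
        path = os.path.join(out, "diff_correlation.tsv")
        return path, write_tsv(
            path,
            ["residA", "residB", "c_apo", "c_holo", "delta"],
            (
                (f"{a[0]}{a[1]}", f"{b[0]}{b[1]}", f"{cA:.6f}", f"{cH:.6f}", f"{d:.6f}")
                for (a, b), cA, cH, d in rows[:200]
            ),
        )

    _table(bundle, f"{apo}_vs_{holo}", "diff_correlation", corr_diff_fn)

    def pca_fn():
        ra, rh = runs[apo], runs[holo]
        sa = select(ra.traj.topology, "name CA and protein")
        sh = select(rh.traj.topology, "name CA and protein")
        model = dynamics.combined_pca(
            ra.traj, rh.traj, sa, sh, ra.window, rh.window, labelA=apo, labelB=holo
        )
        path = os.path.join(out, "pca_projections.tsv")
        rows = []
        for label, proj in model.projections.items():
            rows.extend((label, i, p[0], p[1]) for i, p in enumerate(proj[:, :2]))
        n = write_tsv(path, ["system", "frame", "EV1", "EV2"], rows)
        write_tsv(
            os.path.join(out, "pca_eigenvalues.tsv"),
            ["mode", "eigenvalue_A2"],
            enumerate(model.eigenvalues[:20]),
        )
        for mode in (0, 1):
            dynamics.export_mode_morph(
                model, ra.traj.topology, mode, os.path.join(out, f"pca_morph_EV{mode + 1}.pdb")
            )
        return path, n

    _table(bundle, f"{apo}_vs_{holo}", "combined_pca", pca_fn)


def run_analysis(config: AnalysisConfig) -> ReportBundle:
    """Execute every per-system analysis, then every comparison.

    Deterministic for a given config + seed; partial failures are isolated
    per table and recorded in the bundle and the run log.
    """
    os.makedirs(config.output_dir, exist_ok=True)
    np.random.seed(config.seed)  # analyses are deterministic; belt and braces
    bundle = ReportBundle(config.output_dir, {}, {}, {"seed": config.seed})
    runs: dict[str, _SystemRun] = {}
    for sys_cfg in config.systems:
        try:
            runs[sys_cfg.label] = _SystemRun(config, sys_cfg)
        except Exception as exc:
            bundle.errors[f"{sys_cfg.label}/load"] = f"{type(exc).__name__}: {exc}"
            log.error("loading %s failed: %s", sys_cfg.label, exc)
            continue
        _analyze_system(config, runs[sys_cfg.label], os.path.join(config.output_dir, sys_cfg.label), bundle)
    for apo, holo in config.comparisons:
        if apo in runs and holo in runs:
            _compare(config, runs, apo, holo, bundle)
        else:
            bundle.errors[f"{apo}_vs_{holo}"] = "one or both systems failed to load"
    cfg_repr = json.dumps(
        {
            "systems": [[s.label, s.topology, s.trajectory] for s in config.systems],
            "selections": config.selections,
            "cutoffs": config.cutoffs,
            "seed": config.seed,
        },
        sort_keys=True,
    )
    bundle.summary["config_sha256"] = hashlib.sha256(cfg_repr.encode()).hexdigest()
    bundle.summary["errors"] = bundle.errors
    write_json(os.path.join(config.output_dir, "summary.json"), bundle.summary)
    return bundle
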