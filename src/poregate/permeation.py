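"""Directional ion permeation detection, occupancy and dwell-time statistics.

A permeation event is positional: one ion passing, in order, through the
selectivity-filter (SF) entrance, the helix-bundle-crossing (HBC) gate, and
the G-loop gate. Detection runs a per-ion finite-state machine over the
boundary z-levels with hysteresis; an ion leaving back through its entry
side resets the machine, and a completed pass only counts when the SF entry
itself was observed inside the analysed window.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .traj_io import FrameWindow, Selection, Trajectory

__all__ = [
    "CompartmentModel",
    "PermeationEvent",
    "OccupancyDistribution",
    "DwellProfile",
    "build_compartments",
    "detect_permeation_events",
    "occupancy_distribution",
    "dwell_profile",
]

DEFAULT_RADIAL_CUTOFF = 10.0  # Angstrom
DEFAULT_HYSTERESIS = 2.0  # Angstrom

REGIONS = ("sf", "cavity", "gloop")


@dataclass
class CompartmentModel:
    """Per-frame channel compartment boundaries along z plus the pore axis.

    Boundaries are stored top (extracellular) to bottom: z_ext_gate (SF top),
    z_sf_bottom, z_hbc, z_gloop. ``axis_xy`` is the per-frame (x, y) of the
    pore axis (assumed parallel to z after alignment).
    """

    z_ext_gate: np.ndarray
    z_sf_bottom: np.ndarray
    z_hbc: np.ndarray
    z_gloop: np.ndarray
    axis_xy: np.ndarray  # (n_frames, 2)
    radial_cutoff: float = DEFAULT_RADIAL_CUTOFF
    hysteresis: float = DEFAULT_HYSTERESIS

    def __post_init__(self):
        if self.radial_cutoff <= 0:
            raise ValueError("radial_cutoff must be > 0")
        if self.hysteresis < 0:
            raise ValueError("hysteresis must be >= 0")
        order = np.stack([self.z_ext_gate, self.z_sf_bottom, self.z_hbc, self.z_gloop])
        bad = np.nonzero(~np.all(np.diff(order, axis=0) < 0, axis=0))[0]
        if len(bad):
            raise ValueError(
                f"compartment z-ordering violated at frame {int(bad[0])}: "
                "expected z_ext_gate > z_sf_bottom > z_hbc > z_gloop "
                "(wrong selections or unaligned input?)"
            )

    @property
    def n_frames(self) -> int:
        return len(self.z_ext_gate)

    def boundaries(self) -> np.ndarray:
        """(4, n_frames) array ordered top to bottom."""
        return np.stack([self.z_ext_gate, self.z_sf_bottom, self.z_hbc, self.z_gloop])

    def region_slab(self, region: str) -> tuple[np.ndarray, np.ndarray]:
        """(z_low, z_high) per frame for a named region."""
        if region == "sf":
            return self.z_sf_bottom, self.z_ext_gate
        if region == "cavity":
            return self.z_hbc, self.z_sf_bottom
        if region == "gloop":
            return self.z_gloop, self.z_hbc
        raise ValueError(f"unknown region {region!r}")


@dataclass(frozen=True)
class PermeationEvent:
    """One completed directional pore crossing by one ion.

    The three frames mark, in the direction of travel, the SF-side entry,
    the HBC crossing and the G-loop-side exit.
    """

    ion: int  # atom index
    frame_enter_sf: int
    frame_cross_hbc: int
    frame_exit_gloop: int
    direction: str  # ext_to_int | int_to_ext

    def __post_init__(self):
        if not self.frame_enter_sf <= self.frame_cross_hbc <= self.frame_exit_gloop:
            raise ValueError("event frames out of order")


@dataclass
class OccupancyDistribution:
    region: str
    percent_of_frames: dict[int, float]  # ion count -> percent

    def __post_init__(self):
        total = sum(self.percent_of_frames.values())
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"occupancy percentages sum to {total}, not 100")


@dataclass
class DwellProfile:
    scope: str  # all_channel_ions | permeating_ions_only
    per_region_percent: dict[str, float]  # regions + "unassigned"
    per_residue_percent: dict[tuple[str, int], float]
    total_ion_frames: int


def build_compartments(
    traj: Trajectory,
    sf_sel: Selection,
    hbc_sel: Selection,
    gloop_sel: Selection,
    radial_cutoff: float = DEFAULT_RADIAL_CUTOFF,
    hysteresis: float = DEFAULT_HYSTERESIS,
    axis_sel: Selection | None = None,
) -> CompartmentModel:
    """Derive per-frame compartment boundaries from residue selections.

    The SF selection is split by residue: the SF top boundary is the
    per-frame centroid z of its highest residue (judged at frame 0), the SF
    bottom that of its lowest; HBC and G-loop boundaries are the centroid z
    of their whole selections. The pore axis is the per-frame (x, y)
    centroid of ``axis_sel`` (default: all protein CA atoms).
    """
    for name, sel in (("sf", sf_sel), ("hbc", hbc_sel), ("gloop", gloop_sel)):
        if sel.empty:
            raise ValueError(f"{name} selection is empty")
    topo = traj.topology
    sf_residues: dict[tuple, list[int]] = {}
    for i in sf_sel.atom_indices:
        sf_residues.setdefault(topo.residue_key(int(i)), []).append(int(i))
    z0 = traj.coordinates[0, :, 2]
    res_z0 = {k: float(np.mean(z0[idx])) for k, idx in sf_residues.items()}
    top_key = max(res_z0, key=res_z0.get)
    bot_key = min(res_z0, key=res_z0.get)
    top_idx = np.asarray(sf_residues[top_key])
    bot_idx = np.asarray(sf_residues[bot_key])

    z = traj.coordinates[:, :, 2]
    z_ext = z[:, top_idx].mean(axis=1)
    z_sfb = z[:, bot_idx].mean(axis=1)
    z_hbc = z[:, hbc_sel.atom_indices].mean(axis=1)
    z_glp = z[:, gloop_sel.atom_indices].mean(axis=1)

    if axis_sel is None:
        mask = (topo.names == "CA") & ~(topo.is_ion | topo.is_ligand)
        axis_idx = np.nonzero(mask)[0]
    else:
        axis_idx = axis_sel.atom_indices
    if len(axis_idx) == 0:
        raise ValueError("axis selection is empty")
    axis_xy = traj.coordinates[:, axis_idx, :2].mean(axis=1)

    return CompartmentModel(z_ext, z_sfb, z_hbc, z_glp, axis_xy, radial_cutoff, hysteresis)


def _ion_series(traj: Trajectory, ion_atom: int, model: CompartmentModel):
    xyz = traj.coordinates[:, ion_atom, :]
    r = np.hypot(xyz[:, 0] - model.axis_xy[:, 0], xyz[:, 1] - model.axis_xy[:, 1])
    return xyz[:, 2], r


def detect_permeation_events(
    traj: Trajectory,
    ions: Selection,
    model: CompartmentModel,
    direction: str = "ext_to_int",
    window: FrameWindow | None = None,
) -> list[PermeationEvent]:
    """Run the per-ion crossing state machine and collect completed events.

    States advance when the ion's z passes a boundary by more than the
    hysteresis margin while its radial distance from the pore axis is within
    the radial cutoff. Ions starting mid-pore initialize to the matching
    state but earn no event until an in-window SF-side entry is observed.
    """
    if direction not in ("ext_to_int", "int_to_ext"):
        raise ValueError(f"unknown direction {direction!r}")
    if window is None:
        window = FrameWindow(0, traj.n_frames)
    window.validate(traj.n_frames)
    frames = window.indices()
    bounds = model.boundaries()  # (4, n_frames), top to bottom
    h = model.hysteresis
    events: list[PermeationEvent] = []
    for ion_atom in ions.atom_indices:
        z_all, r_all = _ion_series(traj, int(ion_atom), model)
        if direction == "ext_to_int":
            z = z_all[frames]
            b = bounds[:, frames]
        else:  # mirror: run the same descending machine on flipped z
            z = -z_all[frames]
            b = -bounds[::-1, frames]
        r = r_all[frames]
        # state: number of boundaries crossed downward (0 = outside entry side)
        z0 = z[0]
        state = int(np.sum(z0 < b[:, 0] - h))
        crossing_frames: list[int | None] = [None, None, None, None]
        for t in range(len(frames)):
            if z[t] > b[0, t] + h:
                state = 0
                crossing_frames = [None, None, None, None]
                continue
            while state < 4 and z[t] < b[state, t] - h and r[t] <= model.radial_cutoff:
                crossing_frames[state] = int(frames[t])
                state += 1
                if state == 4:
                    if crossing_frames[0] is not None:
                        events.append(
                            PermeationEvent(
                                ion=int(ion_atom),
                                frame_enter_sf=crossing_frames[0],
                                frame_cross_hbc=crossing_frames[2],
                                frame_exit_gloop=crossing_frames[3],
                                direction=direction,
                            )
                        )
                    crossing_frames = [None, None, None, None]
    return events


def occupancy_distribution(
    traj: Trajectory,
    ions: Selection,
    model: CompartmentModel,
    region: str,
    window: FrameWindow | None = None,
) -> OccupancyDistribution:
    """Percent of window frames holding k ions inside the region's slab
    (and within the radial cutoff), for each observed k."""
    if window is None:
        window = FrameWindow(0, traj.n_frames)
    window.validate(traj.n_frames)
    frames = window.indices()
    if len(frames) == 0:
        raise ValueError("empty frame window")
    zlo, zhi = model.region_slab(region)
    counts = np.zeros(len(frames), dtype=int)
    for ion_atom in ions.atom_indices:
        z, r = _ion_series(traj, int(ion_atom), model)
        inside = (
            (z[frames] > zlo[frames])
            & (z[frames] <= zhi[frames])
            & (r[frames] <= model.radial_cutoff)
        )
        counts += inside
    ks, freq = np.unique(counts, return_counts=True)
    percent = {int(k): 100.0 * int(f) / len(frames) for k, f in zip(ks, freq)}
    return OccupancyDistribution(region, percent)


def dwell_profile(
    traj: Trajectory,
    ions: Selection,
    model: CompartmentModel,
    residues: Selection,
    scope: str = "all_channel_ions",
    assign_cutoff: float = 5.0,
    window: FrameWindow | None = None,
) -> DwellProfile:
    """Where in-channel ions spend their time, by region and by residue.

    Each in-channel ion-frame (z between the G-loop and SF-top boundaries,
    radius within the cutoff) is attributed to the residue whose nearest
    heavy atom is closest, if within ``assign_cutoff`` (ties break to the
    lower (chain, resid)); otherwise to "unassigned". With scope
    ``permeating_ions_only`` only ions with a recorded ext_to_int event
    contribute, and only between that event's entry and exit frames.
    """
    if assign_cutoff <= 0:
        raise ValueError("assign_cutoff must be > 0")
    if scope not in ("all_channel_ions", "permeating_ions_only"):
        raise ValueError(f"unknown scope {scope!r}")
    if residues.empty:
        raise ValueError("residue selection is empty")
    if window is None:
        window = FrameWindow(0, traj.n_frames)
    window.validate(traj.n_frames)
    frames = window.indices()
    topo = traj.topology

    res_atoms: dict[tuple[str, int], np.ndarray] = {}
    heavy = topo.heavy_mask()
    for i in residues.atom_indices:
        if not heavy[i]:
            continue
        key = (str(topo.chains[i]), int(topo.resids[i]))
        res_atoms.setdefault(key, []).append(int(i))
    res_keys = sorted(res_atoms)
    res_idx = [np.asarray(res_atoms[k]) for k in res_keys]

    allowed: dict[int, np.ndarray] | None = None
    if scope == "permeating_ions_only":
        events = detect_permeation_events(traj, ions, model, "ext_to_int", window)
        allowed = {}
        for ev in events:
            mask = allowed.setdefault(ev.ion, np.zeros(traj.n_frames, dtype=bool))
            mask[ev.frame_enter_sf : ev.frame_exit_gloop + 1] = True

    region_frames = {r: 0 for r in REGIONS}
    region_frames["unassigned"] = 0
    residue_frames = {k: 0 for k in res_keys}
    residue_frames_unassigned = 0
    total = 0
    slabs = {r: model.region_slab(r) for r in REGIONS}
    for ion_atom in ions.atom_indices:
        ion_atom = int(ion_atom)
        if allowed is not None and ion_atom not in allowed:
            continue
        z, r = _ion_series(traj, ion_atom, model)
        in_channel = (
            (z[frames] > model.z_gloop[frames])
            & (z[frames] <= model.z_ext_gate[frames])
            & (r[frames] <= model.radial_cutoff)
        )
        if allowed is not None:
            in_channel &= allowed[ion_atom][frames]
        for t in np.nonzero(in_channel)[0]:
            f = frames[t]
            total += 1
            zf = z[f]
            assigned_region = "unassigned"
            for reg in REGIONS:
                zlo, zhi = slabs[reg]
                if zlo[f] < zf <= zhi[f]:
                    assigned_region = reg
                    break
            region_frames[assigned_region] += 1
            pos = traj.coordinates[f, ion_atom]
            best_key = None
            best_d = np.inf
            for key, idx in zip(res_keys, res_idx):
                d = float(np.sqrt(((traj.coordinates[f, idx] - pos) ** 2).sum(axis=1)).min())
                # res_keys is sorted, so on a tie the lower (chain, resid) wins
                if d < best_d:
                    best_d = d
                    best_key = key
            if best_key is None or best_d > assign_cutoff:
                residue_frames_unassigned += 1
            else:
                residue_frames[best_key] += 1

    def pct(n):
        return 100.0 * n / total if total else 0.0

    per_region = {k: pct(v) for k, v in region_frames.items()}
    per_residue = {k: pct(v) for k, v in residue_frames.items() if v}
    per_residue["unassigned"] = pct(residue_frames_unassigned)
    return DwellProfile(scope, per_region, per_residue, total)
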