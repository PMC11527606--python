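"""Salt-bridge, hydrogen-bond and hydrophobic contact networks.

Per-frame contacts are reduced to per-pair formed fractions over an analysis
window, two systems' tables are differenced (holo - apo), and the largest
absolute changes ranked. Pair keys carry chain IDs so inter-subunit pairs
are first-class.

Geometric criteria (the conventional defaults below are configurable):
salt bridge, min basic-N to acidic-O distance <= 4.0 A; hydrogen bond,
donor-heavy to acceptor distance <= 3.5 A and D-H...A angle >= 135 deg;
hydrophobic, min nonpolar side-chain carbon distance <= 4.5 A. Histidine
counts as basic only in its doubly protonated form (HIP, or HID/HIE/HIS
carrying both ring protons).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .traj_io import FrameWindow, Selection, Topology, Trajectory, write_tsv

__all__ = [
    "ContactCriteria",
    "PairFractionTable",
    "DifferenceTable",
    "LigandContactProfile",
    "detect_contacts_frame",
    "pair_fractions",
    "difference_table",
    "top_differences",
    "ligand_contact_profile",
]

# charged-group atom names
BASIC_GROUP_ATOMS = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "HIP": ("ND1", "NE2"),
}
ACIDIC_GROUP_ATOMS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}

# side-chain hydrogen-bond donor heavy atoms / acceptors (backbone N/O are
# added separately for every amino-acid residue)
DONOR_ATOMS = {
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "ASN": ("ND2",),
    "GLN": ("NE2",),
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "TRP": ("NE1",),
    "HIS": ("ND1", "NE2"),
    "HID": ("ND1",),
    "HIE": ("NE2",),
    "HIP": ("ND1", "NE2"),
    "CYS": ("SG",),
}
ACCEPTOR_ATOMS = {
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "HIS": ("ND1", "NE2"),
    "HID": ("NE2",),
    "HIE": ("ND1",),
    "MET": ("SD",),
}

HYDROPHOBIC_RESNAMES = frozenset(
    {"ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "TRP", "CYS"}
)
_BACKBONE_C = frozenset({"C", "CA"})

PairKey = tuple[tuple[str, int, str], tuple[str, int, str]]  # (chain, resid, resname)


@dataclass
class ContactCriteria:
    contact_type: str  # salt_bridge | hbond | hydrophobic
    distance_cutoff: float
    angle_cutoff: float | None = None  # degrees, hbond only
    basic_atoms: dict = field(default_factory=lambda: dict(BASIC_GROUP_ATOMS))
    acidic_atoms: dict = field(default_factory=lambda: dict(ACIDIC_GROUP_ATOMS))
    donor_atoms: dict = field(default_factory=lambda: dict(DONOR_ATOMS))
    acceptor_atoms: dict = field(default_factory=lambda: dict(ACCEPTOR_ATOMS))
    hydrophobic_resnames: frozenset = HYDROPHOBIC_RESNAMES
    include_backbone_hbonds: bool = True

    def __post_init__(self):
        if self.contact_type not in ("salt_bridge", "hbond", "hydrophobic"):
            raise ValueError(f"unknown contact type {self.contact_type!r}")
        if self.distance_cutoff <= 0:
            raise ValueError("distance_cutoff must be > 0")
        if self.contact_type == "hbond":
            if self.angle_cutoff is None:
                self.angle_cutoff = 135.0
            if not 0 < self.angle_cutoff <= 180:
                raise ValueError("angle_cutoff must be in (0, 180]")

    @classmethod
    def salt_bridge(cls, distance_cutoff: float = 4.0) -> "ContactCriteria":
        return cls("salt_bridge", distance_cutoff)

    @classmethod
    def hbond(cls, distance_cutoff: float = 3.5, angle_cutoff: float = 135.0) -> "ContactCriteria":
        return cls("hbond", distance_cutoff, angle_cutoff)

    @classmethod
    def hydrophobic(cls, distance_cutoff: float = 4.5) -> "ContactCriteria":
        return cls("hydrophobic", distance_cutoff)


@dataclass
class PairFractionTable:
    system_label: str
    contact_type: str
    window: FrameWindow
    entries: dict[PairKey, float]

    def fraction(self, pair: PairKey) -> float:
        """Fraction for a pair; pairs never formed read as 0."""
        return self.entries.get(_canonical(pair), 0.0)


@dataclass
class DifferenceTable:
    apo_label: str
    holo_label: str
    contact_type: str
    entries: dict[PairKey, float]  # delta = holo - apo


@dataclass
class LigandContactProfile:
    ligand: str
    per_residue_percent: dict[tuple[str, int, str], float]


def _canonical(pair: PairKey) -> PairKey:
    a, b = pair
    return (a, b) if a <= b else (b, a)


def _residue_groups(topology: Topology) -> dict[tuple[str, int, str], np.ndarray]:
    groups: dict[tuple[str, int, str], list[int]] = {}
    for i in range(topology.n_atoms):
        if topology.is_ion[i] or topology.is_ligand[i]:
            continue
        key = (str(topology.chains[i]), int(topology.resids[i]), str(topology.resnames[i]))
        groups.setdefault(key, []).append(i)
    return {k: np.asarray(v) for k, v in groups.items()}


def _his_is_basic(topology: Topology, idx: np.ndarray, resname: str) -> bool:
    if resname == "HIP":
        return True
    if resname in ("HIS", "HID", "HIE"):
        names = set(topology.names[idx])
        return {"HD1", "HE2"} <= names
    return False


class _ContactIndex:
    """Pre-resolved atom groups per residue for one (topology, criteria)."""

    def __init__(self, topology: Topology, criteria: ContactCriteria):
        self.criteria = criteria
        self.topology = topology
        groups = _residue_groups(topology)
        c = criteria
        self.group_a: dict = {}
        self.group_b: dict = {}
        self.hydrogens: dict = {}
        if c.contact_type == "salt_bridge":
            for key, idx in groups.items():
                resname = key[2]
                basic_names = c.basic_atoms.get(resname)
                if basic_names is None and _his_is_basic(topology, idx, resname):
                    basic_names = ("ND1", "NE2")
                if basic_names:
                    sub = idx[np.isin(topology.names[idx], basic_names)]
                    if len(sub):
                        self.group_a[key] = sub
                acidic_names = c.acidic_atoms.get(resname)
                if acidic_names:
                    sub = idx[np.isin(topology.names[idx], acidic_names)]
                    if len(sub):
                        self.group_b[key] = sub
        elif c.contact_type == "hydrophobic":
            for key, idx in groups.items():
                if key[2] not in c.hydrophobic_resnames:
                    continue
                sub = idx[
                    (topology.elements[idx] == "C")
                    & ~np.isin(topology.names[idx], sorted(_BACKBONE_C))
                ]
                if len(sub):
                    self.group_a[key] = sub
            self.group_b = self.group_a
        else:  # hbond
            for key, idx in groups.items():
                resname = key[2]
                donor_names = list(c.donor_atoms.get(resname, ()))
                acceptor_names = list(c.acceptor_atoms.get(resname, ()))
                if c.include_backbone_hbonds:
                    donor_names.append("N")
                    acceptor_names.append("O")
                donors = idx[np.isin(topology.names[idx], donor_names)]
                # a donor heavy atom is only usable with an attached hydrogen
                hyd = idx[topology.elements[idx] == "H"]
                if len(donors) and len(hyd):
                    self.group_a[key] = donors
                    self.hydrogens[key] = hyd
                acceptors = idx[np.isin(topology.names[idx], acceptor_names)]
                if len(acceptors):
                    self.group_b[key] = acceptors

    def candidate_pairs(self):
        for ka in self.group_a:
            for kb in self.group_b:
                if ka == kb:
                    continue
                if ka[0] == kb[0] and abs(ka[1] - kb[1]) <= 1:
                    continue  # same or backbone-adjacent residue
                if self.criteria.contact_type == "hydrophobic" and ka > kb:
                    continue  # symmetric criterion: visit each pair once
                yield ka, kb


def _min_dist(coords: np.ndarray, ia: np.ndarray, ib: np.ndarray) -> float:
    diff = coords[ia][:, None, :] - coords[ib][None, :, :]
    return float(np.sqrt((diff**2).sum(axis=2)).min())


def _hbond_formed(
    coords: np.ndarray,
    donors: np.ndarray,
    hydrogens: np.ndarray,
    acceptors: np.ndarray,
    dist_cut: float,
    angle_cut: float,
) -> bool:
    for d in donors:
        dh = coords[hydrogens] - coords[d]
        attached = hydrogens[np.linalg.norm(dh, axis=1) <= 1.25]
        if not len(attached):
            continue
        for a in acceptors:
            if np.linalg.norm(coords[a] - coords[d]) > dist_cut:
                continue
            for h in attached:
                hd = coords[d] - coords[h]
                ha = coords[a] - coords[h]
                denom = np.linalg.norm(hd) * np.linalg.norm(ha)
                if denom < 1e-12:
                    continue
                cosang = np.clip(hd @ ha / denom, -1.0, 1.0)
                if np.degrees(np.arccos(cosang)) >= angle_cut:
                    return True
    return False


def detect_contacts_frame(
    frame_coords: np.ndarray,
    topology: Topology,
    criteria: ContactCriteria,
    _index: _ContactIndex | None = None,
) -> set[PairKey]:
    """Residue pairs satisfying the criteria in one coordinate frame.

    Intra-residue and backbone-adjacent (|delta resid| <= 1, same chain)
    pairs are excluded. Residue types missing from the atom tables simply
    contribute no candidate groups.
    """
    index = _index if _index is not None else _ContactIndex(topology, criteria)
    c = criteria
    out: set[PairKey] = set()
    for ka, kb in index.candidate_pairs():
        pair = _canonical((ka, kb))
        if pair in out:
            continue
        if c.contact_type == "hbond":
            if _hbond_formed(
                frame_coords,
                index.group_a[ka],
                index.hydrogens[ka],
                index.group_b[kb],
                c.distance_cutoff,
                c.angle_cutoff,
            ):
                out.add(pair)
        else:
            if _min_dist(frame_coords, index.group_a[ka], index.group_b[kb]) <= c.distance_cutoff:
                out.add(pair)
    return out


def pair_fractions(
    traj: Trajectory,
    criteria: ContactCriteria,
    window: FrameWindow | None = None,
    system_label: str = "",
) -> PairFractionTable:
    """Formed-frame fraction per canonical residue pair over the window.

    Pairs never formed are omitted (lookups return 0).
    """
    if window is None:
        window = FrameWindow.full(traj)
    window.validate(traj.n_frames)
    frames = window.indices()
    if len(frames) == 0:
        raise ValueError("empty frame window")
    index = _ContactIndex(traj.topology, criteria)
    counts: dict[PairKey, int] = {}
    for f in frames:
        for pair in detect_contacts_frame(traj.coordinates[f], traj.topology, criteria, index):
            counts[pair] = counts.get(pair, 0) + 1
    entries = {pair: n / len(frames) for pair, n in sorted(counts.items())}
    return PairFractionTable(system_label, criteria.contact_type, window, entries)


def difference_table(apo: PairFractionTable, holo: PairFractionTable) -> DifferenceTable:
    """Delta = holo - apo per pair; the pair universes are unioned with
    missing entries read as 0. Antisymmetric under swapping the systems."""
    if apo.contact_type != holo.contact_type:
        raise ValueError(
            f"contact type mismatch: {apo.contact_type} vs {holo.contact_type}"
        )
    pairs = sorted(set(apo.entries) | set(holo.entries))
    entries = {p: holo.fraction(p) - apo.fraction(p) for p in pairs}
    return DifferenceTable(apo.system_label, holo.system_label, apo.contact_type, entries)


def top_differences(
    diff: DifferenceTable, k: int | None = None, threshold: float | None = None
) -> list[tuple[PairKey, float]]:
    """Pairs ranked by |delta| descending; ties break on the canonical pair
    key, so the ordering is stable and deterministic."""
    if not diff.entries:
        raise ValueError("empty difference table")
    if k is not None and k <= 0:
        raise ValueError("k must be > 0")
    ranked = sorted(diff.entries.items(), key=lambda kv: (-abs(kv[1]), kv[0]))
    if threshold is not None:
        ranked = [(p, d) for p, d in ranked if abs(d) >= threshold]
    if k is not None:
        ranked = ranked[:k]
    return ranked


def ligand_contact_profile(
    traj: Trajectory,
    ligand: Selection,
    protein_residues: Selection,
    cutoff: float = 4.5,
    window: FrameWindow | None = None,
) -> LigandContactProfile:
    """Percent of window frames with any ligand heavy atom within ``cutoff``
    of any heavy atom of each protein residue."""
    if ligand.empty:
        raise ValueError("ligand selection is empty")
    if window is None:
        window = FrameWindow.full(traj)
    window.validate(traj.n_frames)
    frames = window.indices()
    topo = traj.topology
    heavy = topo.heavy_mask()
    lig_idx = np.asarray([i for i in ligand.atom_indices if heavy[i]])
    if len(lig_idx) == 0:
        raise ValueError("ligand selection has no heavy atoms")
    res_atoms: dict[tuple[str, int, str], list[int]] = {}
    for i in protein_residues.atom_indices:
        if not heavy[i]:
            continue
        key = (str(topo.chains[i]), int(topo.resids[i]), str(topo.resnames[i]))
        res_atoms.setdefault(key, []).append(int(i))
    counts = {k: 0 for k in res_atoms}
    for f in frames:
        coords = traj.coordinates[f]
        for key, idx in res_atoms.items():
            if _min_dist(coords, np.asarray(idx), lig_idx) <= cutoff:
                counts[key] += 1
    percent = {k: 100.0 * n / len(frames) for k, n in sorted(counts.items())}
    return LigandContactProfile(ligand.expression, percent)


def write_fraction_tsv(path: str, table: PairFractionTable) -> int:
    rows = (
        (a[0], a[1], a[2], b[0], b[1], b[2], table.contact_type, frac)
        for (a, b), frac in table.entries.items()
    )
    return write_tsv(
        path,
        ["chainA", "residA", "resnameA", "chainB", "residB", "resnameB", "type", "fraction"],
        rows,
    )


def write_difference_tsv(path: str, diff: DifferenceTable) -> int:
    rows = (
        (a[0], a[1], a[2], b[0], b[1], b[2], diff.contact_type, delta)
        for (a, b), delta in diff.entries.items()
    )
    return write_tsv(
        path,
        ["chainA", "residA", "resnameA", "chainB", "residB", "resnameB", "type", "delta"],
        rows,
    )
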