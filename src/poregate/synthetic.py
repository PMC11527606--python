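"""Synthetic C4-symmetric toy-channel generator with planted ground truth.

Everything here is kinematic bead placement — no force field, no energies.
The generator exists so that every analysis operation in this package can be
tested against exactly known quantities: gate apertures follow a prescribed
schedule, scripted ions complete or abort pore crossings, contact pairs are
formed in an exact number of frames, residue-pair displacement correlations
have a prescribed analytic value, and backbone dihedrals are built by
internal-coordinate construction to planted values.

Randomness: a single integer seed is split into per-concern substreams via
``np.random.default_rng([seed, stream_id])`` with stream ids 0 (ions),
1 (contacts), 2 (correlations), 3 (torsions).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .traj_io import Topology, Trajectory

__all__ = [
    "ChannelSpec",
    "GateSchedule",
    "IonScript",
    "ContactPlan",
    "CorrelationPlan",
    "TorsionPlan",
    "generate_topology",
    "generate_trajectory",
    "complete_crossing_script",
    "abort_script",
    "retrograde_script",
    "parked_script",
]

_CHAINS = ("A", "B", "C", "D")

# substream ids for the seed-splitting scheme
_STREAM_IONS, _STREAM_CONTACTS, _STREAM_CORR, _STREAM_TORSION = 0, 1, 2, 3


@dataclass
class ChannelSpec:
    """Geometry of the toy channel: 4 chains around the z-axis.

    ``z_extents`` is (z_int, z_ext) with the extracellular side at larger z.
    ``gate_layout`` maps gate name -> (residue_number, z_position); gates must
    be ordered SF above HBC above G-loop. ``sf_layout`` is
    ((first_resid, last_resid), (z_low, z_high)) for the selectivity filter.
    """

    residues_per_subunit: int = 16
    pore_radius: float = 10.0
    z_extents: tuple[float, float] = (-25.0, 25.0)
    gate_layout: dict[str, tuple[int, float]] = field(
        default_factory=lambda: {"HBC": (8, 0.0), "Gloop": (12, -15.0)}
    )
    sf_layout: tuple[tuple[int, int], tuple[float, float]] = ((3, 5), (15.0, 20.0))
    n_ions: int = 0
    n_ligands: int = 0
    seed: int = 0

    def __post_init__(self):
        z_int, z_ext = self.z_extents
        if z_ext <= z_int:
            raise ValueError("z_extents must be (z_int, z_ext) with z_ext > z_int")
        (sf_lo, sf_hi), (zlo, zhi) = self.sf_layout
        if not (1 <= sf_lo <= sf_hi <= self.residues_per_subunit):
            raise ValueError("sf_layout residue range outside subunit")
        special = [r for r, _ in self.gate_layout.values()]
        if any(not (1 <= r <= self.residues_per_subunit) for r in special):
            raise ValueError(
                "gate residue outside subunit: increase residues_per_subunit"
            )
        zs = sorted(self.gate_layout.values(), key=lambda t: -t[1])
        for (ra, za), (rb, zb) in zip(zs, zs[1:]):
            if za <= zb:
                raise ValueError("gate z positions must be distinct and ordered")
        if self.gate_layout and zlo <= max(z for _, z in self.gate_layout.values()):
            raise ValueError("SF must lie above all gates")

    @property
    def gate_z(self) -> dict[str, float]:
        return {k: z for k, (_, z) in self.gate_layout.items()}


@dataclass
class GateSchedule:
    """Per-frame target aperture (Angstrom) for one named gate."""

    gate_name: str
    kind: str  # constant | square | sine
    params: dict

    @classmethod
    def constant(cls, gate_name: str, value: float) -> "GateSchedule":
        return cls(gate_name, "constant", {"value": value})

    @classmethod
    def square(
        cls, gate_name: str, low: float, high: float, period: int, duty: float
    ) -> "GateSchedule":
        """Square wave: the first round(duty*period) frames of each period are
        at ``high``, the rest at ``low``. Choose period | n_frames and
        duty*period integral for an exact open fraction."""
        return cls(
            gate_name,
            "square",
            {"low": low, "high": high, "period": period, "duty": duty},
        )

    @classmethod
    def sine(
        cls, gate_name: str, mean: float, amplitude: float, period: int
    ) -> "GateSchedule":
        return cls(
            gate_name, "sine", {"mean": mean, "amplitude": amplitude, "period": period}
        )

    def distances(self, n_frames: int) -> np.ndarray:
        t = np.arange(n_frames)
        if self.kind == "constant":
            d = np.full(n_frames, float(self.params["value"]))
        elif self.kind == "square":
            p = int(self.params["period"])
            n_high = int(round(self.params["duty"] * p))
            d = np.where(
                (t % p) < n_high, float(self.params["high"]), float(self.params["low"])
            )
        elif self.kind == "sine":
            d = self.params["mean"] + self.params["amplitude"] * np.sin(
                2 * np.pi * t / self.params["period"]
            )
        else:
            raise ValueError(f"unknown schedule kind {self.kind!r}")
        if np.any(d <= 0):
            raise ValueError("gate schedule produces non-positive aperture")
        return d


@dataclass
class IonScript:
    """Scripted z-motion for one ion: piecewise-linear between waypoints.

    ``waypoints`` is a list of (frame, z) with strictly increasing frames;
    before the first / after the last waypoint the ion holds that z. Lateral
    (x, y) motion is ``radial_offset`` plus seeded Gaussian noise with SD
    ``lateral_noise_sd``, radius-clipped to 0.8 * pore_radius (or to
    |radial_offset| if that is larger, so ions can be parked outside the
    pore on purpose). ``outcome`` is declarative bookkeeping used for the
    ground-truth manifest: complete | abort | retrograde | parked.
    """

    ion_index: int
    waypoints: list[tuple[int, float]]
    lateral_noise_sd: float = 0.5
    radial_offset: float = 0.0
    outcome: str = "parked"

    def __post_init__(self):
        frames = [f for f, _ in self.waypoints]
        if not self.waypoints:
            raise ValueError("ion script needs at least one waypoint")
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError("ion waypoints must be strictly increasing in frame")

    def z_series(self, n_frames: int) -> np.ndarray:
        frames = np.asarray([f for f, _ in self.waypoints], dtype=np.float64)
        zs = np.asarray([z for _, z in self.waypoints], dtype=np.float64)
        return np.interp(np.arange(n_frames, dtype=np.float64), frames, zs)

    @property
    def direction(self) -> str:
        return "ext_to_int" if self.waypoints[0][1] >= self.waypoints[-1][1] else "int_to_ext"


def complete_crossing_script(
    spec: ChannelSpec,
    ion_index: int,
    start_frame: int,
    end_frame: int,
    margin: float = 8.0,
    lateral_noise_sd: float = 0.5,
) -> IonScript:
    """Full extracellular -> intracellular crossing between the two frames."""
    z_int, z_ext = spec.z_extents
    return IonScript(
        ion_index,
        [(start_frame, z_ext + margin), (end_frame, z_int - margin)],
        lateral_noise_sd=lateral_noise_sd,
        outcome="complete",
    )


def _cavity_mid_z(spec: ChannelSpec) -> float:
    top_gate_z = max(z for _, z in spec.gate_layout.values())
    sf_z_low = spec.sf_layout[1][0]
    return (sf_z_low + top_gate_z) / 2.0


def abort_script(
    spec: ChannelSpec,
    ion_index: int,
    start_frame: int,
    turn_frame: int,
    end_frame: int,
    turn_z: float | None = None,
    margin: float = 8.0,
    lateral_noise_sd: float = 0.5,
) -> IonScript:
    """Descend into the cavity, turn around, and leave through the top."""
    z_int, z_ext = spec.z_extents
    if turn_z is None:
        turn_z = _cavity_mid_z(spec)
    return IonScript(
        ion_index,
        [
            (start_frame, z_ext + margin),
            (turn_frame, turn_z),
            (end_frame, z_ext + margin),
        ],
        lateral_noise_sd=lateral_noise_sd,
        outcome="abort",
    )


def retrograde_script(
    spec: ChannelSpec,
    ion_index: int,
    start_frame: int,
    turn_frame: int,
    end_frame: int,
    turn_z: float | None = None,
    margin: float = 8.0,
    lateral_noise_sd: float = 0.5,
) -> IonScript:
    """Against-field excursion: rise from the intracellular side through the
    G-loop and HBC gates into the cavity, then fall back out. Does not
    complete a crossing in either direction."""
    z_int, z_ext = spec.z_extents
    if turn_z is None:
        turn_z = _cavity_mid_z(spec)
    return IonScript(
        ion_index,
        [
            (start_frame, z_int - margin),
            (turn_frame, turn_z),
            (end_frame, z_int - margin),
        ],
        lateral_noise_sd=lateral_noise_sd,
        outcome="retrograde",
    )


def parked_script(
    ion_index: int,
    z: float,
    radial_offset: float = 0.0,
    lateral_noise_sd: float = 0.0,
) -> IonScript:
    return IonScript(
        ion_index,
        [(0, z)],
        lateral_noise_sd=lateral_noise_sd,
        radial_offset=radial_offset,
        outcome="parked",
    )


@dataclass
class ContactPlan:
    """Plant a pairwise contact formed in exactly round(f * n_frames) frames.

    ``pair`` is ((chainA, residA), (chainB, residB)); for hbond plans the
    first residue is the donor. The two interacting beads sit at
    ``formed_distance`` in formed frames and ``broken_distance`` otherwise;
    both must clear the analysis cutoff by >= 0.5 A on their own side.
    """

    pair: tuple[tuple[str, int], tuple[str, int]]
    contact_type: str  # salt_bridge | hbond | hydrophobic
    planted_fraction: float
    formed_distance: float = 3.0
    broken_distance: float = 9.0

    def __post_init__(self):
        if not 0.0 <= self.planted_fraction <= 1.0:
            raise ValueError("planted_fraction must be in [0, 1]")
        if self.contact_type not in ("salt_bridge", "hbond", "hydrophobic"):
            raise ValueError(f"unknown contact type {self.contact_type!r}")
        if self.formed_distance >= self.broken_distance:
            raise ValueError("formed_distance must be < broken_distance")


@dataclass
class CorrelationPlan:
    """Plant a displacement correlation between two residues' CA beads.

    Both CAs get x-displacements x_i(t) = a*s(t) + e_i(t) with the shared
    latent series s and per-residue noise, with a and the noise variance
    solving rho = a^2 / (a^2 + sigma^2); the second residue's loading is
    negated for negative rho.
    """

    pair: tuple[tuple[str, int], tuple[str, int]]
    target_rho: float
    amplitude: float = 0.5

    def __post_init__(self):
        if not -1.0 < self.target_rho < 1.0:
            raise ValueError("target_rho must be in (-1, 1)")


@dataclass
class TorsionPlan:
    """Plant backbone phi/psi for one interior residue (degrees)."""

    residue: tuple[str, int]
    planted_phi: float
    planted_psi: float
    jitter_sd: float = 0.0

    def __post_init__(self):
        for v in (self.planted_phi, self.planted_psi):
            if not -180.0 < v <= 180.0:
                raise ValueError("planted dihedrals must be in (-180, 180]")


# --------------------------------------------------------------------------
# topology construction
# --------------------------------------------------------------------------

# role -> (resname, side-chain beads as (name, element))
_ROLE_BEADS = {
    "plain": ("GLY", []),
    "gate": ("PHE", [("CZ", "C")]),
    "salt_pos": ("LYS", [("NZ", "N")]),
    "salt_neg": ("GLU", [("OE1", "O")]),
    "hb_donor": ("SER", [("OG", "O"), ("HG", "H")]),
    "hb_acceptor": ("ASN", [("OD1", "O")]),
    "hydrophobic": ("LEU", [("CD1", "C")]),
}


def _residue_z_positions(spec: ChannelSpec) -> np.ndarray:
    """Per-residue anchor z, resid 1 extracellular -> resid R intracellular."""
    r = spec.residues_per_subunit
    z_int, z_ext = spec.z_extents
    z = np.linspace(z_ext, z_int, r)
    (sf_lo, sf_hi), (sf_zlo, sf_zhi) = spec.sf_layout
    sf_ids = np.arange(sf_lo, sf_hi + 1)
    z[sf_ids - 1] = np.linspace(sf_zhi, sf_zlo, len(sf_ids))
    for resid, gz in spec.gate_layout.values():
        z[resid - 1] = gz
    return z


def _assign_roles(
    spec: ChannelSpec,
    contacts: Sequence[ContactPlan],
    torsions: Sequence[TorsionPlan],
) -> dict[tuple[str, int], str]:
    roles: dict[tuple[str, int], str] = {}
    gate_resids = {r for r, _ in spec.gate_layout.values()}
    for chain in _CHAINS:
        for r in gate_resids:
            roles[(chain, r)] = "gate"

    def claim(key: tuple[str, int], role: str):
        if key[0] not in _CHAINS or not 1 <= key[1] <= spec.residues_per_subunit:
            raise ValueError(f"plan references unknown residue {key}")
        prev = roles.get(key)
        if prev is not None and prev != role:
            raise ValueError(f"residue {key} claimed by conflicting roles {prev}/{role}")
        roles[key] = role

    pair_roles = {
        "salt_bridge": ("salt_pos", "salt_neg"),
        "hbond": ("hb_donor", "hb_acceptor"),
        "hydrophobic": ("hydrophobic", "hydrophobic"),
    }
    seen: set[tuple] = set()
    for plan in contacts:
        key = (tuple(sorted(plan.pair)), plan.contact_type)
        if key in seen:
            raise ValueError(f"duplicate contact plan for {plan.pair}")
        seen.add(key)
        ra, rb = pair_roles[plan.contact_type]
        claim(plan.pair[0], ra)
        claim(plan.pair[1], rb)
    planned = set()
    for plan in torsions:
        chain, resid = plan.residue
        if not 1 < resid < spec.residues_per_subunit:
            raise ValueError(f"torsion plan residue {plan.residue} must be interior")
        for r in (resid - 1, resid, resid + 1):
            if (chain, r) in planned:
                raise ValueError("torsion plans must not be adjacent")
        planned.add((chain, resid))
        if roles.get((chain, resid)) not in (None, "plain"):
            raise ValueError(f"torsion plan conflicts with role at {plan.residue}")
    return roles


class _Layout:
    """Atom bookkeeping: index lookup tables built alongside the topology."""

    def __init__(self):
        self.names: list[str] = []
        self.elements: list[str] = []
        self.resids: list[int] = []
        self.resnames: list[str] = []
        self.chains: list[str] = []
        self.coords: list[tuple[float, float, float]] = []
        self.index: dict[tuple[str, int, str], int] = {}  # (chain, resid, name)

    def add(self, chain, resid, resname, name, element, xyz):
        self.index[(chain, resid, name)] = len(self.names)
        self.names.append(name)
        self.elements.append(element)
        self.resids.append(resid)
        self.resnames.append(resname)
        self.chains.append(chain)
        self.coords.append(tuple(float(v) for v in xyz))


def _build_layout(
    spec: ChannelSpec, roles: dict[tuple[str, int], str]
) -> tuple[_Layout, np.ndarray]:
    lay = _Layout()
    zpos = _residue_z_positions(spec)
    gate_by_resid = {r: (name, gz) for name, (r, gz) in spec.gate_layout.items()}
    for k, chain in enumerate(_CHAINS):
        theta = math.pi / 2.0 * k
        radial = np.array([math.cos(theta), math.sin(theta), 0.0])
        tangent = np.array([-math.sin(theta), math.cos(theta), 0.0])
        zhat = np.array([0.0, 0.0, 1.0])
        for resid in range(1, spec.residues_per_subunit + 1):
            role = roles.get((chain, resid), "plain")
            resname, beads = _ROLE_BEADS[role]
            anchor = radial * spec.pore_radius + zhat * zpos[resid - 1]
            lay.add(chain, resid, resname, "N", "N", anchor - 1.3 * tangent + 0.6 * zhat)
            lay.add(chain, resid, resname, "CA", "C", anchor)
            cpos = anchor + 1.3 * tangent - 0.6 * zhat
            lay.add(chain, resid, resname, "C", "C", cpos)
            lay.add(chain, resid, resname, "O", "O", cpos + 1.2 * radial)
            for bead_name, bead_el in beads:
                if role == "gate":
                    _, gz = gate_by_resid[resid]
                    pos = radial * 4.0 + zhat * gz  # radius overwritten per frame
                else:
                    pos = anchor - 2.0 * radial
                    if bead_name == "HG":
                        pos = pos - 1.0 * radial  # placeholder; re-aimed by plans
                lay.add(chain, resid, resname, bead_name, bead_el, pos)
    z_int, z_ext = spec.z_extents
    for i in range(spec.n_ions):
        ang = 2 * math.pi * i / max(spec.n_ions, 1)
        lay.add(
            "I",
            i + 1,
            "K",
            "K",
            "K",
            (2.0 * math.cos(ang), 2.0 * math.sin(ang), z_ext + 8.0 + 3.0 * i),
        )
    for i in range(spec.n_ligands):
        ang = 2 * math.pi * i / max(spec.n_ligands, 1)
        rad = spec.pore_radius + 6.0
        lay.add(
            "X",
            i + 1,
            "CHS",
            "C1",
            "C",
            (rad * math.cos(ang), rad * math.sin(ang), 0.0),
        )
    return lay, zpos


def _layout_topology(lay: _Layout) -> Topology:
    return Topology(lay.names, lay.resids, lay.resnames, lay.chains, elements=lay.elements)


def generate_topology(spec: ChannelSpec) -> Topology:
    """Topology of the bare channel (no plans): 4 chains A-D with C4 symmetry,
    gate residues carrying a single side-chain bead, plus ions and ligands."""
    roles = _assign_roles(spec, (), ())
    lay, _ = _build_layout(spec, roles)
    return _layout_topology(lay)


# --------------------------------------------------------------------------
# trajectory construction
# --------------------------------------------------------------------------

def _dihedral_deg(p0, p1, p2, p3) -> float:
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 /= np.linalg.norm(b1)
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    x = v @ w
    y = np.cross(b1, v) @ w
    return math.degrees(math.atan2(y, x))


def _nerf_batch(a, b, c, bond: float, angle_deg: float, dihedral_deg: np.ndarray):
    """Place atom d for each frame given frames' a, b, c positions.

    a, b, c: (n, 3) arrays; dihedral_deg: (n,). Returns (n, 3). The dihedral
    a-b-c-d of the result equals ``dihedral_deg`` under the standard signed
    convention (verified round-trip in the test suite).
    """
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    c = np.atleast_2d(c)
    ang = math.radians(angle_deg)
    dih = np.radians(np.atleast_1d(dihedral_deg))
    bc = c - b
    bc /= np.linalg.norm(bc, axis=1, keepdims=True)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    m = np.cross(n, bc)
    d_local = np.stack(
        [
            -bond * math.cos(ang) * np.ones_like(dih),
            bond * math.sin(ang) * np.cos(dih),
            bond * math.sin(ang) * np.sin(dih),
        ],
        axis=1,
    )
    return c + d_local[:, 0:1] * bc + d_local[:, 1:2] * m + d_local[:, 2:3] * n


def generate_trajectory(
    spec: ChannelSpec,
    schedules: Sequence[GateSchedule] = (),
    ions: Sequence[IonScript] = (),
    contacts: Sequence[ContactPlan] = (),
    correlations: Sequence[CorrelationPlan] = (),
    torsions: Sequence[TorsionPlan] = (),
    n_frames: int = 100,
    seed: int | None = None,
) -> tuple[Trajectory, dict]:
    """Realize all plans into a trajectory plus a ground-truth manifest.

    Guarantees: gate diagonal minimum distances track their schedules
    exactly; each contact plan is formed in exactly
    round(planted_fraction * n_frames) frames (frames chosen by seeded
    sampling without replacement); correlation plans have the stated
    analytic rho; torsion plans reproduce their dihedrals exactly at zero
    jitter. Identical (spec, plans, seed) give byte-identical output.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    seed = spec.seed if seed is None else seed
    roles = _assign_roles(spec, contacts, torsions)
    lay, _ = _build_layout(spec, roles)
    topo = _layout_topology(lay)
    base = np.asarray(lay.coords, dtype=np.float64)
    coords = np.repeat(base[None, :, :], n_frames, axis=0)

    manifest: dict = {
        "n_frames": n_frames,
        "seed": seed,
        "spec": {
            "residues_per_subunit": spec.residues_per_subunit,
            "pore_radius": spec.pore_radius,
            "z_extents": list(spec.z_extents),
            "gate_layout": {k: list(v) for k, v in spec.gate_layout.items()},
            "sf_layout": [list(spec.sf_layout[0]), list(spec.sf_layout[1])],
            "n_ions": spec.n_ions,
            "n_ligands": spec.n_ligands,
        },
        "gate_schedules": {},
        "event_counts": {"ext_to_int": 0, "int_to_ext": 0},
        "ion_scripts": [],
        "contacts": [],
        "correlations": [],
        "torsions": [],
    }

    # --- gates ------------------------------------------------------------
    scheduled = set()
    for sched in schedules:
        if sched.gate_name not in spec.gate_layout:
            raise ValueError(f"schedule names unknown gate {sched.gate_name!r}")
        if sched.gate_name in scheduled:
            raise ValueError(f"duplicate schedule for gate {sched.gate_name!r}")
        scheduled.add(sched.gate_name)
        resid, gz = spec.gate_layout[sched.gate_name]
        d = sched.distances(n_frames)
        for k, chain in enumerate(_CHAINS):
            theta = math.pi / 2.0 * k
            bead = lay.index[(chain, resid, "CZ")]
            coords[:, bead, 0] = d / 2.0 * math.cos(theta)
            coords[:, bead, 1] = d / 2.0 * math.sin(theta)
            coords[:, bead, 2] = gz
        manifest["gate_schedules"][sched.gate_name] = d.tolist()

    # --- ions -------------------------------------------------------------
    rng_ions = np.random.default_rng([seed, _STREAM_IONS])
    seen_ion_idx = set()
    for script in ions:
        if not 0 <= script.ion_index < spec.n_ions:
            raise ValueError(f"ion script index {script.ion_index} out of range")
        if script.ion_index in seen_ion_idx:
            raise ValueError(f"multiple scripts for ion {script.ion_index}")
        seen_ion_idx.add(script.ion_index)
        atom = lay.index[("I", script.ion_index + 1, "K")]
        z = script.z_series(n_frames)
        noise = rng_ions.normal(0.0, script.lateral_noise_sd or 0.0, size=(n_frames, 2))
        x = script.radial_offset + noise[:, 0]
        y = noise[:, 1]
        rmax = max(abs(script.radial_offset), 0.8 * spec.pore_radius)
        r = np.hypot(x, y)
        over = r > rmax
        if np.any(over):
            scale = rmax / r[over]
            x[over] *= scale
            y[over] *= scale
        coords[:, atom, 0] = x
        coords[:, atom, 1] = y
        coords[:, atom, 2] = z
        if script.outcome == "complete":
            manifest["event_counts"][script.direction] += 1
        manifest["ion_scripts"].append(
            {
                "ion_index": script.ion_index,
                "atom_index": atom,
                "waypoints": [list(w) for w in script.waypoints],
                "outcome": script.outcome,
                "direction": script.direction,
            }
        )

    # --- contacts ---------------------------------------------------------
    rng_contacts = np.random.default_rng([seed, _STREAM_CONTACTS])
    bead_of = {
        "salt_pos": "NZ",
        "salt_neg": "OE1",
        "hb_donor": "OG",
        "hb_acceptor": "OD1",
        "hydrophobic": "CD1",
    }
    for plan in contacts:
        (ca, ra), (cb, rb) = plan.pair
        role_a = roles[(ca, ra)]
        role_b = roles[(cb, rb)]
        ia = lay.index[(ca, ra, bead_of[role_a])]
        ib = lay.index[(cb, rb, bead_of[role_b])]
        pa = base[ia]
        u = base[ib] - pa
        norm = np.linalg.norm(u)
        if norm < 1e-9:
            u = np.array([1.0, 0.0, 0.0])
        else:
            u = u / norm
        n_formed = int(round(plan.planted_fraction * n_frames))
        formed = np.sort(rng_contacts.choice(n_frames, size=n_formed, replace=False))
        dist = np.full(n_frames, plan.broken_distance)
        dist[formed] = plan.formed_distance
        coords[:, ib, :] = pa[None, :] + dist[:, None] * u[None, :]
        if plan.contact_type == "hbond":
            ih = lay.index[(ca, ra, "HG")]
            coords[:, ih, :] = pa[None, :] + 1.0 * u[None, :]
        manifest["contacts"].append(
            {
                "pair": [[ca, ra], [cb, rb]],
                "contact_type": plan.contact_type,
                "planted_fraction": plan.planted_fraction,
                "n_formed": n_formed,
                "formed_frames": formed.tolist(),
            }
        )

    # --- correlations -----------------------------------------------------
    rng_corr = np.random.default_rng([seed, _STREAM_CORR])
    for plan in correlations:
        (ca, ra), (cb, rb) = plan.pair
        ia = lay.index[(ca, ra, "CA")]
        ib = lay.index[(cb, rb, "CA")]
        rho = plan.target_rho
        a = plan.amplitude * math.sqrt(abs(rho))
        sd = plan.amplitude * math.sqrt(1.0 - abs(rho))
        s = rng_corr.standard_normal(n_frames)
        xa = a * s + sd * rng_corr.standard_normal(n_frames)
        xb = math.copysign(1.0, rho) * a * s + sd * rng_corr.standard_normal(n_frames)
        if rho == 0.0:
            xa = sd * rng_corr.standard_normal(n_frames)
            xb = sd * rng_corr.standard_normal(n_frames)
        coords[:, ia, 0] += xa
        coords[:, ib, 0] += xb
        manifest["correlations"].append(
            {"pair": [[ca, ra], [cb, rb]], "target_rho": rho}
        )

    # --- torsions ---------------------------------------------------------
    rng_tor = np.random.default_rng([seed, _STREAM_TORSION])
    for plan in torsions:
        chain, resid = plan.residue
        i_cprev = lay.index[(chain, resid - 1, "C")]
        i_n = lay.index[(chain, resid, "N")]
        i_ca = lay.index[(chain, resid, "CA")]
        i_c = lay.index[(chain, resid, "C")]
        i_o = lay.index[(chain, resid, "O")]
        i_nnext = lay.index[(chain, resid + 1, "N")]
        phi = plan.planted_phi + plan.jitter_sd * rng_tor.standard_normal(n_frames)
        psi = plan.planted_psi + plan.jitter_sd * rng_tor.standard_normal(n_frames)
        a = coords[:, i_cprev, :]
        b = coords[:, i_n, :]
        c = coords[:, i_ca, :]
        new_c = _nerf_batch(a, b, c, 1.52, 111.0, phi)
        coords[:, i_o, :] += new_c - coords[:, i_c, :]  # O rides along with C
        coords[:, i_c, :] = new_c
        coords[:, i_nnext, :] = _nerf_batch(b, c, new_c, 1.33, 116.5, psi)
        manifest["torsions"].append(
            {
                "residue": [chain, resid],
                "planted_phi": plan.planted_phi,
                "planted_psi": plan.planted_psi,
                "jitter_sd": plan.jitter_sd,
            }
        )

    return Trajectory(topo, coords), manifest
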