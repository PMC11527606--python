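"""Per-frame gate aperture distances, open/closed classification, histograms.

The frame's gate distance is, by default, the mean over the two diagonal
subunit pairs (A-C and B-D) of the per-pair minimum inter-atomic distance
between the gate residues' atoms; the pairing rule is configurable
(``diagonal`` | ``adjacent`` | ``global_min``). Open/closed uses a strict
``distance > cutoff`` comparison, so ties count as closed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .traj_io import BACKBONE_NAMES, FrameWindow, Topology, Trajectory, write_tsv

__all__ = ["GateDefinition", "GateTrace", "GateStats", "gate_distance_trace", "open_fraction"]

DEFAULT_OPEN_CUTOFF = 5.69  # Angstrom


@dataclass(frozen=True)
class GateDefinition:
    """One gate: a residue number on each of the four subunits.

    ``atom_scope``: sidechain_heavy (default; falls back to CA for residues
    without side-chain atoms) | all_heavy | CA.
    """

    name: str
    residue_number: int
    atom_scope: str = "sidechain_heavy"
    chains: tuple[str, ...] = ("A", "B", "C", "D")

    def __post_init__(self):
        if len(self.chains) != 4:
            raise ValueError("a gate needs exactly 4 subunits")
        if self.atom_scope not in ("sidechain_heavy", "all_heavy", "CA"):
            raise ValueError(f"unknown atom_scope {self.atom_scope!r}")

    def resolve(self, topology: Topology) -> dict[str, np.ndarray]:
        """Per-subunit atom indices in scope; raises naming an empty subunit."""
        out: dict[str, np.ndarray] = {}
        heavy = topology.heavy_mask()
        for chain in self.chains:
            in_res = (topology.chains == chain) & (topology.resids == self.residue_number)
            if self.atom_scope == "CA":
                mask = in_res & (topology.names == "CA")
            elif self.atom_scope == "all_heavy":
                mask = in_res & heavy
            else:
                side = ~np.isin(topology.names, sorted(BACKBONE_NAMES))
                mask = in_res & heavy & side
                if not mask.any():
                    mask = in_res & (topology.names == "CA")
            idx = np.nonzero(mask)[0]
            if len(idx) == 0:
                raise ValueError(
                    f"gate {self.name!r}: no atoms for residue "
                    f"{self.residue_number} on subunit {chain!r}"
                )
            out[chain] = idx
        return out


@dataclass
class GateTrace:
    gate: GateDefinition
    distances: np.ndarray  # Angstrom, one per selected frame
    window: FrameWindow
    frame_indices: np.ndarray = field(default=None)

    def __post_init__(self):
        self.distances = np.asarray(self.distances, dtype=np.float64)
        if np.any(self.distances < 0):
            raise ValueError("gate distances must be >= 0")


@dataclass
class GateStats:
    gate_name: str
    open_fraction: float
    cutoff: float
    histogram: tuple[np.ndarray, np.ndarray]  # (bin edges, counts)
    mean_distance: float
    min_distance: float
    max_distance: float

    def to_dict(self) -> dict:
        edges, counts = self.histogram
        return {
            "gate": self.gate_name,
            "open_fraction": self.open_fraction,
            "cutoff": self.cutoff,
            "mean_distance": self.mean_distance,
            "min_distance": self.min_distance,
            "max_distance": self.max_distance,
            "histogram_edges": edges.tolist(),
            "histogram_counts": counts.tolist(),
        }


def _pair_min(coords_frame: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray) -> float:
    diff = coords_frame[idx_a][:, None, :] - coords_frame[idx_b][None, :, :]
    return float(np.sqrt((diff**2).sum(axis=2)).min())


def gate_distance_trace(
    traj: Trajectory,
    gate: GateDefinition,
    window: FrameWindow | None = None,
    pairing: str = "diagonal",
) -> GateTrace:
    """Aperture distance per frame for one gate.

    ``diagonal``: mean of the A-C and B-D pair minima (default).
    ``adjacent``: mean of the four adjacent pair minima.
    ``global_min``: minimum over all six subunit pairs.
    """
    if window is None:
        window = FrameWindow.full(traj)
    window.validate(traj.n_frames)
    groups = gate.resolve(traj.topology)
    chains = list(gate.chains)
    if pairing == "diagonal":
        pairs = [(0, 2), (1, 3)]
        reduce = np.mean
    elif pairing == "adjacent":
        pairs = [(0, 1), (1, 2), (2, 3), (3, 0)]
        reduce = np.mean
    elif pairing == "global_min":
        pairs = [(a, b) for a in range(4) for b in range(a + 1, 4)]
        reduce = np.min
    else:
        raise ValueError(f"unknown pairing {pairing!r}")
    frames = window.indices()
    dists = np.empty(len(frames))
    for out_i, f in enumerate(frames):
        frame = traj.coordinates[f]
        vals = [_pair_min(frame, groups[chains[a]], groups[chains[b]]) for a, b in pairs]
        dists[out_i] = reduce(vals)
    return GateTrace(gate, dists, window, frame_indices=frames)


def open_fraction(
    trace: GateTrace,
    cutoff: float = DEFAULT_OPEN_CUTOFF,
    bin_width: float = 0.25,
    bins: np.ndarray | None = None,
) -> GateStats:
    """Fraction of frames with distance strictly greater than the cutoff,
    plus a histogram of the aperture distribution."""
    d = trace.distances
    if len(d) == 0:
        raise ValueError("empty gate trace")
    if bins is None:
        lo = np.floor(d.min() / bin_width) * bin_width
        hi = np.ceil(d.max() / bin_width) * bin_width
        if hi <= lo:
            hi = lo + bin_width
        bins = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(d, bins=bins)
    return GateStats(
        gate_name=trace.gate.name,
        open_fraction=float(np.count_nonzero(d > cutoff)) / len(d),
        cutoff=cutoff,
        histogram=(edges, counts),
        mean_distance=float(d.mean()),
        min_distance=float(d.min()),
        max_distance=float(d.max()),
    )


def write_gate_trace_tsv(path: str, trace: GateTrace, times=None, cutoff: float = DEFAULT_OPEN_CUTOFF) -> int:
    frames = trace.frame_indices
    if times is None:
        times = frames.astype(float)
    rows = (
        (int(f), float(t), trace.gate.name, float(d), int(d > cutoff))
        for f, t, d in zip(frames, times, trace.distances)
    )
    return write_tsv(path, ["frame", "time_ns", "gate_name", "distance_A", "is_open"], rows)
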