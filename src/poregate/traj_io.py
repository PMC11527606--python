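"""Topology/trajectory I/O, atom selections and tabular output.

Internal conventions: coordinates in Angstrom, the pore axis is z with the
extracellular side at larger z, atom and frame indices are 0-based, residue
numbers are kept as authored in the source file (1-based in practice).
Residue identity is the triple (chain_id, residue_number, insertion_code).
"""
from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Topology",
    "Trajectory",
    "Selection",
    "FrameWindow",
    "SelectionError",
    "read_topology",
    "read_trajectory",
    "select",
    "write_pdb",
    "write_tsv",
    "write_json",
    "principal_axis_align",
    "DEFAULT_ION_RESNAMES",
    "DEFAULT_LIGAND_RESNAMES",
    "BACKBONE_NAMES",
]

DEFAULT_ION_RESNAMES = frozenset(
    {"K", "K+", "POT", "NA", "NA+", "SOD", "CL", "CL-", "CLA", "MG", "ZN"}
)
DEFAULT_LIGAND_RESNAMES = frozenset({"PIP", "PIP2", "PI2", "CHS", "CHL", "CLR", "Y01"})
BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})


def _guess_element(name: str, resname: str, ion_resnames: frozenset) -> str:
    """Element from the atom name, PDB-style (digits stripped, first letter)."""
    if resname.upper() in ion_resnames:
        return name.strip("0123456789+-").capitalize() or "X"
    stripped = name.strip("0123456789")
    if not stripped:
        return "X"
    if stripped[0] == "H" or (name[0].isdigit() and "H" in stripped):
        return "H"
    return stripped[0].upper()


class Topology:
    """Static atom metadata for one system, stored as parallel numpy arrays."""

    def __init__(
        self,
        names: Sequence[str],
        resids: Sequence[int],
        resnames: Sequence[str],
        chains: Sequence[str],
        elements: Sequence[str] | None = None,
        icodes: Sequence[str] | None = None,
        is_ion: Sequence[bool] | None = None,
        is_ligand: Sequence[bool] | None = None,
        ion_resnames: frozenset = DEFAULT_ION_RESNAMES,
        ligand_resnames: frozenset = DEFAULT_LIGAND_RESNAMES,
    ):
        self.names = np.asarray(names, dtype="U6")
        self.resids = np.asarray(resids, dtype=np.int64)
        self.resnames = np.asarray(resnames, dtype="U6")
        self.chains = np.asarray(chains, dtype="U2")
        n = len(self.names)
        if not (len(self.resids) == len(self.resnames) == len(self.chains) == n):
            raise ValueError("topology array length mismatch")
        if icodes is None:
            icodes = [""] * n
        self.icodes = np.asarray(icodes, dtype="U2")
        if elements is None:
            elements = [
                _guess_element(nm, rn, ion_resnames)
                for nm, rn in zip(self.names, self.resnames)
            ]
        self.elements = np.asarray(elements, dtype="U2")
        upper = np.char.upper(self.resnames)
        if is_ion is None:
            is_ion = np.isin(upper, sorted(ion_resnames))
        if is_ligand is None:
            is_ligand = np.isin(upper, sorted(ligand_resnames)) & ~np.asarray(is_ion)
        self.is_ion = np.asarray(is_ion, dtype=bool)
        self.is_ligand = np.asarray(is_ligand, dtype=bool)

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def atoms(self) -> list[tuple]:
        """(index, name, element, resid, resname, chain, is_ion, is_ligand) rows."""
        return [
            (
                i,
                self.names[i],
                self.elements[i],
                int(self.resids[i]),
                self.resnames[i],
                self.chains[i],
                bool(self.is_ion[i]),
                bool(self.is_ligand[i]),
            )
            for i in range(self.n_atoms)
        ]

    def residue_key(self, i: int) -> tuple[str, int, str]:
        return (str(self.chains[i]), int(self.resids[i]), str(self.icodes[i]))

    def iter_residues(self) -> Iterator[tuple[tuple[str, int, str], np.ndarray]]:
        """Yield ((chain, resid, icode), atom_indices) in file order."""
        keys = {}
        for i in range(self.n_atoms):
            keys.setdefault(self.residue_key(i), []).append(i)
        for key, idx in keys.items():
            yield key, np.asarray(idx, dtype=np.int64)

    def heavy_mask(self) -> np.ndarray:
        return self.elements != "H"


@dataclass
class Trajectory:
    """Per-frame coordinates (Angstrom) bound to a Topology."""

    topology: Topology
    coordinates: np.ndarray  # (n_frames, n_atoms, 3)
    frame_times: np.ndarray | None = None  # ns

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"coordinate atom count {self.coordinates.shape[1]} != "
                f"topology atom count {self.topology.n_atoms}"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates contain non-finite values")
        if self.frame_times is None:
            self.frame_times = np.arange(self.n_frames, dtype=np.float64)
        else:
            self.frame_times = np.asarray(self.frame_times, dtype=np.float64)

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]


@dataclass(frozen=True)
class FrameWindow:
    """Half-open frame interval [start, end) sampled every `stride` frames."""

    start: int
    end: int
    stride: int = 1

    def __post_init__(self):
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"invalid window [{self.start}, {self.end})")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")

    def validate(self, n_frames: int) -> "FrameWindow":
        if self.end > n_frames:
            raise ValueError(f"window end {self.end} exceeds n_frames {n_frames}")
        return self

    def indices(self) -> np.ndarray:
        return np.arange(self.start, self.end, self.stride, dtype=np.int64)

    @property
    def n_selected(self) -> int:
        return len(range(self.start, self.end, self.stride))

    @classmethod
    def full(cls, traj: Trajectory, stride: int = 1) -> "FrameWindow":
        return cls(0, traj.n_frames, stride)


@dataclass(frozen=True)
class Selection:
    """Resolved atom selection; indices are ordered and unique."""

    expression: str
    atom_indices: np.ndarray
    granularity: str = "atom"  # atom | residue

    def __len__(self) -> int:
        return len(self.atom_indices)

    @property
    def empty(self) -> bool:
        return len(self.atom_indices) == 0


# --------------------------------------------------------------------------
# PDB parsing / writing
# --------------------------------------------------------------------------

def _parse_pdb_atom_line(line: str):
    serial = line[6:11].strip()
    name = line[12:16].strip()
    resname = line[17:21].strip()
    chain = line[21].strip() or "A"
    resid = int(line[22:26])
    icode = line[26].strip()
    x = float(line[30:38])
    y = float(line[38:46])
    z = float(line[46:54])
    element = line[76:78].strip() if len(line) >= 78 else ""
    return serial, name, resname, chain, resid, icode, (x, y, z), element


def read_topology(
    path: str,
    format: str = "pdb",
    ion_resnames: Iterable[str] = DEFAULT_ION_RESNAMES,
    ligand_resnames: Iterable[str] = DEFAULT_LIGAND_RESNAMES,
) -> Topology:
    """Read a PDB file's first model into a Topology.

    Ions and ligands are flagged by configurable residue-name lists.
    Raises on a missing file, zero ATOM/HETATM records, or duplicate atom
    serial numbers (the error names the offending line).
    """
    if format.lower() != "pdb":
        raise ValueError(f"unsupported topology format: {format}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    names, resids, resnames, chains, icodes, elements = [], [], [], [], [], []
    seen_serials: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "ENDMDL":
                break
            if rec not in ("ATOM  ", "HETATM"):
                continue
            serial, name, resname, chain, resid, icode, _, element = (
                _parse_pdb_atom_line(line)
            )
            if serial and serial in seen_serials:
                raise ValueError(
                    f"duplicate atom serial {serial} at line {lineno} of {path}"
                )
            seen_serials.add(serial)
            names.append(name)
            resids.append(resid)
            resnames.append(resname)
            chains.append(chain)
            icodes.append(icode)
            elements.append(element)
    if not names:
        raise ValueError(f"no atoms found in {path}")
    ion_set = frozenset(r.upper() for r in ion_resnames)
    lig_set = frozenset(r.upper() for r in ligand_resnames)
    elements = [
        e if e else _guess_element(n, r, ion_set)
        for e, n, r in zip(elements, names, resnames)
    ]
    return Topology(
        names,
        resids,
        resnames,
        chains,
        elements=elements,
        icodes=icodes,
        ion_resnames=ion_set,
        ligand_resnames=lig_set,
    )


def _read_pdb_frames(path: str, n_atoms: int) -> np.ndarray:
    frames: list[list[tuple]] = []
    current: list[tuple] = []
    saw_model = False
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec == "MODEL ":
                saw_model = True
                current = []
            elif rec in ("ATOM  ", "HETATM"):
                *_, xyz, _ = _parse_pdb_atom_line(line)
                current.append(xyz)
            elif rec == "ENDMDL":
                frames.append(current)
                current = []
    if not saw_model:
        frames = [current] if current else []
    elif current:
        frames.append(current)
    if not frames:
        raise ValueError(f"no coordinate frames found in {path}")
    for i, fr in enumerate(frames):
        if len(fr) != n_atoms:
            raise ValueError(
                f"frame {i} of {path} has {len(fr)} atoms, topology has {n_atoms}"
            )
    return np.asarray(frames, dtype=np.float64)


def read_trajectory(
    topology: Topology, path: str, format: str | None = None
) -> Trajectory:
    """Read a DCD, XTC, or multi-model PDB trajectory (coordinates in Angstrom).

    XTC coordinates (stored in nm) are converted to Angstrom. An atom-count
    mismatch raises an error stating both counts; a truncated binary file
    raises an error reporting the last complete frame index.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format is None:
        format = os.path.splitext(path)[1].lstrip(".").lower() or "pdb"
    format = format.lower()
    if format == "pdb":
        coords = _read_pdb_frames(path, topology.n_atoms)
        return Trajectory(topology, coords)
    if format in ("dcd", "xtc"):
        if format == "dcd":
            from MDAnalysis.coordinates.DCD import DCDReader as Reader
        else:
            from MDAnalysis.coordinates.XTC import XTCReader as Reader
        try:
            reader = Reader(path)
        except Exception as exc:  # corrupt header
            raise ValueError(f"cannot read {format} file {path}: {exc}") from exc
        if reader.n_atoms != topology.n_atoms:
            reader.close()
            raise ValueError(
                f"trajectory {path} has {reader.n_atoms} atoms, "
                f"topology has {topology.n_atoms}"
            )
        frames = []
        declared = reader.n_frames
        if format == "dcd":
            # NSET from the raw DCD header; MDAnalysis silently sizes the
            # reader by file length, hiding truncated final frames.
            with open(path, "rb") as fh:
                head = fh.read(12)
            if len(head) == 12 and head[4:8] == b"CORD":
                nset = int.from_bytes(head[8:12], "little", signed=True)
                if nset > 0:
                    declared = max(declared, nset)
        try:
            for ts in reader:
                # MDAnalysis returns Angstrom for both formats.
                frames.append(np.array(ts.positions, dtype=np.float64))
        except (EOFError, OSError, ValueError) as exc:
            raise ValueError(
                f"truncated trajectory {path}: last complete frame index "
                f"{len(frames) - 1} ({exc})"
            ) from exc
        finally:
            reader.close()
        if not frames:
            raise ValueError(f"no frames in {path}")
        if len(frames) < declared:
            raise ValueError(
                f"truncated trajectory {path}: header declares {declared} "
                f"frames, last complete frame index {len(frames) - 1}"
            )
        return Trajectory(topology, np.asarray(frames))
    raise ValueError(f"unsupported trajectory format: {format}")


def _format_pdb_name(name: str) -> str:
    # PDB atom names of <4 chars start in column 14
    return f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"


def write_pdb(topology: Topology, coordinates: np.ndarray, path: str) -> None:
    """Write coordinates as single- or multi-model PDB (%.3f precision)."""
    coords = np.asarray(coordinates, dtype=np.float64)
    if coords.ndim == 2:
        coords = coords[None]
    if coords.shape[1] != topology.n_atoms:
        raise ValueError("coordinate/topology atom count mismatch")
    multi = coords.shape[0] > 1
    with open(path, "w") as fh:
        for m in range(coords.shape[0]):
            if multi:
                fh.write(f"MODEL     {m + 1:4d}\n")
            for i in range(topology.n_atoms):
                rec = (
                    "HETATM"
                    if topology.is_ion[i] or topology.is_ligand[i]
                    else "ATOM  "
                )
                x, y, z = coords[m, i]
                fh.write(
                    f"{rec}{(i % 99999) + 1:5d} {_format_pdb_name(topology.names[i])}"
                    f" {topology.resnames[i]:<3s} {topology.chains[i]:1s}"
                    f"{topology.resids[i]:4d}{topology.icodes[i]:1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                    f"{topology.elements[i]:>2s}\n"
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def write_trajectory_dcd(traj: Trajectory, path: str) -> None:
    from MDAnalysis.coordinates.DCD import DCDWriter

    with DCDWriter(path, n_atoms=traj.topology.n_atoms) as w:
        import MDAnalysis as mda

        u = mda.Universe.empty(traj.topology.n_atoms, trajectory=True)
        for frame in traj.coordinates:
            u.atoms.positions = frame.astype(np.float32)
            w.write(u.atoms)


# --------------------------------------------------------------------------
# Selection grammar
# --------------------------------------------------------------------------

class SelectionError(ValueError):
    """Raised for selection expressions that do not parse."""


_FIELDS = {"chain", "resid", "resname", "name"}
_KEYWORDS = {"and", "or", "not", "all", "none", "ion", "ligand", "protein", "backbone"}


def _tokenize(expr: str) -> list[tuple[str, int]]:
    tokens = []
    i = 0
    while i < len(expr):
        c = expr[i]
        if c.isspace():
            i += 1
            continue
        if c in "()":
            tokens.append((c, i))
            i += 1
            continue
        j = i
        while j < len(expr) and not expr[j].isspace() and expr[j] not in "()":
            j += 1
        tokens.append((expr[i:j], i))
        i = j
    return tokens


class _Parser:
    def __init__(self, expr: str, topology: Topology):
        self.expr = expr
        self.top = topology
        self.tokens = _tokenize(expr)
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else (None, len(self.expr))

    def next(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def fail(self, msg: str, col: int):
        raise SelectionError(f"{msg} at column {col + 1} in {self.expr!r}")

    def parse(self) -> np.ndarray:
        if not self.tokens:
            self.fail("empty selection expression", 0)
        mask = self.expr_rule()
        tok, col = self.peek()
        if tok is not None:
            self.fail(f"unexpected token {tok!r}", col)
        return mask

    def expr_rule(self) -> np.ndarray:
        mask = self.term_rule()
        while self.peek()[0] == "or":
            self.next()
            mask = mask | self.term_rule()
        return mask

    def term_rule(self) -> np.ndarray:
        mask = self.factor_rule()
        while self.peek()[0] == "and":
            self.next()
            mask = mask & self.factor_rule()
        return mask

    def factor_rule(self) -> np.ndarray:
        tok, col = self.peek()
        if tok is None:
            self.fail("unexpected end of expression", col)
        if tok == "not":
            self.next()
            return ~self.factor_rule()
        if tok == "(":
            self.next()
            mask = self.expr_rule()
            tok2, col2 = self.next()
            if tok2 != ")":
                self.fail("expected ')'", col2)
            return mask
        return self.primitive_rule()

    def _values(self, col: int) -> list[str]:
        vals = []
        while True:
            tok, _ = self.peek()
            if tok is None or tok in _KEYWORDS or tok in _FIELDS or tok in "()":
                break
            vals.append(self.next()[0])
        if not vals:
            self.fail("expected one or more values", col)
        return vals

    def primitive_rule(self) -> np.ndarray:
        tok, col = self.next()
        t = self.top
        n = t.n_atoms
        if tok == "all":
            return np.ones(n, dtype=bool)
        if tok == "none":
            return np.zeros(n, dtype=bool)
        if tok == "ion":
            return t.is_ion.copy()
        if tok == "ligand":
            return t.is_ligand.copy()
        if tok == "protein":
            return ~(t.is_ion | t.is_ligand)
        if tok == "backbone":
            return np.isin(t.names, sorted(BACKBONE_NAMES)) & ~(t.is_ion | t.is_ligand)
        if tok == "chain":
            vals = self._values(col)
            return np.isin(t.chains, vals)
        if tok == "resname":
            vals = [v.upper() for v in self._values(col)]
            return np.isin(np.char.upper(t.resnames), vals)
        if tok == "name":
            vals = [v.upper() for v in self._values(col)]
            return np.isin(np.char.upper(t.names), vals)
        if tok == "resid":
            vals = self._values(col)
            mask = np.zeros(n, dtype=bool)
            for v in vals:
                if ":" in v:
                    lo, _, hi = v.partition(":")
                    try:
                        lo_i, hi_i = int(lo), int(hi)
                    except ValueError:
                        self.fail(f"bad resid range {v!r}", col)
                    mask |= (t.resids >= lo_i) & (t.resids <= hi_i)
                else:
                    try:
                        mask |= t.resids == int(v)
                    except ValueError:
                        self.fail(f"bad resid {v!r}", col)
            return mask
        self.fail(f"unknown selection token {tok!r}", col)


def select(topology: Topology, expression: str, granularity: str = "atom") -> Selection:
    """Resolve a selection expression against a topology.

    Grammar: ``chain``, ``resid`` (values and lo:hi ranges), ``resname``,
    ``name``, the nullary keywords ``all``/``none``/``ion``/``ligand``/
    ``protein``/``backbone``, combined with ``and``/``or``/``not`` and
    parentheses. Deterministic, order-stable (ascending atom index). Empty
    results are allowed but emit a warning.
    """
    mask = _Parser(expression, topology).parse()
    idx = np.nonzero(mask)[0]
    if granularity == "residue" and len(idx):
        keys = {topology.residue_key(i) for i in idx}
        idx = np.asarray(
            [i for i in range(topology.n_atoms) if topology.residue_key(i) in keys],
            dtype=np.int64,
        )
    elif granularity not in ("atom", "residue"):
        raise ValueError(f"unknown granularity {granularity!r}")
    if len(idx) == 0:
        warnings.warn(f"selection {expression!r} matched no atoms", stacklevel=2)
    return Selection(expression, idx, granularity)


# --------------------------------------------------------------------------
# Alignment and tabular output
# --------------------------------------------------------------------------

def principal_axis_align(traj: Trajectory, selection: Selection) -> Trajectory:
    """Rotate each frame so the selection's principal axis lies along +z.

    The centroid of the selection is moved to the origin. The sign of the
    axis is fixed deterministically (axis z-component >= 0, then x >= 0);
    inputs whose extracellular side should point to +z must be checked by
    the caller. Alignment is always explicit, never applied silently.
    """
    idx = selection.atom_indices
    if len(idx) < 3:
        raise ValueError("need >= 3 atoms to define a principal axis")
    out = np.empty_like(traj.coordinates)
    for f in range(traj.n_frames):
        pts = traj.coordinates[f, idx]
        centroid = pts.mean(axis=0)
        centered = pts - centroid
        cov = centered.T @ centered / len(idx)
        eigvals, eigvecs = np.linalg.eigh(cov)
        axis = eigvecs[:, np.argmax(eigvals)]
        if axis[2] < 0 or (axis[2] == 0 and axis[0] < 0):
            axis = -axis
        z = np.array([0.0, 0.0, 1.0])
        v = np.cross(axis, z)
        s = np.linalg.norm(v)
        c = float(axis @ z)
        if s < 1e-12:
            rot = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
        else:
            vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
            rot = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
        out[f] = (traj.coordinates[f] - centroid) @ rot.T
    return Trajectory(traj.topology, out, traj.frame_times)


def format_value(v, float_fmt: str = "%.6g") -> str:
    if isinstance(v, float) or isinstance(v, np.floating):
        return float_fmt % v
    return str(v)


def write_tsv(path: str, header: Sequence[str], rows: Iterable[Sequence], float_fmt: str = "%.6g") -> int:
    """Write a UTF-8 TSV with header row and '.' decimal separator.

    Returns the number of data rows written.
    """
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(format_value(v, float_fmt) for v in row) + "\n")
            n += 1
    return n


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.integer):
            return int(o)
        if isinstance(o, np.floating):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json(path: str, obj) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, cls=_NumpyEncoder)
        fh.write("\n")
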