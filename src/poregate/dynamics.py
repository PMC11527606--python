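"""Superposition-based collective dynamics: RMSD/RMSF, combined PCA over two
concatenated ensembles, residue displacement cross-correlations (DCCM), and
circular-statistics backbone torsion summaries.

All angle averaging is circular (atan2 of mean sin/cos): arithmetic means of
dihedrals near +/-180 degrees are meaningless.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .traj_io import FrameWindow, Selection, Topology, Trajectory, write_pdb

__all__ = [
    "SuperpositionResult",
    "RMSFProfile",
    "CovarianceModel",
    "CorrelationMatrix",
    "TorsionSummary",
    "superpose",
    "rmsd_trace",
    "rmsf_profile",
    "combined_pca",
    "correlation_matrix",
    "correlation_difference",
    "torsion_summary",
    "dihedral_series",
    "circular_mean_deg",
    "circular_sd_deg",
]


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # applied after rotation
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def superpose(
    mobile: np.ndarray, reference: np.ndarray, selection: Selection | np.ndarray | None = None
) -> SuperpositionResult:
    """Least-squares rigid superposition (Kabsch) of one frame onto another.

    ``mobile`` and ``reference`` are (n_atoms, 3) frames; the fit uses the
    selected atoms (all atoms when selection is None) and the returned RMSD
    is over those atoms. Requires >= 3 non-collinear fit atoms.
    """
    idx = _sel_indices(selection, len(mobile))
    x = np.asarray(mobile, dtype=np.float64)[idx]
    y = np.asarray(reference, dtype=np.float64)[idx]
    if len(x) < 3:
        raise ValueError("superposition needs >= 3 atoms")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    # collinearity check: rank of the fit-atom cloud
    if np.linalg.matrix_rank(xc, tol=1e-8) < 2:
        raise ValueError("superposition atoms are collinear")
    h = xc.T @ yc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = y.mean(axis=0) - x.mean(axis=0) @ rot.T
    moved = x @ rot.T + trans
    rmsd = float(np.sqrt(((moved - y) ** 2).sum(axis=1).mean()))
    return SuperpositionResult(rot, trans, rmsd)


def _sel_indices(selection, n_atoms: int) -> np.ndarray:
    if selection is None:
        return np.arange(n_atoms)
    if isinstance(selection, Selection):
        return selection.atom_indices
    return np.asarray(selection, dtype=np.int64)


def rmsd_trace(
    traj: Trajectory,
    reference: np.ndarray,
    selection: Selection | None = None,
    window: FrameWindow | None = None,
    fit: bool = True,
) -> np.ndarray:
    """Per-frame RMSD (Angstrom) of the selection against a reference frame,
    after optimal superposition (or raw when fit=False)."""
    if window is None:
        window = FrameWindow.full(traj)
    window.validate(traj.n_frames)
    idx = _sel_indices(selection, traj.topology.n_atoms)
    out = np.empty(window.n_selected)
    for i, f in enumerate(window.indices()):
        if fit:
            out[i] = superpose(traj.coordinates[f], reference, idx).rmsd
        else:
            diff = traj.coordinates[f, idx] - np.asarray(reference)[idx]
            out[i] = float(np.sqrt((diff**2).sum(axis=1).mean()))
    return out


@dataclass
class RMSFProfile:
    residue_keys: list[tuple[str, int]]
    values: np.ndarray  # Angstrom


def _superposed_ensemble(
    coords: np.ndarray, fit_idx: np.ndarray, n_iter: int = 2, tol: float = 1e-4
) -> np.ndarray:
    """Superpose every frame onto the ensemble mean, iterating mean ->
    superpose -> mean for a self-consistent reference.

    Batched Kabsch: one 3x3 SVD per frame, vectorized across frames.
    """
    work = np.array(coords, dtype=np.float64)
    mean = work[0]
    for _ in range(n_iter):
        ref = mean[fit_idx]
        ref_centroid = ref.mean(axis=0)
        ref_c = ref - ref_centroid
        x = work[:, fit_idx]
        x_centroid = x.mean(axis=1, keepdims=True)
        h = np.einsum("tni,nj->tij", x - x_centroid, ref_c)
        u, _, vt = np.linalg.svd(h)
        d = np.sign(np.linalg.det(u) * np.linalg.det(vt))
        flip = np.repeat(np.eye(3)[None], len(work), axis=0)
        flip[:, 2, 2] = d
        rot = np.einsum("tji,tjk,tlk->til", vt, flip, u)  # vt.T @ flip @ u.T
        work = np.einsum("tai,tji->taj", work - x_centroid, rot) + ref_centroid
        new_mean = work.mean(axis=0)
        shift = float(np.abs(new_mean - mean).max())
        mean = new_mean
        if shift < tol:
            break
    return work


def rmsf_profile(
    traj: Trajectory,
    selection: Selection | None = None,
    window: FrameWindow | None = None,
    fit: bool = True,
) -> RMSFProfile:
    """Per-residue CA fluctuation around the window-mean structure.

    rmsf_i = sqrt(<|r_i - <r_i>|^2>) computed per selected atom, then
    reported per residue (mean over that residue's selected atoms).
    """
    if window is None:
        window = FrameWindow.full(traj)
    window.validate(traj.n_frames)
    idx = _sel_indices(selection, traj.topology.n_atoms)
    sub = traj.coordinates[window.indices()][:, idx]
    if fit:
        sub = _superposed_ensemble(sub, np.arange(len(idx)))
    mean = sub.mean(axis=0)
    per_atom = np.sqrt(((sub - mean) ** 2).sum(axis=2).mean(axis=0))
    topo = traj.topology
    by_res: dict[tuple[str, int], list[float]] = {}
    for local_i, atom_i in enumerate(idx):
        key = (str(topo.chains[atom_i]), int(topo.resids[atom_i]))
        by_res.setdefault(key, []).append(per_atom[local_i])
    keys = sorted(by_res)
    return RMSFProfile(keys, np.asarray([float(np.mean(by_res[k])) for k in keys]))


@dataclass
class CovarianceModel:
    atom_indices: np.ndarray
    mean_coordinates: np.ndarray  # (n_sel, 3)
    eigenvalues: np.ndarray  # descending, A^2
    eigenvectors: np.ndarray  # (3n, n_modes), columns orthonormal
    projections: dict[str, np.ndarray]  # system label -> (n_frames, n_modes)

    @property
    def total_variance(self) -> float:
        return float(self.eigenvalues.sum())

    def variance_share(self, mode: int) -> float:
        return float(self.eigenvalues[mode] / self.eigenvalues.sum())

    def mode_vector(self, mode: int) -> np.ndarray:
        return self.eigenvectors[:, mode]


def _matched_indices(
    topoA: Topology, selA: Selection, topoB: Topology, selB: Selection
) -> tuple[np.ndarray, np.ndarray]:
    def keys(topo, sel):
        return [
            (str(topo.chains[i]), int(topo.resids[i]), str(topo.resnames[i]), str(topo.names[i]))
            for i in sel.atom_indices
        ]

    ka, kb = keys(topoA, selA), keys(topoB, selB)
    if ka != kb:
        missing = sorted(set(ka) ^ set(kb))
        raise ValueError(f"selection mismatch between systems: {missing[:10]}")
    return selA.atom_indices, selB.atom_indices


def combined_pca(
    trajA: Trajectory,
    trajB: Trajectory,
    selectionA: Selection,
    selectionB: Selection | None = None,
    windowA: FrameWindow | None = None,
    windowB: FrameWindow | None = None,
    labelA: str = "A",
    labelB: str = "B",
    fit: bool = True,
) -> CovarianceModel:
    """PCA of the concatenated ensembles of two systems.

    All frames of both windows are superposed onto the combined mean
    (iterated twice; skipped for pre-aligned input when fit=False), the 3N
    covariance of the selected coordinates is eigen-decomposed, and
    per-frame projections are labeled by source system. The selections must
    resolve to the same residue/atom list.
    """
    if selectionB is None:
        selectionB = selectionA
    idxA, idxB = _matched_indices(trajA.topology, selectionA, trajB.topology, selectionB)
    if windowA is None:
        windowA = FrameWindow.full(trajA)
    if windowB is None:
        windowB = FrameWindow.full(trajB)
    windowA.validate(trajA.n_frames)
    windowB.validate(trajB.n_frames)
    subA = trajA.coordinates[windowA.indices()][:, idxA]
    subB = trajB.coordinates[windowB.indices()][:, idxB]
    combined = np.concatenate([subA, subB], axis=0)
    if fit:
        combined = _superposed_ensemble(combined, np.arange(combined.shape[1]))
    nsel = combined.shape[1]
    flat = combined.reshape(len(combined), 3 * nsel)
    mean = flat.mean(axis=0)
    centered = flat - mean
    cov = centered.T @ centered / len(flat)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    proj = centered @ eigvecs
    nA = len(subA)
    return CovarianceModel(
        atom_indices=idxA,
        mean_coordinates=mean.reshape(nsel, 3),
        eigenvalues=eigvals,
        eigenvectors=eigvecs,
        projections={labelA: proj[:nA], labelB: proj[nA:]},
    )


def export_mode_morph(
    model: CovarianceModel,
    topology: Topology,
    mode: int,
    path: str,
    n_steps: int = 6,
    span_sd: float = 2.0,
) -> None:
    """Write a multi-model PDB interpolating the mean structure along one
    mode between -span_sd and +span_sd standard deviations of its
    projection (default six steps)."""
    all_proj = np.concatenate([p[:, mode] for p in model.projections.values()])
    sd = float(all_proj.std())
    vec = model.mode_vector(mode).reshape(-1, 3)
    amplitudes = np.linspace(-span_sd * sd, span_sd * sd, n_steps)
    frames = np.asarray([model.mean_coordinates + a * vec for a in amplitudes])
    sub = _subset_topology(topology, model.atom_indices)
    write_pdb(sub, frames, path)


def _subset_topology(topology: Topology, idx: np.ndarray) -> Topology:
    return Topology(
        topology.names[idx],
        topology.resids[idx],
        topology.resnames[idx],
        topology.chains[idx],
        elements=topology.elements[idx],
        icodes=topology.icodes[idx],
        is_ion=topology.is_ion[idx],
        is_ligand=topology.is_ligand[idx],
    )


@dataclass
class CorrelationMatrix:
    residue_keys: list[tuple[str, int]]
    matrix: np.ndarray  # symmetric, unit diagonal

    def value(self, res_a: tuple[str, int], res_b: tuple[str, int]) -> float:
        i = self.residue_keys.index(res_a)
        j = self.residue_keys.index(res_b)
        return float(self.matrix[i, j])


def correlation_matrix(
    traj: Trajectory,
    selection: Selection | None = None,
    window: FrameWindow | None = None,
    fit: bool = True,
) -> CorrelationMatrix:
    """Normalized CA displacement cross-correlations (DCCM).

    Frames are superposed to the window mean (fitting on all protein atoms,
    which keeps the fit from being dominated by the few mobile CAs); per
    residue the CA displacement dr_i(t) = r_i(t) - <r_i> is used, and
    c_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2><|dr_j|^2>). Zero-variance
    residues are reported as 0 off-diagonal with a warning.
    """
    if window is None:
        window = FrameWindow.full(traj)
    window.validate(traj.n_frames)
    topo = traj.topology
    protein = ~(topo.is_ion | topo.is_ligand)
    if selection is None:
        idx = np.nonzero((topo.names == "CA") & protein)[0]
    else:
        mask = np.zeros(topo.n_atoms, dtype=bool)
        mask[selection.atom_indices] = True
        idx = np.nonzero(mask & (topo.names == "CA"))[0]
    if len(idx) < 2:
        raise ValueError("need >= 2 residues with CA atoms")
    if window.n_selected < 2:
        raise ValueError("need >= 2 frames")
    if fit:
        fit_idx = np.nonzero(protein)[0]
        frames = _superposed_ensemble(traj.coordinates[window.indices()], fit_idx)
        sub = frames[:, idx]
    else:
        sub = traj.coordinates[window.indices()][:, idx]
    disp = sub - sub.mean(axis=0)
    inner = np.einsum("tix,tjx->ij", disp, disp) / len(disp)
    var = np.diag(inner).copy()
    zero = var <= 1e-14
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance residues; correlations set to 0")
        var[zero] = 1.0
    denom = np.sqrt(np.outer(var, var))
    c = inner / denom
    c[zero, :] = 0.0
    c[:, zero] = 0.0
    np.fill_diagonal(c, 1.0)
    keys = [(str(topo.chains[i]), int(topo.resids[i])) for i in idx]
    return CorrelationMatrix(keys, c)


def correlation_difference(
    apo: CorrelationMatrix,
    holo: CorrelationMatrix,
    pairs: list[tuple[tuple[str, int], tuple[str, int]]] | None = None,
) -> list[tuple[tuple, float, float, float]]:
    """Rows (pair, c_apo, c_holo, delta) with delta = c_holo - c_apo."""
    if apo.residue_keys != holo.residue_keys:
        raise ValueError("residue lists differ between systems")
    if pairs is None:
        n = len(apo.residue_keys)
        pairs = [
            (apo.residue_keys[i], apo.residue_keys[j])
            for i in range(n)
            for j in range(i + 1, n)
        ]
    rows = []
    for ra, rb in pairs:
        ca = apo.value(ra, rb)
        ch = holo.value(ra, rb)
        rows.append(((ra, rb), ca, ch, ch - ca))
    return rows


# --------------------------------------------------------------------------
# torsions
# --------------------------------------------------------------------------

def dihedral_series(
    coords: np.ndarray, i0: int, i1: int, i2: int, i3: int
) -> np.ndarray:
    """Signed dihedral (degrees, (-180, 180]) over frames for 4 atom indices."""
    p0 = coords[:, i0]
    p1 = coords[:, i1]
    p2 = coords[:, i2]
    p3 = coords[:, i3]
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1, axis=1, keepdims=True)
    v = b0 - (b0 * b1).sum(axis=1, keepdims=True) * b1
    w = b2 - (b2 * b1).sum(axis=1, keepdims=True) * b1
    x = (v * w).sum(axis=1)
    y = (np.cross(b1, v) * w).sum(axis=1)
    ang = np.degrees(np.arctan2(y, x))
    ang[ang <= -180.0] = 180.0
    return ang


def circular_mean_deg(angles_deg: np.ndarray) -> float:
    rad = np.radians(angles_deg)
    mean = math.degrees(math.atan2(np.sin(rad).mean(), np.cos(rad).mean()))
    return 180.0 if mean <= -180.0 else mean


def circular_sd_deg(angles_deg: np.ndarray) -> float:
    rad = np.radians(angles_deg)
    r = math.hypot(np.sin(rad).mean(), np.cos(rad).mean())
    r = min(max(r, 1e-300), 1.0)
    return math.degrees(math.sqrt(-2.0 * math.log(r)))


@dataclass
class TorsionSummary:
    """Circular phi/psi statistics per residue plus the raw per-frame series
    (for dial plots: the series starts at the window's first frame)."""

    phi_mean: dict[tuple[str, int], float]
    psi_mean: dict[tuple[str, int], float]
    phi_sd: dict[tuple[str, int], float]
    psi_sd: dict[tuple[str, int], float]
    phi_series: dict[tuple[str, int], np.ndarray]
    psi_series: dict[tuple[str, int], np.ndarray]


def torsion_summary(traj: Trajectory, window: FrameWindow | None = None) -> TorsionSummary:
    """Backbone phi (C_{i-1}, N_i, CA_i, C_i) and psi (N_i, CA_i, C_i,
    N_{i+1}) per interior residue, summarized with circular statistics.

    Residues missing backbone atoms are skipped with a warning; chain
    termini lack phi or psi and are omitted for that angle.
    """
    if window is None:
        window = FrameWindow.full(traj)
    window.validate(traj.n_frames)
    topo = traj.topology
    coords = traj.coordinates[window.indices()]

    backbone: dict[tuple[str, int], dict[str, int]] = {}
    for i in range(topo.n_atoms):
        if topo.is_ion[i] or topo.is_ligand[i]:
            continue
        nm = str(topo.names[i])
        if nm in ("N", "CA", "C"):
            backbone.setdefault((str(topo.chains[i]), int(topo.resids[i])), {})[nm] = i

    phi_mean, psi_mean, phi_sd, psi_sd = {}, {}, {}, {}
    phi_series, psi_series = {}, {}
    for (chain, resid), atoms in sorted(backbone.items()):
        if set(atoms) != {"N", "CA", "C"}:
            warnings.warn(f"residue {chain}{resid} missing backbone atoms; skipped")
            continue
        prev = backbone.get((chain, resid - 1))
        nxt = backbone.get((chain, resid + 1))
        if prev and set(prev) == {"N", "CA", "C"}:
            series = dihedral_series(coords, prev["C"], atoms["N"], atoms["CA"], atoms["C"])
            phi_series[(chain, resid)] = series
            phi_mean[(chain, resid)] = circular_mean_deg(series)
            phi_sd[(chain, resid)] = circular_sd_deg(series)
        if nxt and set(nxt) == {"N", "CA", "C"}:
            series = dihedral_series(coords, atoms["N"], atoms["CA"], atoms["C"], nxt["N"])
            psi_series[(chain, resid)] = series
            psi_mean[(chain, resid)] = circular_mean_deg(series)
            psi_sd[(chain, resid)] = circular_sd_deg(series)
    return TorsionSummary(phi_mean, psi_mean, phi_sd, psi_sd, phi_series, psi_series)
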