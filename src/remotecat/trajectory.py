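"""Cα trajectory analytics: superposition, RMSF, principal components.

Works on multi-frame coordinate arrays from any source (multi-model PDB,
plain per-frame XYZ text, or in-memory arrays). Frames are rigid-body
aligned to a reference by the Kabsch least-squares rotation before
fluctuation analysis, so RMSF and PCA reflect internal motion only.

Covariance is the plain (non-mass-weighted) 3N x 3N Cα convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .structure import read_structure

__all__ = [
    "Trajectory",
    "kabsch",
    "superpose",
    "rmsf",
    "pca",
    "read_multimodel_pdb",
]


@dataclass
class Trajectory:
    """frames x sites x 3 coordinates (Å) with site labels."""

    coords: np.ndarray
    labels: list[tuple[str, int]] | None = None
    frame_spacing: float | None = None
    rmsd_to_reference: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, sites, 3)")
        if self.coords.shape[0] < 2:
            raise ValueError("need at least 2 frames")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_sites(self) -> int:
        return self.coords.shape[1]


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t minimizing ||(P @ R + t) - Q||.

    Proper rotation is enforced (no reflection).
    """
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    if S[1] < 1e-10:
        warnings.warn("near-degenerate (collinear) configuration; alignment proceeds")
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    t = qc - pc @ R
    return R, t


def superpose(traj: Trajectory, reference: int | np.ndarray = 0) -> Trajectory:
    """Rigid-body align every frame to the reference (frame index or an
    explicit sites x 3 array); per-frame RMSD to the reference is stored."""
    ref = traj.coords[reference] if isinstance(reference, (int, np.integer)) else np.asarray(reference, float)
    if ref.shape != traj.coords.shape[1:]:
        raise ValueError("reference must match the trajectory's site count")
    aligned = np.empty_like(traj.coords)
    rmsd = np.empty(traj.n_frames)
    for k in range(traj.n_frames):
        R, t = kabsch(traj.coords[k], ref)
        aligned[k] = traj.coords[k] @ R + t
        rmsd[k] = np.sqrt(((aligned[k] - ref) ** 2).sum(axis=1).mean())
    return Trajectory(aligned, labels=traj.labels, frame_spacing=traj.frame_spacing,
                      rmsd_to_reference=rmsd)


def rmsf(traj: Trajectory) -> np.ndarray:
    """Per-site root-mean-square fluctuation about the trajectory mean (Å)."""
    mean = traj.coords.mean(axis=0)
    return np.sqrt(((traj.coords - mean) ** 2).sum(axis=2).mean(axis=0))


def pca(traj: Trajectory, n_components: int | None = None):
    """PCA of the flattened (frames x 3N) centered coordinates.

    Returns (eigenvalues, eigenvectors, projections): eigenvalues
    non-increasing (Å^2), eigenvectors as columns (3N x k), projections per
    frame (frames x k). Components beyond the covariance rank are flagged by
    zero eigenvalues.
    """
    X = traj.coords.reshape(traj.n_frames, -1)
    if n_components is None:
        n_components = min(X.shape)
    if traj.n_frames <= n_components:
        n_components = traj.n_frames - 1
    Xc = X - X.mean(axis=0)
    C = (Xc.T @ Xc) / (traj.n_frames - 1)
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals)[::-1]
    vals, vecs = np.clip(vals[order], 0.0, None), vecs[:, order]
    vals, vecs = vals[:n_components], vecs[:, :n_components]
    proj = Xc @ vecs
    return vals, vecs, proj


def read_multimodel_pdb(pdb_text: str, atom_name: str = "CA") -> Trajectory:
    """Trajectory from a multi-MODEL PDB, selecting one atom per residue."""
    import gemmi

    st = gemmi.read_pdb_string(pdb_text)
    frames = []
    labels = None
    for model in st:
        pts, labs = [], []
        for ch in model:
            for res in ch:
                for at in res:
                    if at.name == atom_name:
                        pts.append([at.pos.x, at.pos.y, at.pos.z])
                        labs.append((ch.name, res.seqid.num))
                        break
        frames.append(pts)
        if labels is None:
            labels = labs
    arr = np.asarray(frames, dtype=float)
    return Trajectory(arr, labels=labels)
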