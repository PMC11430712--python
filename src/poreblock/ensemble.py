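"""Essential dynamics: Cartesian covariance PCA and RMSIP subspace overlap.

A :class:`ModeSet` holds the leading eigenvectors (principal modes) of the
Cartesian covariance matrix of a selection, after iterative superposition of
every frame onto the trajectory mean.  The root-mean-square inner product,

    RMSIP(η, ν; n) = sqrt( (1/n) Σᵢ Σⱼ (ηᵢ·νⱼ)² ),

measures the overlap of two n-mode essential subspaces and lies in [0, 1]:
1 for identical subspaces, 0 for mutually orthogonal ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .core import Trajectory, kabsch_rotation

__all__ = ["ModeSet", "pca_modes", "rmsip"]


@dataclass
class ModeSet:
    """Principal modes of a selection: orthonormal 3M×n eigenvectors, Å² eigenvalues."""

    selection: np.ndarray
    mean_structure: np.ndarray  # (M, 3)
    eigenvectors: np.ndarray  # (3M, n), columns orthonormal
    eigenvalues: np.ndarray  # (n,), descending, >= 0

    def __post_init__(self) -> None:
        G = self.eigenvectors.T @ self.eigenvectors
        if not np.allclose(G, np.eye(G.shape[0]), atol=1e-8):
            raise ValueError("eigenvectors are not orthonormal to 1e-8")
        ev = self.eigenvalues
        if np.any(ev < -1e-10) or np.any(np.diff(ev) > 1e-10):
            raise ValueError("eigenvalues must be non-negative and sorted descending")

    @property
    def n_modes(self) -> int:
        return self.eigenvectors.shape[1]

    def save(self, path: str | Path) -> None:
        """Plain-text serialization: header, eigenvalues row, eigenvector matrix."""
        with open(path, "w") as fh:
            fh.write(f"# poreblock ModeSet: {len(self.selection)} atoms, {self.n_modes} modes\n")
            fh.write("# selection: " + " ".join(map(str, self.selection)) + "\n")
            fh.write("# eigenvalues_A2: " + " ".join(f"{v:.10g}" for v in self.eigenvalues) + "\n")
            np.savetxt(fh, np.hstack([self.mean_structure.reshape(-1, 1), self.eigenvectors]))

    @classmethod
    def load(cls, path: str | Path) -> "ModeSet":
        lines = Path(path).read_text().splitlines()
        selection = np.array(lines[1].split(":", 1)[1].split(), dtype=int)
        eigenvalues = np.array(lines[2].split(":", 1)[1].split(), dtype=float)
        body = np.loadtxt(lines[3:])
        return cls(
            selection=selection,
            mean_structure=body[:, 0].reshape(-1, 3),
            eigenvectors=body[:, 1:],
            eigenvalues=eigenvalues,
        )


def _superpose_onto(X: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Rigidly superpose each frame of X (F, M, 3) onto ref (M, 3)."""
    ref_c = ref - ref.mean(axis=0)
    out = np.empty_like(X)
    for k in range(X.shape[0]):
        P = X[k] - X[k].mean(axis=0)
        R = kabsch_rotation(P, ref_c)
        out[k] = P @ R.T
    return out


def pca_modes(traj: Trajectory, selection: Iterable[int], n_modes: int = 10) -> ModeSet:
    """Covariance PCA of a selection after twice-iterated mean superposition.

    Frames are first superposed onto frame 0, a mean computed, then
    superposed onto that mean and the mean recomputed (two iterations); the
    3M×3M Cartesian covariance is eigen-decomposed and the top ``n_modes``
    retained.  Raises when the covariance rank cannot support ``n_modes``
    (rank ≤ n_frames − 1).
    """
    sel = sorted(set(selection))
    if not sel:
        raise ValueError("selection is empty")
    if traj.n_frames <= n_modes:
        raise ValueError(f"need more than {n_modes} frames for {n_modes} modes")
    idx = traj.topology.indices(sel)
    X = traj.coordinates()[:, idx, :]  # (F, M, 3)

    Y = _superpose_onto(X, X[0])
    mean = Y.mean(axis=0)
    Y = _superpose_onto(X, mean)
    mean = Y.mean(axis=0)

    F, M, _ = Y.shape
    D = (Y - mean).reshape(F, 3 * M)
    cov = D.T @ D / (F - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    rank = int(np.sum(evals > evals[0] * 1e-10)) if evals[0] > 1e-18 else 0
    if rank > 0 and n_modes > rank:
        raise ValueError(f"covariance rank {rank} cannot support {n_modes} modes")
    # a strictly rigid ensemble (rank 0) legitimately returns all-zero eigenvalues
    return ModeSet(
        selection=np.asarray(sel),
        mean_structure=mean,
        eigenvectors=evecs[:, :n_modes],
        eigenvalues=np.clip(evals[:n_modes], 0.0, None),
    )


def rmsip(modes_a: ModeSet, modes_b: ModeSet, n: int = 10) -> float:
    """Root-mean-square inner product of the first ``n`` modes of each set."""
    if modes_a.eigenvectors.shape[0] != modes_b.eigenvectors.shape[0]:
        raise ValueError("mode sets have different dimensionality")
    if modes_a.n_modes < n or modes_b.n_modes < n:
        raise ValueError(f"both mode sets must provide at least n={n} modes")
    A = modes_a.eigenvectors[:, :n]
    B = modes_b.eigenvectors[:, :n]
    value = float(np.sqrt(((A.T @ B) ** 2).sum() / n))
    assert -1e-12 <= value <= 1.0 + 1e-12, "RMSIP out of [0, 1]"
    return min(max(value, 0.0), 1.0)
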