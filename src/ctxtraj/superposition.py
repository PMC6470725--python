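"""Least-squares superposition and fluctuation statistics.

Kabsch's SVD solution is used throughout: the returned rotation is always a
proper rotation (det +1, reflections excluded).  RMSD series, the iterative
average structure, and per-residue Calpha RMSF follow the usual Calpha-trace
conventions with uniform weights by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_io import ConformationalEnsemble, ca_indices

__all__ = [
    "SuperpositionResult",
    "kabsch",
    "superpose_frames",
    "rmsd_series",
    "mean_structure",
    "rmsf",
]


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, proper
    translation: np.ndarray  # nm; transform is (P - com_P) @ R.T + com_Q
    rmsd: float  # nm

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return (coords - self.com_p) @ self.rotation.T + self.com_q

    # centers stored for applying the fit to other selections
    com_p: np.ndarray | None = None
    com_q: np.ndarray | None = None


def _weighted(P: np.ndarray, w: np.ndarray) -> np.ndarray:
    return (P * w[:, None]).sum(axis=0) / w.sum()


def kabsch(
    P: np.ndarray, Q: np.ndarray, weights: np.ndarray | None = None
) -> SuperpositionResult:
    """Optimal proper rotation/translation superposing ``P`` onto ``Q``."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must be matching n x 3 arrays")
    n = P.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    com_p, com_q = _weighted(P, w), _weighted(Q, w)
    Pc, Qc = P - com_p, Q - com_q
    if np.linalg.matrix_rank(Pc, tol=1e-10) < 2:
        raise ValueError("degenerate (collinear) geometry")
    Hmat = (w[:, None] * Pc).T @ Qc
    U, S, Vt = np.linalg.svd(Hmat)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    Rot = Vt.T @ D @ U.T
    diff = Pc @ Rot.T - Qc
    rmsd = float(np.sqrt((w * np.sum(diff**2, axis=1)).sum() / w.sum()))
    return SuperpositionResult(
        rotation=Rot, translation=com_q - com_p, rmsd=rmsd, com_p=com_p, com_q=com_q
    )


def _batched_superpose(
    X: np.ndarray, ref: np.ndarray, weights: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Superpose every frame of ``X`` (F x n x 3) onto ``ref``; returns the
    transformed frames and per-frame RMSD.  Vectorized over frames."""
    F, n, _ = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    wsum = w.sum()
    com_x = (X * w[None, :, None]).sum(axis=1) / wsum
    com_r = _weighted(ref, w)
    Xc = X - com_x[:, None]
    Rc = ref - com_r
    Hmat = np.einsum("fni,nj->fij", w[None, :, None] * Xc, Rc)
    U, S, Vt = np.linalg.svd(Hmat)
    d = np.sign(np.linalg.det(np.einsum("fij,fjk->fik", U, Vt)))
    D = np.zeros((F, 3, 3))
    D[:, 0, 0] = D[:, 1, 1] = 1.0
    D[:, 2, 2] = d
    Rot = np.einsum("fji,fjk,fkl->fil", Vt, D, U.transpose(0, 2, 1))
    # rotation maps frame coords onto reference frame
    aligned = np.einsum("fij,fnj->fni", Rot, Xc) + com_r
    diff = aligned - ref
    rmsd = np.sqrt(np.einsum("n,fn->f", w, np.sum(diff**2, axis=2)) / wsum)
    return aligned, rmsd


def rmsd_series(
    e: ConformationalEnsemble,
    reference: np.ndarray,
    selection: np.ndarray | None = None,
) -> tuple[np.ndarray, float, float]:
    """Per-frame Calpha RMSD (nm) after superposition, plus mean and SD."""
    sel = ca_indices(e.topology) if selection is None else np.asarray(selection)
    if sel.size == 0:
        raise ValueError("empty selection")
    ref = np.asarray(reference, dtype=float)
    if ref.shape[0] == e.n_atoms and sel.max() < ref.shape[0]:
        ref = ref[sel]
    if ref.shape != (sel.size, 3):
        raise ValueError("reference does not match the selection")
    _, rmsds = _batched_superpose(e.coordinates[:, sel], ref)
    return rmsds, float(rmsds.mean()), float(rmsds.std(ddof=0))


def mean_structure(
    e: ConformationalEnsemble,
    selection: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> tuple[np.ndarray, bool]:
    """Iterative average: superpose all frames on the current mean, re-average,
    until the mean moves less than ``tol`` nm (RMS).  Returns (coords, converged)."""
    if e.n_frames < 2:
        raise ValueError("need at least 2 frames")
    sel = ca_indices(e.topology) if selection is None else np.asarray(selection)
    X = e.coordinates[:, sel]
    mean = X[0].copy()
    for _ in range(max_iter):
        aligned, _ = _batched_superpose(X, mean)
        new_mean = aligned.mean(axis=0)
        shift = float(np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1))))
        mean = new_mean
        if shift < tol:
            return mean, True
    warnings.warn(
        f"mean structure did not converge in {max_iter} iterations", stacklevel=2
    )
    return mean, False


def rmsf(
    e: ConformationalEnsemble,
    reference: np.ndarray | str = "self-average",
    selection: np.ndarray | None = None,
) -> np.ndarray:
    """Per-selected-atom RMSF (nm) after superposing every frame on the
    reference (the iterative self-average by default, or external coords to
    measure fluctuation about another peptide's average conformation)."""
    sel = ca_indices(e.topology) if selection is None else np.asarray(selection)
    if sel.size == 0:
        raise ValueError("no Calpha atoms in selection")
    if isinstance(reference, str):
        if reference != "self-average":
            raise ValueError("reference must be coordinates or 'self-average'")
        ref, _ = mean_structure(e, selection=sel)
    else:
        ref = np.asarray(reference, dtype=float)
        if ref.shape[0] == e.n_atoms:
            ref = ref[sel]
    aligned, _ = _batched_superpose(e.coordinates[:, sel], ref)
    mean_pos = aligned.mean(axis=0)
    return np.sqrt(np.mean(np.sum((aligned - mean_pos) ** 2, axis=2), axis=0))
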