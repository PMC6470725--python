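"""Essential-dynamics subspaces and RMSIP/nRMSIP overlap.

The essential subspace of an ensemble is the span of the leading eigenvectors
of the covariance of superposed Calpha coordinates.  Overlap between two
subspaces uses the root-mean-square inner product

    RMSIP = sqrt( (1/N) * sum_i sum_j (eta_i^A . eta_j^B)^2 )

over the first N eigenvectors of each, and its normalized form

    nRMSIP = RMSIP(A, B) / sqrt( RMSIP(A1, A2) * RMSIP(B1, B2) )

where A1/A2 (B1/B2) are bases from the first and second temporal halves of
each trajectory, computed independently.  nRMSIP corrects for finite-sampling
self-consistency; values can marginally exceed 1 and are reported unclipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import ConformationalEnsemble, ca_indices
from .superposition import _batched_superpose, mean_structure

__all__ = [
    "EssentialBasis",
    "essential_basis",
    "rmsip",
    "nrmsip",
    "overlap_matrix",
    "classify_overlap",
    "OVERLAP_CLASSES",
]

#: Four-class scheme for pairwise subspace-overlap reporting.
OVERLAP_CLASSES = (
    (0.65, 0.75, "[0.65, 0.75)"),
    (0.75, 0.85, "[0.75, 0.85)"),
    (0.85, 0.95, "[0.85, 0.95)"),
    (0.95, float("inf"), "[0.95, inf)"),
)


@dataclass
class EssentialBasis:
    """Top eigenvectors/eigenvalues of the superposed-coordinate covariance."""

    eigenvectors: np.ndarray  # d x N, orthonormal columns
    eigenvalues: np.ndarray  # nm^2, descending (all modes, not only the top N)
    n_frames: int
    selection: np.ndarray

    @property
    def dim(self) -> int:
        return self.eigenvectors.shape[0]

    @property
    def n_vectors(self) -> int:
        return self.eigenvectors.shape[1]


def essential_basis(
    e: ConformationalEnsemble,
    selection: np.ndarray | None = None,
    n_vectors: int = 10,
) -> EssentialBasis:
    """Covariance eigenbasis of the Calpha trace after superposition on the
    iterative mean structure."""
    sel = ca_indices(e.topology) if selection is None else np.asarray(selection)
    d = 3 * sel.size
    if n_vectors > d:
        raise ValueError(f"requested {n_vectors} eigenvectors in dimension {d}")
    mean, _ = mean_structure(e, selection=sel)
    aligned, _ = _batched_superpose(e.coordinates[:, sel], mean)
    flat = aligned.reshape(e.n_frames, d)
    cov = np.cov(flat - flat.mean(axis=0), rowvar=False, bias=False)
    evals, evecs = np.linalg.eigh(np.atleast_2d(cov))
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    if np.any(evals < -1e-12):
        raise ValueError("covariance numerically indefinite")
    return EssentialBasis(
        eigenvectors=evecs[:, order[:n_vectors]],
        eigenvalues=np.clip(evals, 0.0, None),
        n_frames=e.n_frames,
        selection=sel,
    )


def rmsip(
    a: EssentialBasis | np.ndarray,
    b: EssentialBasis | np.ndarray,
    n_vectors: int | None = None,
) -> float:
    """Root-mean-square inner product of two orthonormal eigenvector sets."""
    A = a.eigenvectors if isinstance(a, EssentialBasis) else np.asarray(a)
    B = b.eigenvectors if isinstance(b, EssentialBasis) else np.asarray(b)
    if A.shape[0] != B.shape[0]:
        raise ValueError(
            f"dimension mismatch: {A.shape[0]} vs {B.shape[0]} coordinates"
        )
    N = n_vectors or min(A.shape[1], B.shape[1])
    if N > A.shape[1] or N > B.shape[1]:
        raise ValueError("n_vectors exceeds available eigenvectors")
    overlap = A[:, :N].T @ B[:, :N]
    return float(np.sqrt(np.sum(overlap**2) / N))


def _halves(e: ConformationalEnsemble) -> tuple[ConformationalEnsemble, ConformationalEnsemble]:
    from dataclasses import replace

    mid = e.n_frames // 2
    first = replace(e, coordinates=e.coordinates[:mid], times=e.times[:mid])
    second = replace(e, coordinates=e.coordinates[mid:], times=e.times[mid:])
    return first, second


def self_consistency(
    e: ConformationalEnsemble,
    selection: np.ndarray | None = None,
    n_vectors: int = 10,
) -> float:
    """RMSIP between bases of the first and second temporal halves, each
    superposed on its own mean."""
    h1, h2 = _halves(e)
    b1 = essential_basis(h1, selection=selection, n_vectors=n_vectors)
    b2 = essential_basis(h2, selection=selection, n_vectors=n_vectors)
    return rmsip(b1, b2)


def nrmsip(
    ea: ConformationalEnsemble,
    eb: ConformationalEnsemble,
    selection: np.ndarray | None = None,
    n_vectors: int = 10,
) -> float:
    """Normalized RMSIP of two ensembles (half-trajectory normalization)."""
    for e in (ea, eb):
        if e.n_frames < 4:
            raise ValueError("each ensemble needs at least 4 frames")
    ba = essential_basis(ea, selection=selection, n_vectors=n_vectors)
    bb = essential_basis(eb, selection=selection, n_vectors=n_vectors)
    cross = rmsip(ba, bb)
    saa = self_consistency(ea, selection=selection, n_vectors=n_vectors)
    sbb = self_consistency(eb, selection=selection, n_vectors=n_vectors)
    denom = np.sqrt(saa * sbb)
    if denom < 1e-12:
        raise ValueError(
            "zero self-overlap in a trajectory half: sampling not converged"
        )
    return float(cross / denom)


def overlap_matrix(
    ensembles: list[ConformationalEnsemble],
    selection: np.ndarray | None = None,
    n_vectors: int = 10,
    normalized: bool = True,
) -> np.ndarray:
    """Symmetric pairwise RMSIP (or nRMSIP) matrix; diagonal fixed to 1."""
    if len(ensembles) < 2:
        raise ValueError("need at least 2 ensembles")
    m = len(ensembles)
    out = np.eye(m)
    bases = [
        essential_basis(e, selection=selection, n_vectors=n_vectors)
        for e in ensembles
    ]
    selfs = (
        [self_consistency(e, selection=selection, n_vectors=n_vectors) for e in ensembles]
        if normalized
        else None
    )
    for i in range(m):
        for j in range(i + 1, m):
            v = rmsip(bases[i], bases[j])
            if normalized:
                v = v / np.sqrt(selfs[i] * selfs[j])
            out[i, j] = out[j, i] = v
    return out


def classify_overlap(value: float) -> str:
    """Map an overlap value to its four-class label (or 'below 0.65')."""
    if value < 0:
        raise ValueError("overlap must be >= 0")
    for lo, hi, label in OVERLAP_CLASSES:
        if lo <= value < hi:
            return label
    return "below 0.65"
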