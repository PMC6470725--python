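"""Dihedral PCA, free-energy landscapes and conformational basin extraction.

The workflow mirrors the standard dPCA analysis of peptide trajectories:
backbone phi/psi torsions are extracted per frame, encoded as
(cos, sin) pairs to remove angular periodicity, the covariance of the encoded
matrix is eigendecomposed, and the first two principal components are binned
into a two-dimensional free-energy landscape

    dG(x, y) = -R * T * ln( rho(x, y) / rho_max )

with R the gas constant and rho the bin occupancy probability.  Basins are
identified with k-means on the projection and the lowest-energy conformer of
each basin extracted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_io import ConformationalEnsemble
from .geometry import dihedral

#: Gas constant, kJ mol^-1 K^-1.
R_GAS = 8.314462618e-3

#: Simulation/production temperature of the study conditions, K.
DEFAULT_TEMPERATURE = 310.0

__all__ = [
    "DihedralSeries",
    "DPCAModel",
    "FELGrid",
    "ClusterModel",
    "extract_dihedrals",
    "dpca_encode",
    "pca",
    "free_energy_landscape",
    "cluster_landscape",
    "count_basins",
    "basin_free_energies",
    "representative_conformations",
    "R_GAS",
    "DEFAULT_TEMPERATURE",
]


@dataclass
class DihedralSeries:
    """Backbone torsions: frames x residues arrays of phi and psi (radians).

    ``residue_indices`` are the 1-based residues the columns refer to.  For a
    full chain the first residue has no phi and the last no psi; series built
    over an interior range (the default, residues 2..n-1) have both defined
    for every column.
    """

    phi: np.ndarray
    psi: np.ndarray
    residue_indices: np.ndarray

    def __post_init__(self) -> None:
        self.phi = np.atleast_2d(np.asarray(self.phi, dtype=float))
        self.psi = np.atleast_2d(np.asarray(self.psi, dtype=float))
        if self.phi.shape != self.psi.shape:
            raise ValueError("phi and psi must have identical shapes")
        self.residue_indices = np.asarray(self.residue_indices, dtype=int)
        if self.residue_indices.shape != (self.phi.shape[1],):
            raise ValueError("residue_indices must match the residue axis")

    @property
    def n_frames(self) -> int:
        return self.phi.shape[0]

    @property
    def n_residues(self) -> int:
        return self.phi.shape[1]


@dataclass
class DPCAModel:
    """Eigendecomposition of the covariance of the encoded dihedral matrix."""

    mean: np.ndarray
    eigenvectors: np.ndarray  # p x K, orthonormal columns
    eigenvalues: np.ndarray  # descending, >= 0

    def project(self, X: np.ndarray, n_components: int | None = None) -> np.ndarray:
        V = self.eigenvectors
        if n_components is not None:
            V = V[:, :n_components]
        return (np.asarray(X) - self.mean) @ V


@dataclass
class FELGrid:
    """Binned 2-D free-energy landscape over (dPC1, dPC2)."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray
    temperature: float
    delta_g: np.ndarray = field(init=False)  # kJ/mol, NaN on empty bins
    occupied: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.occupied = self.counts > 0
        total = self.counts.sum()
        rho = self.counts / total
        rho_max = rho.max()
        with np.errstate(divide="ignore"):
            dg = -R_GAS * self.temperature * np.log(rho / rho_max)
        dg[~self.occupied] = np.nan
        # the maximally occupied bin sits at exactly zero by construction
        dg[rho == rho_max] = 0.0
        self.delta_g = dg

    @property
    def rho_max(self) -> float:
        return float(self.counts.max() / self.counts.sum())

    def bin_of(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map projection points to (ix, iy) bin indices (edge-clipped)."""
        pts = np.atleast_2d(points)
        ix = np.clip(
            np.searchsorted(self.x_edges, pts[:, 0], side="right") - 1,
            0,
            len(self.x_edges) - 2,
        )
        iy = np.clip(
            np.searchsorted(self.y_edges, pts[:, 1], side="right") - 1,
            0,
            len(self.y_edges) - 2,
        )
        return ix, iy

    def delta_g_of(self, points: np.ndarray) -> np.ndarray:
        ix, iy = self.bin_of(points)
        return self.delta_g[ix, iy]


@dataclass
class ClusterModel:
    """k-means basin assignment on the 2-D projection with diagnostics."""

    k: int
    assignments: np.ndarray  # 1-based cluster labels per frame
    centroids: np.ndarray
    sse: float
    silhouette_width: float  # average silhouette over (sub)sampled frames
    seed: int


# ---------------------------------------------------------------------------


def extract_dihedrals(
    e: ConformationalEnsemble, residues: tuple[int, int] | None = None
) -> DihedralSeries:
    """phi/psi torsions for the requested 1-based inclusive residue range.

    Defaults to residues 2..n-1 of the (single-chain) topology so that both
    torsions are defined for every reported residue.  phi = C(i-1)-N-CA-C,
    psi = N-CA-C-N(i+1), IUPAC sign convention.
    """
    top = e.topology
    chain_resids = [r for (_, r) in top.residue_ids]
    protein = [
        r
        for (c, r) in top.residue_ids
        if top.atom_indices(r, c, names={"CA"}).size
    ]
    if residues is None:
        residues = (protein[1], protein[-2])
    lo, hi = residues
    wanted = [r for r in protein if lo <= r <= hi]

    def backbone_atom(resid: int, name: str) -> int:
        idx = top.atom_indices(resid, names={name}, role="backbone")
        if not idx.size:
            raise ValueError(f"residue {resid} lacks backbone atom {name}")
        return int(idx[0])

    X = e.coordinates
    phi = np.empty((e.n_frames, len(wanted)))
    psi = np.empty((e.n_frames, len(wanted)))
    for col, r in enumerate(wanted):
        c_prev = backbone_atom(r - 1, "C")
        n_i = backbone_atom(r, "N")
        ca_i = backbone_atom(r, "CA")
        c_i = backbone_atom(r, "C")
        n_next = backbone_atom(r + 1, "N")
        phi[:, col] = dihedral(X[:, c_prev], X[:, n_i], X[:, ca_i], X[:, c_i])
        psi[:, col] = dihedral(X[:, n_i], X[:, ca_i], X[:, c_i], X[:, n_next])
    return DihedralSeries(phi=phi, psi=psi, residue_indices=np.array(wanted))


def dpca_encode(d: DihedralSeries) -> np.ndarray:
    """frames x 4m matrix of per-residue blocks [cos phi, sin phi, cos psi, sin psi]."""
    blocks = np.stack(
        [np.cos(d.phi), np.sin(d.phi), np.cos(d.psi), np.sin(d.psi)], axis=2
    )
    return blocks.reshape(d.n_frames, 4 * d.n_residues)


def pca(X: np.ndarray) -> DPCAModel:
    """PCA via eigendecomposition of the covariance of ``X`` (frames x p).

    Deterministic up to column sign; the sign of each eigenvector is fixed so
    its largest-magnitude loading is positive.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be frames x p with at least 2 frames")
    mean = X.mean(axis=0)
    cov = np.cov(X - mean, rowvar=False, bias=False)
    cov = np.atleast_2d(cov)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # deterministic sign convention
    for j in range(evecs.shape[1]):
        i_max = np.argmax(np.abs(evecs[:, j]))
        if evecs[i_max, j] < 0:
            evecs[:, j] = -evecs[:, j]
    return DPCAModel(mean=mean, eigenvectors=evecs, eigenvalues=evals)


def free_energy_landscape(
    proj: np.ndarray,
    n_bins: int | tuple[int, int] = 100,
    temperature: float = DEFAULT_TEMPERATURE,
    pad_fraction: float = 0.01,
) -> FELGrid:
    """Bin a frames x 2 projection and convert occupancies to dG (kJ/mol).

    The grid covers the projection's bounding box expanded by ``pad_fraction``
    on each side.  Empty bins are masked (NaN), never assigned a finite energy.
    """
    proj = np.atleast_2d(np.asarray(proj, dtype=float))
    if proj.shape[1] != 2:
        raise ValueError("projection must be frames x 2")
    if isinstance(n_bins, int):
        n_bins = (n_bins, n_bins)
    if min(n_bins) < 2:
        raise ValueError("need at least 2 bins per axis")
    edges = []
    for axis, nb in enumerate(n_bins):
        lo, hi = proj[:, axis].min(), proj[:, axis].max()
        span = (hi - lo) or 1e-9
        pad = pad_fraction * span
        edges.append(np.linspace(lo - pad, hi + pad, nb + 1))
    counts, _, _ = np.histogram2d(proj[:, 0], proj[:, 1], bins=edges)
    return FELGrid(
        x_edges=edges[0], y_edges=edges[1], counts=counts, temperature=temperature
    )


def cluster_landscape(
    proj: np.ndarray,
    k_candidates=(2, 3, 4, 5),
    seed: int = 0,
    n_init: int = 50,
    silhouette_sample: int = 5000,
) -> tuple[dict[int, ClusterModel], int]:
    """k-means over candidate k with SSE and silhouette diagnostics.

    Returns the per-k models and the selected k (maximum average silhouette
    width).  The silhouette is evaluated on a seeded subsample when the frame
    count exceeds ``silhouette_sample``.
    """
    from sklearn.cluster import KMeans
    from sklearn.metrics import silhouette_score

    proj = np.atleast_2d(np.asarray(proj, dtype=float))
    n = proj.shape[0]
    n_distinct = np.unique(proj, axis=0).shape[0]
    models: dict[int, ClusterModel] = {}
    for k in k_candidates:
        if not 2 <= k < n:
            raise ValueError(f"k={k} outside [2, n_frames)")
        if k >= n_distinct:
            raise ValueError(f"k={k} >= {n_distinct} distinct points")
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(proj)
        if n > silhouette_sample:
            sil = silhouette_score(
                proj, km.labels_, sample_size=silhouette_sample, random_state=seed
            )
        else:
            sil = silhouette_score(proj, km.labels_)
        models[k] = ClusterModel(
            k=k,
            assignments=km.labels_ + 1,
            centroids=km.cluster_centers_,
            sse=float(km.inertia_),
            silhouette_width=float(sil),
            seed=seed,
        )
    best_k = max(models, key=lambda k: models[k].silhouette_width)
    return models, best_k


def _basin_totals(grid: FELGrid, max_delta_g: float, min_bins: int) -> np.ndarray:
    """Summed bin counts of each basin.

    Basins are 8-connected components of occupied bins that (a) contain at
    least ``min_bins`` bins and (b) descend below ``max_delta_g`` somewhere.
    Counts are summed over the whole component, so the cap selects which
    components qualify without truncating their tails.
    """
    from scipy import ndimage

    labels, n = ndimage.label(grid.occupied, structure=np.ones((3, 3), dtype=int))
    totals = []
    for b in range(1, n + 1):
        member = labels == b
        if member.sum() < min_bins:
            continue
        if np.nanmin(grid.delta_g[member]) > max_delta_g:
            continue
        totals.append(grid.counts[member].sum())
    return np.asarray(totals)


def count_basins(grid: FELGrid, max_delta_g: float = 5.0, min_bins: int = 2) -> int:
    """Number of distinct basins (see :func:`_basin_totals`).

    The default cap of 5 kJ/mol (~2 RT at 310 K) keeps metastable minima
    while excluding rarely visited outlier regions; empty bins never connect
    basins, so regions separated by unsampled space are always distinct."""
    return int(_basin_totals(grid, max_delta_g, min_bins).size)


def basin_free_energies(
    grid: FELGrid, max_delta_g: float = 5.0, min_bins: int = 2
) -> np.ndarray:
    """Free energy of each basin from its total occupancy, sorted ascending.

    The free energy of basin b is -R T ln(N_b / N_max) with N_b its summed
    bin counts: the state free energy obtained by integrating over the whole
    basin rather than reading a single bin.  The most occupied basin sits at
    exactly 0.
    """
    totals = _basin_totals(grid, max_delta_g, min_bins)
    dg = -R_GAS * grid.temperature * np.log(totals / totals.max())
    return np.sort(dg) + 0.0  # normalize -0.0


@dataclass
class Conformer:
    """One representative conformation: a frame in its basin's lowest-dG bin."""

    rank: int  # 1 = lowest energy basin
    cluster: int
    frame_index: int
    delta_g: float  # kJ/mol of the bin the frame sits in


def representative_conformations(
    clusters: ClusterModel,
    grid: FELGrid,
    proj: np.ndarray,
    e: ConformationalEnsemble | None = None,
) -> list[Conformer]:
    """Per basin, the frame in its minimum-dG occupied bin nearest the bin
    center; basins ordered from lowest to highest minimum dG."""
    proj = np.atleast_2d(np.asarray(proj, dtype=float))
    dg_frames = grid.delta_g_of(proj)
    ix, iy = grid.bin_of(proj)
    picks = []
    for c in range(1, clusters.k + 1):
        members = np.flatnonzero(clusters.assignments == c)
        if members.size == 0:
            warnings.warn(f"cluster {c} is empty; skipped", stacklevel=2)
            continue
        dg_min = np.nanmin(dg_frames[members])
        in_best_bin = members[dg_frames[members] == dg_min]
        bx, by = ix[in_best_bin[0]], iy[in_best_bin[0]]
        cx = 0.5 * (grid.x_edges[bx] + grid.x_edges[bx + 1])
        cy = 0.5 * (grid.y_edges[by] + grid.y_edges[by + 1])
        d2 = (proj[in_best_bin, 0] - cx) ** 2 + (proj[in_best_bin, 1] - cy) ** 2
        picks.append((dg_min, c, int(in_best_bin[np.argmin(d2)])))
    picks.sort()
    return [
        Conformer(rank=r + 1, cluster=c, frame_index=f, delta_g=float(dg))
        for r, (dg, c, f) in enumerate(picks)
    ]
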