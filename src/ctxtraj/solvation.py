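"""Solvent accessibility and hydration-shell statistics.

SASA uses the Shrake-Rupley algorithm: each heavy atom is covered with a
deterministic golden-spiral point mesh at radius r_atom + r_probe (probe
0.14 nm, 1000 points by default) and the accessible fraction of points is
converted to area.  Per-residue SASA is normalized by the residue type's
maximum SASA (mSASA) from reference tripeptide simulations to give rSASA.

Hydration is measured from single-site water positions: a radial distribution
function g(r) around selected centers, and the probability of finding water
within a shell (0.5 nm by default), reported either as the mean water count
normalized by the bulk-density expectation for the same shell volume (the
default, a dimensionless occupancy that is 1 in bulk) or as the raw count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core_io import ConformationalEnsemble, MolecularTopology, SOLVENT_RESIDUES

__all__ = [
    "SolvationProfile",
    "RadialDistribution",
    "sasa",
    "rsasa",
    "rdf",
    "shell_probability",
    "LEE_RICHARDS_RADII",
    "MSASA_NM2",
]

#: Heavy-atom radii (nm), Lee & Richards style; user-overridable.
LEE_RICHARDS_RADII = {
    "C": 0.170,
    "N": 0.155,
    "O": 0.152,
    "S": 0.180,
    "P": 0.180,
    "H": 0.110,
}

#: Maximum residue SASA (nm^2) from reference tripeptide ensembles:
#: Acetyl-Ala-Xaa-Ala-NH2 for Abu/Ser and the disulfide-bonded
#: (Acetyl-Ala-Cys-Ala-NH2)2 dimer for Cys.
MSASA_NM2 = {"CYS": 0.758, "SER": 1.219, "ABU": 1.347}


@dataclass
class SolvationProfile:
    residue_indices: np.ndarray
    sasa: np.ndarray  # nm^2
    rsasa: np.ndarray | None = None
    shell_probability: np.ndarray | None = None


@dataclass
class RadialDistribution:
    bin_edges: np.ndarray  # nm
    g: np.ndarray
    bulk_density: float  # nm^-3

    def integrated_count(self, r_cut: float) -> float:
        """Mean number of waters within r_cut implied by integrating
        rho_bulk * g(r) * 4 pi r^2 dr over the bins up to r_cut."""
        centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        widths = np.diff(self.bin_edges)
        mask = self.bin_edges[1:] <= r_cut + 1e-12
        return float(
            np.sum(
                self.bulk_density
                * self.g[mask]
                * 4.0
                * math.pi
                * centers[mask] ** 2
                * widths[mask]
            )
        )


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral mesh of ``n`` points on the unit sphere."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def _frame_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float,
    mesh: np.ndarray,
) -> np.ndarray:
    """Per-atom accessible area for one frame (nm^2)."""
    n = coords.shape[0]
    ext = radii + probe
    areas = np.empty(n)
    for i in range(n):
        pts = coords[i] + ext[i] * mesh
        d = np.linalg.norm(coords[i] - coords, axis=1)
        neighbors = np.flatnonzero((d < ext[i] + ext) & (np.arange(n) != i))
        if neighbors.size:
            dist2 = np.sum(
                (pts[:, None, :] - coords[neighbors][None, :, :]) ** 2, axis=2
            )
            buried = np.any(dist2 < (ext[neighbors] ** 2)[None, :], axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * math.pi * ext[i] ** 2 * frac
    return areas


def sasa(
    e: ConformationalEnsemble,
    radii: dict[str, float] | None = None,
    probe: float = 0.14,
    n_points: int = 1000,
    include_hydrogens: bool = False,
    per_atom: bool = False,
) -> np.ndarray:
    """Shrake-Rupley SASA (nm^2) per residue, averaged over frames.

    Solvent and ion atoms are ignored.  Hydrogens are excluded by default
    (heavy-atom convention); set ``include_hydrogens`` to count them with
    their own radius.  ``per_atom`` returns the per-atom breakdown instead.
    """
    rtable = radii or LEE_RICHARDS_RADII
    top = e.topology
    keep = [
        i
        for i, a in enumerate(top.atoms)
        if a.role in {"backbone", "sidechain"}
        and (include_hydrogens or a.element != "H")
    ]
    for i in keep:
        if top.atoms[i].element not in rtable:
            raise ValueError(f"no radius for element {top.atoms[i].element!r}")
    rad = np.array([rtable[top.atoms[i].element] for i in keep])
    mesh = _sphere_points(n_points)
    atom_areas = np.zeros(len(keep))
    for f in range(e.n_frames):
        atom_areas += _frame_sasa(e.coordinates[f][keep], rad, probe, mesh)
    atom_areas /= e.n_frames
    if per_atom:
        return atom_areas
    resids = sorted({top.atoms[i].residue_index for i in keep})
    out = np.zeros(len(resids))
    pos = {r: k for k, r in enumerate(resids)}
    for area, i in zip(atom_areas, keep):
        out[pos[top.atoms[i].residue_index]] += area
    return out


def rsasa(
    sasa_value: float,
    residue_type: str,
    msasa: dict[str, float] | None = None,
) -> float:
    """SASA normalized by the residue type's maximum SASA (dimensionless).

    Values above 1 are possible (conformations more exposed than the
    reference tripeptide) and are returned as-is.
    """
    table = msasa or MSASA_NM2
    rtype = residue_type.upper()
    if rtype not in table:
        raise KeyError(f"no mSASA reference for residue type {rtype!r}")
    return float(sasa_value) / table[rtype]


def _water_indices(top: MolecularTopology) -> np.ndarray:
    idx = [
        i
        for i, a in enumerate(top.atoms)
        if a.residue_name in SOLVENT_RESIDUES and a.atom_name.startswith("O")
    ]
    return np.asarray(idx, dtype=int)


def _bulk_density(e: ConformationalEnsemble, waters: np.ndarray) -> float:
    if e.box is None:
        raise ValueError("ensemble has no box; cannot derive bulk density")
    return waters.size / float(np.prod(e.box))


def rdf(
    e: ConformationalEnsemble,
    centers: np.ndarray,
    r_max: float = 1.0,
    dr: float = 0.01,
    bulk_density: float | None = None,
) -> RadialDistribution:
    """Radial distribution function of water oxygens around ``centers``
    (atom indices), averaged over frames and centers."""
    waters = _water_indices(e.topology)
    if waters.size == 0:
        raise ValueError("ensemble contains no solvent")
    centers = np.atleast_1d(np.asarray(centers, dtype=int))
    rho = bulk_density if bulk_density is not None else _bulk_density(e, waters)
    edges = np.arange(0.0, r_max + dr / 2, dr)
    counts = np.zeros(len(edges) - 1)
    for f in range(e.n_frames):
        for c in centers:
            d = np.linalg.norm(e.coordinates[f, waters] - e.coordinates[f, c], axis=1)
            h, _ = np.histogram(d, bins=edges)
            counts += h
    counts /= e.n_frames * centers.size
    shell_vol = 4.0 / 3.0 * math.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    g = counts / (rho * shell_vol)
    return RadialDistribution(bin_edges=edges, g=g, bulk_density=rho)


def shell_probability(
    e: ConformationalEnsemble,
    center: int,
    r_cut: float = 0.5,
    mode: str = "shell_occupancy_norm",
    bulk_density: float | None = None,
) -> float:
    """Water presence in the shell of radius ``r_cut`` around atom ``center``.

    ``shell_occupancy_norm`` (default): mean water count in the shell divided
    by the bulk-density expectation for the same shell volume (1 in bulk,
    matching the interpretation of integrating g(r) over the shell).
    ``mean_count``: the raw mean count.
    """
    waters = _water_indices(e.topology)
    if waters.size == 0:
        raise ValueError("ensemble contains no solvent")
    if e.box is not None and r_cut > float(np.min(e.box)) / 2:
        raise ValueError("r_cut exceeds half the smallest box dimension")
    d = np.linalg.norm(
        e.coordinates[:, waters] - e.coordinates[:, [center]], axis=2
    )
    mean_count = float(np.mean(np.sum(d <= r_cut, axis=1)))
    if mode == "mean_count":
        return mean_count
    if mode != "shell_occupancy_norm":
        raise ValueError("mode must be 'shell_occupancy_norm' or 'mean_count'")
    rho = bulk_density if bulk_density is not None else _bulk_density(e, waters)
    expectation = rho * 4.0 / 3.0 * math.pi * r_cut**3
    return mean_count / expectation
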