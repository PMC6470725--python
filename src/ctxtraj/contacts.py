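"""Residue-residue contacts, geometric H-bonds and the CbetaHbeta statistic.

Contacts follow the heavy-atom minimum-distance convention (<= 0.5 nm by
default) separately for backbone-backbone and sidechain-sidechain atom sets.
H-bonds use the geometric criterion of a donor-acceptor distance <= 0.35 nm
and a deviation from donor-H-acceptor linearity <= 30 degrees.  Disulfide
surrogacy is quantified by the distance between the mass-weighted centers of
{Cbeta, Hbeta1, Hbeta2} of a residue pair, with contact declared below the
one-sided 95% threshold of a bonded reference dipeptide (0.26 nm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_io import ConformationalEnsemble, MolecularTopology

__all__ = [
    "ContactMap",
    "ContactStat",
    "HBond",
    "contact_map",
    "hbonds",
    "cbeta_com_stat",
    "ci95_threshold",
    "ATOMIC_MASSES",
    "CBETA_CONTACT_THRESHOLD",
]

ATOMIC_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "P": 30.974}

#: One-sided 95% CbetaHbeta center-of-mass contact threshold (nm) of the
#: disulfide-bonded reference dipeptide.
CBETA_CONTACT_THRESHOLD = 0.26

_BACKBONE_HEAVY = {"N", "CA", "C", "O", "OXT"}


@dataclass
class ContactMap:
    """Symmetric residue-residue contact-probability matrix.

    ``missing`` flags residues without heavy atoms of the requested role
    (e.g. Gly sidechains); their rows/columns are NaN, not zero.
    """

    probabilities: np.ndarray
    residue_indices: np.ndarray
    mode: str  # "BB-BB" | "SC-SC"
    cutoff: float  # nm
    missing: np.ndarray  # bool per residue


@dataclass
class ContactStat:
    """Center-of-mass distance statistics for one residue pair."""

    pair: tuple[int, int]
    mean: float  # nm
    sd: float
    probability: float  # fraction of frames with distance <= threshold
    threshold: float
    distances: np.ndarray


@dataclass
class HBond:
    donor_residue: int
    donor_atom: str
    acceptor_residue: int
    acceptor_atom: str
    occupancy: float


def _role_heavy_indices(top: MolecularTopology, resid: int, mode: str) -> np.ndarray:
    heavy = top.heavy_indices(resid)
    names = [top.atoms[i].atom_name for i in heavy]
    if mode == "BB-BB":
        keep = [i for i, nm in zip(heavy, names) if nm in _BACKBONE_HEAVY]
    elif mode == "SC-SC":
        keep = [i for i, nm in zip(heavy, names) if nm not in _BACKBONE_HEAVY]
    else:
        raise ValueError("mode must be 'BB-BB' or 'SC-SC'")
    return np.asarray(keep, dtype=int)


def contact_map(
    e: ConformationalEnsemble, mode: str = "SC-SC", cutoff: float = 0.5
) -> ContactMap:
    """Probability, over frames, that the minimum heavy-atom distance between
    two residues (within the requested role) is <= ``cutoff`` nm."""
    top = e.topology
    protein = {a.residue_index for a in top.atoms if a.role in {"backbone", "sidechain"}}
    resids = [r for (_, r) in top.residue_ids if r in protein]
    groups = [_role_heavy_indices(top, r, mode) for r in resids]
    n = len(resids)
    prob = np.full((n, n), np.nan)
    missing = np.array([g.size == 0 for g in groups])
    X = e.coordinates
    for a in range(n):
        if missing[a]:
            continue
        prob[a, a] = 1.0
        for b in range(a + 1, n):
            if missing[b]:
                continue
            d = np.linalg.norm(
                X[:, groups[a], None, :] - X[:, None, groups[b], :], axis=-1
            )
            p = float(np.mean(d.min(axis=(1, 2)) <= cutoff))
            prob[a, b] = prob[b, a] = p
    return ContactMap(
        probabilities=prob,
        residue_indices=np.asarray(resids),
        mode=mode,
        cutoff=cutoff,
        missing=missing,
    )


def _find_donors(top: MolecularTopology, coords0: np.ndarray, attach: float = 0.125):
    """(heavy, H) donor pairs: N/O atoms with a hydrogen within ``attach`` nm
    in the first frame (bonding by proximity; topologies carry no bond list)."""
    donors = []
    h_atoms = [i for i, a in enumerate(top.atoms) if a.element == "H"]
    for i, a in enumerate(top.atoms):
        if a.element not in {"N", "O"} or a.role in {"solvent", "ion"}:
            continue
        for h in h_atoms:
            if top.atoms[h].residue_index != a.residue_index:
                continue
            if np.linalg.norm(coords0[i] - coords0[h]) <= attach:
                donors.append((i, h))
    return donors


def hbonds(
    e: ConformationalEnsemble,
    r_cut: float = 0.35,
    ang_cut: float = 30.0,
    min_residue_sep: int = 1,
) -> list[HBond]:
    """Per donor/acceptor H-bond occupancies over frames.

    A bond exists in a frame iff d(donor, acceptor) <= ``r_cut`` nm and the
    deviation from donor-H-acceptor linearity is <= ``ang_cut`` degrees.
    Donors lacking a resolvable hydrogen are skipped with a warning.
    """
    top = e.topology
    X = e.coordinates
    donors = _find_donors(top, X[0])
    donor_residues = {top.atoms[d].residue_index for d, _ in donors}
    chain_starts = {}
    for a in top.atoms:
        if a.role in {"backbone", "sidechain"}:
            chain_starts[a.chain_id] = min(
                chain_starts.get(a.chain_id, a.residue_index), a.residue_index
            )
    skipped = [
        a.residue_index
        for a in top.atoms
        if a.atom_name == "N"
        and a.role == "backbone"
        and a.residue_index not in donor_residues
        and a.residue_index != chain_starts.get(a.chain_id)
        and a.residue_name != "PRO"
    ]
    if skipped:
        warnings.warn(
            f"backbone N donors without attached H skipped at residues {skipped}",
            stacklevel=2,
        )
    acceptors = [
        i
        for i, a in enumerate(top.atoms)
        if a.element in {"N", "O"} and a.role not in {"solvent", "ion"}
    ]
    out = []
    for d, h in donors:
        rd = top.atoms[d].residue_index
        for acc in acceptors:
            if acc == d or acc == h:
                continue
            ra = top.atoms[acc].residue_index
            if abs(ra - rd) < min_residue_sep:
                continue
            dv = X[:, acc] - X[:, d]
            dist = np.linalg.norm(dv, axis=1)
            hv = X[:, h] - X[:, d]
            av = X[:, acc] - X[:, h]
            # deviation from linearity at H: angle between D->H and H->A
            cosang = np.sum(hv * av, axis=1) / (
                np.linalg.norm(hv, axis=1) * np.linalg.norm(av, axis=1)
            )
            dev = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            occ = float(np.mean((dist <= r_cut) & (dev <= ang_cut)))
            if occ > 0:
                out.append(
                    HBond(
                        donor_residue=rd,
                        donor_atom=top.atoms[d].atom_name,
                        acceptor_residue=ra,
                        acceptor_atom=top.atoms[acc].atom_name,
                        occupancy=occ,
                    )
                )
    return out


def _cbeta_com(e: ConformationalEnsemble, resid: int) -> np.ndarray:
    top = e.topology
    idx = top.atom_indices(resid, names={"CB", "HB1", "HB2"})
    if idx.size != 3:
        raise ValueError(
            f"residue {resid} lacks Cbeta/Hbeta1/Hbeta2 atoms required for the "
            "CbetaHbeta center-of-mass statistic"
        )
    masses = np.array([ATOMIC_MASSES[top.atoms[i].element] for i in idx])
    return np.einsum("fai,a->fi", e.coordinates[:, idx], masses) / masses.sum()


def cbeta_com_stat(
    e: ConformationalEnsemble,
    pair: tuple[int, int],
    threshold: float = CBETA_CONTACT_THRESHOLD,
) -> ContactStat:
    """Mean +/- SD of the CbetaHbeta COM distance for a residue pair and the
    probability of contact at the given threshold (nm)."""
    com_a = _cbeta_com(e, pair[0])
    com_b = _cbeta_com(e, pair[1])
    d = np.linalg.norm(com_a - com_b, axis=1)
    return ContactStat(
        pair=pair,
        mean=float(d.mean()),
        sd=float(d.std(ddof=0)),
        probability=float(np.mean(d <= threshold)),
        threshold=threshold,
        distances=d,
    )


def ci95_threshold(reference_distances: np.ndarray) -> float:
    """One-sided upper 95th percentile of a reference distance distribution."""
    d = np.asarray(reference_distances, dtype=float)
    if d.size < 100:
        raise ValueError("need at least 100 reference samples")
    return float(np.percentile(d, 95.0))
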