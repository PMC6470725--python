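"""DSSP-style secondary-structure assignment from backbone geometry.

Hydrogen bonds are scored with the Kabsch-Sander electrostatic model

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)   [kcal/mol, r in A]

and declared when E < -0.5 kcal/mol.  The bond pattern then drives the
standard assignment: n-turns give 3/4/5-helices (G/H/I), bridge patterns give
beta structure (B isolated, E in ladders), remaining turn positions give T,
Calpha kinks above 70 degrees give bends (S), everything else is coil (C).
Labels are reduced to the three reported classes (alpha-helix, beta-sheet,
beta-turn/bend, remainder coil) through a configurable map.

Amide hydrogens must be present in the input (the synthetic generators place
them); they are never reconstructed.  Prolines and chain-start residues carry
no amide H and simply cannot donate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import ConformationalEnsemble

__all__ = [
    "SecondaryStructureTrace",
    "ks_hbond_energy",
    "assign_secondary_structure",
    "ss_fractions",
    "HBOND_ENERGY_CUTOFF",
    "DEFAULT_REDUCTION",
]

#: Kabsch-Sander bond threshold, kcal/mol.
HBOND_ENERGY_CUTOFF = -0.5

#: Reduction of the 8 DSSP labels to the reported classes.  G and I are
#: pooled with coil (3/10- and pi-helix are rare); both readings of
#: "beta-turn/bend" are supported by overriding this map.
DEFAULT_REDUCTION = {
    "H": "alpha_helix",
    "E": "beta_sheet",
    "B": "beta_sheet",
    "T": "beta_turn_bend",
    "S": "beta_turn_bend",
    "G": "coil",
    "I": "coil",
    "C": "coil",
}

CLASS_ORDER = ("alpha_helix", "beta_sheet", "beta_turn_bend", "coil")


def ks_hbond_energy(
    c: np.ndarray, o: np.ndarray, n: np.ndarray, h: np.ndarray
) -> float | np.ndarray:
    """Kabsch-Sander electrostatic H-bond energy (kcal/mol), coordinates in nm.

    ``c``/``o`` belong to the acceptor carbonyl, ``n``/``h`` to the donor
    amide.  Batched over leading axes.
    """
    c, o, n, h = (np.asarray(x, dtype=float) for x in (c, o, n, h))

    def dist_a(p, q):  # nm -> Angstrom
        return 10.0 * np.linalg.norm(p - q, axis=-1)

    r_on, r_ch, r_oh, r_cn = dist_a(o, n), dist_a(c, h), dist_a(o, h), dist_a(c, n)
    if np.any(np.minimum.reduce([r_on, r_ch, r_oh, r_cn]) < 1e-9):
        raise ValueError("coincident atoms in H-bond energy evaluation")
    e = 0.084 * 332.0 * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
    return float(e) if e.ndim == 0 else e


@dataclass
class SecondaryStructureTrace:
    """frames x residues DSSP labels plus the class-reduction map."""

    labels: np.ndarray  # dtype '<U1'
    residue_indices: np.ndarray
    reduction: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_REDUCTION))

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]

    @property
    def n_residues(self) -> int:
        return self.labels.shape[1]

    def reduced(self) -> np.ndarray:
        out = np.empty(self.labels.shape, dtype="<U16")
        for lab, cls in self.reduction.items():
            out[self.labels == lab] = cls
        return out


def _backbone_coords(e: ConformationalEnsemble):
    """Per-residue backbone atom coordinates; errors name the missing atom."""
    top = e.topology
    residues = [
        (c, r)
        for (c, r) in top.residue_ids
        if top.atom_indices(r, c, names={"CA"}).size
    ]
    coords = {}
    for name in ("N", "CA", "C", "O"):
        idx = []
        for c, r in residues:
            a = top.atom_indices(r, c, names={name}, role="backbone")
            if not a.size:
                raise ValueError(f"residue {r} missing backbone atom {name}")
            idx.append(a[0])
        coords[name] = e.coordinates[:, idx]  # frames x nres x 3
    h_idx = []
    for c, r in residues:
        a = top.atom_indices(r, c, names={"H", "HN"}, role="backbone")
        h_idx.append(a[0] if a.size else -1)
    H = np.where(
        np.array(h_idx)[None, :, None] >= 0,
        e.coordinates[:, np.maximum(h_idx, 0)],
        np.nan,
    )
    chains = [c for c, _ in residues]
    resnames = [top.residue_name(r, c) for c, r in residues]
    for k, (c, r) in enumerate(residues):
        is_start = k == 0 or chains[k - 1] != chains[k]
        if h_idx[k] < 0 and resnames[k] != "PRO" and not is_start:
            raise ValueError(f"residue {r} missing amide H (required for assignment)")
    return coords, H, chains, [r for _, r in residues]


def assign_secondary_structure(
    e: ConformationalEnsemble,
    reduction: dict[str, str] | None = None,
    bend_angle: float = 70.0,
    ca_cutoff: float = 0.9,
) -> SecondaryStructureTrace:
    """Assign per-frame DSSP labels {H,G,I,E,B,T,S,C} to every residue.

    ``ca_cutoff`` (nm) prunes residue pairs whose Calpha atoms are too far
    apart to H-bond, as in the original algorithm.
    """
    coords, H, chains, resids = _backbone_coords(e)
    F = e.n_frames
    R = len(resids)
    labels = np.full((F, R), "C", dtype="<U1")

    def same_chain(i: int, j: int) -> bool:
        return chains[i] == chains[j]

    CA = coords["CA"]
    for f in range(F):
        cN, cC, cO, cCA, cH = (
            coords["N"][f],
            coords["C"][f],
            coords["O"][f],
            CA[f],
            H[f],
        )
        # H-bond matrix: hb[i, j] = CO(i) -> NH(j)
        d_ca = np.linalg.norm(cCA[:, None] - cCA[None, :], axis=-1)
        hb = np.zeros((R, R), dtype=bool)
        for i in range(R):
            for j in range(R):
                if i == j or (same_chain(i, j) and abs(resids[i] - resids[j]) < 2):
                    continue
                if d_ca[i, j] > ca_cutoff or np.isnan(cH[j, 0]):
                    continue
                energy = ks_hbond_energy(cC[i], cO[i], cN[j], cH[j])
                hb[i, j] = energy < HBOND_ENERGY_CUTOFF

        def turn(i: int, n: int) -> bool:
            return (
                i + n < R
                and same_chain(i, i + n)
                and resids[i + n] - resids[i] == n
                and hb[i, i + n]
            )

        lab = np.full(R, "C", dtype="<U1")

        def put(i: int, code: str) -> None:
            # priority H > E > B > G > I > T > S
            order = "CSTIGBEH"
            if order.index(code) > order.index(lab[i]):
                lab[i] = code

        # bends first (lowest priority)
        for i in range(2, R - 2):
            if not (same_chain(i - 2, i) and same_chain(i, i + 2)):
                continue
            u = cCA[i] - cCA[i - 2]
            v = cCA[i + 2] - cCA[i]
            cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
            if np.degrees(np.arccos(np.clip(cosang, -1, 1))) > bend_angle:
                put(i, "S")
        # turns
        for n in (3, 4, 5):
            for i in range(R):
                if turn(i, n):
                    for k in range(i + 1, i + n):
                        put(k, "T")
        # bridges and ladders
        bridge = np.zeros((R, R), dtype=bool)
        for i in range(1, R - 1):
            for j in range(1, R - 1):
                if same_chain(i, j) and abs(resids[i] - resids[j]) < 3:
                    continue
                para = (hb[i - 1, j] and hb[j, i + 1]) or (hb[j - 1, i] and hb[i, j + 1])
                anti = (hb[i, j] and hb[j, i]) or (hb[i - 1, j + 1] and hb[j - 1, i + 1])
                if para or anti:
                    bridge[i, j] = True
        in_ladder = np.zeros((R, R), dtype=bool)
        for i in range(R):
            for j in range(R):
                if not bridge[i, j]:
                    continue
                for di, dj in ((1, 1), (1, -1)):
                    i2, j2 = i + di, j + dj
                    if 0 <= i2 < R and 0 <= j2 < R and bridge[i2, j2]:
                        in_ladder[i, j] = in_ladder[i2, j2] = True
        for i in range(R):
            if np.any(in_ladder[i]):
                put(i, "E")
            elif np.any(bridge[i]):
                put(i, "B")
        # helices (highest priority)
        for n, code in ((5, "I"), (3, "G"), (4, "H")):
            for i in range(1, R):
                if turn(i - 1, n) and turn(i, n):
                    for k in range(i, i + n):
                        put(k, code)
        labels[f] = lab

    return SecondaryStructureTrace(
        labels=labels,
        residue_indices=np.asarray(resids),
        reduction=dict(reduction or DEFAULT_REDUCTION),
    )


def ss_fractions(
    trace: SecondaryStructureTrace, per_residue: bool = False
):
    """Fraction of cells per reduced class; sums to 1 including coil.

    Global mode returns a dict class -> fraction; per-residue mode returns a
    classes x residues dict of arrays (averaged over frames only).
    """
    if trace.labels.size == 0:
        raise ValueError("empty trace")
    reduced = trace.reduced()
    if per_residue:
        return {
            cls: (reduced == cls).mean(axis=0) for cls in CLASS_ORDER
        }
    return {cls: float((reduced == cls).mean()) for cls in CLASS_ORDER}
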