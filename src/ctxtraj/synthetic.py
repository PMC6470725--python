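"""Ground-truth synthetic ensembles for every analysis stage.

Real inputs to this package are microsecond MD trajectories; these generators
produce small ensembles whose statistical structure is known exactly, so each
analysis operation can be tested against its generating parameters:

* metastable backbone dynamics: per-residue phi/psi series driven by a hidden
  Markov chain with von Mises emissions, plus NeRF reconstruction of a
  poly-Ala-like backbone so the same ground truth exists in Cartesian form;
* Gaussian fluctuation ensembles about a reference with prescribed (optionally
  low-rank) covariance, for RMSF and essential-subspace recovery;
* solvation scenes with single-site waters at controlled local density around
  tagged atoms, for RDF / hydration-shell statistics;
* ideal alpha-helix and flat antiparallel two-strand beta-sheet geometries for
  secondary-structure assignment.

Every generator takes an explicit integer seed and draws from a single
``numpy.random.Generator``; outputs are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core_io import AtomRecord, ConformationalEnsemble, MolecularTopology
from .dpca import DihedralSeries
from .geometry import place_atom

__all__ = [
    "DihedralStateSpec",
    "MarkovChainSpec",
    "SolvationSceneSpec",
    "BackboneGeometry",
    "LowRankCovariance",
    "gen_markov_dihedrals",
    "rebuild_chain",
    "gen_fluctuation_ensemble",
    "gen_solvation_frames",
    "low_rank_modes",
    "ideal_helix",
    "antiparallel_sheet",
]


# ---------------------------------------------------------------------------
# dihedral state machinery


@dataclass
class DihedralStateSpec:
    """Per-state, per-residue von Mises emission parameters.

    ``phi_means`` and ``psi_means`` are K x m arrays (radians, in (-pi, pi]);
    ``kappa`` is a scalar or K x m array of concentrations (>= 0).
    """

    phi_means: np.ndarray
    psi_means: np.ndarray
    kappa: float | np.ndarray = 50.0

    def __post_init__(self) -> None:
        self.phi_means = np.atleast_2d(np.asarray(self.phi_means, dtype=float))
        self.psi_means = np.atleast_2d(np.asarray(self.psi_means, dtype=float))
        if self.phi_means.shape != self.psi_means.shape:
            raise ValueError("phi_means and psi_means must have the same shape")
        for arr in (self.phi_means, self.psi_means):
            if np.any(arr <= -np.pi) or np.any(arr > np.pi):
                raise ValueError("angle means must lie in (-pi, pi]")
        if np.any(np.asarray(self.kappa) < 0):
            raise ValueError("kappa must be >= 0")

    @property
    def n_states(self) -> int:
        return self.phi_means.shape[0]

    @property
    def n_residues(self) -> int:
        return self.phi_means.shape[1]


@dataclass
class MarkovChainSpec:
    """Row-stochastic transition matrix and initial distribution."""

    transition: np.ndarray
    initial: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        T = self.transition
        if T.ndim != 2 or T.shape[0] != T.shape[1]:
            raise ValueError("transition matrix must be square")
        if np.any(T < 0) or np.any(np.abs(T.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("transition matrix rows must be non-negative and sum to 1")
        if self.initial is None:
            self.initial = self.stationary_distribution()
        else:
            self.initial = np.asarray(self.initial, dtype=float)
            if np.any(self.initial < 0) or abs(self.initial.sum() - 1.0) > 1e-12:
                raise ValueError("initial distribution must be a probability vector")

    @property
    def n_states(self) -> int:
        return self.transition.shape[0]

    def stationary_distribution(self) -> np.ndarray:
        evals, evecs = np.linalg.eig(self.transition.T)
        i = np.argmin(np.abs(evals - 1.0))
        pi = np.real(evecs[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()


def gen_markov_dihedrals(
    states: DihedralStateSpec,
    chain: MarkovChainSpec,
    n_frames: int,
    seed: int,
) -> tuple[DihedralSeries, np.ndarray]:
    """Sample a hidden-state path and von Mises phi/psi emissions.

    Returns the dihedral series and the true state path (for recovery tests).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if states.n_states != chain.n_states:
        raise ValueError("state count mismatch between emission and chain specs")
    rng = np.random.default_rng(seed)
    K = chain.n_states
    path = np.empty(n_frames, dtype=int)
    path[0] = rng.choice(K, p=chain.initial)
    for t in range(1, n_frames):
        path[t] = rng.choice(K, p=chain.transition[path[t - 1]])
    kappa = np.broadcast_to(
        np.asarray(states.kappa, dtype=float), states.phi_means.shape
    )
    phi = rng.vonmises(states.phi_means[path], kappa[path])
    psi = rng.vonmises(states.psi_means[path], kappa[path])
    series = DihedralSeries(
        phi=phi, psi=psi, residue_indices=np.arange(1, states.n_residues + 1)
    )
    return series, path


# ---------------------------------------------------------------------------
# NeRF backbone reconstruction


@dataclass(frozen=True)
class BackboneGeometry:
    """Ideal bond lengths (nm) and angles (degrees) for chain reconstruction."""

    n_ca: float = 0.1458
    ca_c: float = 0.1525
    c_n: float = 0.1329
    c_o: float = 0.1231
    n_h: float = 0.101
    ca_cb: float = 0.153
    cb_h: float = 0.109
    cb_g: float = 0.152
    ang_n_ca_c: float = 111.0
    ang_ca_c_n: float = 116.2
    ang_c_n_ca: float = 121.7
    ang_ca_c_o: float = 120.5
    ang_c_n_h: float = 119.5
    ang_n_ca_cb: float = 110.5
    ang_ca_cb_x: float = 109.5


_GAMMA_ATOM = {"CYS": ("SG", "S", 0.181), "ABU": ("CG", "C", 0.152), "SER": ("OG", "O", 0.143)}


def rebuild_chain(
    d: DihedralSeries,
    geometry: BackboneGeometry | None = None,
    residue_names: list[str] | None = None,
    with_cbeta: bool = False,
    omega: float = math.pi,
    chain_id: str = "A",
    first_residue: int = 1,
    spacing_ns: float = 0.1,
) -> ConformationalEnsemble:
    """Rebuild a Cartesian backbone from phi/psi torsions (NeRF construction).

    The chain is poly-Ala-like: N, H (from residue 2 on; none for Pro), CA, C,
    O per residue, plus optional CB/HB1/HB2 and a gamma atom (SG/CG/OG for
    Cys/Abu/Ser) when ``with_cbeta`` is set.  Omega is fixed (default 180
    degrees).  Extracting phi/psi from the result reproduces the inputs to
    floating-point accuracy.
    """
    g = geometry or BackboneGeometry()
    F, m = d.phi.shape
    names = residue_names or ["ALA"] * m
    if len(names) != m:
        raise ValueError("residue_names length must match residue count")
    rad = np.deg2rad

    N = [None] * m
    CA = [None] * m
    C = [None] * m
    # residue 1 in the xy-plane
    N[0] = np.zeros((F, 3))
    CA[0] = np.tile([g.n_ca, 0.0, 0.0], (F, 1))
    theta = rad(g.ang_n_ca_c)
    C[0] = CA[0] + g.ca_c * np.array([-math.cos(theta), math.sin(theta), 0.0])
    for i in range(1, m):
        N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1], g.c_n, rad(g.ang_ca_c_n), d.psi[:, i - 1])
        CA[i] = place_atom(CA[i - 1], C[i - 1], N[i], g.n_ca, rad(g.ang_c_n_ca), omega)
        C[i] = place_atom(C[i - 1], N[i], CA[i], g.ca_c, rad(g.ang_n_ca_c), d.phi[:, i])

    coords: list[np.ndarray] = []
    records: list[AtomRecord] = []

    def add(name: str, element: str, resid: int, resname: str, xyz: np.ndarray, role: str) -> None:
        records.append(
            AtomRecord(name, element, resid, resname, chain_id=chain_id, role=role)
        )
        coords.append(xyz)

    for i in range(m):
        resid = first_residue + i
        rname = names[i].upper()
        add("N", "N", resid, rname, N[i], "backbone")
        if i > 0 and rname != "PRO":
            O_prev = place_atom(
                N[i - 1], CA[i - 1], C[i - 1], g.c_o, rad(g.ang_ca_c_o), d.psi[:, i - 1] - math.pi
            )
            H = place_atom(O_prev, C[i - 1], N[i], g.n_h, rad(g.ang_c_n_h), math.pi)
            add("H", "H", resid, rname, H, "backbone")
        add("CA", "C", resid, rname, CA[i], "backbone")
        add("C", "C", resid, rname, C[i], "backbone")
        O = place_atom(N[i], CA[i], C[i], g.c_o, rad(g.ang_ca_c_o), d.psi[:, i] - math.pi)
        add("O", "O", resid, rname, O, "backbone")
        if with_cbeta:
            CB = place_atom(C[i], N[i], CA[i], g.ca_cb, rad(g.ang_n_ca_cb), rad(-122.6))
            add("CB", "C", resid, rname, CB, "sidechain")
            HB1 = place_atom(N[i], CA[i], CB, g.cb_h, rad(g.ang_ca_cb_x), rad(60.0))
            HB2 = place_atom(N[i], CA[i], CB, g.cb_h, rad(g.ang_ca_cb_x), rad(-60.0))
            add("HB1", "H", resid, rname, HB1, "sidechain")
            add("HB2", "H", resid, rname, HB2, "sidechain")
            if rname in _GAMMA_ATOM:
                gname, gel, gbond = _GAMMA_ATOM[rname]
                G = place_atom(N[i], CA[i], CB, gbond, rad(114.0), math.pi)
                add(gname, gel, resid, rname, G, "sidechain")

    xyz = np.stack(coords, axis=1)  # frames x atoms x 3
    top = MolecularTopology(atoms=records)
    return ConformationalEnsemble(
        topology=top, coordinates=xyz, times=spacing_ns * np.arange(F, dtype=float)
    )


# ---------------------------------------------------------------------------
# Gaussian fluctuation ensembles


@dataclass
class LowRankCovariance:
    """Low-rank covariance: orthonormal displacement modes with variances."""

    modes: np.ndarray  # d x k, d = 3 * n_atoms
    variances: np.ndarray  # nm^2, k

    def __post_init__(self) -> None:
        self.modes = np.asarray(self.modes, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        if np.any(self.variances < 0):
            raise ValueError("variances must be >= 0 (covariance must be PSD)")
        gram = self.modes.T @ self.modes
        if not np.allclose(gram, np.eye(self.modes.shape[1]), atol=1e-8):
            raise ValueError("modes must have orthonormal columns")


def _rigid_body_modes(reference: np.ndarray) -> np.ndarray:
    """Orthonormal basis of rigid translations and infinitesimal rotations."""
    n = reference.shape[0]
    center = reference - reference.mean(axis=0)
    modes = []
    for ax in range(3):
        t = np.zeros((n, 3))
        t[:, ax] = 1.0
        modes.append(t.ravel())
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = 1.0
        modes.append(np.cross(center, e).ravel())
    M = np.stack(modes, axis=1)
    q, r = np.linalg.qr(M)
    keep = np.abs(np.diag(r)) > 1e-12
    return q[:, keep]


def low_rank_modes(
    reference: np.ndarray, rank: int, seed: int, remove_rigid: bool = True
) -> np.ndarray:
    """Random orthonormal displacement modes, orthogonal to rigid-body motion.

    Useful for building :class:`LowRankCovariance` specs whose modes survive
    superposition unchanged.
    """
    reference = np.asarray(reference, dtype=float)
    d = 3 * reference.shape[0]
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((d, rank))
    if remove_rigid:
        rb = _rigid_body_modes(reference)
        raw -= rb @ (rb.T @ raw)
    q, _ = np.linalg.qr(raw)
    return q[:, :rank]


def gen_fluctuation_ensemble(
    reference: np.ndarray,
    covariance: float | np.ndarray | LowRankCovariance,
    n_frames: int,
    seed: int,
    topology: MolecularTopology | None = None,
    spacing_ns: float = 0.1,
) -> ConformationalEnsemble:
    """Sample frames ~ N(reference, covariance).

    ``covariance`` is a scalar sigma (nm; isotropic per coordinate), an
    n_atoms x 3 x 3 per-atom covariance stack, or a :class:`LowRankCovariance`.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.ndim != 2 or reference.shape[1] != 3:
        raise ValueError("reference must be n_atoms x 3")
    n = reference.shape[0]
    rng = np.random.default_rng(seed)
    if isinstance(covariance, LowRankCovariance):
        if covariance.modes.shape[0] != 3 * n:
            raise ValueError("mode dimension must equal 3 * n_atoms")
        z = rng.standard_normal((n_frames, covariance.variances.size))
        disp = (z * np.sqrt(covariance.variances)) @ covariance.modes.T
        xyz = reference[None] + disp.reshape(n_frames, n, 3)
    elif np.isscalar(covariance):
        sigma = float(covariance)
        if sigma < 0:
            raise ValueError("sigma must be >= 0")
        xyz = reference[None] + sigma * rng.standard_normal((n_frames, n, 3))
    else:
        cov = np.asarray(covariance, dtype=float)
        if cov.shape != (n, 3, 3):
            raise ValueError("per-atom covariance must be n_atoms x 3 x 3")
        evals, evecs = np.linalg.eigh(cov)
        if np.any(evals < -1e-10):
            raise ValueError("covariance must be positive semidefinite")
        evals = np.clip(evals, 0.0, None)
        L = evecs * np.sqrt(evals)[:, None, :]  # per-atom factor
        z = rng.standard_normal((n_frames, n, 3))
        xyz = reference[None] + np.einsum("aij,faj->fai", L, z)
    if topology is None:
        topology = _point_topology(n)
    return ConformationalEnsemble(
        topology=topology,
        coordinates=xyz,
        times=spacing_ns * np.arange(n_frames, dtype=float),
    )


def _point_topology(n_atoms: int) -> MolecularTopology:
    """A minimal Calpha-trace topology: one Ca pseudo-atom per residue."""
    atoms = [
        AtomRecord("CA", "C", i + 1, "ALA", chain_id="A", role="backbone")
        for i in range(n_atoms)
    ]
    return MolecularTopology(atoms=atoms)


# ---------------------------------------------------------------------------
# solvation scenes


@dataclass
class SolvationSceneSpec:
    """Solute plus single-site waters at controlled local density.

    Waters are placed uniformly at ``bulk_density`` (nm^-3) outside an
    exclusion radius around every solute atom; within ``shell_radius`` of each
    tagged atom, density is ``multiplier`` times bulk.
    """

    solute_coords: np.ndarray
    box: np.ndarray  # orthorhombic lengths, nm
    bulk_density: float = 33.0  # bulk water number density at ambient conditions
    tagged: tuple[int, ...] = ()
    multiplier: float = 1.0
    exclusion_radius: float = 0.0
    shell_radius: float = 0.5

    def __post_init__(self) -> None:
        self.solute_coords = np.atleast_2d(np.asarray(self.solute_coords, dtype=float))
        self.box = np.asarray(self.box, dtype=float)
        if self.bulk_density < 0 or self.multiplier < 0:
            raise ValueError("densities must be >= 0")
        if self.exclusion_radius < 0:
            raise ValueError("exclusion radius must be >= 0")
        for t in self.tagged:
            lo = self.solute_coords[t] - self.shell_radius
            hi = self.solute_coords[t] + self.shell_radius
            if np.any(lo < 0) or np.any(hi > self.box):
                raise ValueError(
                    f"shell of tagged atom {t} does not fit inside the box"
                )


def gen_solvation_frames(
    spec: SolvationSceneSpec, n_frames: int, seed: int, spacing_ns: float = 0.1
) -> ConformationalEnsemble:
    """Sample solvated frames with a fixed water count per frame.

    The total count is apportioned per frame between the bulk region and the
    tagged shells (multinomial with weights proportional to region volume x
    density multiplier), so shell occupancies follow the prescribed local
    density while the frame-to-frame atom count stays constant.
    """
    rng = np.random.default_rng(seed)
    S = spec.solute_coords
    V_box = float(np.prod(spec.box))
    r_ex = spec.exclusion_radius
    r_sh = spec.shell_radius
    v_sphere = lambda r: 4.0 / 3.0 * math.pi * r**3  # noqa: E731
    v_shell = max(v_sphere(r_sh) - v_sphere(min(r_ex, r_sh)), 0.0)
    n_tag = len(spec.tagged)
    untagged = [i for i in range(S.shape[0]) if i not in spec.tagged]
    v_bulk = V_box - n_tag * v_sphere(r_sh) - len(untagged) * v_sphere(r_ex)
    if v_bulk <= 0:
        raise ValueError("exclusion/shell volumes exceed the box volume")
    weights = np.array([spec.bulk_density * v_bulk] + [
        spec.multiplier * spec.bulk_density * v_shell for _ in spec.tagged
    ])
    n_waters = int(round(weights.sum()))
    if n_waters == 0:
        raise ValueError("scene contains no waters; increase density or box")
    probs = weights / weights.sum()

    def sample_bulk(k: int) -> np.ndarray:
        out = np.empty((k, 3))
        filled = 0
        while filled < k:
            cand = rng.uniform(0.0, spec.box, size=(max(2 * (k - filled), 16), 3))
            ok = np.ones(len(cand), dtype=bool)
            for j, atom in enumerate(S):
                dist = np.linalg.norm(cand - atom, axis=1)
                cut = r_sh if j in spec.tagged else r_ex
                ok &= dist > cut
            good = cand[ok]
            take = min(len(good), k - filled)
            out[filled : filled + take] = good[:take]
            filled += take
        return out

    def sample_shell(center: np.ndarray, k: int) -> np.ndarray:
        out = np.empty((k, 3))
        filled = 0
        r_lo3 = min(r_ex, r_sh) ** 3
        while filled < k:
            m = max(2 * (k - filled), 16)
            u = rng.uniform(size=m)
            r = (r_lo3 + u * (r_sh**3 - r_lo3)) ** (1.0 / 3.0)
            v = rng.standard_normal((m, 3))
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            cand = center + r[:, None] * v
            ok = np.all(cand >= 0, axis=1) & np.all(cand <= spec.box, axis=1)
            for j, atom in enumerate(S):
                if np.array_equal(atom, center):
                    continue
                ok &= np.linalg.norm(cand - atom, axis=1) > r_ex
            good = cand[ok]
            take = min(len(good), k - filled)
            out[filled : filled + take] = good[:take]
            filled += take
        return out

    frames = np.empty((n_frames, S.shape[0] + n_waters, 3))
    frames[:, : S.shape[0]] = S
    for f in range(n_frames):
        counts = rng.multinomial(n_waters, probs)
        placed = [sample_bulk(counts[0])]
        for t_idx, t in enumerate(spec.tagged):
            placed.append(sample_shell(S[t], counts[1 + t_idx]))
        frames[f, S.shape[0] :] = np.concatenate(placed, axis=0)

    atoms = [
        AtomRecord(f"C{i + 1}", "C", 1, "ALA", chain_id="A", role="sidechain")
        for i in range(S.shape[0])
    ]
    for w in range(n_waters):
        atoms.append(
            AtomRecord("O", "O", 2 + w, "HOH", chain_id="W", role="solvent")
        )
    top = MolecularTopology(atoms=atoms)
    return ConformationalEnsemble(
        topology=top,
        coordinates=frames,
        times=spacing_ns * np.arange(n_frames, dtype=float),
        box=spec.box,
    )


# ---------------------------------------------------------------------------
# reference secondary-structure geometries


def ideal_helix(
    n_residues: int = 12, n_frames: int = 1, with_cbeta: bool = False
) -> ConformationalEnsemble:
    """Ideal alpha-helix: every residue at (phi, psi) = (-57, -47) degrees."""
    phi = np.full((n_frames, n_residues), np.deg2rad(-57.0))
    psi = np.full((n_frames, n_residues), np.deg2rad(-47.0))
    d = DihedralSeries(phi=phi, psi=psi, residue_indices=np.arange(1, n_residues + 1))
    return rebuild_chain(d, with_cbeta=with_cbeta)


def antiparallel_sheet(
    n_residues: int = 6,
    separations: np.ndarray | None = None,
    offsets: np.ndarray | None = None,
) -> ConformationalEnsemble:
    """Two antiparallel fully extended strands paired by backbone H-bonds.

    Strand A is built flat in the xy-plane (phi = psi = 180 degrees); strand B
    is its 180-degree rotation about z through the centroid, translated to the
    inter-strand separation and registry shift that maximize the number of
    Kabsch-Sander H-bonds (deterministic grid search).
    """
    from .secondary_structure import ks_hbond_energy, HBOND_ENERGY_CUTOFF

    phi = np.full((1, n_residues), np.pi)
    psi = np.full((1, n_residues), np.pi)
    d = DihedralSeries(phi=phi, psi=psi, residue_indices=np.arange(1, n_residues + 1))
    strand = rebuild_chain(d)
    A = strand.coordinates[0]
    centroid = A.mean(axis=0)
    B0 = A.copy()
    B0[:, 0] = 2 * centroid[0] - B0[:, 0]
    B0[:, 1] = 2 * centroid[1] - B0[:, 1]

    top = strand.topology

    def atom(resid: int, name: str, X: np.ndarray) -> np.ndarray | None:
        idx = top.atom_indices(resid, names={name})
        return X[idx[0]] if idx.size else None

    def count_bonds(B: np.ndarray) -> tuple[int, float]:
        n_bonds, e_tot = 0, 0.0
        for i in range(1, n_residues + 1):
            for j in range(1, n_residues + 1):
                for acc, don in ((A, B), (B, A)):
                    c, o = atom(i, "C", acc), atom(i, "O", acc)
                    n_, h = atom(j, "N", don), atom(j, "H", don)
                    if h is None:
                        continue
                    e = ks_hbond_energy(c, o, n_, h)
                    if e < HBOND_ENERGY_CUTOFF:
                        n_bonds += 1
                        e_tot += e
        return n_bonds, e_tot

    if separations is None:
        separations = np.arange(0.40, 0.60, 0.01)
    if offsets is None:
        offsets = np.arange(-0.40, 0.40, 0.02)
    best = None
    for sep in separations:
        for off in offsets:
            B = B0 + np.array([off, sep, 0.0])
            # reject sterically clashed placements (closest approach should be
            # a normal H...O hydrogen bond, ~0.19 nm)
            d_min = np.min(
                np.linalg.norm(A[:, None, :] - B[None, :, :], axis=-1)
            )
            if d_min < 0.17:
                continue
            nb, et = count_bonds(B)
            key = (-nb, et)
            if best is None or key < best[0]:
                best = (key, B)
    if best is None:
        raise RuntimeError("no clash-free strand placement found")
    B = best[1]

    atoms = list(top.atoms) + [
        AtomRecord(
            a.atom_name,
            a.element,
            a.residue_index + n_residues,
            a.residue_name,
            chain_id="B",
            role=a.role,
        )
        for a in top.atoms
    ]
    coords = np.concatenate([A, B], axis=0)[None]
    return ConformationalEnsemble(
        topology=MolecularTopology(atoms=atoms),
        coordinates=coords,
        times=np.array([0.0]),
    )
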