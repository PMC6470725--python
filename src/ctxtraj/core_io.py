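"""Structures, ensembles and selections.

Internal units are nm for coordinates and ns for time throughout the package.
PDB/GRO/XTC parsing and writing are delegated to :mod:`mdtraj`; this module
owns the domain model (atom roles, author-style 1-based residue numbering,
validation) and the equilibration-discard/stride preprocessing applied to
every trajectory before analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "AtomRecord",
    "MolecularTopology",
    "ConformationalEnsemble",
    "StructureParseError",
    "read_structure",
    "read_ensemble",
    "write_ensemble",
    "preprocess_ensemble",
    "select",
]

#: Backbone atom names (amide H may be written H or HN depending on the source).
BACKBONE_ATOMS = {"N", "CA", "C", "O", "H", "HN", "OXT"}

#: Residue names recognized as solvent (single-site or multi-site water models).
SOLVENT_RESIDUES = {"HOH", "SOL", "WAT", "TIP3"}

#: Residue names recognized as monatomic ions.
ION_RESIDUES = {"NA", "CL", "K", "MG", "ZN", "CA2", "NA+", "CL-"}

_STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    # L-alpha-aminobutyric acid, the isosteric Cys replacement
    "ABU",
}


class StructureParseError(ValueError):
    """Raised when a structure or trajectory file fails validation."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the molecular topology."""

    atom_name: str
    element: str
    residue_index: int  # 1-based, author numbering
    residue_name: str
    chain_id: str = "A"
    role: str = "sidechain"  # backbone | sidechain | solvent | ion


@dataclass
class MolecularTopology:
    """Ordered atoms plus a derived residue index and disulfide annotations."""

    atoms: list[AtomRecord]
    disulfide_pairs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for i, j in self.disulfide_pairs:
            for r in (i, j):
                if self.residue_name(r) != "CYS":
                    raise ValueError(
                        f"disulfide pair ({i}, {j}) references non-Cys residue {r}"
                    )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def residue_ids(self) -> list[tuple[str, int]]:
        """Ordered unique (chain_id, residue_index) pairs."""
        seen: dict[tuple[str, int], None] = {}
        for a in self.atoms:
            seen.setdefault((a.chain_id, a.residue_index), None)
        return list(seen)

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)

    def residue_name(self, residue_index: int, chain_id: str | None = None) -> str:
        for a in self.atoms:
            if a.residue_index == residue_index and (
                chain_id is None or a.chain_id == chain_id
            ):
                return a.residue_name
        raise KeyError(f"no residue {residue_index}")

    def atom_indices(
        self,
        residue_index: int | None = None,
        chain_id: str | None = None,
        names: set[str] | None = None,
        role: str | None = None,
    ) -> np.ndarray:
        idx = [
            k
            for k, a in enumerate(self.atoms)
            if (residue_index is None or a.residue_index == residue_index)
            and (chain_id is None or a.chain_id == chain_id)
            and (names is None or a.atom_name in names)
            and (role is None or a.role == role)
        ]
        return np.asarray(idx, dtype=int)

    def heavy_indices(self, residue_index: int, role: str | None = None) -> np.ndarray:
        idx = [
            k
            for k, a in enumerate(self.atoms)
            if a.residue_index == residue_index
            and a.element != "H"
            and (role is None or a.role == role)
        ]
        return np.asarray(idx, dtype=int)


@dataclass
class ConformationalEnsemble:
    """frames x atoms x 3 coordinates (nm) with strictly increasing times (ns)."""

    topology: MolecularTopology
    coordinates: np.ndarray
    times: np.ndarray
    box: np.ndarray | None = None  # orthorhombic lengths (nm), optional

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must be frames x atoms x 3")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise StructureParseError(
                f"atom-count mismatch: topology has {self.topology.n_atoms} atoms, "
                f"coordinates have {self.coordinates.shape[1]}"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates")
        self.times = np.asarray(self.times, dtype=float)
        if self.times.shape != (self.coordinates.shape[0],):
            raise ValueError("times must have one entry per frame")
        if self.n_frames > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]


# ---------------------------------------------------------------------------
# role assignment and mdtraj conversion


def _assign_role(atom_name: str, residue_name: str) -> str:
    if residue_name in SOLVENT_RESIDUES:
        return "solvent"
    if residue_name in ION_RESIDUES:
        return "ion"
    if atom_name in BACKBONE_ATOMS:
        return "backbone"
    return "backbone" if atom_name in {"H1", "H2", "H3"} else "sidechain"


def _element_of(md_atom) -> str:
    sym = md_atom.element.symbol if md_atom.element is not None else ""
    if not sym or sym == "VS":
        sym = md_atom.name.strip()[0]
    return sym


def _topology_from_mdtraj(mdtop) -> MolecularTopology:
    records = []
    for chain in mdtop.chains:
        chain_id = chr(ord("A") + (chain.index % 26))
        for res in chain.residues:
            rname = res.name.upper()
            if rname not in _STANDARD_AA | SOLVENT_RESIDUES | ION_RESIDUES:
                raise StructureParseError(f"unknown residue name: {rname!r}")
            for atom in res.atoms:
                records.append(
                    AtomRecord(
                        atom_name=atom.name,
                        element=_element_of(atom),
                        residue_index=res.index + 1,
                        residue_name=rname,
                        chain_id=chain_id,
                        role=_assign_role(atom.name, rname),
                    )
                )
    return MolecularTopology(atoms=records)


def _topology_to_mdtraj(top: MolecularTopology):
    import mdtraj as md
    from mdtraj.core import element as elem

    mdtop = md.Topology()
    chain = None
    res = None
    current: tuple[str, int] | None = None
    current_chain: str | None = None
    for a in top.atoms:
        if a.chain_id != current_chain:
            chain = mdtop.add_chain()
            current_chain = a.chain_id
            current = None
        if (a.chain_id, a.residue_index) != current:
            res = mdtop.add_residue(a.residue_name, chain, resSeq=a.residue_index)
            current = (a.chain_id, a.residue_index)
        try:
            e = elem.get_by_symbol(a.element)
        except KeyError:
            e = elem.virtual
        mdtop.add_atom(a.atom_name, e, res)
    return mdtop


# ---------------------------------------------------------------------------
# readers / writers


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = Path(path).suffix.lower().lstrip(".")
    return suffix or "pdb"


def read_structure(
    path: str | Path, format: str | None = None
) -> tuple[MolecularTopology, np.ndarray]:
    """Read a PDB or GRO file; return the topology and first-frame nm coordinates.

    Multi-model PDB files are accepted; the model count is available by reading
    the file as an ensemble via :func:`read_ensemble`.
    """
    import mdtraj as md

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt not in {"pdb", "gro"}:
        raise ValueError(f"unsupported structure format: {fmt}")
    try:
        if fmt == "pdb":
            traj = md.load_pdb(str(path), standard_names=False)
        else:
            traj = md.load(str(path))
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise StructureParseError(f"failed to parse {path.name}: {exc}") from exc
    top = _topology_from_mdtraj(traj.topology)
    return top, np.array(traj.xyz[0], dtype=float)


def read_ensemble(
    path: str | Path,
    topology: MolecularTopology | None = None,
    dt_ns: float = 0.1,
    topology_path: str | Path | None = None,
) -> ConformationalEnsemble:
    """Load a multi-model PDB or XTC-style trajectory as an ensemble.

    ``dt_ns`` is the frame spacing used when the file carries no usable time
    information (multi-model PDB); XTC times are taken from the file.
    """
    import mdtraj as md

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, None)
    try:
        if fmt == "pdb":
            traj = md.load_pdb(str(path), standard_names=False)
        elif fmt == "gro":
            traj = md.load(str(path))
        elif topology_path is not None:
            traj = md.load(str(path), top=str(topology_path))
        else:
            raise ValueError(
                f"trajectory format {fmt!r} requires topology_path for atom metadata"
            )
    except StructureParseError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StructureParseError(f"failed to parse {path.name}: {exc}") from exc
    top = topology if topology is not None else _topology_from_mdtraj(traj.topology)
    if traj.n_atoms != top.n_atoms:
        raise StructureParseError(
            f"atom-count mismatch: expected {top.n_atoms}, found {traj.n_atoms}"
        )
    times_ns = np.asarray(traj.time, dtype=float) / 1000.0  # mdtraj uses ps
    if fmt == "pdb" or (
        traj.n_frames > 1 and not np.all(np.diff(times_ns) > 0)
    ):
        # the PDB format carries no time axis; synthesize from dt_ns
        times_ns = dt_ns * np.arange(traj.n_frames, dtype=float)
    box = None
    if traj.unitcell_lengths is not None:
        box = np.array(traj.unitcell_lengths[0], dtype=float)
    ens = ConformationalEnsemble(
        topology=top,
        coordinates=np.array(traj.xyz, dtype=float),
        times=times_ns,
        box=box,
    )
    if box is not None:
        _assert_whole_molecule(ens)
    return ens


def _assert_whole_molecule(e: ConformationalEnsemble, max_bond: float = 0.25) -> None:
    """Reject wrapped molecules: any peptide bond longer than ``max_bond`` nm.

    The package assumes whole, unwrapped molecules; re-imaging is out of scope.
    """
    top = e.topology
    for chain_id, resid in top.residue_ids:
        c_i = top.atom_indices(resid, chain_id, names={"C"}, role="backbone")
        n_next = top.atom_indices(resid + 1, chain_id, names={"N"}, role="backbone")
        if c_i.size and n_next.size:
            d = np.linalg.norm(
                e.coordinates[0, c_i[0]] - e.coordinates[0, n_next[0]]
            )
            if d > max_bond:
                raise StructureParseError(
                    f"broken molecule: peptide bond {resid}-{resid + 1} is "
                    f"{d:.3f} nm (> {max_bond} nm); re-image before loading"
                )


def write_ensemble(path: str | Path, e: ConformationalEnsemble) -> None:
    """Write an ensemble as multi-model PDB or XTC, inferred from the suffix."""
    import mdtraj as md

    mdtop = _topology_to_mdtraj(e.topology)
    kwargs = {}
    if e.box is not None:
        n = e.n_frames
        kwargs["unitcell_lengths"] = np.tile(e.box, (n, 1))
        kwargs["unitcell_angles"] = np.full((n, 3), 90.0)
    traj = md.Trajectory(
        xyz=e.coordinates.astype(np.float32),
        topology=mdtop,
        time=e.times * 1000.0,
        **kwargs,
    )
    traj.save(str(path))


# ---------------------------------------------------------------------------
# preprocessing


def preprocess_ensemble(
    e: ConformationalEnsemble, discard: float = 200.0, stride: float = 0.1
) -> ConformationalEnsemble:
    """Drop the equilibration segment and subsample at a fixed stride.

    ``discard`` (ns): frames with time <= discard are removed.  ``stride``
    (ns): must be an integer multiple of the native frame spacing; every
    k-th surviving frame is kept, starting with the first one.
    """
    if discard < 0:
        raise ValueError("discard must be >= 0")
    if stride <= 0:
        raise ValueError("stride must be > 0")
    keep = e.times > discard + 1e-9  # tolerance for accumulated float spacing
    if not np.any(keep):
        raise ValueError(
            f"discard of {discard} ns removes all {e.n_frames} frames "
            f"(trajectory ends at {e.times[-1]} ns)"
        )
    times = e.times[keep]
    if times.size > 1:
        native = float(np.min(np.diff(times)))
        ratio = stride / native
        k = int(round(ratio))
        if k < 1 or abs(ratio - k) > 1e-6:
            raise ValueError(
                f"stride {stride} ns is not an integer multiple of the native "
                f"frame spacing {native} ns"
            )
    else:
        k = 1
    idx = np.flatnonzero(keep)[::k]
    return replace(
        e,
        coordinates=e.coordinates[idx],
        times=e.times[idx],
    )


# ---------------------------------------------------------------------------
# selections


def select(top: MolecularTopology, expression: str) -> np.ndarray:
    """Resolve a selection expression to atom indices.

    Grammar: clauses joined by ``and``; each clause is one of
    ``resid A-B`` / ``resid A`` (1-based, inclusive), ``name N1 N2 ...``,
    or a role keyword (``backbone``, ``sidechain``, ``solvent``, ``ion``,
    ``protein``).  Example: ``"resid 2-35 and backbone"``.
    """
    mask = np.ones(top.n_atoms, dtype=bool)
    clauses = [c.strip() for c in expression.split(" and ")]
    for clause in clauses:
        if not clause:
            continue
        tokens = clause.split()
        key = tokens[0].lower()
        if key == "resid":
            sel = np.zeros(top.n_atoms, dtype=bool)
            for spec in tokens[1:]:
                if "-" in spec:
                    lo, hi = (int(x) for x in spec.split("-"))
                else:
                    lo = hi = int(spec)
                for i, a in enumerate(top.atoms):
                    if lo <= a.residue_index <= hi:
                        sel[i] = True
            mask &= sel
        elif key == "name":
            wanted = set(tokens[1:])
            mask &= np.array([a.atom_name in wanted for a in top.atoms])
        elif key in {"backbone", "sidechain", "solvent", "ion"}:
            mask &= np.array([a.role == key for a in top.atoms])
        elif key == "protein":
            mask &= np.array(
                [a.role in {"backbone", "sidechain"} for a in top.atoms]
            )
        else:
            raise ValueError(f"unknown selection clause: {clause!r}")
    return np.flatnonzero(mask)


def ca_indices(
    top: MolecularTopology, residues: tuple[int, int] | None = None
) -> np.ndarray:
    """Atom indices of Calpha atoms, optionally restricted to a 1-based
    inclusive residue range."""
    idx = [
        k
        for k, a in enumerate(top.atoms)
        if a.atom_name == "CA"
        and a.role == "backbone"
        and (residues is None or residues[0] <= a.residue_index <= residues[1])
    ]
    return np.asarray(idx, dtype=int)
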