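"""End-to-end per-peptide analysis and pairwise comparison bundles.

``run_analysis`` orchestrates the full trajectory-analysis layer on one
ensemble: preprocessing, RMSD/RMSF, secondary-structure fractions, contact
maps and H-bonds, optional CbetaHbeta pair statistics, optional solvation,
dihedral PCA with free-energy landscape, basin clustering and lowest-energy
conformer extraction.  Outputs are plain CSV/JSON plus a multi-model PDB of
representative conformers, with a manifest recording the configuration hash
and seed so identical runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import core_io, contacts, dpca, essential, secondary_structure, solvation, superposition

logger = logging.getLogger("ctxtraj")


@dataclass
class AnalysisConfig:
    """Analysis parameters; defaults follow the study conditions."""

    trajectory: str = ""
    topology: str | None = None
    reference: str | None = None  # external reference structure (PDB)
    name: str = "peptide"
    discard_ns: float = 0.0
    stride_ns: float | None = None
    dihedral_residues: tuple[int, int] | None = None  # default: 2..n-1
    contact_cutoff: float = 0.5  # nm
    hbond_r_cut: float = 0.35  # nm
    hbond_ang_cut: float = 30.0  # degrees
    sasa_probe: float = 0.14  # nm
    sasa_points: int = 1000
    shell_radius: float = 0.5  # nm
    cbeta_threshold: float = contacts.CBETA_CONTACT_THRESHOLD  # nm
    cbeta_pairs: list[tuple[int, int]] = field(default_factory=list)
    temperature: float = dpca.DEFAULT_TEMPERATURE  # K
    n_eigenvectors: int = 10
    fel_bins: int = 100
    k_candidates: tuple[int, ...] = (2, 3, 4, 5)
    seed: int = 0
    out_dir: str = "analysis_out"


def _config_hash(config: AnalysisConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _save_matrix_csv(path: Path, matrix: np.ndarray, labels) -> None:
    pd.DataFrame(matrix, index=labels, columns=labels).to_csv(path, float_format="%.6f")


def run_analysis(
    config: AnalysisConfig, ensemble: core_io.ConformationalEnsemble | None = None
) -> dict:
    """Run every analysis stage; returns the manifest dictionary.

    ``ensemble`` may be passed directly (e.g. freshly simulated) instead of
    ``config.trajectory``.  Stage failures are logged and recorded in the
    manifest; the remaining stages still run.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "name": config.name,
        "config": dataclasses.asdict(config),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
    }

    if ensemble is None:
        if not config.trajectory:
            raise ValueError("no input: set config.trajectory or pass an ensemble")
        if not Path(config.trajectory).exists():
            raise FileNotFoundError(config.trajectory)
        ensemble = core_io.read_ensemble(
            config.trajectory, topology_path=config.topology
        )
    if config.discard_ns > 0 or config.stride_ns is not None:
        native = (
            float(np.min(np.diff(ensemble.times)))
            if ensemble.n_frames > 1
            else 0.1
        )
        ensemble = core_io.preprocess_ensemble(
            ensemble, discard=config.discard_ns, stride=config.stride_ns or native
        )
    manifest["n_frames"] = ensemble.n_frames
    ca = core_io.ca_indices(ensemble.topology)
    summary: dict = {"name": config.name, "n_frames": ensemble.n_frames}

    def stage(label):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                fn()
                manifest["stages"][label] = {"status": "ok"}
            except Exception as exc:  # noqa: BLE001 - partial bundles are a contract
                logger.exception("stage %s failed", label)
                manifest["stages"][label] = {"status": "failed", "error": str(exc)}
            manifest["stages"][label]["seconds"] = round(
                time.perf_counter() - t0, 3
            )

        return wrap

    @stage("rmsd")
    def _rmsd():
        avg, _ = superposition.mean_structure(ensemble, selection=ca)
        series, mean, sd = superposition.rmsd_series(ensemble, avg, selection=ca)
        df = pd.DataFrame({"time_ns": ensemble.times, "rmsd_avg_nm": series})
        summary["rmsd_avg_nm"] = round(mean, 4)
        summary["rmsd_avg_sd_nm"] = round(sd, 4)
        if config.reference:
            top_ref, xyz_ref = core_io.read_structure(config.reference)
            ca_ref = core_io.ca_indices(top_ref)
            series_ref, mean_r, sd_r = superposition.rmsd_series(
                ensemble, xyz_ref[ca_ref], selection=ca
            )
            df["rmsd_ref_nm"] = series_ref
            summary["rmsd_ref_nm"] = round(mean_r, 4)
            summary["rmsd_ref_sd_nm"] = round(sd_r, 4)
        df.to_csv(out / "rmsd_series.csv", index=False, float_format="%.6f")

    @stage("rmsf")
    def _rmsf():
        values = superposition.rmsf(ensemble, selection=ca)
        resids = [ensemble.topology.atoms[i].residue_index for i in ca]
        pd.DataFrame({"residue": resids, "rmsf_nm": values}).to_csv(
            out / "rmsf.csv", index=False, float_format="%.6f"
        )

    @stage("secondary_structure")
    def _ss():
        trace = secondary_structure.assign_secondary_structure(ensemble)
        fractions = secondary_structure.ss_fractions(trace)
        summary.update({f"rho_{k}": round(v, 4) for k, v in fractions.items()})
        per_res = secondary_structure.ss_fractions(trace, per_residue=True)
        df = pd.DataFrame(per_res)
        df.insert(0, "residue", trace.residue_indices)
        df.to_csv(out / "ss_per_residue.csv", index=False, float_format="%.6f")

    @stage("contacts")
    def _contacts():
        for mode, fname in (("BB-BB", "contacts_bb.csv"), ("SC-SC", "contacts_sc.csv")):
            cmap = contacts.contact_map(
                ensemble, mode=mode, cutoff=config.contact_cutoff
            )
            _save_matrix_csv(out / fname, cmap.probabilities, cmap.residue_indices)

    @stage("hbonds")
    def _hbonds():
        bonds = contacts.hbonds(
            ensemble, r_cut=config.hbond_r_cut, ang_cut=config.hbond_ang_cut
        )
        pd.DataFrame(
            [
                {
                    "donor_residue": b.donor_residue,
                    "donor_atom": b.donor_atom,
                    "acceptor_residue": b.acceptor_residue,
                    "acceptor_atom": b.acceptor_atom,
                    "occupancy": b.occupancy,
                }
                for b in sorted(
                    bonds, key=lambda b: (-b.occupancy, b.donor_residue)
                )
            ]
        ).to_csv(out / "hbonds.csv", index=False, float_format="%.6f")

    if config.cbeta_pairs:

        @stage("cbeta_com")
        def _cbeta():
            rows = []
            for pair in config.cbeta_pairs:
                st = contacts.cbeta_com_stat(
                    ensemble, tuple(pair), threshold=config.cbeta_threshold
                )
                rows.append(
                    {
                        "residue_i": pair[0],
                        "residue_j": pair[1],
                        "D_mean_nm": round(st.mean, 4),
                        "D_sd_nm": round(st.sd, 4),
                        "rho_contact": round(st.probability, 4),
                        "threshold_nm": st.threshold,
                    }
                )
            pd.DataFrame(rows).to_csv(out / "cbeta_com.csv", index=False)

    has_solvent = any(a.role == "solvent" for a in ensemble.topology.atoms)
    if has_solvent:

        @stage("solvation")
        def _solvation():
            areas = solvation.sasa(
                ensemble, probe=config.sasa_probe, n_points=config.sasa_points
            )
            resids = sorted(
                {
                    a.residue_index
                    for a in ensemble.topology.atoms
                    if a.role in {"backbone", "sidechain"}
                }
            )
            df = pd.DataFrame({"residue": resids, "sasa_nm2": areas})
            df.to_csv(out / "solvation.csv", index=False, float_format="%.6f")

    @stage("dpca_fel")
    def _dpca():
        series = dpca.extract_dihedrals(ensemble, residues=config.dihedral_residues)
        X = dpca.dpca_encode(series)
        model = dpca.pca(X)
        proj = model.project(X, n_components=2)
        grid = dpca.free_energy_landscape(
            proj, n_bins=config.fel_bins, temperature=config.temperature
        )
        np.savetxt(out / "fel_delta_g.csv", grid.delta_g, delimiter=",", fmt="%.6f")
        np.savetxt(out / "fel_counts.csv", grid.counts, delimiter=",", fmt="%d")
        models, best_k = dpca.cluster_landscape(
            proj, k_candidates=config.k_candidates, seed=config.seed
        )
        pd.DataFrame(
            [
                {"k": k, "sse": m.sse, "avg_silhouette_width": m.silhouette_width}
                for k, m in sorted(models.items())
            ]
        ).to_csv(out / "cluster_diagnostics.csv", index=False, float_format="%.6f")
        chosen = models[best_k]
        pd.DataFrame(
            {
                "frame": np.arange(len(chosen.assignments)),
                "cluster": chosen.assignments,
                "delta_g_kj_mol": np.round(grid.delta_g_of(proj), 6),
            }
        ).to_csv(out / "cluster_assignments.csv", index=False)
        confs = dpca.representative_conformations(chosen, grid, proj)
        pd.DataFrame(
            [
                {
                    "rank": c.rank,
                    "cluster": c.cluster,
                    "frame": c.frame_index,
                    "delta_g_kj_mol": round(c.delta_g, 6),
                }
            for c in confs
            ]
        ).to_csv(out / "conformers.csv", index=False)
        if confs:
            frames = [c.frame_index for c in confs]
            sub = dataclasses.replace(
                ensemble,
                coordinates=ensemble.coordinates[frames],
                times=np.arange(len(frames), dtype=float),
            )
            core_io.write_ensemble(out / "conformers.pdb", sub)
        summary["best_k"] = best_k
        summary["dpc1_variance"] = round(float(model.eigenvalues[0]), 6)
        summary["dpc2_variance"] = round(float(model.eigenvalues[1]), 6)

    pd.DataFrame([summary]).to_csv(out / "summary.csv", index=False)
    manifest["versions"] = _versions()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest


def _versions() -> dict:
    import sklearn

    from . import __version__

    return {
        "ctxtraj": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
    }


def compare_ensembles(
    ensembles: dict[str, core_io.ConformationalEnsemble],
    n_vectors: int = 10,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Pairwise RMSIP and nRMSIP across named ensembles, with the four-class
    overlap labels; optionally written as CSV."""
    names = list(ensembles)
    ens = [ensembles[n] for n in names]
    raw = essential.overlap_matrix(ens, n_vectors=n_vectors, normalized=False)
    norm = essential.overlap_matrix(ens, n_vectors=n_vectors, normalized=True)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append(
                {
                    "a": names[i],
                    "b": names[j],
                    "rmsip": round(float(raw[i, j]), 4),
                    "nrmsip": round(float(norm[i, j]), 4),
                    "overlap_class": essential.classify_overlap(float(norm[i, j])),
                }
            )
    df = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _save_matrix_csv(out / "rmsip_matrix.csv", raw, names)
        _save_matrix_csv(out / "nrmsip_matrix.csv", norm, names)
        df.to_csv(out / "overlap_classes.csv", index=False)
    return df
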