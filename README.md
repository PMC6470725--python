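# ctxtraj

Trajectory analysis for disulfide-substituted peptide ensembles.

Chlorotoxin (CTX) is a 36-residue scorpion-venom peptide whose αβ fold is
stapled by four disulfide bonds (Cys 2–19, 5–28, 16–33, 20–35).  Replacing
individual cystine pairs with α-aminobutyric acid (Abu) or serine changes the
peptide's flexibility, solvation and conformational sampling — questions that
are answered by analyzing long molecular-dynamics ensembles.  `ctxtraj`
implements that complete analysis layer as a tested, reusable library:

* **structure / ensemble I/O** — PDB (single- and multi-model), GRO and XTC
  via mdtraj, with equilibration-discard and stride preprocessing (nm / ns
  units throughout);
* **secondary structure** — a Kabsch–Sander re-implementation
  (`E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)` kcal/mol, bond when
  `E < −0.5`) with the standard 8-label assignment reduced to
  α-helix / β-sheet / β-turn-bend / coil fractions;
* **superposition** — Kabsch SVD (proper rotations only), RMSD series
  against fixed or iterative-average references, per-residue Cα RMSF;
* **contacts** — heavy-atom contact-probability maps (BB–BB and SC–SC,
  0.5 nm cutoff), geometric H-bonds (0.35 nm / 30°), and the CβHβ¹,²
  center-of-mass distance statistic with its one-sided 95 % contact
  threshold (0.26 nm);
* **solvation** — Shrake–Rupley SASA (0.14 nm probe, 1000 points/sphere),
  rSASA normalization by reference mSASA values (Cys 0.758, Ser 1.219,
  Abu 1.347 nm²), water RDFs and hydration-shell probabilities;
* **dihedral PCA** — sin/cos-encoded φ/ψ PCA, the free-energy landscape
  `ΔG(x, y) = −R·T·ln(ρ(x,y)/ρ_max)` over the first two components at
  T = 310 K, k-means basin identification with silhouette diagnostics, and
  lowest-energy conformer extraction;
* **essential subspaces** — Cα-covariance eigenbases and the overlap
  statistics

  `RMSIP = √( (1/N) Σᵢ Σⱼ (ηᵢᴬ·ηⱼᴮ)² )`,
  `nRMSIP = RMSIP(A,B) / √( RMSIP(A₁,A₂)·RMSIP(B₁,B₂) )`

  with half-trajectory normalization and the four-class reporting scheme
  (0.65–0.75, 0.75–0.85, 0.85–0.95, ≥ 0.95);
* **synthetic ensembles** — generators with exact ground truth (Markov-
  switched von Mises dihedrals with NeRF chain rebuilding, Gaussian
  fluctuation ensembles with prescribed covariance, solvation scenes with
  controlled shell density, ideal helix/sheet geometries), so every stage is
  testable without microsecond MD.

## Worked example

Generate a two-state peptide ensemble (helix-like vs strand-like backbone
states with 3:1 stationary odds), then recover the states from the dihedral
PCA free-energy landscape:

```python
import numpy as np
from ctxtraj import (
    DihedralStateSpec, MarkovChainSpec, gen_markov_dihedrals, rebuild_chain,
    assign_secondary_structure, ss_fractions, extract_dihedrals, dpca_encode,
    pca, free_energy_landscape, cluster_landscape, representative_conformations,
)
from ctxtraj.dpca import basin_free_energies

states = DihedralStateSpec(
    phi_means=np.deg2rad([[-57.0] * 8, [-139.0] * 8]),
    psi_means=np.deg2rad([[-47.0] * 8, [135.0] * 8]),
    kappa=50.0,
)
chain = MarkovChainSpec(transition=[[0.95, 0.05], [0.15, 0.85]])
series, path = gen_markov_dihedrals(states, chain, 20000, seed=42)
ensemble = rebuild_chain(series, with_cbeta=True)

trace = assign_secondary_structure(ensemble)
print("secondary-structure fractions:",
      {k: round(v, 3) for k, v in ss_fractions(trace).items()})

X = dpca_encode(extract_dihedrals(ensemble))
model = pca(X)
proj = model.project(X, n_components=2)
grid = free_energy_landscape(proj, n_bins=40)   # T = 310 K
print("basin free energies (kJ/mol):", np.round(basin_free_energies(grid), 2))

models, best_k = cluster_landscape(proj, k_candidates=(2, 3), seed=0)
for c in representative_conformations(models[best_k], grid, proj):
    print(f"  basin {c.rank}: frame {c.frame_index}, dG = {c.delta_g:.2f} kJ/mol")
```

Output:

```
secondary-structure fractions: {'alpha_helix': 0.551, 'beta_sheet': 0.0, 'beta_turn_bend': 0.004, 'coil': 0.445}
basin free energies (kJ/mol): [0.   2.86]
  basin 1: frame 1283, dG = 0.00 kJ/mol
  basin 2: frame 17985, dG = 2.49 kJ/mol
```

The helix-like state is occupied ~75 % of the time, so roughly half of all
residue×frame cells are α-helical (interior residues of helical frames), and
the minority basin sits `R·T·ln 3 ≈ 2.83 kJ/mol` above the majority basin —
the landscape recovers the generator's stationary odds.

## Command line

```sh
ctxtraj simulate --spec sim.yaml --seed 42 --out demo.pdb
ctxtraj analyze  --config cfg.yaml --out bundle/
ctxtraj compare  --inputs a.pdb --inputs b.pdb -N 10 --out overlap/
ctxtraj report   --bundle bundle/
```

`analyze` writes a per-peptide bundle: summary table (RMSD, secondary-
structure fractions ρ), per-residue fractions and RMSF, contact maps,
H-bond occupancies, CβHβ pair statistics, the FEL grid, cluster diagnostics
and representative conformers (multi-model PDB), plus a manifest with the
config hash and seed.  Identical config + seed reproduces every CSV
byte-for-byte.

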