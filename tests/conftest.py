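"""Shared fixtures: small text fixtures and session-scoped synthetic ensembles."""

from __future__ import annotations

import numpy as np
import pytest

from ctxtraj.synthetic import (
    DihedralStateSpec,
    MarkovChainSpec,
    gen_markov_dihedrals,
)

# Hand-written 3-residue peptide (Ala-Abu-Gly) with full Abu sidechain; used
# for parser, role-assignment and unit-conversion checks.
ABU_PDB = """\
ATOM      1  N   ALA A   1       1.700   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       3.158   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       3.704   1.424   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       2.954   2.401   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       3.672  -0.740  -1.230  1.00  0.00           C
ATOM      6  N   ABU A   2       5.033   1.538   0.020  1.00  0.00           N
ATOM      7  H   ABU A   2       5.633   0.742   0.030  1.00  0.00           H
ATOM      8  CA  ABU A   2       5.664   2.851   0.050  1.00  0.00           C
ATOM      9  C   ABU A   2       7.184   2.722   0.080  1.00  0.00           C
ATOM     10  O   ABU A   2       7.724   1.621   0.090  1.00  0.00           O
ATOM     11  CB  ABU A   2       5.231   3.672   1.270  1.00  0.00           C
ATOM     12  HB1 ABU A   2       5.560   3.170   2.180  1.00  0.00           H
ATOM     13  HB2 ABU A   2       4.142   3.750   1.290  1.00  0.00           H
ATOM     14  CG  ABU A   2       5.840   5.070   1.230  1.00  0.00           C
ATOM     15  N   GLY A   3       7.874   3.854   0.090  1.00  0.00           N
ATOM     16  H   GLY A   3       7.394   4.740   0.080  1.00  0.00           H
ATOM     17  CA  GLY A   3       9.324   3.894   0.120  1.00  0.00           C
ATOM     18  C   GLY A   3       9.904   5.294   0.150  1.00  0.00           C
ATOM     19  O   GLY A   3       9.164   6.284   0.160  1.00  0.00           O
TER
END
"""


@pytest.fixture()
def abu_pdb(tmp_path):
    path = tmp_path / "abu_tripeptide.pdb"
    path.write_text(ABU_PDB)
    return path


def two_state_spec(n_residues: int = 6, kappa: float = 50.0):
    """Helix-like vs strand-like metastable states with 3:1 stationary odds.

    Mean dwell times of 20 / ~7 frames keep the states clearly metastable
    while mixing fast enough that 20k-frame occupancies resolve the 75/25
    stationary distribution to about one percentage point.
    """
    states = DihedralStateSpec(
        phi_means=np.deg2rad([[-57.0] * n_residues, [-139.0] * n_residues]),
        psi_means=np.deg2rad([[-47.0] * n_residues, [135.0] * n_residues]),
        kappa=kappa,
    )
    chain = MarkovChainSpec(transition=[[0.95, 0.05], [0.15, 0.85]])
    return states, chain


@pytest.fixture(scope="session")
def two_state_series():
    """20k-frame two-state Markov-von Mises dihedral series plus true path."""
    states, chain = two_state_spec()
    series, path = gen_markov_dihedrals(states, chain, 20000, seed=11)
    return series, path, chain
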