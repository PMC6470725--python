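"""Contact maps, geometric H-bonds and the CbetaHbeta COM statistic."""

import numpy as np
import pytest

import ctxtraj as ct
from ctxtraj.contacts import ATOMIC_MASSES, ci95_threshold
from ctxtraj.core_io import AtomRecord, ConformationalEnsemble, MolecularTopology
from ctxtraj.dpca import DihedralSeries
from ctxtraj.synthetic import gen_markov_dihedrals, rebuild_chain

from conftest import two_state_spec


@pytest.fixture(scope="module")
def wiggly_peptide():
    """5-residue, 100-frame ensemble with Cbeta/Hbeta sidechains."""
    states, chain = two_state_spec(n_residues=5, kappa=20.0)
    series, _ = gen_markov_dihedrals(states, chain, 100, seed=21)
    return rebuild_chain(series, with_cbeta=True)


def brute_force_contact_map(e, mode, cutoff):
    top = e.topology
    resids = sorted({a.residue_index for a in top.atoms})
    bb = {"N", "CA", "C", "O", "OXT"}
    groups = []
    for r in resids:
        idx = [
            i
            for i, a in enumerate(top.atoms)
            if a.residue_index == r
            and a.element != "H"
            and ((a.atom_name in bb) == (mode == "BB-BB"))
        ]
        groups.append(idx)
    n = len(resids)
    out = np.full((n, n), np.nan)
    for a in range(n):
        if not groups[a]:
            continue
        out[a, a] = 1.0
        for b in range(a + 1, n):
            if not groups[b]:
                continue
            hits = 0
            for f in range(e.n_frames):
                dmin = min(
                    np.linalg.norm(e.coordinates[f, i] - e.coordinates[f, j])
                    for i in groups[a]
                    for j in groups[b]
                )
                hits += dmin <= cutoff
            out[a, b] = out[b, a] = hits / e.n_frames
    return out


class TestContactMap:
    def test_overlapping_pair_probability_one(self):
        atoms = [
            AtomRecord("CB", "C", 1, "ALA", role="sidechain"),
            AtomRecord("CB", "C", 2, "ALA", role="sidechain"),
        ]
        atoms += [AtomRecord("CA", "C", i, "ALA", role="backbone") for i in (1, 2)]
        top = MolecularTopology(atoms=atoms)
        coords = np.zeros((3, 4, 3))
        coords[:, 2] = [0, 1, 0]
        coords[:, 3] = [0, 1.2, 0]
        ens = ConformationalEnsemble(top, coords, np.arange(3.0))
        cmap = ct.contact_map(ens, mode="SC-SC")
        assert cmap.probabilities[0, 1] == 1.0

    def test_counting_four_of_ten_frames(self):
        atoms = [
            AtomRecord("CB", "C", 1, "ALA", role="sidechain"),
            AtomRecord("CB", "C", 2, "ALA", role="sidechain"),
        ]
        top = MolecularTopology(atoms=atoms)
        coords = np.zeros((10, 2, 3))
        coords[:, 1, 0] = 0.8
        coords[:4, 1, 0] = 0.4  # within the 0.5 nm cutoff in 4 frames
        ens = ConformationalEnsemble(top, coords, np.arange(10.0))
        cmap = ct.contact_map(ens, mode="SC-SC")
        assert cmap.probabilities[0, 1] == pytest.approx(0.4)

    @pytest.mark.parametrize("mode", ["BB-BB", "SC-SC"])
    def test_matches_brute_force_enumeration(self, wiggly_peptide, mode):
        cmap = ct.contact_map(wiggly_peptide, mode=mode, cutoff=0.5)
        oracle = brute_force_contact_map(wiggly_peptide, mode, 0.5)
        assert np.allclose(cmap.probabilities, oracle, equal_nan=True)

    def test_symmetric_and_monotone_in_cutoff(self, wiggly_peptide):
        tight = ct.contact_map(wiggly_peptide, mode="SC-SC", cutoff=0.4)
        loose = ct.contact_map(wiggly_peptide, mode="SC-SC", cutoff=0.5)
        P = loose.probabilities
        assert np.allclose(P, P.T, atol=1e-15, equal_nan=True)
        mask = ~np.isnan(P)
        assert np.all(tight.probabilities[mask] <= P[mask])

    def test_glycine_sidechain_flagged_missing(self):
        states, chain = two_state_spec(n_residues=3, kappa=50.0)
        series, _ = gen_markov_dihedrals(states, chain, 5, seed=22)
        ens = rebuild_chain(series, with_cbeta=True)
        # strip residue 2's sidechain to emulate Gly
        import dataclasses

        keep = [
            i
            for i, a in enumerate(ens.topology.atoms)
            if not (a.residue_index == 2 and a.role == "sidechain")
        ]
        gly = dataclasses.replace(
            ens,
            topology=MolecularTopology(atoms=[ens.topology.atoms[i] for i in keep]),
            coordinates=ens.coordinates[:, keep],
        )
        cmap = ct.contact_map(gly, mode="SC-SC")
        assert cmap.missing[1]
        assert np.isnan(cmap.probabilities[1, 0])


def hbond_fixture(d_na, deviation_deg):
    """Single N-H donor and carbonyl O acceptor at given geometry."""
    atoms = [
        AtomRecord("N", "N", 1, "ALA", role="backbone"),
        AtomRecord("H", "H", 1, "ALA", role="backbone"),
        AtomRecord("O", "O", 3, "ALA", role="backbone"),
        AtomRecord("CA", "C", 3, "ALA", role="backbone"),
    ]
    top = MolecularTopology(atoms=atoms)
    ang = np.deg2rad(deviation_deg)
    h = np.array([0.101, 0.0, 0.0])
    # acceptor along the (possibly bent) continuation of N->H
    acc = h + (d_na - 0.101) * np.array([np.cos(ang), np.sin(ang), 0.0])
    coords = np.array([[[0, 0, 0], h, acc, acc + [0.3, 0, 0]]])
    return ConformationalEnsemble(top, coords, np.array([0.0]))


class TestHBonds:
    def test_linear_geometry_bonds(self):
        bonds = ct.hbonds(hbond_fixture(0.29, 0.0))
        assert len(bonds) == 1 and bonds[0].occupancy == 1.0

    def test_bent_geometry_rejected(self):
        assert ct.hbonds(hbond_fixture(0.29, 40.0)) == []

    def test_occupancy_matches_brute_force(self, wiggly_peptide):
        e = wiggly_peptide
        bonds = ct.hbonds(e, min_residue_sep=2)
        top = e.topology
        for b in bonds[:5]:
            don = top.atom_indices(b.donor_residue, names={b.donor_atom})[0]
            h = top.atom_indices(b.donor_residue, names={"H"})[0]
            acc = top.atom_indices(b.acceptor_residue, names={b.acceptor_atom})[0]
            hits = 0
            for f in range(e.n_frames):
                dv = e.coordinates[f, acc] - e.coordinates[f, don]
                hv = e.coordinates[f, h] - e.coordinates[f, don]
                av = e.coordinates[f, acc] - e.coordinates[f, h]
                cosang = hv @ av / (np.linalg.norm(hv) * np.linalg.norm(av))
                dev = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                hits += (np.linalg.norm(dv) <= 0.35) and (dev <= 30.0)
            assert b.occupancy == pytest.approx(hits / e.n_frames)


class TestCbetaComStat:
    def _two_residue(self, com_dists):
        """Two CYS-like residues whose Hbeta midpoints produce the requested
        per-frame COM distances along x."""
        atoms = []
        for r in (1, 2):
            atoms += [
                AtomRecord("CB", "C", r, "CYS", role="sidechain"),
                AtomRecord("HB1", "H", r, "CYS", role="sidechain"),
                AtomRecord("HB2", "H", r, "CYS", role="sidechain"),
            ]
        top = MolecularTopology(atoms=atoms)
        F = len(com_dists)
        coords = np.zeros((F, 6, 3))
        coords[:, 1, 1] = 0.1
        coords[:, 2, 1] = -0.1
        coords[:, 4, 1] = 0.1
        coords[:, 5, 1] = -0.1
        coords[:, 3:, 0] = np.asarray(com_dists)[:, None]
        return ConformationalEnsemble(top, coords, np.arange(F, dtype=float))

    def test_identical_coms(self):
        st = ct.cbeta_com_stat(self._two_residue([0.0, 0.0]), (1, 2))
        assert st.mean == 0.0 and st.probability == 1.0

    def test_default_threshold(self):
        st = ct.cbeta_com_stat(self._two_residue([0.1]), (1, 2))
        assert st.threshold == 0.26

    def test_alternating_series_counting(self):
        st = ct.cbeta_com_stat(self._two_residue([0.2, 0.4] * 5), (1, 2))
        assert st.mean == pytest.approx(0.30)
        assert st.sd == pytest.approx(0.10)
        assert st.probability == pytest.approx(0.5)

    def test_mass_weighting_uses_standard_masses(self):
        assert ATOMIC_MASSES["C"] == 12.011 and ATOMIC_MASSES["H"] == 1.008

    def test_missing_beta_atoms_named(self, wiggly_peptide):
        import dataclasses

        keep = [
            i
            for i, a in enumerate(wiggly_peptide.topology.atoms)
            if not (a.residue_index == 2 and a.atom_name == "HB2")
        ]
        broken = dataclasses.replace(
            wiggly_peptide,
            topology=MolecularTopology(
                atoms=[wiggly_peptide.topology.atoms[i] for i in keep]
            ),
            coordinates=wiggly_peptide.coordinates[:, keep],
        )
        with pytest.raises(ValueError, match="residue 2"):
            ct.cbeta_com_stat(broken, (2, 4))


class TestCi95Threshold:
    def test_point_mass(self):
        assert ci95_threshold(np.full(200, 0.23)) == pytest.approx(0.23)

    def test_normal_distribution_closed_form(self):
        rng = np.random.default_rng(23)
        d = rng.normal(0.23, 0.03, 200000)
        # one-sided 95%: mu + 1.645 sigma
        assert ci95_threshold(d) == pytest.approx(0.23 + 1.6449 * 0.03, abs=0.005)

    def test_uniform_closed_form(self):
        rng = np.random.default_rng(24)
        d = rng.uniform(0.2, 0.3, 200000)
        assert ci95_threshold(d) == pytest.approx(0.295, abs=0.002)

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="100"):
            ci95_threshold(np.full(50, 0.2))
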