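"""Ground-truth generators: statistical structure and reproducibility."""

import numpy as np
import pytest
from scipy import stats

import ctxtraj as ct
from ctxtraj.dpca import DihedralSeries, extract_dihedrals
from ctxtraj.synthetic import (
    DihedralStateSpec,
    LowRankCovariance,
    MarkovChainSpec,
    SolvationSceneSpec,
    gen_fluctuation_ensemble,
    gen_markov_dihedrals,
    gen_solvation_frames,
    low_rank_modes,
    rebuild_chain,
)

from conftest import two_state_spec


class TestMarkovDihedrals:
    def test_absorbing_chain_stays_in_start_state(self):
        states, _ = two_state_spec()
        chain = MarkovChainSpec(transition=np.eye(2), initial=[1.0, 0.0])
        _, path = gen_markov_dihedrals(states, chain, 500, seed=0)
        assert np.all(path == 0)

    def test_high_concentration_emissions_near_means(self):
        # von Mises kappa=400: P(|x - mu| <= 0.15) from numeric integration
        expected = stats.vonmises(kappa=400.0).cdf(0.15) - stats.vonmises(
            kappa=400.0
        ).cdf(-0.15)
        assert expected > 0.99
        states, _ = two_state_spec(kappa=400.0)
        chain = MarkovChainSpec(transition=np.eye(2), initial=[1.0, 0.0])
        series, _ = gen_markov_dihedrals(states, chain, 2000, seed=1)
        dev = np.abs(series.phi - states.phi_means[0])
        frac = np.mean(dev <= 0.15)
        assert frac > 0.99

    def test_occupancy_matches_stationary_within_3se(self):
        states, chain = two_state_spec()
        pi = chain.stationary_distribution()
        assert pi == pytest.approx([0.75, 0.25], abs=1e-12)
        n = 20000
        _, path = gen_markov_dihedrals(states, chain, n, seed=3)
        occ = np.mean(path == 0)
        # correlated samples: effective n reduced by the chain's mixing time
        rho = float(np.corrcoef(path[:-1], path[1:])[0, 1])
        n_eff = n * (1 - rho) / (1 + rho)
        se = np.sqrt(0.75 * 0.25 / n_eff)
        assert abs(occ - 0.75) < 3 * se

    def test_stationary_occupancy_chi2_not_rejected(self):
        states, chain = two_state_spec()
        _, path = gen_markov_dihedrals(states, chain, 50000, seed=4)
        # thin to roughly independent samples before the goodness-of-fit test
        thinned = path[::100]
        counts = np.bincount(thinned, minlength=2)
        _, p = stats.chisquare(counts, f_exp=len(thinned) * np.array([0.75, 0.25]))
        assert p > 0.01

    def test_non_stochastic_matrix_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            MarkovChainSpec(transition=[[0.9, 0.2], [0.5, 0.5]])

    def test_bit_reproducible(self):
        states, chain = two_state_spec()
        s1, p1 = gen_markov_dihedrals(states, chain, 300, seed=9)
        s2, p2 = gen_markov_dihedrals(states, chain, 300, seed=9)
        assert np.array_equal(s1.phi, s2.phi) and np.array_equal(p1, p2)


class TestRebuildChain:
    def test_helix_round_trip(self):
        n = 12
        phi = np.full((1, n), np.deg2rad(-57.0))
        psi = np.full((1, n), np.deg2rad(-47.0))
        d = DihedralSeries(phi=phi, psi=psi, residue_indices=np.arange(1, n + 1))
        ens = rebuild_chain(d)
        out = extract_dihedrals(ens)
        assert out.phi == pytest.approx(phi[:, 1 : n - 1], abs=1e-9)
        assert out.psi == pytest.approx(psi[:, 1 : n - 1], abs=1e-9)

    def test_random_dihedral_round_trip_50_frames(self):
        rng = np.random.default_rng(12)
        n = 8
        phi = rng.uniform(-np.pi + 0.05, np.pi - 0.05, (50, n))
        psi = rng.uniform(-np.pi + 0.05, np.pi - 0.05, (50, n))
        d = DihedralSeries(phi=phi, psi=psi, residue_indices=np.arange(1, n + 1))
        out = extract_dihedrals(rebuild_chain(d))
        assert np.max(np.abs(out.phi - phi[:, 1 : n - 1])) < 1e-6
        assert np.max(np.abs(out.psi - psi[:, 1 : n - 1])) < 1e-6

    def test_calpha_spacing_ideal(self):
        ens = ct.ideal_helix(n_residues=10)
        ca = ct.ca_indices(ens.topology)
        d = np.linalg.norm(np.diff(ens.coordinates[0, ca], axis=0), axis=1)
        assert d == pytest.approx(0.38, abs=0.005)


class TestFluctuationEnsemble:
    def test_zero_covariance_reproduces_reference(self):
        ref = np.random.default_rng(0).normal(size=(7, 3))
        ens = gen_fluctuation_ensemble(ref, 0.0, 5, seed=1)
        assert np.allclose(ens.coordinates, ref[None])

    def test_isotropic_rmsf_closed_form(self):
        # RMSF -> sigma * sqrt(3); 200 atoms keep the rigid-body variance
        # removed by superposition (6 of 600 dof) below the 2% tolerance
        rng = np.random.default_rng(2)
        ref = rng.normal(scale=0.5, size=(200, 3))
        ens = gen_fluctuation_ensemble(ref, 0.05, 20000, seed=3)
        r = ct.rmsf(ens)
        assert np.mean(r) == pytest.approx(0.05 * np.sqrt(3), rel=0.02)

    def test_rank2_covariance_recovered_by_essential_basis(self):
        rng = np.random.default_rng(4)
        ref = rng.normal(scale=0.5, size=(15, 3))
        modes = low_rank_modes(ref, 2, seed=5)
        cov = LowRankCovariance(modes=modes, variances=np.array([0.02, 0.01]))
        ens = gen_fluctuation_ensemble(ref, cov, 20000, seed=6)
        basis = ct.essential_basis(ens, n_vectors=5)
        evals = basis.eigenvalues
        assert np.sum(evals > 1e-10) == 2
        assert evals[0] == pytest.approx(0.02, rel=0.05)
        assert evals[1] == pytest.approx(0.01, rel=0.05)

    def test_non_psd_rejected(self):
        ref = np.zeros((3, 3))
        cov = -0.1 * np.tile(np.eye(3), (3, 1, 1))
        with pytest.raises(ValueError, match="semidefinite"):
            gen_fluctuation_ensemble(ref, cov, 10, seed=0)


class TestSolvationFrames:
    def _spec(self, multiplier, exclusion=0.0):
        return SolvationSceneSpec(
            solute_coords=[[1.5, 1.5, 1.5]],
            box=[3.0, 3.0, 3.0],
            bulk_density=33.0,
            tagged=(0,),
            multiplier=multiplier,
            exclusion_radius=exclusion,
        )

    def test_zero_multiplier_empties_shell(self):
        ens = gen_solvation_frames(self._spec(0.0), 20, seed=7)
        assert ct.shell_probability(ens, 0, mode="mean_count") == 0.0

    @pytest.mark.parametrize("multiplier", [1.0, 0.5])
    def test_shell_probability_matches_multiplier(self, multiplier):
        ens = gen_solvation_frames(self._spec(multiplier), 300, seed=8)
        p = ct.shell_probability(ens, 0)
        assert p == pytest.approx(multiplier, rel=0.08)

    def test_shell_overflowing_box_rejected(self):
        with pytest.raises(ValueError, match="fit inside the box"):
            SolvationSceneSpec(
                solute_coords=[[0.2, 1.5, 1.5]],
                box=[3.0, 3.0, 3.0],
                tagged=(0,),
            )

    def test_reproducible(self):
        e1 = gen_solvation_frames(self._spec(1.0), 5, seed=9)
        e2 = gen_solvation_frames(self._spec(1.0), 5, seed=9)
        assert np.array_equal(e1.coordinates, e2.coordinates)
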