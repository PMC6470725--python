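"""Dihedral extraction, sin/cos encoding, PCA, FEL and basin clustering."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import ctxtraj as ct
from ctxtraj.dpca import (
    DihedralSeries,
    R_GAS,
    basin_free_energies,
    count_basins,
    cluster_landscape,
    dpca_encode,
    free_energy_landscape,
    pca,
    representative_conformations,
)
from ctxtraj.synthetic import gen_markov_dihedrals, rebuild_chain

from conftest import two_state_spec


class TestExtractDihedrals:
    def test_ideal_helix_angles(self):
        ens = ct.ideal_helix(8)
        d = ct.extract_dihedrals(ens)
        assert np.max(np.abs(d.phi - np.deg2rad(-57))) < 1e-4
        assert np.max(np.abs(d.psi - np.deg2rad(-47))) < 1e-4

    def test_residue_range_column_count(self):
        states, chain = two_state_spec(n_residues=36)
        series, _ = gen_markov_dihedrals(states, chain, 2, seed=41)
        ens = rebuild_chain(series)
        d = ct.extract_dihedrals(ens, residues=(2, 35))
        assert d.n_residues == 34
        assert d.residue_indices[0] == 2 and d.residue_indices[-1] == 35

    def test_round_trip_with_rebuild(self):
        rng = np.random.default_rng(42)
        phi = rng.uniform(-3, 3, (10, 6))
        psi = rng.uniform(-3, 3, (10, 6))
        d = DihedralSeries(phi=phi, psi=psi, residue_indices=np.arange(1, 7))
        out = ct.extract_dihedrals(rebuild_chain(d))
        assert np.max(np.abs(out.phi - phi[:, 1:5])) < 1e-6
        assert np.max(np.abs(out.psi - psi[:, 1:5])) < 1e-6


class TestEncode:
    def test_quarter_turn_block(self):
        d = DihedralSeries(
            phi=np.array([[0.0]]),
            psi=np.array([[np.pi / 2]]),
            residue_indices=np.array([1]),
        )
        assert dpca_encode(d)[0] == pytest.approx([1, 0, 0, 1], abs=1e-12)

    def test_unit_norm_identity_per_angle(self):
        rng = np.random.default_rng(43)
        d = DihedralSeries(
            phi=rng.uniform(-np.pi, np.pi, (20, 4)),
            psi=rng.uniform(-np.pi, np.pi, (20, 4)),
            residue_indices=np.arange(1, 5),
        )
        X = dpca_encode(d)
        sq = X.reshape(20, 4, 4) ** 2
        assert sq[..., 0] + sq[..., 1] == pytest.approx(np.ones((20, 4)), abs=1e-12)
        assert sq[..., 2] + sq[..., 3] == pytest.approx(np.ones((20, 4)), abs=1e-12)

    def test_uniform_angles_moments(self):
        rng = np.random.default_rng(44)
        d = DihedralSeries(
            phi=rng.uniform(-np.pi, np.pi, (100000, 1)),
            psi=rng.uniform(-np.pi, np.pi, (100000, 1)),
            residue_indices=np.array([1]),
        )
        X = dpca_encode(d)
        assert X.mean(axis=0) == pytest.approx(np.zeros(4), abs=0.02)
        assert X.var(axis=0) == pytest.approx(0.5 * np.ones(4), abs=0.02)


class TestPca:
    def test_line_in_3d_single_component(self):
        rng = np.random.default_rng(45)
        t = rng.normal(size=300)
        X = np.outer(t, [1.0, 2.0, -1.0])
        model = pca(X)
        assert model.eigenvalues[0] == pytest.approx(np.trace(np.cov(X.T)), rel=1e-10)
        assert model.eigenvalues[1:] == pytest.approx(0.0, abs=1e-10)

    def test_matches_brute_force_eigensolve(self, two_state_series):
        series, _, _ = two_state_series
        X = dpca_encode(series)[:5000]
        model = pca(X)
        cov = np.cov(X - X.mean(0), rowvar=False)
        oracle = np.sort(np.linalg.eigvalsh(cov))[::-1]
        assert model.eigenvalues == pytest.approx(oracle, abs=1e-8)
        # columns orthonormal
        V = model.eigenvectors
        assert V.T @ V == pytest.approx(np.eye(V.shape[1]), abs=1e-10)

    def test_trace_conservation(self):
        rng = np.random.default_rng(46)
        X = rng.normal(size=(200, 7))
        model = pca(X)
        assert model.eigenvalues.sum() == pytest.approx(
            np.trace(np.cov(X.T)), abs=1e-10
        )

    def test_circular_shift_leaves_spectrum(self, two_state_series):
        # rotating every angle by a constant wrap-around offset rotates each
        # (cos, sin) pair: an orthogonal change of basis, so eigenvalues are
        # unchanged -- the encoding has no angular boundary artifact
        series, _, _ = two_state_series
        shift = 2.5
        shifted = DihedralSeries(
            phi=np.angle(np.exp(1j * (series.phi[:4000] + shift))),
            psi=np.angle(np.exp(1j * (series.psi[:4000] + shift))),
            residue_indices=series.residue_indices,
        )
        base = DihedralSeries(
            phi=series.phi[:4000],
            psi=series.psi[:4000],
            residue_indices=series.residue_indices,
        )
        ev1 = pca(dpca_encode(base)).eigenvalues
        ev2 = pca(dpca_encode(shifted)).eigenvalues
        assert ev1 == pytest.approx(ev2, abs=1e-8)


class TestFel:
    def test_rho_max_bin_at_zero(self):
        rng = np.random.default_rng(47)
        grid = free_energy_landscape(rng.normal(size=(500, 2)), n_bins=10)
        assert np.nanmin(grid.delta_g) == 0.0

    def test_two_bin_arithmetic(self):
        proj = np.concatenate(
            [np.tile([0.0, 0.0], (900, 1)), np.tile([1.0, 1.0], (100, 1))]
        )
        grid = free_energy_landscape(proj, n_bins=2, temperature=310.0)
        occupied = np.sort(grid.delta_g[grid.occupied])
        assert occupied[0] == 0.0
        assert occupied[1] == pytest.approx(R_GAS * 310.0 * np.log(9.0), rel=1e-6)

    def test_default_temperature_is_310(self):
        grid = free_energy_landscape(np.zeros((10, 2)) + np.arange(10)[:, None], n_bins=3)
        assert grid.temperature == 310.0

    def test_empty_bins_masked_not_zero(self):
        proj = np.array([[0.0, 0.0], [1.0, 1.0]])
        grid = free_energy_landscape(proj, n_bins=4)
        assert np.isnan(grid.delta_g[~grid.occupied]).all()


class TestClustering:
    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(48)
        a = rng.normal([-3, 0], 0.3, size=(300, 2))
        b = rng.normal([3, 0], 0.3, size=(200, 2))
        proj = np.concatenate([a, b])
        labels_true = np.repeat([0, 1], [300, 200])
        models, best_k = cluster_landscape(proj, k_candidates=(2, 3), seed=0)
        assert best_k == 2
        assert adjusted_rand_score(labels_true, models[2].assignments) == 1.0

    def test_silhouette_matches_brute_force(self):
        rng = np.random.default_rng(49)
        proj = np.concatenate(
            [rng.normal(-2, 0.5, (80, 2)), rng.normal(2, 0.5, (70, 2))]
        )
        models, _ = cluster_landscape(proj, k_candidates=(2,), seed=1)
        m = models[2]
        D = np.linalg.norm(proj[:, None] - proj[None, :], axis=-1)
        sil = []
        for i in range(len(proj)):
            own = m.assignments[i]
            a_i = D[i][(m.assignments == own) & (np.arange(len(proj)) != i)].mean()
            b_i = min(
                D[i][m.assignments == other].mean()
                for other in set(m.assignments) - {own}
            )
            sil.append((b_i - a_i) / max(a_i, b_i))
        assert m.silhouette_width == pytest.approx(np.mean(sil), abs=1e-12)

    def test_sse_non_increasing_in_k(self):
        rng = np.random.default_rng(50)
        proj = rng.normal(size=(400, 2))
        models, _ = cluster_landscape(proj, k_candidates=(2, 3, 4, 5), seed=2)
        sses = [models[k].sse for k in (2, 3, 4, 5)]
        assert all(s2 <= s1 + 1e-9 for s1, s2 in zip(sses, sses[1:]))

    def test_k_beyond_distinct_points_rejected(self):
        proj = np.tile([[0.0, 0.0], [1.0, 1.0]], (5, 1))
        with pytest.raises(ValueError, match="distinct"):
            cluster_landscape(proj, k_candidates=(3,), seed=0)


class TestRepresentativeConformations:
    def test_single_cluster_returns_rho_max_frame(self):
        rng = np.random.default_rng(51)
        proj = rng.normal(size=(500, 2))
        grid = free_energy_landscape(proj, n_bins=8)
        models, _ = cluster_landscape(proj, k_candidates=(2,), seed=3)
        confs = representative_conformations(models[2], grid, proj)
        assert confs[0].delta_g == 0.0
        frames = [c.frame_index for c in confs]
        assert len(set(frames)) == len(frames)
        assert all(0 <= f < 500 for f in frames)

    def test_two_basin_order_and_ddg(self, two_state_series):
        series, path, chain = two_state_series
        X = dpca_encode(series)
        model = pca(X)
        proj = model.project(X, 2)
        grid = free_energy_landscape(proj, n_bins=40)
        assert count_basins(grid) == 2
        models, _ = cluster_landscape(proj, k_candidates=(2,), seed=4)
        confs = representative_conformations(models[2], grid, proj)
        # majority basin first
        maj_cluster = confs[0].cluster
        frames_maj = models[2].assignments == maj_cluster
        assert np.mean(frames_maj) > 0.5
        target = R_GAS * 310.0 * np.log(3.0)
        # single-bin conformer labels carry binning noise; the integrated
        # basin occupancies pin the free-energy gap much more tightly
        ddg_bins = confs[1].delta_g - confs[0].delta_g
        assert ddg_bins == pytest.approx(target, abs=0.6)
        dg_basins = basin_free_energies(grid)
        assert dg_basins[1] - dg_basins[0] == pytest.approx(target, abs=0.2)
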