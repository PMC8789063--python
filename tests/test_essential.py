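"""Iterative superposition, PCA mode recovery, projections, surfaces."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import junctionmd as jm
from junctionmd.constants import kT_kcal
from junctionmd.essential import align_modes
from junctionmd.synth import _helical_mean


class TestIterativeSuperposition:
    def test_rigid_motions_removed_exactly(self):
        rng = np.random.default_rng(30)
        base = _helical_mean(30)
        frames = np.empty((20, 30, 3))
        for f in range(20):
            Q = Rotation.random(random_state=rng).as_matrix()
            frames[f] = base @ Q.T + rng.normal(0, 10, 3)
        aligned = jm.iterative_superposition(frames)
        for f in range(20):
            assert np.abs(aligned.frames[f] - aligned.mean).max() < 1e-8
        assert aligned.history[-1] < 1e-4

    def test_already_aligned_fixed_point(self):
        rng = np.random.default_rng(31)
        base = _helical_mean(20)
        frames = base + rng.normal(0, 0.01, (50, 20, 3))
        pre = jm.iterative_superposition(frames)
        again = jm.iterative_superposition(pre.frames)
        assert len(again.history) <= 2
        np.testing.assert_allclose(again.mean, pre.mean, atol=1e-6)

    def test_two_frames_converge(self):
        base = _helical_mean(25)
        rot = base @ Rotation.from_rotvec([0, 0, np.pi]).as_matrix().T
        aligned = jm.iterative_superposition(np.array([base, rot]))
        assert aligned.history[-1] < 1e-4

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError, match="2 frames"):
            jm.iterative_superposition(_helical_mean(10)[None])


class TestEssentialModes:
    def test_single_planted_mode_recovery(self):
        spec = jm.ModeEnsembleSpec(
            n_atoms=30, n_frames=5000, mode_variances=(4.0,), noise_sigma2=1e-4
        )
        frames, mean, modes, _ = jm.gen_mode_ensemble(spec, seed=32)
        ms = align_modes(
            jm.essential_modes(jm.iterative_superposition(frames)), mean
        )
        assert ms.eigenvalues[0] == pytest.approx(4.0, rel=0.1)
        assert abs(ms.eigenvectors[0] @ modes[0]) > 0.99

    def test_two_mode_recovery_order_and_crosstalk(self, planted_mode_data):
        spec, frames, mean, modes = planted_mode_data
        ms = align_modes(
            jm.essential_modes(jm.iterative_superposition(frames)), mean
        )
        assert ms.eigenvalues[0] > ms.eigenvalues[1]
        assert ms.eigenvalues[0] == pytest.approx(9.0, rel=0.1)
        assert ms.eigenvalues[1] == pytest.approx(1.0, rel=0.1)
        # cross-talk between recovered and planted off-pair < 1%
        assert abs(ms.eigenvectors[0] @ modes[1]) < 0.01
        assert abs(ms.eigenvectors[1] @ modes[0]) < 0.01

    def test_white_noise_null_spectrum(self):
        rng = np.random.default_rng(33)
        n, m = 4000, 20
        mean = _helical_mean(m)
        frames = mean + rng.normal(0, 0.5, (n, m, 3))
        ms = jm.essential_modes(jm.iterative_superposition(frames))
        # Marchenko-Pastur-like spread around sigma^2 = 0.25; no dominant mode
        upper = 0.25 * (1 + np.sqrt(3 * m / n)) ** 2
        assert ms.eigenvalues[0] < 1.6 * upper

    def test_orthonormality_and_variance_bookkeeping(self, planted_mode_data):
        spec, frames, mean, modes = planted_mode_data
        aligned = jm.iterative_superposition(frames)
        ms = jm.essential_modes(aligned)
        G = ms.eigenvectors @ ms.eigenvectors.T
        np.testing.assert_allclose(G, np.eye(len(ms.eigenvalues)), atol=1e-8)
        X = aligned.frames.reshape(aligned.n_frames, -1) - aligned.mean.reshape(1, -1)
        total = np.trace((X.T @ X) / aligned.n_frames)
        assert ms.total_variance == pytest.approx(total - ms.rigid_mass, rel=1e-6)
        assert ms.n_discarded_zero_modes == 6

    def test_too_few_frames(self):
        with pytest.raises(ValueError):
            jm.essential_modes(
                jm.AlignedEnsemble(np.zeros((5, 10, 3)), np.zeros((10, 3)))
            )


@pytest.fixture(scope="module")
def modeset(planted_mode_data):
    spec, frames, mean, modes = planted_mode_data
    aligned = jm.iterative_superposition(frames)
    return aligned, jm.essential_modes(aligned)


class TestProjection:

    def test_mean_projects_to_zero(self, modeset):
        aligned, ms = modeset
        assert jm.project(ms.mean[None], ms.eigenvectors[0], ms.mean)[0] == pytest.approx(0.0, abs=1e-9)

    def test_unit_displacement(self, modeset):
        aligned, ms = modeset
        x = ms.mean + 2.5 * ms.eigenvectors[0].reshape(-1, 3)
        p = jm.project(x[None], ms.eigenvectors[0], ms.mean, check_alignment=False)
        assert p[0] == pytest.approx(2.5, abs=1e-9)

    def test_projection_variance_matches_eigenvalue(self, modeset):
        aligned, ms = modeset
        p1 = jm.project(aligned.frames, ms.eigenvectors[0], ms.mean)
        assert p1.var() == pytest.approx(ms.eigenvalues[0], rel=1e-9)

    def test_unaligned_input_detected(self, modeset):
        aligned, ms = modeset
        with pytest.raises(ValueError, match="unaligned"):
            jm.project(aligned.frames + 50.0, ms.eigenvectors[0], ms.mean)

    def test_backproject_inverse_and_residual_orthogonality(self, modeset):
        aligned, ms = modeset
        assert np.allclose(jm.backproject(0.0, ms.eigenvectors[0], ms.mean), ms.mean)
        p = 1.7
        x = jm.backproject(p, ms.eigenvectors[0], ms.mean)
        assert jm.project(x[None], ms.eigenvectors[0], ms.mean,
                          check_alignment=False)[0] == pytest.approx(p)
        # rank-k residual orthogonal to all k modes
        k = 2
        frame = aligned.frames[10]
        dev = (frame - ms.mean).reshape(-1)
        recon = sum(
            (dev @ ms.eigenvectors[i]) * ms.eigenvectors[i] for i in range(k)
        )
        resid = dev - recon
        for i in range(k):
            assert abs(resid @ ms.eigenvectors[i]) < 1e-8

    def test_linear_path_rmsd(self, modeset):
        aligned, ms = modeset
        sigma = np.sqrt(ms.eigenvalues[0])
        ends = jm.backproject(np.array([-3 * sigma, 3 * sigma]),
                              ms.eigenvectors[0], ms.mean)
        rmsd = np.sqrt(((ends[0] - ends[1]) ** 2).sum() / ms.mean.shape[0])
        assert rmsd == pytest.approx(6 * sigma / np.sqrt(ms.mean.shape[0]), rel=1e-9)

    def test_meta_ensemble_pooled_variance(self):
        # concatenating sub-ensembles before PCA: per-system projections
        # have finite variance and pool back to the meta eigenvalue
        specs = [
            jm.ModeEnsembleSpec(n_atoms=30, n_frames=1500,
                                mode_variances=(v,), noise_sigma2=1e-4,
                                rigid_motions=False)
            for v in (4.0, 16.0)
        ]
        parts = [jm.gen_mode_ensemble(s, seed=40 + i)[0] for i, s in enumerate(specs)]
        meta = np.concatenate(parts)
        aligned = jm.iterative_superposition(meta)
        ms = jm.essential_modes(aligned)
        p = jm.project(aligned.frames, ms.eigenvectors[0], ms.mean)
        halves = [p[: len(parts[0])], p[len(parts[0]) :]]
        pooled = np.concatenate(halves)
        assert np.isfinite([h.var() for h in halves]).all()
        assert pooled.var() == pytest.approx(ms.eigenvalues[0], rel=1e-9)


class TestProjectionSurface:
    def test_single_point_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            surf = jm.projection_surface(np.zeros(100), np.zeros(100))
        assert np.nanmin(surf.free_energy) == 0.0
        assert (surf.counts > 0).sum() == 1

    def test_bin_area_default(self):
        rng = np.random.default_rng(41)
        surf = jm.projection_surface(rng.normal(0, 1, 1000), rng.normal(0, 1, 1000))
        assert surf.bin_area == pytest.approx(0.04)

    def test_gaussian_boltzmann_inversion(self):
        rng = np.random.default_rng(42)
        n, sigma = 200000, 1.0
        p1, p2 = rng.normal(0, sigma, n), rng.normal(0, sigma, n)
        surf = jm.projection_surface(p1, p2, temperature=298.0)
        kT = kT_kcal(298.0)
        xc = (surf.x_edges[:-1] + surf.x_edges[1:]) / 2
        yc = (surf.y_edges[:-1] + surf.y_edges[1:]) / 2
        xx, yy = np.meshgrid(xc, yc, indexing="ij")
        r2 = xx**2 + yy**2
        mask = (r2 < 4.0) & np.isfinite(surf.free_energy)
        expected = kT * r2[mask] / (2 * sigma**2)
        resid = surf.free_energy[mask] - expected
        # remove the reference offset (most populated bin is noisy)
        resid -= resid.mean()
        assert np.abs(resid).mean() < 0.05 * kT + 0.02

    def test_two_cluster_free_energy_gap(self):
        rng = np.random.default_rng(43)
        n = 200000
        n1 = int(0.95 * n)
        p1 = np.concatenate([rng.normal(-5, 0.5, n1), rng.normal(5, 0.5, n - n1)])
        p2 = np.concatenate([rng.normal(0, 0.5, n1), rng.normal(0, 0.5, n - n1)])
        surf = jm.projection_surface(p1, p2, temperature=298.0)
        xc = (surf.x_edges[:-1] + surf.x_edges[1:]) / 2
        left = surf.free_energy[xc < 0, :]
        right = surf.free_energy[xc > 0, :]
        dF = np.nanmin(right) - np.nanmin(left)
        kT = kT_kcal(298.0)
        assert dF == pytest.approx(kT * np.log(19), rel=0.1)

    def test_empty_bins_flagged_not_zero(self):
        rng = np.random.default_rng(44)
        surf = jm.projection_surface(rng.normal(0, 1, 500), rng.normal(0, 1, 500))
        assert np.isnan(surf.free_energy[surf.counts == 0]).all()
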