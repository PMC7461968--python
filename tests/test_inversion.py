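"""Dipole inversion: TKD exactness/attenuation, L2 oracle, MEDI, streaking."""

import numpy as np
import pytest
from scipy.sparse.linalg import LinearOperator, cg

from qsmtrend import (
    AcquisitionParams,
    KSpaceGrid,
    L2Config,
    MEDIConfig,
    ROIProtocol,
    TKDConfig,
    VSharpConfig,
    extract_roi_stats,
    field_to_wrapped_phase,
    kernel_cone_mask,
    l2_invert,
    l2_lambda_sweep,
    laplacian_unwrap,
    make_dipole_kernel,
    medi_invert,
    phase_to_ppm,
    streaking_metric,
    tkd_invert,
    vsharp,
)
from qsmtrend.inversion import _apply_dipole, _forward_diff, _forward_diff_adjoint, _l2_solve
from qsmtrend.phase_processing import TissueField


def referenced_truth(truth, mask):
    """Ground truth referenced to the reconstruction's zero-mean-over-mask convention."""
    return truth.chi_internal.data - truth.chi_internal.data[mask].mean()


def full_tissue(data):
    return TissueField(
        data=data, mask=np.ones(data.shape, bool), voxel_size=(1.0, 1.0, 1.0), units="ppm"
    )


def abs_roi_means(chi, labels, protocol=ROIProtocol(n_replicates=1)):
    return {s.nucleus: abs(s.mean_chi) for s in extract_roi_stats(chi, labels, protocol)}


@pytest.fixture(scope="module")
def kernel16():
    return make_dipole_kernel(KSpaceGrid((16, 16, 16)))


class TestTKD:
    def test_zero_field_gives_zero_map(self, kernel16):
        for delta in (0.05, 0.25, 0.5):
            chi = tkd_invert(full_tissue(np.zeros((16, 16, 16))), kernel16, TKDConfig(delta))
            assert np.all(chi.data == 0)

    def test_delta_out_of_range_rejected(self):
        for delta in (0.0, -0.1, 2.0 / 3.0):
            with pytest.raises(ValueError):
                TKDConfig(delta=delta)

    def test_exact_off_cone_recovery(self, kernel16):
        """Fields with no spectral content near the cone invert exactly."""
        rng = np.random.default_rng(0)
        delta = 0.15
        spectrum = np.fft.fftn(rng.normal(size=(16, 16, 16)))
        spectrum[np.abs(kernel16.values) <= delta + 0.02] = 0
        chi_true = np.real(np.fft.ifftn(spectrum))
        phi = np.real(np.fft.ifftn(kernel16.values * np.fft.fftn(chi_true)))
        rec = tkd_invert(full_tissue(phi), kernel16, TKDConfig(delta))
        assert np.allclose(rec.data, chi_true - chi_true.mean(), atol=1e-10)

    def test_roi_means_non_increasing_in_delta(self, truth48, tissue48):
        """Larger thresholds attenuate reconstructed susceptibility."""
        means = {}
        for delta in (0.2, 0.3, 0.4):
            rec = tkd_invert(tissue48, truth48.kernel, TKDConfig(delta))
            means[delta] = abs_roi_means(rec, truth48.labels)
        for name in ("Cd", "Pt", "Gp", "Sn"):
            assert means[0.2][name] >= means[0.3][name] >= means[0.4][name]

    def test_underestimation_correction_improves_recovery(self, truth64, tissue64):
        raw = tkd_invert(tissue64, truth64.kernel, TKDConfig(0.25))
        corr = tkd_invert(tissue64, truth64.kernel, TKDConfig(0.25, correct_underestimation=True))
        gt = referenced_truth(truth64, corr.mask)
        gm = {s.nucleus: s.mean_chi for s in extract_roi_stats_on(gt, corr.mask, truth64.labels)}

        def worst_error(rec):
            rm = {
                s.nucleus: s.mean_chi
                for s in extract_roi_stats(rec, truth64.labels, ROIProtocol(n_replicates=1))
            }
            return max(abs(rm[k] - gm[k]) / abs(gm[k]) for k in gm)

        assert worst_error(corr) < worst_error(raw)

    def test_reconstruction_mean_over_mask_is_zero(self, truth48, tissue48):
        rec = tkd_invert(tissue48, truth48.kernel, TKDConfig(0.25))
        assert abs(rec.data[rec.mask].mean()) < 1e-12
        assert np.all(rec.data[~rec.mask] == 0)


def extract_roi_stats_on(data, mask, labels):
    class _V:
        pass

    v = _V()
    v.data = data
    v.mask = mask
    return extract_roi_stats(v, labels, ROIProtocol(n_replicates=1))


class TestL2:
    def test_zero_field_gives_zero_map(self, kernel16):
        chi = l2_invert(full_tissue(np.zeros((16, 16, 16))), kernel16, L2Config(lam=0.01))
        assert np.all(chi.data == 0)

    def test_nonpositive_lambda_rejected(self, kernel16):
        with pytest.raises(ValueError):
            L2Config(lam=-1.0)
        with pytest.raises(ValueError):
            _l2_solve(np.zeros((16, 16, 16)), kernel16, 0.0)

    def test_closed_form_matches_iterative_minimizer(self, kernel16):
        """k-space solution equals CG on the explicit normal equations to 1e-6."""
        rng = np.random.default_rng(1)
        chi_true = rng.normal(size=(16, 16, 16))
        phi = _apply_dipole(kernel16, chi_true)
        lam = 0.01
        closed = _l2_solve(phi, kernel16, lam)

        def matvec(v_flat):
            v = v_flat.reshape(16, 16, 16)
            out = _apply_dipole(kernel16, _apply_dipole(kernel16, v))
            for axis in range(3):
                out = out + lam * _forward_diff_adjoint(_forward_diff(v, axis, 1.0), axis, 1.0)
            return out.ravel()

        op = LinearOperator((16**3, 16**3), matvec=matvec, dtype=float)
        rhs = _apply_dipole(kernel16, phi).ravel()
        iterative, info = cg(op, rhs, rtol=1e-12, maxiter=3000)
        assert info == 0
        rel = np.linalg.norm(iterative.reshape(16, 16, 16) - closed) / np.linalg.norm(closed)
        assert rel < 1e-6

    def test_residual_non_decreasing_along_lambda(self, kernel16):
        rng = np.random.default_rng(2)
        phi = _apply_dipole(kernel16, rng.normal(size=(16, 16, 16)))
        residuals = []
        for lam in np.logspace(-4, 0, 10):
            chi = _l2_solve(phi, kernel16, lam)
            residuals.append(np.linalg.norm(_apply_dipole(kernel16, chi) - phi))
        assert np.all(np.diff(residuals) >= -1e-12)


class TestLambdaSweep:
    def test_endpoints_and_path_monotonicity(self, kernel16):
        rng = np.random.default_rng(3)
        phi = _apply_dipole(kernel16, rng.normal(size=(16, 16, 16)))
        sweep = l2_lambda_sweep(full_tissue(phi), kernel16, L2Config(sweep_points=12))
        assert sweep.lambdas[0] == pytest.approx(1e-4, rel=1e-12)
        assert sweep.lambdas[-1] == pytest.approx(1.0, rel=1e-12)
        assert np.all(np.diff(sweep.residual_norms) >= -1e-12)
        assert np.all(np.diff(sweep.penalty_norms) <= 1e-12)

    def test_corner_beats_endpoints_on_noisy_phantom(self, truth48):
        """L-curve corner reconstruction error <= both sweep endpoints."""
        acq = AcquisitionParams(snr=50.0)
        wrapped, _ = field_to_wrapped_phase(truth48.field_total, acq, rng_seed=3)
        tissue = phase_to_ppm(vsharp(laplacian_unwrap(wrapped), truth48.mask, VSharpConfig()))
        sweep = l2_lambda_sweep(tissue, truth48.kernel, L2Config(sweep_points=15))
        assert not sweep.degenerate

        def recon_error(lam):
            chi = l2_invert(tissue, truth48.kernel, L2Config(lam=lam))
            gt = referenced_truth(truth48, chi.mask)
            return np.linalg.norm(chi.data[chi.mask] - gt[chi.mask])

        corner = recon_error(sweep.optimal_lambda)
        assert corner <= recon_error(sweep.lambdas[0])
        assert corner <= recon_error(sweep.lambdas[-1])

    def test_degenerate_sweep_falls_back_to_mid_lambda(self, kernel16):
        sweep = l2_lambda_sweep(full_tissue(np.zeros((16, 16, 16))), kernel16, L2Config(sweep_points=9))
        assert sweep.degenerate
        assert sweep.optimal_lambda == pytest.approx(sweep.lambdas[4])

    def test_too_few_points_rejected(self, kernel16):
        with pytest.raises(ValueError):
            l2_lambda_sweep(full_tissue(np.zeros((16, 16, 16))), kernel16, L2Config(sweep_points=2))


@pytest.fixture(scope="module")
def medi_problem():
    n = 32
    x = np.arange(n) - (n - 1) / 2
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    mask = X**2 + Y**2 + Z**2 <= 13**2
    chi_true = np.zeros((n, n, n))
    chi_true[((X - 3) ** 2 / 9 + Y**2 / 16 + Z**2 / 9) <= 1] = 0.1
    kernel = make_dipole_kernel(KSpaceGrid((n, n, n)))
    phi = _apply_dipole(kernel, chi_true)
    magnitude = np.where(mask, 1.0 + 0.2 * (chi_true > 0), 0.05)
    return kernel, phi, magnitude, mask, chi_true


class TestMEDI:
    def test_zero_field_gives_zero_map(self, medi_problem):
        kernel, phi, magnitude, mask, _ = medi_problem
        tissue = TissueField(np.zeros(phi.shape), mask, (1.0, 1.0, 1.0), "ppm")
        rec = medi_invert(tissue, magnitude, mask, kernel)
        assert np.all(rec.data == 0)

    def test_objective_non_increasing_across_outer_iterations(self, medi_problem):
        """IRLS majorize-minimize: the smoothed objective cannot increase."""
        kernel, phi, magnitude, mask, _ = medi_problem
        tissue = TissueField(phi, mask, (1.0, 1.0, 1.0), "ppm")
        rec = medi_invert(tissue, magnitude, mask, kernel, MEDIConfig(lam=1000.0))
        trace = np.array(rec.objective_trace)
        assert len(trace) >= 2
        assert np.all(np.diff(trace) <= 1e-8 * np.maximum(np.abs(trace[:-1]), 1.0))

    def test_data_dominant_limit_matches_small_delta_tkd(self, medi_problem):
        """Uniform magnitude + huge lambda approaches TKD with delta -> 0 off the cone."""
        kernel, phi, _, _, _ = medi_problem
        full = np.ones(phi.shape, bool)
        tissue = TissueField(phi, full, (1.0, 1.0, 1.0), "ppm")
        rec = medi_invert(
            tissue,
            np.ones(phi.shape),
            full,
            kernel,
            MEDIConfig(lam=1e7, max_outer_iters=10, max_cg_iters=300, rel_tol=1e-4),
        )
        tkd = tkd_invert(tissue, kernel, TKDConfig(delta=0.01))
        well = np.abs(kernel.values) > 0.15
        a = np.fft.fftn(rec.data)[well]
        b = np.fft.fftn(tkd.data)[well]
        assert np.linalg.norm(a - b) / np.linalg.norm(b) < 0.05

    def test_nonpositive_magnitude_rejected(self, medi_problem):
        kernel, phi, _, mask, _ = medi_problem
        tissue = TissueField(phi, mask, (1.0, 1.0, 1.0), "ppm")
        with pytest.raises(ValueError, match="magnitude"):
            medi_invert(tissue, np.zeros(phi.shape), mask, kernel)


class TestStreakingMetric:
    def test_exact_reconstruction_scores_zero(self, truth48):
        gt = truth48.chi_internal.data
        assert streaking_metric(gt, gt, mask=truth48.mask) == 0.0

    def test_cone_supported_perturbation_increases_metric(self, truth48, tissue48):
        rec = tkd_invert(tissue48, truth48.kernel, TKDConfig(0.3))
        gt = truth48.chi_internal.data
        base = streaking_metric(rec, gt, mask=rec.mask)
        cone = kernel_cone_mask(truth48.kernel, 0.1) & ~kernel_cone_mask(truth48.kernel, 1e-9)
        rng = np.random.default_rng(2)
        spectrum = np.where(cone, np.fft.fftn(rng.normal(size=rec.data.shape)), 0)
        pert = np.real(np.fft.ifftn(spectrum))
        pert *= 0.02 / np.abs(pert).max()
        assert streaking_metric(rec.data + pert, gt, mask=rec.mask) > base

    def test_larger_threshold_suppresses_noise_streaks(self, truth48):
        """In the noise-dominated regime, delta = 0.3 streaks less than 0.2."""
        acq = AcquisitionParams(snr=10.0)
        wrapped, _ = field_to_wrapped_phase(truth48.field_total, acq, rng_seed=5)
        tissue = phase_to_ppm(vsharp(laplacian_unwrap(wrapped), truth48.mask, VSharpConfig()))
        gt = truth48.chi_internal.data
        metrics = {}
        for delta in (0.2, 0.3):
            rec = tkd_invert(tissue, truth48.kernel, TKDConfig(delta))
            metrics[delta] = streaking_metric(rec, gt, mask=rec.mask)
        assert metrics[0.3] <= metrics[0.2]
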