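"""Spherical harmonics, Funk–Radon ODFs, GFA, peaks, and QA/NQA."""

import numpy as np
import pytest

from hydikit.gradients import DWIDataset
from hydikit.phantom import (
    AcquisitionSpec,
    CompartmentSpec,
    compartment_signal,
    make_gradient_scheme,
)
from hydikit.qbi import (
    ODFField,
    SphereGrid,
    find_peaks,
    fit_sh,
    frt_coefficients,
    frt_odf,
    gfa,
    n_coefficients,
    qa_nqa,
    sh_basis,
    sh_degrees,
)

from conftest import single_tensor_dataset


class TestSphereGrid:
    def test_size_and_unit_norms(self, sphere):
        assert len(sphere) >= 100
        np.testing.assert_allclose(
            np.linalg.norm(sphere.vertices, axis=1), 1.0, atol=1e-12
        )

    def test_neighbor_graph_connected(self, sphere):
        seen = {0}
        frontier = [0]
        while frontier:
            i = frontier.pop()
            for j in sphere.neighbors[i]:
                if j not in seen:
                    seen.add(j)
                    frontier.append(int(j))
        assert len(seen) == len(sphere)


class TestFitSH:
    def test_constant_signal_only_l0(self, sphere):
        acq = AcquisitionSpec(shell_bvalues=(3000.0,), directions_per_shell=60, n_b0=1,
                              grid_shape=(1, 1, 1))
        gtab = make_gradient_scheme(acq, seed=0)
        signal = np.full((1, 1, 1, len(gtab)), 2.5)
        shf = fit_sh(DWIDataset(signal, np.eye(4), gtab))
        coefs = shf.coefficients[1][0, 0, 0]
        assert coefs.size == 45
        assert np.abs(coefs[1:]).max() < 1e-10
        assert coefs[0] != 0

    def test_exact_recovery_of_order4_signal(self):
        acq = AcquisitionSpec(shell_bvalues=(3000.0,), directions_per_shell=60, n_b0=1,
                              grid_shape=(1, 1, 1))
        gtab = make_gradient_scheme(acq, seed=2)
        rng = np.random.default_rng(0)
        true_coefs = rng.normal(size=n_coefficients(4))
        dirs = gtab.bvecs[gtab.bvals > 0]
        sig = sh_basis(4, dirs) @ true_coefs
        signal = np.zeros((1, 1, 1, len(gtab)))
        signal[..., gtab.bvals > 0] = sig
        signal[..., gtab.bvals == 0] = 1.0
        shf = fit_sh(DWIDataset(signal, np.eye(4), gtab), order=4, regularization=0.0)
        np.testing.assert_allclose(shf.coefficients[1][0, 0, 0], true_coefs, atol=1e-8)

    def test_regularization_shrinks_high_order_energy(self):
        ds, _ = single_tensor_dataset(grid=(1, 1, 1), seed=3)
        rng = np.random.default_rng(42)
        noisy = DWIDataset(
            ds.signal + rng.normal(0, 10.0, ds.signal.shape), ds.affine, ds.gtab
        )
        c0 = fit_sh(noisy, regularization=0.0).coefficients[1][0, 0, 0]
        c6 = fit_sh(noisy, regularization=0.006).coefficients[1][0, 0, 0]
        high = np.array([l >= 6 for l, _ in sh_degrees(8)])
        assert np.sum(c6[high] ** 2) < np.sum(c0[high] ** 2)

    def test_order_autoreduction(self):
        ds, _ = single_tensor_dataset(n_dirs=20, grid=(1, 1, 1))
        shf = fit_sh(ds, order=8)
        assert shf.orders[1] == 4  # 15 coefficients fit 20 directions


class TestFRT:
    def test_isotropic_signal_constant_odf(self, sphere):
        d = 1.0e-3
        ds, _ = single_tensor_dataset(eigenvalues=(d, d, d), grid=(1, 1, 1))
        odf = frt_odf(fit_sh(ds), sphere)
        psi = odf.values[0, 0, 0]
        assert (psi.max() - psi.min()) < 1e-10 * psi.mean()

    def test_analytic_matches_great_circle_integration(self, sphere):
        # brute-force Funk–Radon: average over 720 points on each equator
        rng = np.random.default_rng(1)
        order = 8
        coefs = rng.normal(size=n_coefficients(order))
        analytic = frt_coefficients(coefs, order) @ sh_basis(order, sphere.vertices).T

        t = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        numeric = np.empty(len(sphere))
        for i, u in enumerate(sphere.vertices):
            probe = np.array([1.0, 0, 0]) if abs(u[0]) < 0.9 else np.array([0.0, 1, 0])
            e1 = np.cross(u, probe)
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(u, e1)
            circle = np.outer(np.cos(t), e1) + np.outer(np.sin(t), e2)
            numeric[i] = 2 * np.pi * np.mean(sh_basis(order, circle) @ coefs)
        scale = np.abs(analytic).max()
        np.testing.assert_allclose(analytic / scale, numeric / scale, atol=1e-3)

    def test_single_fiber_odf_peak_near_truth(self, sphere):
        axis = np.array([1.0, 0.0, 0.0])
        ds, _ = single_tensor_dataset(axis=axis, shell_bvalues=(3000.0,), grid=(1, 1, 1))
        odf = frt_odf(fit_sh(ds), sphere)
        psi = odf.values[0, 0, 0]
        i = int(np.argmax(psi))
        best = sphere.vertices[i]
        ang = np.degrees(np.arccos(np.clip(abs(best @ axis), -1, 1)))
        # within one grid step of the true direction
        nbr = sphere.vertices[sphere.neighbors[i]]
        step = np.degrees(np.arccos(np.clip(np.abs(nbr @ best), -1, 1))).max()
        assert ang <= step


class TestGFA:
    def test_constant_odf_zero(self, sphere):
        odf = _toy_odf(np.full((1, len(sphere)), 3.3), sphere)
        assert gfa(odf).values[0, 0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_single_nonzero_sample_is_one(self, sphere):
        psi = np.zeros((1, len(sphere)))
        psi[0, 17] = 2.0
        assert gfa(_toy_odf(psi, sphere)).values[0, 0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_direct_formula(self, sphere):
        rng = np.random.default_rng(8)
        psi = rng.uniform(0.1, 2.0, (5, len(sphere)))
        got = gfa(_toy_odf(psi, sphere)).values[:, 0, 0]
        n = psi.shape[1]
        expected = np.sqrt(
            n * np.sum((psi - psi.mean(1, keepdims=True)) ** 2, 1)
            / ((n - 1) * np.sum(psi**2, 1))
        )
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_bounds_and_scale_invariance(self, sphere):
        rng = np.random.default_rng(9)
        psi = rng.uniform(0, 1, (20, len(sphere)))
        vals = gfa(_toy_odf(psi, sphere)).values[:, 0, 0]
        assert np.all((vals >= 0) & (vals <= 1))
        scaled = gfa(_toy_odf(4.2 * psi, sphere)).values[:, 0, 0]
        np.testing.assert_allclose(vals, scaled, rtol=1e-12)

    def test_all_zero_odf_gfa_zero(self, sphere):
        assert gfa(_toy_odf(np.zeros((1, len(sphere))), sphere)).values[0, 0, 0] == 0.0


class TestPeaks:
    def test_single_fiber_one_refined_peak(self, sphere):
        axis = np.array([1.0, 0.0, 0.0])
        ds, _ = single_tensor_dataset(axis=axis, shell_bvalues=(3000.0,), grid=(1, 1, 1))
        peaks = find_peaks(frt_odf(fit_sh(ds), sphere))
        assert peaks.n_peaks[0, 0, 0] == 1
        d = peaks.principal_direction[0, 0, 0]
        ang = np.degrees(np.arccos(np.clip(abs(d @ axis), -1, 1)))
        assert ang < 1.0  # off-grid refinement beats the ~4 deg vertex spacing

    def test_crossing_fibers_two_peaks_90_deg(self, sphere):
        acq = AcquisitionSpec(shell_bvalues=(4000.0,), directions_per_shell=60, n_b0=1,
                              grid_shape=(1, 1, 1))
        gtab = make_gradient_scheme(acq, seed=0)
        comps = [
            CompartmentSpec.from_axis((1.7e-3, 2e-4, 2e-4), (1, 0, 0), 0.5),
            CompartmentSpec.from_axis((1.7e-3, 2e-4, 2e-4), (0, 1, 0), 0.5),
        ]
        sig = compartment_signal(gtab, comps, 1000.0)
        ds = DWIDataset(sig.reshape(1, 1, 1, -1), np.eye(4), gtab)
        peaks = find_peaks(frt_odf(fit_sh(ds), sphere))
        assert peaks.n_peaks[0, 0, 0] >= 2
        d1, d2 = peaks.directions[0, 0, 0, :2]
        sep = np.degrees(np.arccos(np.clip(abs(d1 @ d2), -1, 1)))
        assert sep == pytest.approx(90.0, abs=5.0)

    def test_flat_odf_flagged_degenerate(self, sphere):
        peaks = find_peaks(_toy_odf(np.full((1, len(sphere)), 1.0), sphere))
        assert bool(peaks.degenerate[0, 0, 0])
        assert peaks.n_peaks[0, 0, 0] == 1  # deterministic placeholder

    def test_min_separation_enforced(self, sphere):
        rng = np.random.default_rng(12)
        psi = rng.uniform(0.5, 1.5, (10, len(sphere)))
        peaks = find_peaks(_toy_odf(psi, sphere), min_separation_deg=25.0)
        for v in range(10):
            n = peaks.n_peaks[v, 0, 0]
            for a in range(n):
                for b in range(a + 1, n):
                    da = peaks.directions[v, 0, 0, a]
                    db = peaks.directions[v, 0, 0, b]
                    sep = np.degrees(np.arccos(np.clip(abs(da @ db), -1, 1)))
                    assert sep >= 25.0 - 1e-6


class TestQA:
    def test_isotropic_voxel_zero_qa(self, sphere):
        psi = np.vstack([np.full(len(sphere), 1.0), np.full(len(sphere), 0.5)])
        psi[1, 3] = 1.5  # second voxel carries the anisotropy
        peaks = find_peaks(_toy_odf(psi, sphere))
        _, qa = qa_nqa(peaks)
        assert qa[0, 0, 0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_max_nqa_is_one(self, sphere):
        rng = np.random.default_rng(5)
        psi = rng.uniform(0.2, 1.0, (8, len(sphere)))
        nqa, _ = qa_nqa(find_peaks(_toy_odf(psi, sphere)))
        assert np.nanmax(nqa.values) == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_two_voxel_example(self, sphere):
        n = len(sphere)
        psi = np.vstack([np.full(n, 0.8), np.full(n, 0.4)])
        psi[0, 10] = 1.3
        psi[1, 20] = 0.9
        peaks = find_peaks(_toy_odf(psi, sphere))
        _, qa = qa_nqa(peaks)
        z0 = 1.0 / 0.8  # max over volume of the per-voxel ODF minimum
        assert qa[0, 0, 0, 0] == pytest.approx(z0 * (1.3 - 0.8), rel=1e-12)
        assert qa[1, 0, 0, 0] == pytest.approx(z0 * (0.9 - 0.4), rel=1e-12)

    def test_shared_scale_override(self, sphere):
        psi = np.full((1, len(sphere)), 0.5)
        psi[0, 4] = 1.0
        peaks = find_peaks(_toy_odf(psi, sphere))
        nqa_own, qa = qa_nqa(peaks)
        nqa_shared, _ = qa_nqa(peaks, qa_max=2 * np.nanmax(qa[..., 0]))
        assert np.nanmax(nqa_own.values) == pytest.approx(1.0)
        assert np.nanmax(nqa_shared.values) == pytest.approx(0.5)


def _toy_odf(psi_rows: np.ndarray, sphere: SphereGrid) -> ODFField:
    n = psi_rows.shape[0]
    values = psi_rows.reshape(n, 1, 1, -1).astype(float)
    mask = np.ones((n, 1, 1), dtype=bool)
    return ODFField(values, sphere, mask)
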