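"""SNR, smoothing, BH-FDR, and voxel-wise/ROI trend regressions."""

import numpy as np
import pytest

from hydikit.dti import ScalarMap
from hydikit.gradients import DWIDataset, GradientTable
from hydikit.stats import (
    fdr_bh,
    gaussian_smooth,
    roi_mean_trend,
    snr,
    voxelwise_shell_regression,
)


def _smap(values):
    values = np.asarray(values, dtype=float)
    return ScalarMap("X", values, np.isfinite(values))


class TestSNR:
    def test_single_b0_rejected(self):
        gtab = GradientTable(
            [0.0, 1000.0] + [1000.0] * 6,
            np.vstack([np.zeros(3), np.random.default_rng(0).normal(size=(7, 3))]),
        )
        ds = DWIDataset(np.ones((2, 2, 1, 8)), np.eye(4), gtab)
        with pytest.raises(ValueError, match="at least 2 b0"):
            snr(ds, np.ones((2, 2, 1), dtype=bool))

    def test_noiseless_b0_gives_inf_with_warning(self, noiseless_phantom):
        ds, truth = noiseless_phantom
        with pytest.warns(UserWarning, match="noise = 0"):
            rep = snr(ds, truth.masks["bundle"])
        assert all(np.isinf(v) for v in rep.per_shell.values())

    def test_nominal_snr_recovered(self):
        # full-size bundle (320 voxels): the b0-spread estimator carries a
        # small upward bias (5-sample SD underestimates sigma by c4≈0.94)
        # but must land within 10% of the nominal shell-1 SNR
        from hydikit.phantom import PhantomSpec, build_phantom

        ds, truth = build_phantom(PhantomSpec(nominal_snr=40.0, seed=2))
        rep = snr(ds, truth.masks["bundle"])
        assert rep.per_shell[1] == pytest.approx(40.0, rel=0.10)

    def test_snr_decreases_across_shells(self, noisy_phantom):
        ds, truth = noisy_phantom
        rep = snr(ds, truth.masks["bundle"])
        vals = [rep.per_shell[s] for s in range(1, 6)]
        assert np.all(np.diff(vals) < 0)

    def test_scheme_snr_is_mean_of_member_shells(self, noisy_phantom):
        ds, truth = noisy_phantom
        rep = snr(ds, truth.masks["bundle"])
        for k in range(1, 6):
            expected = np.mean([rep.per_shell[s] for s in range(1, k + 1)])
            assert rep.per_scheme[k] == pytest.approx(expected, rel=1e-12)


class TestSmoothing:
    def test_fwhm_zero_identity(self):
        rng = np.random.default_rng(0)
        m = _smap(rng.normal(size=(6, 6, 4)))
        out = gaussian_smooth(m, 0.0)
        np.testing.assert_array_equal(out.values, m.values)

    def test_constant_map_unchanged(self):
        m = _smap(np.full((8, 8, 4), 2.5))
        out = gaussian_smooth(m, 3.0)
        np.testing.assert_allclose(out.values, 2.5, rtol=1e-10)

    def test_delta_mass_conserved(self):
        vals = np.zeros((15, 15, 15))
        vals[7, 7, 7] = 1.0
        out = gaussian_smooth(_smap(vals), 3.0)
        assert out.values.sum() == pytest.approx(1.0, abs=1e-6)

    def test_commutes_with_scaling(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(6, 6, 6))
        a = gaussian_smooth(_smap(4.0 * vals), 3.0).values
        b = 4.0 * gaussian_smooth(_smap(vals), 3.0).values
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_nan_aware_renormalization(self):
        vals = np.full((8, 8, 4), 1.7)
        vals[:2] = np.nan
        out = gaussian_smooth(_smap(vals), 3.0)
        finite = np.isfinite(vals)
        np.testing.assert_allclose(out.values[finite], 1.7, rtol=1e-10)
        assert np.all(np.isnan(out.values[~finite]))

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            gaussian_smooth(_smap(np.zeros((3, 3, 3))), -1.0)


class TestFdrBH:
    def test_all_small_all_rejected(self):
        crit, rej = fdr_bh(np.full(100, 0.001), q=0.05)
        assert crit == 0.001
        assert rej.all()

    def test_all_large_none_rejected(self):
        crit, rej = fdr_bh(np.full(10, 0.9), q=0.05)
        assert crit == 0.0
        assert not rej.any()

    def test_worked_step_up_example(self):
        crit, rej = fdr_bh([0.001, 0.01, 0.02, 0.03, 0.5], q=0.05)
        assert crit == 0.03
        assert rej.sum() == 4

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(200):
            m = rng.integers(1, 40)
            p = rng.uniform(size=m)
            crit, rej = fdr_bh(p, q=0.05)
            # O(m²) step-up oracle
            crit_oracle = 0.0
            ps = np.sort(p)
            for i in range(m):
                if ps[i] <= (i + 1) / m * 0.05:
                    crit_oracle = ps[i]
            assert crit == pytest.approx(crit_oracle, abs=0)
            np.testing.assert_array_equal(rej, p <= crit_oracle)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(2)
        p = rng.uniform(size=500) ** 2
        _, rej = fdr_bh(p, q=0.05)
        ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
        np.testing.assert_array_equal(rej, ref)

    def test_monotone_in_q(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=200)
        prev = np.zeros(200, dtype=bool)
        for q in (0.01, 0.05, 0.1, 0.2):
            _, rej = fdr_bh(p, q=q)
            assert np.all(prev <= rej)
            prev = rej

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([], q=0.05)


class TestVoxelwiseRegression:
    def test_exact_linear_maps(self):
        mask = np.ones((5, 5, 2), dtype=bool)
        maps, codes = [], []
        for code in range(1, 6):
            maps.append(np.full((5, 5, 2), 0.5 - 0.05 * code))
            codes.append(code)
        res = voxelwise_shell_regression(maps, codes, mask)
        np.testing.assert_allclose(res.slope[mask], -0.05, atol=1e-12)
        assert res.significant[mask].all()

    def test_engine_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(31)
        mask = np.ones((4, 3, 1), dtype=bool)
        codes = np.tile(np.arange(1, 6), 3)
        ages = np.repeat([10.0, 15.0, 24.0], 5)
        maps = [rng.normal(size=(4, 3, 1)) for _ in codes]
        res = voxelwise_shell_regression(maps, codes, mask, ages=ages)
        x = sm.add_constant(np.column_stack([codes, ages]))
        for idx in np.ndindex(4, 3, 1):
            y = np.array([m[idx] for m in maps])
            fit = sm.OLS(y, x).fit()
            assert res.slope[idx] == pytest.approx(fit.params[1], abs=1e-10)
            assert res.t[idx] == pytest.approx(fit.tvalues[1], abs=1e-10)
            assert res.p[idx] == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_null_maps_control_false_discoveries(self):
        rng = np.random.default_rng(5)
        mask = np.ones((10, 10, 10), dtype=bool)
        codes = np.tile(np.arange(1, 6), 3)
        n_reps, fdp = 25, []
        for _ in range(n_reps):
            maps = [rng.normal(size=(10, 10, 10)) for _ in codes]
            res = voxelwise_shell_regression(maps, codes, mask, q=0.05)
            n_rej = int(res.significant.sum())
            fdp.append(1.0 if n_rej > 0 else 0.0)  # all discoveries false under null
        se = np.sqrt(0.05 * 0.95 / n_reps)
        assert np.mean(fdp) <= 0.05 + 3 * se

    def test_all_nan_voxels_excluded(self):
        mask = np.ones((2, 2, 1), dtype=bool)
        maps = [np.full((2, 2, 1), 0.5 - 0.01 * c) for c in range(1, 6)]
        for m in maps:
            m[0, 0, 0] = np.nan
        res = voxelwise_shell_regression(maps, [1, 2, 3, 4, 5], mask)
        assert np.isnan(res.p[0, 0, 0])
        assert not res.significant[0, 0, 0]


class TestRoiMeanTrend:
    def test_single_voxel_roi(self):
        roi = np.zeros((3, 3, 1), dtype=bool)
        roi[1, 1, 0] = True
        maps = [np.full((3, 3, 1), float(c)) for c in range(1, 6)]
        table, trend = roi_mean_trend(maps, [1, 2, 3, 4, 5], roi)
        np.testing.assert_allclose(table["mean"], [1, 2, 3, 4, 5])
        assert trend.slope == pytest.approx(1.0, abs=1e-12)

    def test_means_match_brute_force_masked_average(self):
        rng = np.random.default_rng(13)
        roi = rng.uniform(size=(6, 6, 3)) > 0.5
        maps = [rng.normal(size=(6, 6, 3)) for _ in range(3)]
        table, _ = roi_mean_trend(maps, [1, 2, 3], roi)
        for i, m in enumerate(maps):
            total, count = 0.0, 0
            for idx in np.ndindex(*m.shape):
                if roi[idx]:
                    total += m[idx]
                    count += 1
            assert table["mean"][i] == pytest.approx(total / count, rel=1e-12)

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            roi_mean_trend([np.ones((2, 2, 1))], [1], np.zeros((2, 2, 1), dtype=bool))
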