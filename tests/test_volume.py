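"""Volume operations: masks, rendering, resampling, symmetry averaging,
operator refinement, FSC and filtering."""

import numpy as np
import pytest

import mtseam as ms
from mtseam.errors import (
    DegenerateCorrelationError,
    EmptyDensityError,
    EmptyMaskError,
    GeometryError,
    ParameterError,
)


def _gaussian_blob(n=48, vs=2.0, offset=(8.0, 3.0, 0.0), sigma=6.0):
    zz, yy, xx = np.indices((n, n, n), dtype=float)
    c = (n - 1) / 2.0
    ox, oy, oz = np.asarray(offset) / vs
    g = np.exp(
        -(((xx - c - ox) ** 2 + (yy - c - oy) ** 2 + (zz - c - oz) ** 2) * vs**2)
        / (2.0 * sigma**2)
    )
    return ms.DensityMap(g, vs)


class TestMakeMask:
    def test_empty_support_raises(self):
        with pytest.raises(EmptyMaskError):
            ms.make_mask_from_density(ms.DensityMap(np.zeros((8, 8, 8)), 1.0), 0.5)

    def test_half_max_support_of_blob(self):
        """Binary support at threshold 0.5 reproduces the half-max isosurface."""
        blob = _gaussian_blob()
        mask = ms.make_mask_from_density(blob, threshold=0.5, extend=0.0, soft_edge=0.0)
        expected = blob.grid >= 0.5 * blob.grid.max()
        assert np.array_equal(mask.grid > 0.5, expected)
        assert set(np.unique(mask.grid)) <= {0.0, 1.0}

    def test_soft_edge_produces_intermediate_values(self):
        mask = ms.make_mask_from_density(_gaussian_blob(), 0.5, extend=2.0, soft_edge=6.0)
        rim = (mask.grid > 0.0) & (mask.grid < 1.0)
        assert rim.any()
        assert mask.grid.min() >= 0.0 and mask.grid.max() <= 1.0

    def test_bad_threshold(self):
        with pytest.raises(ParameterError):
            ms.make_mask_from_density(_gaussian_blob(), 1.5)


class TestRenderTemplateDensity:
    def test_single_point_integral(self):
        m = ms.render_template_density(
            np.array([[48.0, 48.0, 48.0]]), 1.0, sigma=4.0, shape=(48, 48, 48), voxel_size=2.0
        )
        assert m.grid.argmax() == np.ravel_multi_index((24, 24, 24), m.shape)
        # voxel sum equals the point weight (Gaussians are normalised so that
        # the gridded integral carries the weight)
        assert np.isclose(m.grid.sum(), 1.0, rtol=1e-3)

    def test_linearity_of_two_points(self):
        p1, p2 = [30.0, 48.0, 48.0], [66.0, 48.0, 48.0]
        kw = dict(sigma=4.0, shape=(48, 48, 48), voxel_size=2.0)
        both = ms.render_template_density(np.array([p1, p2]), 1.0, **kw)
        a = ms.render_template_density(np.array([p1]), 1.0, **kw)
        b = ms.render_template_density(np.array([p2]), 1.0, **kw)
        assert np.allclose(both.grid, a.grid + b.grid, atol=1e-12)

    def test_axial_autocorrelation_peaks_at_dimer_rise(self):
        """A column of dimers spaced 82.293 A puts the first off-origin
        autocorrelation peak at that spacing."""
        rise = 82.293
        zs = 40.0 + np.arange(4) * rise
        pts = np.array([[64.0, 64.0, z] for z in zs])
        m = ms.render_template_density(pts, 1.0, sigma=5.0, shape=(200, 64, 64), voxel_size=2.0)
        profile = m.grid.sum(axis=(1, 2))
        ac = np.correlate(profile, profile, mode="full")[len(profile) - 1 :]
        lags = np.arange(len(ac)) * 2.0
        interior = (lags > 50) & (lags < 120)
        peak_lag = lags[interior][np.argmax(ac[interior])]
        assert abs(peak_lag - rise) <= 2.0  # one voxel

    def test_all_points_outside_frame(self):
        with pytest.raises(EmptyDensityError):
            ms.render_template_density(
                np.array([[500.0, 0.0, 0.0]]), 1.0, sigma=3.0, shape=(32, 32, 32), voxel_size=2.0
            )


class TestTransformMap:
    def test_identity_trilinear_bitexact(self):
        blob = _gaussian_blob()
        out = ms.transform_map(blob, ms.RigidTransform.identity(), "trilinear")
        assert np.array_equal(out.grid, blob.grid)

    @pytest.mark.parametrize("interp", ["cubic", "fourier"])
    def test_full_turn_recovers_input(self, interp):
        blob = _gaussian_blob()
        op = ms.SymOperator(index=1, psi_deg=360.0)
        T = ms.operator_to_transform(op, blob.center)
        out = ms.transform_map(blob, T, interp)
        assert np.abs(out.grid - blob.grid).max() < 1e-6 * blob.grid.max()

    @pytest.mark.parametrize("interp", ["cubic", "fourier"])
    def test_rotate_and_back(self, interp):
        blob = _gaussian_blob()
        op = ms.SymOperator(index=1, psi_deg=-27.69, dz=9.495)
        T = ms.operator_to_transform(op, blob.center)
        back = ms.transform_map(ms.transform_map(blob, T, interp), T.inverse(), interp)
        tol = 1e-8 if interp == "fourier" else 2e-3
        assert np.abs(back.grid - blob.grid).max() < tol * blob.grid.max()

    def test_fourier_matches_cubic_on_smooth_map(self):
        blob = _gaussian_blob()
        op = ms.SymOperator(index=1, psi_deg=100.0, dz=5.0, dx=1.2, dy=-0.7)
        T = ms.operator_to_transform(op, blob.center)
        f = ms.transform_map(blob, T, "fourier")
        c = ms.transform_map(blob, T, "cubic")
        assert np.abs(f.grid - c.grid).max() < 1e-3 * blob.grid.max()


class TestApplyLocalSymmetry:
    def test_symmetric_map_is_fixed_point(self, mid_map, mid_mask, mid_symmetrised):
        dmap, _ = mid_map
        dev = np.abs(mid_symmetrised.grid - dmap.grid).max() / dmap.grid.max()
        assert dev < 1e-3

    def test_idempotence(self, mid_map, mid_mask, mid_symmetrised):
        _, gt = mid_map
        twice = ms.apply_local_symmetry(mid_symmetrised, mid_mask, gt.operators)
        dev = np.abs(twice.grid - mid_symmetrised.grid).max() / mid_symmetrised.grid.max()
        assert dev < 1e-3

    def test_mean_conservation(self, mid_map, mid_mask, mid_symmetrised):
        dmap, _ = mid_map
        rel = abs(mid_symmetrised.grid.mean() - dmap.grid.mean()) / abs(dmap.grid.mean())
        assert rel < 0.005

    def test_untouched_outside_supports(self, mid_map, mid_mask, mid_symmetrised):
        """A corner far from every protofilament copy keeps its exact values."""
        dmap, _ = mid_map
        corner = (slice(0, 6), slice(0, 6), slice(0, 6))
        assert np.allclose(mid_symmetrised.grid[corner], dmap.grid[corner], atol=1e-12)

    def test_noise_scaling_with_fold(self, mid_map, mid_mask, mid_symmetrised):
        """Averaging f independent copies shrinks masked noise sigma by sqrt(f)."""
        dmap, gt = mid_map
        rng = np.random.default_rng(7)
        sigma = 0.2 * dmap.grid.max()
        noisy = dmap.with_grid(dmap.grid + sigma * rng.standard_normal(dmap.shape))
        support = mid_mask.grid > 0.9
        for ops, fold in [(gt.operators, 13), (gt.operators.with_excluded({1, 2, 11, 12}), 9)]:
            sym_noisy = ms.apply_local_symmetry(noisy, mid_mask, ops)
            sym_clean = (
                mid_symmetrised
                if fold == 13
                else ms.apply_local_symmetry(dmap, mid_mask, ops)
            )
            resid = (sym_noisy.grid - sym_clean.grid)[support]
            assert np.isclose(sigma / resid.std(), np.sqrt(fold), rtol=0.10)

    def test_needs_two_operators(self, mid_map, mid_mask):
        dmap, gt = mid_map
        ops = gt.operators.with_excluded(set(range(1, 13)))
        with pytest.raises(ParameterError):
            ms.apply_local_symmetry(dmap, mid_mask, ops)

    def test_geometry_mismatch(self, mid_map):
        dmap, gt = mid_map
        bad = ms.SoftMask(np.ones((10, 10, 10)), dmap.voxel_size)
        with pytest.raises(GeometryError):
            ms.apply_local_symmetry(dmap, bad, gt.operators)


class TestRefineOperators:
    def test_ideal_operators_are_a_fixed_point(self, small_map, small_mask):
        """On a map built with the ideal ladder, refinement stays put."""
        dmap, gt = small_map
        search = ms.SearchGrid(psi_range=0.5, dz_range=0.5)
        refined = ms.refine_operators(dmap, small_mask, gt.operators, search)
        for before, after in zip(gt.operators.operators, refined.operators):
            assert abs(after.psi_deg - before.psi_deg) <= 0.1 + 1e-9
            assert abs(after.dz - before.dz) <= 0.1 + 1e-9

    def test_objective_never_decreases(self, small_map, small_mask):
        from mtseam.volume import _MaskedSampler

        dmap, gt = small_map
        sampler = _MaskedSampler(dmap, small_mask)
        c = dmap.center
        refined = ms.refine_operators(
            dmap, small_mask, gt.operators, ms.SearchGrid(psi_range=1.0, dz_range=1.0)
        )
        for before, after in zip(gt.operators.operators[1:], refined.operators[1:]):
            ncc_before = sampler.ncc(ms.operator_to_transform(before, c))
            ncc_after = sampler.ncc(ms.operator_to_transform(after, c))
            assert ncc_after >= ncc_before - 1e-12

    def test_flat_region_degenerate(self):
        flat = ms.DensityMap(np.ones((24, 24, 24)), 2.0)
        mask = ms.SoftMask(np.pad(np.ones((8, 8, 8)), 8), 2.0)
        ops = ms.make_operators(ms.LatticeSpec(n_pf=4, dimer_rise=10.0, starts_dimers=1.0))
        with pytest.raises(DegenerateCorrelationError):
            ms.refine_operators(flat, mask, ops)


class TestComputeFSC:
    def test_self_correlation_is_one(self, small_map):
        dmap, _ = small_map
        curve = ms.compute_fsc(dmap, dmap)
        assert np.allclose(curve.correlations, 1.0, atol=1e-12)

    def test_independent_noise_decorrelated(self):
        rng = np.random.default_rng(0)
        n = 48
        a = ms.DensityMap(rng.standard_normal((n, n, n)), 2.0)
        b = ms.DensityMap(rng.standard_normal((n, n, n)), 2.0)
        curve = ms.compute_fsc(a, b)
        # shell voxel counts ~ 4 pi k^2; |FSC| stays within 3 standard errors
        for i in range(1, len(curve.correlations)):
            count = 4.0 * np.pi * i**2
            assert abs(curve.correlations[i]) < 3.0 / np.sqrt(count)

    def test_symmetry_and_scale_invariance(self, small_map):
        dmap, _ = small_map
        rng = np.random.default_rng(1)
        other = dmap.with_grid(dmap.grid + 0.1 * dmap.grid.max() * rng.standard_normal(dmap.shape))
        c1 = ms.compute_fsc(dmap, other)
        c2 = ms.compute_fsc(other, dmap)
        c3 = ms.compute_fsc(dmap.with_grid(5.0 * dmap.grid), other)
        assert np.allclose(c1.correlations, c2.correlations, atol=1e-12)
        assert np.allclose(c1.correlations, c3.correlations, atol=1e-12)

    def test_grid_mismatch(self, small_map):
        dmap, _ = small_map
        with pytest.raises(GeometryError):
            ms.compute_fsc(dmap, ms.DensityMap(np.zeros((10, 10, 10)), 2.0))

    def test_resolution_interpolates_crossing(self):
        curve = ms.FSCCurve(np.array([0.0, 0.1, 0.2]), np.array([1.0, 0.5, 0.0]))
        # crosses 0.143 between 0.1 and 0.2; linear interpolation
        f = 0.1 + (0.5 - 0.143) / 0.5 * 0.1
        assert np.isclose(curve.resolution_at(0.143), 1.0 / f)


class TestLowpassFilter:
    def test_mean_preserved_exactly(self, small_map):
        dmap, _ = small_map
        out = ms.lowpass_filter(dmap, 10.0)
        assert np.isclose(out.grid.mean(), dmap.grid.mean(), rtol=1e-12)

    def test_noise_power_beyond_cutoff_suppressed(self):
        rng = np.random.default_rng(2)
        n, vs = 64, 2.0
        noise = ms.DensityMap(rng.standard_normal((n, n, n)), vs)
        out = ms.lowpass_filter(noise, 10.0)
        freqs = np.fft.fftfreq(n, d=vs)
        kz, ky, kx = np.meshgrid(freqs, freqs, freqs, indexing="ij", sparse=True)
        r = np.sqrt(kx**2 + ky**2 + kz**2)
        beyond = r > 1.0 / 10.0 + 2.0 / (n * vs)
        p_in = (np.abs(np.fft.fftn(noise.grid)) ** 2)[beyond].sum()
        p_out = (np.abs(np.fft.fftn(out.grid)) ** 2)[beyond].sum()
        assert p_out < 0.01 * p_in

    def test_near_nyquist_cutoff_is_identity(self):
        """A cutoff just above Nyquist passes (essentially) the whole band."""
        blob = _gaussian_blob(sigma=8.0)
        out = ms.lowpass_filter(blob, 2.0 * blob.voxel_size + 0.1)
        assert np.abs(out.grid - blob.grid).max() < 1e-6 * blob.grid.max()

    def test_cutoff_below_nyquist_rejected(self, small_map):
        dmap, _ = small_map
        with pytest.raises(ParameterError):
            ms.lowpass_filter(dmap, 2.0 * dmap.voxel_size)
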