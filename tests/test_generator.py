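"""Unit and property tests of the displacement-field generator."""

import numpy as np
import pytest
from scipy import ndimage as ndi

import ducsim as ds
from ducsim.contours import SliceSurface, fill_loop, trace_boundary
from ducsim.errors import GeometryError
from ducsim.generator import (
    DUParams,
    apply_displacement,
    averaged_response,
    contrast_response,
    displacement_magnitudes,
    perturbation_anchor,
    sample_variation,
    sobel_gradient,
    tg_profile,
    truncated_gaussian,
)
from ducsim.grids import CTVolume, ROIMask


# ---------------------------------------------------------------- Sobel


class TestSobelGradient:
    def test_flat_image_zero(self):
        assert np.allclose(sobel_gradient(np.full((8, 8), 40.0)), 0)

    def test_matches_direct_convolution(self):
        """Output equals explicit 3x3 Sobel convolution (edge-replicated)."""
        rng = np.random.default_rng(0)
        img = rng.normal(size=(12, 15)) * 100
        dx, dy = 0.8, 1.2
        kx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], float)  # d/dx (rows)
        gx = ndi.correlate(img, kx.T, mode="nearest") / (8 * dx)
        gy = ndi.correlate(img, kx, mode="nearest") / (8 * dy)
        expect = np.hypot(gx, gy)
        got = sobel_gradient(img, (dx, dy))
        assert np.allclose(got, expect)

    def test_vertical_step_interior_response(self):
        """Unit step of height h: interior response equals the kernel's step
        response scaled by h/(8*dx)."""
        h = 120.0
        img = np.zeros((9, 9))
        img[5:, :] = h
        g = sobel_gradient(img, (1.0, 1.0))
        # step response of [-1,-2,-1;0,0,0;1,2,1] across the edge rows = 4h
        assert np.allclose(g[4, 2:7], 4 * h / 8)
        assert np.allclose(g[5, 2:7], 4 * h / 8)
        assert np.allclose(g[2, 2:7], 0)

    def test_linear_ramp_uniform_interior(self):
        m = 7.5  # HU per mm
        x = np.arange(20) * 1.0
        img = np.tile(m * x[:, None], (1, 16))
        g = sobel_gradient(img, (1.0, 1.0))
        assert np.allclose(g[1:-1, 1:-1], m)

    def test_small_slice_rejected(self):
        with pytest.raises(GeometryError):
            sobel_gradient(np.zeros((2, 5)))


# ----------------------------------------------------- contrast response


class TestContrastResponse:
    @pytest.mark.parametrize(
        "g,a,expect", [(0.0, 50.0, 1.0), (50.0, 50.0, 0.5), (450.0, 50.0, 0.1)]
    )
    def test_closed_form(self, g, a, expect):
        assert contrast_response(g, a) == pytest.approx(expect)

    def test_strictly_decreasing(self):
        g = np.linspace(0, 500, 100)
        f = contrast_response(g, 50.0)
        assert np.all(np.diff(f) < 0)
        assert np.all((f > 0) & (f <= 1))

    def test_negative_gradient_rejected(self):
        with pytest.raises(ValueError):
            contrast_response(-1.0, 50.0)


# ----------------------------------------------------- averaged response


class TestAveragedResponse:
    def test_constant_preserved(self):
        assert np.allclose(averaged_response(np.full(40, 0.37), 15), 0.37)

    def test_impulse_response_is_box(self):
        """A unit spike spreads to value 1/31 over 31 consecutive positions."""
        f = np.zeros(40)
        f[7] = 1.0
        out = averaged_response(f, 15)
        assert np.sum(out > 0) == 31
        assert np.allclose(out[out > 0], 1 / 31)

    @pytest.mark.parametrize("R,k", [(40, 15), (100, 15), (9, 15), (31, 15), (5, 2)])
    def test_matches_brute_force_circular_mean(self, R, k):
        rng = np.random.default_rng(R + k)
        f = rng.random(R)
        k_eff = min(k, (R - 1) // 2)
        expect = np.array(
            [np.mean([f[(s + i) % R] for i in range(-k_eff, k_eff + 1)]) for s in range(R)]
        )
        assert np.allclose(averaged_response(f, k), expect)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            averaged_response(np.array([]), 15)


# ------------------------------------------------------ random variation


class TestSampleVariation:
    def test_median_probability_maps_to_zero(self):
        class FixedRng:
            def random(self, n):
                return np.full(n, 0.5)

        w = sample_variation(5, 50.0, 0.02, FixedRng())
        assert np.all(w == 0.0)

    def test_moments_match_gaussian(self):
        """Monte-Carlo mean/SD agree with Gaussian(0, C*sigma)."""
        rng = np.random.default_rng(42)
        C, sigma, n = 50.0, 0.02, 100_000
        w = sample_variation(n, C, sigma, rng)
        se = C * sigma / np.sqrt(n)
        assert abs(w.mean()) < 3 * se
        assert abs(w.std() / (C * sigma) - 1) < 0.02

    def test_sd_scales_linearly_with_C(self):
        rng = np.random.default_rng(7)
        w1 = sample_variation(100_000, 50.0, 0.02, rng)
        rng = np.random.default_rng(7)
        w2 = sample_variation(100_000, 100.0, 0.02, rng)
        assert w2.std() / w1.std() == pytest.approx(2.0, rel=0.05)

    def test_reproducible_given_seed(self):
        a = sample_variation(64, 50, 0.02, np.random.default_rng(3))
        b = sample_variation(64, 50, 0.02, np.random.default_rng(3))
        assert np.array_equal(a, b)


# --------------------------------------------------- truncated Gaussian


class TestTruncatedGaussian:
    def test_peak_value(self):
        w0 = 20.0
        assert truncated_gaussian(10, 10, 100, w0) == pytest.approx(
            1 / (np.sqrt(2 * np.pi) * w0)
        )

    def test_circular_symmetry_and_antipodal_minimum(self):
        R, s0, w0 = 100, 30, 20.0
        vals = truncated_gaussian(np.arange(R), s0, R, w0)
        for d in range(1, R // 2):
            assert vals[(s0 + d) % R] == pytest.approx(vals[(s0 - d) % R])
        assert np.argmin(vals) == (s0 + R // 2) % R

    def test_closed_form_at_distance(self):
        R, w0 = 100, 20.0
        peak = 1 / (np.sqrt(2 * np.pi) * w0)
        assert truncated_gaussian(40, 20, R, w0) == pytest.approx(peak * np.exp(-0.5))

    def test_normalized_profile_peaks_at_one(self):
        prof = tg_profile(80, 17, 16.0, mode="normalized")
        assert prof[17] == pytest.approx(1.0)
        verb = tg_profile(80, 17, 16.0, mode="verbatim")
        assert np.allclose(prof, verb / verb.max())

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            truncated_gaussian(100, 0, 100, 20.0)


# -------------------------------------------------------------- anchor


def _cylinder_ct_and_surfaces(arc=None, nz=5, radius=14, shape=(48, 48)):
    """Cylinder with a sharp edge; optional low-contrast angular arc."""
    nx, ny = shape
    xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    cx = cy = nx // 2
    r = np.hypot(xx - cx, yy - cy)
    step = np.clip(radius + 0.5 - r, 0, 1)  # sharp sigmoid-ish edge
    img2d = 200.0 * step
    if arc is not None:
        theta = np.arctan2(yy - cy, xx - cx)
        lo, hi, factor = arc
        in_arc = (theta >= lo) & (theta <= hi)
        img2d = np.where(in_arc, 200.0 * factor * step, img2d)
    vol = np.repeat(img2d[:, :, None], nz, axis=2)
    mask = np.repeat((r <= radius)[:, :, None], nz, axis=2)
    ct = CTVolume(vol, (1, 1, 2.5))
    m = ROIMask(mask, (1, 1, 2.5))
    return ct, m, ds.surfaces_for_roi(m)


class TestPerturbationAnchor:
    def test_single_slice_degenerate_chain(self):
        ct, m, surfs = _cylinder_ct_and_surfaces(nz=1)
        res = perturbation_anchor(ct, [surfs[0]])
        assert res.chains.shape == (surfs[0].R, 1)
        assert np.array_equal(res.chains[:, 0], np.arange(surfs[0].R))
        g = sobel_gradient(ct.axial_slice(0), (1, 1))
        gv = g[surfs[0].L[:, 0], surfs[0].L[:, 1]]
        assert res.s0 == np.argmin(gv)

    def test_anchor_lands_in_low_contrast_arc(self):
        """The arc with reduced edge step attracts the anchor."""
        ct, m, surfs = _cylinder_ct_and_surfaces(arc=(0.4, 1.6, 0.2))
        res = perturbation_anchor(ct, surfs)
        x, y = surfs[0].L[res.s0]
        theta = np.arctan2(y - 24, x - 24)
        assert 0.4 - 0.3 <= theta <= 1.6 + 0.3

    def test_tie_break_smallest_index(self):
        """Uniform gradient along the contour: anchor is index 0, stably."""
        ct, m, surfs = _cylinder_ct_and_surfaces()
        flat = CTVolume(np.zeros_like(ct.intensities), ct.spacing)
        r1 = perturbation_anchor(flat, surfs)
        r2 = perturbation_anchor(flat, surfs)
        assert r1.s0 == r2.s0 == 0


# -------------------------------------------- displacement magnitudes


class TestDisplacementMagnitudes:
    def test_uniform_slice_is_w_times_tg(self):
        """With F~=1 everywhere, D is exactly the W*TG product."""
        ct, m, surfs = _cylinder_ct_and_surfaces(nz=1)
        surf = surfs[0]
        flat = np.zeros((48, 48))
        params = DUParams(C=50, sigma_roi=0.02, seed=0)
        f = displacement_magnitudes(surf, flat, params, 5, np.random.default_rng(0))
        w = sample_variation(surf.R, 50, 0.02, np.random.default_rng(0))
        tg = tg_profile(surf.R, 5, params.w0_fraction * surf.R, "normalized")
        assert np.allclose(f.f_avg, 1.0)
        assert np.allclose(f.d, w * tg)

    def test_component_product_equivalence(self):
        """D equals the elementwise product of independently computed parts."""
        ct, m, surfs = _cylinder_ct_and_surfaces()
        surf = surfs[1]
        g = sobel_gradient(ct.axial_slice(surf.z), (1, 1))
        params = DUParams(C=100, sigma_roi=0.03, seed=9)
        f = displacement_magnitudes(surf, g, params, 11, np.random.default_rng(9))
        fct = contrast_response(g[surf.L[:, 0], surf.L[:, 1]], params.a)
        favg = averaged_response(fct, params.k)
        w = sample_variation(surf.R, 100, 0.03, np.random.default_rng(9))
        tg = tg_profile(surf.R, 11, params.w0_fraction * surf.R, "normalized")
        assert np.allclose(f.d, w * tg * favg)

    def test_localization_expected_magnitude(self):
        """E|D| at the anchor exceeds E|D| at the antipode by TG(0)/TG(R/2)."""
        ct, m, surfs = _cylinder_ct_and_surfaces(nz=1)
        surf = surfs[0]
        flat = np.zeros((48, 48))
        params = DUParams(C=50, sigma_roi=0.02, seed=0)
        s0 = 7
        at_anchor, at_anti = [], []
        anti = (s0 + surf.R // 2) % surf.R
        for seed in range(1000):
            f = displacement_magnitudes(
                surf, flat, params, s0, np.random.default_rng(seed)
            )
            at_anchor.append(abs(f.d[s0]))
            at_anti.append(abs(f.d[anti]))
        tg = tg_profile(surf.R, s0, params.w0_fraction * surf.R, "normalized")
        expect_ratio = tg[s0] / tg[anti]
        got = np.mean(at_anchor) / np.mean(at_anti)
        assert got == pytest.approx(expect_ratio, rel=0.15)


# ----------------------------------------------------- apply displacement


def _disk_surface(radius=20, n=64):
    xx, yy = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    disk = (xx - n // 2) ** 2 + (yy - n // 2) ** 2 <= radius**2
    return SliceSurface(0, trace_boundary(disk)), (n, n)


class TestApplyDisplacement:
    def test_zero_displacement_identity(self):
        surf, shape = _disk_surface()
        out = apply_displacement(surf, np.zeros(surf.R), (1, 1), shape)
        assert np.array_equal(out.L, surf.L)

    @pytest.mark.parametrize("d,r_new", [(2.0, 22.0), (-2.0, 18.0)])
    def test_uniform_displacement_changes_area_analytically(self, d, r_new):
        """Constant +-2 voxel displacement on a radius-20 circle matches
        pi*(20 +- 2)^2 within 5%."""
        surf, shape = _disk_surface()
        out = apply_displacement(surf, np.full(surf.R, d), (1, 1), shape)
        area = fill_loop(out.L, shape).sum()
        assert area == pytest.approx(np.pi * r_new**2, rel=0.05)

    def test_collapse_raises(self):
        from ducsim.errors import CollapsedContourError

        surf, shape = _disk_surface(radius=5)
        with pytest.raises(CollapsedContourError):
            apply_displacement(surf, np.full(surf.R, -5.5), (1, 1), shape)


# -------------------------------------------------------- full pipeline


class TestGenerateDuContour:
    def test_determinism_bitwise(self, pelvis):
        ct, masks = pelvis
        p = DUParams(C=100, seed=11, smoothing_sigma=1.5)
        a = ds.generate_du_contour(ct, masks["prostate"], p)
        b = ds.generate_du_contour(ct, masks["prostate"], p)
        assert np.array_equal(a.voxels, b.voxels)

    def test_zero_variation_limit_reproduces_input(self, pelvis):
        """For C below 1e-6 the unsmoothed output equals the input mask."""
        ct, masks = pelvis
        p = DUParams(C=1e-7, seed=2, smooth=False)
        out = ds.generate_du_contour(ct, masks["prostate"], p)
        assert np.array_equal(out.voxels, masks["prostate"].voxels)

    def test_cropping_changes_no_voxel(self, pelvis):
        ct, masks = pelvis
        a = ds.generate_du_contour(
            ct, masks["rectum"], DUParams(C=100, seed=5, smoothing_sigma=1.5, crop_margin=20)
        )
        b = ds.generate_du_contour(
            ct, masks["rectum"], DUParams(C=100, seed=5, smoothing_sigma=1.5, crop_margin=None)
        )
        assert np.array_equal(a.voxels, b.voxels)

    def test_output_is_valid_binary_mask(self, pelvis):
        ct, masks = pelvis
        out = ds.generate_du_contour(
            ct, masks["bladder"], DUParams(C=200, seed=3, smoothing_sigma=1.5)
        )
        assert out.voxels.dtype == bool
        assert out.shape == masks["bladder"].shape
        assert out.spacing == masks["bladder"].spacing
        assert not out.is_empty()

    def test_mean_displacement_monotone_in_C(self, pelvis):
        """Mean |D| grows strictly along the C schedule (fields only)."""
        from ducsim.generator import _gradient_cache

        ct, masks = pelvis
        m = masks["prostate"]
        surfs = ds.surfaces_for_roi(m, on_too_small="skip")
        anchor = perturbation_anchor(ct, surfs)
        grad_at = _gradient_cache(ct)
        means = []
        for C in ds.C_SCHEDULE:
            params = DUParams(C=C, sigma_roi=0.03, seed=0)
            vals = []
            for seed in range(50):
                children = np.random.SeedSequence(seed).spawn(len(surfs))
                for i, surf in enumerate(surfs):
                    f = displacement_magnitudes(
                        surf, grad_at(surf.z), params,
                        int(anchor.chains[anchor.s0, i]),
                        np.random.default_rng(children[i]), sigma=0.03,
                    )
                    vals.append(np.mean(np.abs(f.d)))
            means.append(np.mean(vals))
        assert all(b > a for a, b in zip(means, means[1:]))

    def test_contrast_targeting_low_contrast_arc(self):
        """Boundary displacement concentrates in a constructed low-contrast arc."""
        arc = ds.LowContrastArc("prostate", 0.5, 1.5, factor=0.15)
        ct, masks = ds.make_phantom(ds.pelvis_spec(seed=2, arcs=[arc]))
        m = masks["prostate"]
        surfs = ds.surfaces_for_roi(m, on_too_small="skip")
        anchor = perturbation_anchor(ct, surfs)
        from ducsim.generator import _gradient_cache

        grad_at = _gradient_cache(ct)
        inside, outside = [], []
        for seed in range(50):
            params = DUParams(C=100, seed=seed)
            children = np.random.SeedSequence(seed).spawn(len(surfs))
            for i, surf in enumerate(surfs):
                f = displacement_magnitudes(
                    surf, grad_at(surf.z), params,
                    int(anchor.chains[anchor.s0, i]),
                    np.random.default_rng(children[i]), sigma=0.03,
                )
                theta = np.arctan2(surf.L[:, 1] - 62, surf.L[:, 0] - 48)
                in_arc = (theta >= 0.5) & (theta <= 1.5)
                if in_arc.any():
                    inside.append(np.mean(np.abs(f.d[in_arc])))
                if (~in_arc).any():
                    outside.append(np.mean(np.abs(f.d[~in_arc])))
        assert np.mean(inside) > np.mean(outside)
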