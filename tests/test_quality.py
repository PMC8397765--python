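"""Quality metrics: resolution, FMCR, UTS, GSE, summaries, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tendonct import (ComputationError, PhantomSpec, SubVolume,
                      ValidationError, degrade, estimate_resolution,
                      fiber_matrix_masks, fmcr, gse, make_fat_cell_phantom,
                      make_fiber_phantom, summarize, three_class_otsu, uts)


def brute_force_middle_band(hist):
    """Independent oracle: scan every two-threshold partition of the
    histogram, maximize the between-class variance written as
    sum_k w_k (mu_k - mu_T)^2, and count the middle band."""
    h = np.asarray(hist, dtype=float)
    p = h / h.sum()
    bins = np.arange(h.size, dtype=float)
    mu_total = (p * bins).sum()
    best, best_ij = -np.inf, None
    for i in range(h.size - 2):
        for j in range(i + 1, h.size - 1):
            score = 0.0
            for lo, hi in ((0, i + 1), (i + 1, j + 1), (j + 1, h.size)):
                w = p[lo:hi].sum()
                if w > 0:
                    mu = (p[lo:hi] * bins[lo:hi]).sum() / w
                    score += w * (mu - mu_total) ** 2
            if score > best:
                best, best_ij = score, (i, j)
    i, j = best_ij
    return int(h[i + 1:j + 1].sum())


class TestSummarize:
    def test_constant_repeats(self):
        s = summarize([5.0, 5.0, 5.0])
        assert (s.mean, s.sd, s.cv, s.n_repeats) == (5.0, 0.0, 0.0, 3)

    def test_hand_arithmetic(self):
        s = summarize([4.0, 6.0])
        assert s.mean == 5.0
        assert s.sd == pytest.approx(np.sqrt(2))
        assert s.cv == pytest.approx(np.sqrt(2) / 5)

    def test_cv_invariant_under_positive_rescale(self, rng):
        vals = rng.uniform(1, 5, 6)
        assert summarize(vals * 7.3).cv == pytest.approx(summarize(vals).cv)

    def test_too_few_repeats_rejected(self):
        with pytest.raises(ValidationError):
            summarize([1.0])

    def test_zero_mean_rejected(self):
        with pytest.raises(ComputationError):
            summarize([-1.0, 1.0])


class TestFMCR:
    def sub(self, data, label="fibers"):
        return SubVolume(np.asarray(data, dtype=float), 1.0, label)

    def test_direct_equation_arithmetic(self):
        # Fibers: values 8/12 (mean 10, sd 2); matrix: 4/8 (mean 6, sd 2)
        # -> (10-6)/sqrt((4+4)/2) = 2.
        n = 4000
        data = np.zeros(2 * n)
        data[:n] = np.tile([8.0, 12.0], n // 2)
        data[n:] = np.tile([4.0, 8.0], n // 2)
        sub = self.sub(data.reshape(20, 20, 20))
        fiber = np.zeros(sub.shape, dtype=bool).reshape(-1)
        fiber[:n] = True
        matrix = ~fiber
        assert fmcr(sub, fiber.reshape(sub.shape),
                    matrix.reshape(sub.shape)) == pytest.approx(2.0)

    def test_null_case_same_distribution(self, rng):
        data = rng.normal(5.0, 1.0, (40, 40, 40))
        fiber = np.zeros(data.shape, dtype=bool)
        fiber.reshape(-1)[::2] = True
        val = fmcr(self.sub(data), fiber, ~fiber)
        assert abs(val) < 0.02  # ~ 4/sqrt(n) sampling error

    def test_recovers_analytic_cnr_of_generative_model(self):
        spec = PhantomSpec(shape=(128, 128, 128), voxel_size=1.63,
                           fiber_radius=8.0, fiber_gap=3.0,
                           fiber_level=1.0, matrix_level=0.0)
        vol = make_fiber_phantom(spec)
        truth = vol.data > 0.5
        s = 0.25
        noisy = degrade(vol, 0.0, s, 0.0, seed=2)
        val = fmcr(SubVolume(noisy.data, 1.63, "fibers"), truth, ~truth)
        assert val == pytest.approx(1.0 / s, rel=0.05)

    def test_sign_preserved_when_contrast_inverted(self, rng):
        data = rng.normal(0.0, 1.0, (40, 40, 40))
        fiber = np.zeros(data.shape, dtype=bool)
        fiber.reshape(-1)[::2] = True
        data[fiber] -= 3.0  # fibers darker than matrix
        assert fmcr(self.sub(data), fiber, ~fiber) < 0

    def test_overlapping_masks_rejected(self, rng):
        data = rng.normal(size=(20, 20, 20))
        mask = np.ones(data.shape, dtype=bool)
        with pytest.raises(ValidationError, match="overlap"):
            fmcr(self.sub(data), mask, mask)

    def test_undersized_masks_rejected(self, rng):
        data = rng.normal(size=(20, 20, 20))
        fiber = np.zeros(data.shape, dtype=bool)
        fiber[0, 0, :5] = True
        with pytest.raises(ValidationError, match="1000"):
            fmcr(self.sub(data), fiber, ~fiber)


class TestThreeClassOtsu:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        w = rng.dirichlet([2.0, 2.0, 2.0])
        means = np.sort(rng.uniform(0, 63, 3))
        sds = rng.uniform(1.0, 8.0, 3)
        samples = np.concatenate([
            rng.normal(m, s, int(2000 * wk) + 10)
            for m, s, wk in zip(means, sds, w)
        ])
        hist, _ = np.histogram(samples, bins=64)
        i, j = three_class_otsu(hist)
        assert int(hist[i + 1:j + 1].sum()) == brute_force_middle_band(hist)

    def test_degenerate_histogram_rejected(self):
        with pytest.raises(ValidationError):
            three_class_otsu(np.zeros(256))


class TestUTS:
    def test_perfectly_bimodal_phantom_has_zero_uncertainty(self):
        vol = make_fiber_phantom(PhantomSpec(shape=(32, 64, 64)))
        value, _ = uts(SubVolume(vol.data, 1.0, "fibers"))
        assert value == 0.0

    def test_matches_exhaustive_search_on_mixture_volume(self, rng):
        data = np.concatenate([rng.normal(0, 1, 122_144),
                               rng.normal(6, 1.5, 140_000)])
        sub = SubVolume(data.reshape(64, 64, 64), 1.0, "fibers")
        value, _ = uts(sub)
        hist, _ = np.histogram(sub.data, bins=256,
                               range=(sub.data.min(), sub.data.max()))
        assert value == pytest.approx(
            100.0 * brute_force_middle_band(hist) / sub.data.size)

    def test_prefilter_stable_on_smooth_noiseless_phantom(self):
        # Band-limited regime: field blurred well beyond the 1-voxel
        # prefilter, so filtering barely moves the thresholds.
        spec = PhantomSpec(shape=(32, 256, 256), voxel_size=1.0,
                           fiber_radius=32.0, fiber_gap=12.0)
        vol = degrade(make_fiber_phantom(spec), 3.0, 0.0, 0.0)
        sub = SubVolume(vol.data, 1.0, "fibers")
        _, p0 = uts(sub, None)
        _, p1 = uts(sub, 1.0)
        bin_width = (vol.data.max() - vol.data.min()) / 256
        assert abs(p1["t_low"] - p0["t_low"]) <= bin_width
        assert abs(p1["t_high"] - p0["t_high"]) <= bin_width

    def test_constant_volume_rejected(self):
        sub = SubVolume(np.ones((32, 32, 32)), 1.0, "fibers")
        with pytest.raises(ComputationError, match="degenerate"):
            uts(sub)

    def test_requires_fiber_label(self, fat_volume):
        sub = SubVolume(fat_volume.data, 1.0, "fat_cells")
        with pytest.raises(ValidationError):
            uts(sub)


class TestResolution:
    def test_white_noise_saturates_at_nyquist(self, rng):
        sub = SubVolume(rng.normal(size=(64, 64, 64)), 1.63, "fibers")
        assert estimate_resolution(sub) == pytest.approx(2 * 1.63)

    def test_monotone_in_blur(self, fiber_volume):
        estimates = []
        for sigma_vox in (0.5, 1.0, 2.0):
            d = degrade(fiber_volume, sigma_vox * 1.63, 0.05, 0.0, seed=5)
            sub = SubVolume(d.data, 1.63, "fibers")
            estimates.append(estimate_resolution(sub))
        assert estimates[0] < estimates[1] < estimates[2]

    def test_invariant_under_gray_rescale(self, noisy_fiber_sub):
        scaled = SubVolume(noisy_fiber_sub.data * 37.0 + 11.0, 1.63, "fibers")
        assert estimate_resolution(scaled) == pytest.approx(
            estimate_resolution(noisy_fiber_sub))

    def test_small_subvolume_rejected(self, rng):
        sub = SubVolume(rng.normal(size=(32, 64, 64)), 1.0, "fibers")
        with pytest.raises(ValidationError, match="64"):
            estimate_resolution(sub)

    def test_requires_fiber_label(self, fat_volume):
        sub = SubVolume(fat_volume.data, 1.0, "fat_cells")
        with pytest.raises(ValidationError):
            estimate_resolution(sub)


class TestGSE:
    def test_uniform_volume_raises_no_edges(self):
        sub = SubVolume(np.full((32, 32, 32), 2.0), 1.0, "fat_cells")
        with pytest.raises(ComputationError, match="no edges"):
            gse(sub)

    def test_monotone_decreasing_in_blur(self, fat_volume):
        values = []
        for sigma in (0.5, 1.0, 2.0):
            d = degrade(fat_volume, sigma, 0.02, 0.0, seed=6)
            values.append(gse(SubVolume(d.data, 1.0, "fat_cells")))
        assert values[0] > values[1] > values[2]

    def test_matches_independent_slicewise_recomputation(self):
        # Minimal oracle: explicit central differences on interior pixels of
        # each slice, Otsu threshold on the pooled magnitudes, mean above it.
        from skimage.filters import threshold_otsu
        spec = PhantomSpec(shape=(48, 48, 48), voxel_size=1.0,
                           sphere_radius_range=(10.0, 10.0), sphere_count=1,
                           seed=3, fiber_level=4.0, matrix_level=1.0)
        vol = make_fat_cell_phantom(spec)
        mags = np.zeros(vol.shape)
        for iz, sl in enumerate(vol.data):
            gy = np.zeros_like(sl)
            gx = np.zeros_like(sl)
            gy[1:-1, :] = (sl[2:, :] - sl[:-2, :]) / 2.0
            gx[:, 1:-1] = (sl[:, 2:] - sl[:, :-2]) / 2.0
            mags[iz] = np.hypot(gy, gx)
        thr = threshold_otsu(mags, nbins=256)
        expected = mags[mags > thr].mean()
        assert gse(SubVolume(vol.data, 1.0, "fat_cells")) == pytest.approx(expected)

    def test_scales_linearly_with_gray_rescale(self, fat_volume):
        d = degrade(fat_volume, 1.0, 0.0, 0.0)
        base = gse(SubVolume(d.data, 1.0, "fat_cells"))
        scaled = gse(SubVolume(d.data * 5.0, 1.0, "fat_cells"))
        assert scaled == pytest.approx(5.0 * base)

    def test_requires_fat_cell_label(self, noisy_fiber_sub):
        with pytest.raises(ValidationError):
            gse(noisy_fiber_sub)


class TestSharedInvariances:
    def test_all_metrics_invariant_under_additive_offset(self, noisy_fiber_sub,
                                                         fat_volume):
        shifted = SubVolume(noisy_fiber_sub.data + 123.0, 1.63, "fibers")
        assert estimate_resolution(shifted) == pytest.approx(
            estimate_resolution(noisy_fiber_sub))
        u0, _ = uts(noisy_fiber_sub)
        u1, _ = uts(shifted)
        assert u1 == pytest.approx(u0)
        f0, m0 = fiber_matrix_masks(noisy_fiber_sub)
        assert fmcr(shifted, f0, m0) == pytest.approx(
            fmcr(noisy_fiber_sub, f0, m0))
        d = degrade(fat_volume, 1.0, 0.02, 0.0, seed=6)
        fat = SubVolume(d.data, 1.0, "fat_cells")
        fat_shift = SubVolume(d.data + 123.0, 1.0, "fat_cells")
        assert gse(fat_shift) == pytest.approx(gse(fat))

    def test_fmcr_and_uts_invariant_under_gray_rescale(self, noisy_fiber_sub):
        scaled = SubVolume(noisy_fiber_sub.data * 9.0, 1.63, "fibers")
        f0, m0 = fiber_matrix_masks(noisy_fiber_sub)
        assert fmcr(scaled, f0, m0) == pytest.approx(
            fmcr(noisy_fiber_sub, f0, m0))
        assert uts(scaled)[0] == pytest.approx(uts(noisy_fiber_sub)[0])
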