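import numpy as np
import pytest

from fluoragg.threshold import (
    DegenerateHistogramError,
    FitError,
    ModifiedOtsuConfig,
    apply_threshold,
    apply_threshold_2d,
    average_grayscale,
    estimate_particle_count,
    fit_log_counts,
    fit_log_frequency,
    guess_threshold,
    joint_histogram,
    modified_otsu_2d,
    otsu_1d,
    otsu_2d,
    weighted_median_mask,
    weighted_median_threshold,
)


# ---------------------------------------------------------------- oracles


def otsu1d_oracle(img):
    """Exhaustive scan of the two-class between-class variance."""
    vals = img.ravel().astype(float)
    best_s, best_v = None, -1.0
    for s in range(1, 256):
        lo, hi = vals[vals < s], vals[vals >= s]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size / vals.size, hi.size / vals.size
        v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_v + 1e-12:
            best_s, best_v = s, v
    return best_s


def otsu2d_oracle(g, h):
    """Independent double-loop maximization of tr sigma_B over (s, t)."""
    L = int(max(g.max(), h.max()))
    p = np.zeros((L + 1, L + 1))
    for gi, hi in zip(g.ravel(), h.ravel()):
        p[gi, hi] += 1
    p /= g.size
    ii = np.arange(L + 1)[:, None]
    jj = np.arange(L + 1)[None, :]
    mu_ti = (ii * p).sum()
    mu_tj = (jj * p).sum()
    best = (None, None, -np.inf)
    for s in range(1, L + 1):
        for t in range(1, L + 1):
            w0 = p[:s, :t].sum()
            if w0 <= 0 or w0 >= 1:
                continue
            mi = (ii[:s] * p[:s, :t]).sum()
            mj = (jj[:, :t] * p[:s, :t]).sum()
            tr = ((mu_ti * w0 - mi) ** 2 + (mu_tj * w0 - mj) ** 2) / (w0 * (1 - w0))
            if tr > best[2] + 1e-12:
                best = (s, t, tr)
    return best[0], best[1]


# ----------------------------------------------------------------- tests


class TestApplyThreshold:
    def test_boundary_inclusive(self):
        img = np.array([[3, 9, 200]], dtype=np.uint8)
        np.testing.assert_array_equal(apply_threshold(img, 9), [[0, 1, 1]])

    def test_extremes(self):
        img = np.arange(9, dtype=np.uint8).reshape(3, 3)
        assert apply_threshold(img, 0).all()
        assert not apply_threshold(img, 256).any()


class TestApplyThreshold2D:
    def test_trivial_masks(self):
        g = np.full((3, 3), 200, dtype=np.uint8)
        h = np.full((3, 3), 10, dtype=np.uint8)
        assert apply_threshold_2d(g, h, 0, 0).all()
        assert not apply_threshold_2d(g, h, 100, 50).any()

    def test_matches_pixel_loop(self):
        rng = np.random.default_rng(21)
        g = rng.integers(0, 256, (12, 12)).astype(np.uint8)
        h = rng.integers(0, 256, (12, 12)).astype(np.uint8)
        S, T = 97, 44
        expected = np.zeros_like(g)
        for r in range(12):
            for c in range(12):
                expected[r, c] = 1 if (g[r, c] >= S and h[r, c] >= T) else 0
        np.testing.assert_array_equal(apply_threshold_2d(g, h, S, T), expected)

    def test_foreground_monotone_in_T(self):
        rng = np.random.default_rng(22)
        g = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        h = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        counts = [apply_threshold_2d(g, h, 80, T).sum() for T in range(0, 257, 16)]
        assert all(b <= a for a, b in zip(counts, counts[1:]))


class TestWeightedMedian:
    def test_hand_computed_mad_example(self):
        img = np.array([0, 0, 0, 0, 10, 10, 10, 10, 100], dtype=np.uint8).reshape(3, 3)
        res = weighted_median_threshold(img, weight=4.5)
        assert res.S == pytest.approx(45.0)  # median 10, median |dev| 10

    def test_constant_image_all_ones_with_warning(self, caplog):
        img = np.full((4, 4), 50, dtype=np.uint8)
        with caplog.at_level("WARNING"):
            res = weighted_median_threshold(img)
        assert res.S == 0
        assert weighted_median_mask(img, res).all()

    def test_mask_is_deviation_threshold(self):
        rng = np.random.default_rng(23)
        img = rng.integers(0, 256, (10, 10)).astype(np.uint8)
        res = weighted_median_threshold(img)
        mask = weighted_median_mask(img, res)
        m = res.diagnostics["median"]
        np.testing.assert_array_equal(mask, (np.abs(img.astype(float) - m) >= res.S))

    def test_mean_fallback_on_clipped_background(self):
        # >50% of pixels exactly at the median: the median deviation is 0 but
        # the image is not flat, so the mean-deviation fallback must engage.
        img = np.zeros((10, 10), dtype=np.uint8)
        img[:2, :5] = 200
        res = weighted_median_threshold(img)
        assert res.diagnostics["mean_fallback"]
        assert res.S > 0


class TestOtsu1D:
    def test_two_level_image(self):
        img = np.array([50] * 32 + [200] * 32, dtype=np.uint8).reshape(8, 8)
        res = otsu_1d(img)
        assert 51 <= res.S <= 200
        assert res.S == otsu1d_oracle(img)

    def test_constant_degenerate(self, caplog):
        with caplog.at_level("WARNING"):
            res = otsu_1d(np.full((4, 4), 99, dtype=np.uint8))
        assert res.diagnostics["degenerate"]

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        assert otsu_1d(img).S == otsu1d_oracle(img)

    def test_normalized_threshold_reported(self):
        img = np.array([0] * 8 + [255] * 8, dtype=np.uint8).reshape(4, 4)
        res = otsu_1d(img)
        assert res.diagnostics["S_normalized"] == pytest.approx(res.S / 255)


class TestAverageGrayscale:
    def test_constant_preserved(self):
        img = np.full((6, 6), 81, dtype=np.uint8)
        np.testing.assert_array_equal(average_grayscale(img, 3), img)

    def test_window_one_is_identity(self):
        rng = np.random.default_rng(31)
        img = rng.integers(0, 256, (5, 5)).astype(np.uint8)
        np.testing.assert_array_equal(average_grayscale(img, 1), img)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(32)
        img = rng.integers(0, 256, (5, 5)).astype(np.uint8)
        padded = np.pad(img.astype(float), 1, mode="edge")
        expected = np.empty_like(img)
        for r in range(5):
            for c in range(5):
                expected[r, c] = np.floor(padded[r : r + 3, c : c + 3].mean() + 0.5)
        np.testing.assert_array_equal(average_grayscale(img, 3), expected)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            average_grayscale(np.zeros((4, 4), dtype=np.uint8), 2)


class TestJointHistogram:
    def test_constant_pair_single_cell(self):
        img = np.full((4, 5), 9, dtype=np.uint8)
        jh = joint_histogram(img, img)
        assert jh.L == 9
        assert jh.r[9, 9] == 20 and jh.p[9, 9] == 1.0

    def test_two_pixel_extremes(self):
        g = np.array([[0], [255]], dtype=np.uint8)
        jh = joint_histogram(g, g)
        assert jh.p[0, 0] == 0.5 and jh.p[255, 255] == 0.5

    def test_probabilities_and_marginals(self):
        rng = np.random.default_rng(41)
        g = rng.integers(0, 64, (12, 12)).astype(np.uint8)
        h = average_grayscale(g, 3)
        jh = joint_histogram(g, h)
        assert jh.p.sum() == pytest.approx(1.0)
        np.testing.assert_array_equal(
            jh.r.sum(axis=1), np.bincount(g.ravel(), minlength=jh.L + 1)
        )
        np.testing.assert_array_equal(
            jh.r.sum(axis=0), np.bincount(h.ravel(), minlength=jh.L + 1)
        )

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            joint_histogram(
                np.zeros((2, 2), dtype=np.uint8), np.zeros((3, 3), dtype=np.uint8)
            )


class TestOtsu2D:
    def test_two_block_image(self):
        half = np.full((8, 8), 40, dtype=np.uint8)
        g = np.vstack([half, np.full((8, 8), 200, dtype=np.uint8)])
        res = otsu_2d(g, g)
        assert 40 < res.S <= 200 and 40 < res.T <= 200
        assert (res.S, res.T) == otsu2d_oracle(g, g)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed + 100)
        g = rng.integers(0, 32, (16, 16)).astype(np.uint8)
        h = average_grayscale(g, 3)
        res = otsu_2d(g, h)
        assert (res.S, res.T) == otsu2d_oracle(g, h)

    def test_probability_complement_when_off_quadrants_empty(self):
        # g == h puts all mass on the joint-histogram diagonal, so at any
        # (s, t) with s == t the two off-diagonal quadrants are empty.
        half = np.full((8, 8), 40, dtype=np.uint8)
        g = np.vstack([half, np.full((8, 8), 200, dtype=np.uint8)])
        res = otsu_2d(g, g)
        jh = joint_histogram(g, g)
        s = t = int(res.S)
        w0 = jh.p[:s, :t].sum()
        w1 = jh.p[s:, t:].sum()
        assert w0 + w1 == pytest.approx(1.0)

    def test_degenerate_histogram_raises(self):
        img = np.full((4, 4), 7, dtype=np.uint8)
        with pytest.raises(DegenerateHistogramError):
            otsu_2d(img, img)


class TestLogFrequencyFit:
    def test_cubic_round_trip_recovery(self):
        coeffs = np.array([-2e-5, 1.6e-3, -0.08, 3.0])
        n = np.arange(0, 80)
        counts = np.zeros(256)
        counts[n] = 10 ** np.polyval(coeffs, n)
        fit = fit_log_counts(counts, slope_set_value=-0.05)
        np.testing.assert_allclose(fit.coefficients, coeffs, atol=1e-6)
        # Roots must satisfy the slope equation.
        for root in (fit.T_min, fit.T_max):
            assert np.polyval(np.polyder(coeffs), root) == pytest.approx(-0.05, abs=1e-9)
        assert fit.T_min < fit.T_max

    def test_pure_exponential_has_no_crossing(self):
        n = np.arange(0, 60)
        counts = np.zeros(256)
        counts[n] = 10 ** (4.0 - 0.02 * n)  # constant slope -0.02, never -0.05
        with pytest.raises(FitError):
            fit_log_counts(counts, slope_set_value=-0.05)

    def test_too_few_bins(self):
        counts = np.zeros(256)
        counts[[3, 10, 40]] = 5
        with pytest.raises(FitError):
            fit_log_counts(counts)

    def test_image_interface(self, denoised_disk_fixture):
        h = average_grayscale(denoised_disk_fixture, 3)
        fit = fit_log_frequency(h, slope_set_value=-0.0125)
        assert fit.domain[0] < fit.T_min < fit.T_max <= fit.domain[1]


class TestGuessThreshold:
    def test_reported_worked_examples(self):
        assert guess_threshold(20.11, 49.48, 38) == pytest.approx(29.562)
        assert round(guess_threshold(17.4, 45.76, 48), 1) == pytest.approx(29.2)

    def test_equal_inputs_fixed_point(self):
        assert guess_threshold(17.0, 17.0, 17.0) == pytest.approx(17.0)

    def test_convexity_bound(self):
        rng = np.random.default_rng(55)
        for _ in range(20):
            a, b, c = rng.uniform(0, 255, 3)
            t = guess_threshold(a, b, c)
            assert min(a, b, c) - 1e-9 <= t <= max(a, b, c) + 1e-9

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            guess_threshold(1, 2, 3, w1=-0.1)


class TestEstimateParticleCount:
    def test_all_zero_image(self):
        assert estimate_particle_count(np.zeros((32, 32), dtype=np.uint8)) == 0

    def test_exact_on_subtract_normalized_disks(self, disk_fixture):
        from fluoragg import PipelineConfig
        from fluoragg.imgio import extract_green
        from fluoragg.pipeline import denoise_image

        cfg = PipelineConfig(background_mode="subtract")
        denoised = denoise_image(extract_green(disk_fixture.image), cfg)
        assert estimate_particle_count(denoised) == len(disk_fixture.particles)

    def test_bounded_overcount_on_divide_normalized_disks(self, denoised_disk_fixture, disk_fixture):
        n_true = len(disk_fixture.particles)
        n_e = estimate_particle_count(denoised_disk_fixture)
        assert n_true <= n_e <= n_true + 5

    def test_blank_below_false_positive_bound(self):
        from fluoragg import PipelineConfig, blank_scene
        from fluoragg.imgio import extract_green
        from fluoragg.pipeline import denoise_image

        cfg = PipelineConfig()
        denoised = denoise_image(extract_green(blank_scene(seed=1).image), cfg)
        assert estimate_particle_count(denoised) <= 20


class TestModifiedOtsu2D:
    @staticmethod
    def _simple_scene():
        """Four bright 6x6 squares on a noisy dim background."""
        rng = np.random.default_rng(77)
        g = rng.integers(8, 14, (64, 64)).astype(np.uint8)
        for r, c in ((8, 8), (8, 40), (40, 8), (40, 40)):
            g[r : r + 6, c : c + 6] = 220
        return g, average_grayscale(g, 3)

    def test_immediate_convergence_when_counts_match(self):
        g, h = self._simple_scene()
        res = modified_otsu_2d(g, h)
        d = res.diagnostics
        assert d["N_e"] == 4
        if d["trajectory"][0]["N_g"] == d["N_e"]:
            assert d["iterations"] == 1
            assert res.T == pytest.approx(d["T_guess"])
        assert d["converged"]

    def test_converges_to_true_count_within_feasible_interval(self):
        g, h = self._simple_scene()
        cfg = ModifiedOtsuConfig()
        res = modified_otsu_2d(g, h, cfg)
        from fluoragg.morphology import postprocess
        from fluoragg.features import label_particles

        # Oracle: exhaustive scan of every integer T for the feasible set
        # where the post-processed count equals the true count (4 squares).
        feasible = set()
        for T in range(1, res.diagnostics["L"] + 1):
            mask = postprocess(apply_threshold_2d(g, h, res.S, T), cfg.morphology)
            if label_particles(mask)[1] == 4:
                feasible.add(T)
        assert feasible, "scene must admit a threshold reproducing the true count"
        final_mask = postprocess(apply_threshold_2d(g, h, res.S, res.T), cfg.morphology)
        assert label_particles(final_mask)[1] == 4
        assert int(round(res.T)) in feasible

    def test_never_worse_than_initial_guess(self, denoised_disk_fixture):
        h = average_grayscale(denoised_disk_fixture, 3)
        res = modified_otsu_2d(denoised_disk_fixture, h)
        traj = res.diagnostics["trajectory"]
        final_errs = [abs(t["error"]) for t in traj if t["T"] == res.T]
        assert final_errs
        assert min(final_errs) <= abs(traj[0]["error"])

    def test_diagnostics_complete(self, denoised_disk_fixture):
        h = average_grayscale(denoised_disk_fixture, 3)
        res = modified_otsu_2d(denoised_disk_fixture, h)
        for key in ("T_otsu", "T_min", "T_max", "T_guess", "N_e", "iterations", "trajectory"):
            assert key in res.diagnostics
        assert res.method == "modified_otsu2d"
        assert 0 <= res.S <= res.diagnostics["L"]
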