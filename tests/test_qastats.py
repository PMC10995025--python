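"""MTF measurement and agreement statistics against enumeration oracles."""

import itertools

import numpy as np
import pytest
from scipy import ndimage

from bonesr.qastats import (
    MTFCurve,
    RoiSet,
    bland_altman,
    mtf_from_line_pairs,
    mtf_percentiles,
    pearson_r,
    weighted_kappa,
    wilcoxon_signed_rank,
)
from bonesr.synthfixtures import (
    LinePairPhantomSpec,
    default_roi_layout,
    make_line_pair_phantom,
)

# even-integer bar periods at 250 um pixels (20, 16, 10, 8, 6, 4 px): binary
# rendering then has exact 50% duty cycle and no sub-harmonic beat patterns
EVEN_FREQS = (2.0, 2.5, 4.0, 5.0, 1e4 / (6 * 250.0), 10.0)


def _phantom_and_rois(freqs=EVEN_FREQS, **kw):
    spec = LinePairPhantomSpec(
        group_frequencies_lp_per_cm=freqs,
        uniform_inserts=(("bright", 0.9), ("dark", 0.1)), **kw)
    vol = make_line_pair_phantom(spec)
    layout = default_roi_layout(spec)
    rois = RoiSet(groups=layout["groups"], noise=layout["noise"],
                  materials=layout["materials"])
    return spec, vol, rois


class TestMTF:
    def test_noise_free_phantom_reads_unity(self):
        spec, vol, rois = _phantom_and_rois()
        curve = mtf_from_line_pairs(vol, rois, spec.group_frequencies_lp_per_cm)
        assert np.all(curve.mtf >= 0.95) and np.all(curve.mtf <= 1.05)
        assert np.all(curve.ci_halfwidth <= 1e-12)

    def test_phantom_without_bars_measures_zero(self):
        # bar level equal to background: no modulation, materials intact
        spec, vol, rois = _phantom_and_rois(bar_level=0.1)
        curve = mtf_from_line_pairs(vol, rois, spec.group_frequencies_lp_per_cm,
                                    normalization="material_pair")
        np.testing.assert_array_equal(curve.mtf, 0.0)

    def test_gaussian_blur_recovers_analytic_mtf(self):
        spec, vol, rois = _phantom_and_rois()
        f_cpp = np.asarray(spec.group_frequencies_lp_per_cm) * spec.pixel_size_um / 1e4
        for sigma in (4.5, 6.0):
            blurred = vol.with_data(np.clip(ndimage.gaussian_filter1d(
                vol.data.astype(float), sigma, axis=2), 0, 1).astype(np.float32))
            curve = mtf_from_line_pairs(blurred, rois,
                                        spec.group_frequencies_lp_per_cm)
            model = np.exp(-2 * np.pi ** 2 * sigma ** 2 * f_cpp ** 2)
            assert np.abs(curve.mtf - model).max() <= 0.05

    def test_monotone_degradation_with_blur(self):
        spec, vol, rois = _phantom_and_rois()
        prev_curve, prev_mtf50 = None, None
        for sigma in (1.0, 2.0, 3.0, 4.5):
            blurred = vol.with_data(np.clip(ndimage.gaussian_filter1d(
                vol.data.astype(float), sigma, axis=2), 0, 1).astype(np.float32))
            curve = mtf_from_line_pairs(blurred, rois,
                                        spec.group_frequencies_lp_per_cm)
            if prev_curve is not None:
                # slack covers float32 rendering ripple, ~1e-4 in amplitude
                assert np.all(curve.mtf <= prev_curve + 1e-3)
                if curve.mtf50_lp_cm is not None and prev_mtf50 is not None:
                    assert curve.mtf50_lp_cm <= prev_mtf50 + 1e-9
            prev_curve, prev_mtf50 = curve.mtf, curve.mtf50_lp_cm

    def test_max_intensity_invariant_to_global_rescale(self):
        spec, vol, rois = _phantom_and_rois()
        blurred = vol.with_data(np.clip(ndimage.gaussian_filter1d(
            vol.data.astype(float), 2.0, axis=2), 0, 1).astype(np.float32))
        c1 = mtf_from_line_pairs(blurred, rois, spec.group_frequencies_lp_per_cm,
                                 normalization="max_intensity")
        scaled = blurred.with_data((blurred.data * 0.5).astype(np.float32))
        c2 = mtf_from_line_pairs(scaled, rois, spec.group_frequencies_lp_per_cm,
                                 normalization="max_intensity")
        np.testing.assert_allclose(c1.mtf, c2.mtf, atol=1e-9)
        assert c1.mtf50_lp_cm == pytest.approx(c2.mtf50_lp_cm, abs=1e-9)

    def test_normalizations_differ_by_positive_scalar(self):
        spec, vol, rois = _phantom_and_rois()
        blurred = vol.with_data(np.clip(ndimage.gaussian_filter1d(
            vol.data.astype(float), 2.0, axis=2), 0, 1).astype(np.float32))
        cm = mtf_from_line_pairs(blurred, rois, spec.group_frequencies_lp_per_cm,
                                 normalization="material_pair")
        cx = mtf_from_line_pairs(blurred, rois, spec.group_frequencies_lp_per_cm,
                                 normalization="max_intensity")
        ratios = cm.mtf[cx.mtf > 1e-6] / cx.mtf[cx.mtf > 1e-6]
        assert ratios.min() > 0
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-9)

    def test_roi_out_of_bounds_rejected(self):
        spec, vol, rois = _phantom_and_rois()
        rois.noise = (0, 10, 0, 10_000)
        with pytest.raises(ValueError):
            mtf_from_line_pairs(vol, rois, spec.group_frequencies_lp_per_cm)


class TestMTFPercentiles:
    def _curve(self, samples):
        f, m = zip(*samples)
        return MTFCurve(frequencies_lp_cm=np.array(f), mtf=np.array(m),
                        ci_halfwidth=np.zeros(len(f)), normalization="material_pair")

    def test_exact_sample_hits(self):
        curve = self._curve([(2, 1.0), (4, 0.5), (8, 0.1)])
        assert mtf_percentiles(curve, [0.5, 0.1]) == [4.0, 8.0]

    def test_linear_interpolation(self):
        curve = self._curve([(2, 0.8), (6, 0.4)])
        assert mtf_percentiles(curve, [0.5]) == [5.0]

    def test_level_never_crossed(self):
        curve = self._curve([(2, 0.9), (4, 0.9), (8, 0.9)])
        assert mtf_percentiles(curve, [0.1]) == [None]

    def test_poly3_on_polynomial_curve(self):
        f = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        m = 1.0 - 0.02 * f ** 3 / 6 - 0.1 * f
        curve = self._curve(list(zip(f, m)))
        [hit] = mtf_percentiles(curve, [0.5], method="poly3")
        # root of the cubic itself
        expected = np.roots([-0.02 / 6, 0, -0.1, 0.5])
        real = [r.real for r in expected if abs(r.imag) < 1e-12 and 1 <= r.real <= 6]
        assert hit == pytest.approx(real[0], abs=1e-6)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, _ = pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        r, _ = pearson_r(x, -x)
        assert r == pytest.approx(-1.0)

    def test_matches_covariance_oracle(self, rng):
        x, y = rng.random(10), rng.random(10)
        r, (lo, hi) = pearson_r(x, y)
        expected = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        assert r == pytest.approx(expected, abs=1e-12)
        z = np.arctanh(r)
        assert lo == pytest.approx(np.tanh(z - 1.96 / np.sqrt(7)), abs=1e-12)
        assert hi == pytest.approx(np.tanh(z + 1.96 / np.sqrt(7)), abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1, 1], [1, 2, 3, 4])


class TestBlandAltman:
    def test_identical_vectors(self):
        bias, sd, lo, hi = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (bias, sd, lo, hi) == (0.0, 0.0, 0.0, 0.0)

    def test_constant_offset(self):
        bias, sd, lo, hi = bland_altman(np.array([6.0, 7.0, 8.0]),
                                        np.array([1.0, 2.0, 3.0]))
        assert bias == 5.0 and sd == 0.0

    def test_matches_hand_computation(self, rng):
        a, b = rng.random(12), rng.random(12)
        bias, sd, lo, hi = bland_altman(a, b)
        d = a - b
        assert bias == pytest.approx(d.mean(), abs=1e-15)
        assert sd == pytest.approx(d.std(ddof=1), abs=1e-15)
        assert lo == pytest.approx(bias - 1.96 * sd, abs=1e-12)
        assert hi == pytest.approx(bias + 1.96 * sd, abs=1e-12)


class TestWeightedKappa:
    def test_identical_ratings(self, rng):
        r1 = rng.integers(1, 6, 40)
        r1[:5] = [1, 2, 3, 4, 5]  # both raters use several categories
        k, _ = weighted_kappa(r1, r1, 5)
        assert k == pytest.approx(1.0)

    def test_independent_ratings_near_zero(self):
        rng = np.random.default_rng(0)
        r1 = rng.integers(1, 6, 4000)
        r2 = rng.integers(1, 6, 4000)
        k, _ = weighted_kappa(r1, r2, 5)
        assert abs(k) < 0.05

    def test_two_level_table_brute_force(self):
        # observed proportions [[0.4, 0.1], [0.1, 0.4]] over n = 20
        r1 = np.array([1] * 10 + [2] * 10)
        r2 = np.array([1] * 8 + [2] * 2 + [1] * 2 + [2] * 8)
        k, _ = weighted_kappa(r1, r2, 2)
        # hand expansion: sum(w o) = 0.2, marginals 0.5/0.5 -> sum(w e) = 0.5
        assert k == pytest.approx(1 - 0.2 / 0.5)

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import cohen_kappa_score

        r1 = rng.integers(1, 5, 60)
        r2 = np.clip(r1 + rng.integers(-1, 2, 60), 1, 4)
        k, (lo, hi) = weighted_kappa(r1, r2, 4)
        ref = cohen_kappa_score(r1, r2, weights="linear")
        assert k == pytest.approx(ref, abs=1e-12)
        assert lo <= k <= hi

    def test_degenerate_marginals_rejected(self):
        with pytest.raises(ValueError):
            weighted_kappa([1, 1, 1], [1, 2, 1], 3)


class TestWilcoxon:
    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    def test_five_positive_differences_exact_p(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = a - np.array([0.5, 0.6, 0.7, 0.8, 0.9])
        stat, p = wilcoxon_signed_rank(a, b)
        # enumeration over all 2^5 sign assignments: two-sided p = 2/32
        assert p == pytest.approx(2 / 32)

    def test_exact_p_matches_enumeration(self, rng):
        d = rng.normal(0.3, 1.0, 8)
        d = d[d != 0]
        ranks = np.argsort(np.argsort(np.abs(d))) + 1
        w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
        count = sum(
            min(sum(r for r, s in zip(ranks, signs) if s),
                sum(r for r, s in zip(ranks, signs) if not s)) <= w_obs
            for signs in itertools.product([True, False], repeat=len(d))
        )
        expected = count / 2 ** len(d)
        stat, p = wilcoxon_signed_rank(d, np.zeros_like(d))
        assert p == pytest.approx(min(1.0, expected), abs=1e-12)

    def test_bonferroni_arithmetic(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = a - 0.5
        _, p1 = wilcoxon_signed_rank(a, b, bonferroni_m=1)
        _, p3 = wilcoxon_signed_rank(a, b, bonferroni_m=3)
        assert p3 == pytest.approx(min(1.0, 3 * p1))
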