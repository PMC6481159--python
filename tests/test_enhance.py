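import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sshos.enhance import (
    DegenerateImageError,
    EstimationError,
    enhance,
    estimate_abc,
    intensify,
    local_mean,
    map_entropy,
    neutrosophic_components,
    optimal_b,
    s_function,
    unsharp_sharpen,
)
from sshos.io import GrayImage


class TestLocalMean:
    def test_constant_is_fixed_point(self):
        np.testing.assert_allclose(local_mean(np.full((7, 7), 0.3), 3), 0.3)

    def test_single_impulse_center(self):
        img = np.zeros((5, 5))
        img[2, 2] = 1.0
        assert local_mean(img, 3)[2, 2] == pytest.approx(1 / 9)

    def test_matches_bruteforce_with_reflect_padding(self, rng):
        img = rng.random((7, 7))
        w = 3
        padded = np.pad(img, 1, mode="symmetric")
        expected = np.empty_like(img)
        for i in range(7):
            for j in range(7):
                expected[i, j] = padded[i : i + w, j : j + w].mean()
        np.testing.assert_allclose(local_mean(img, w), expected)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            local_mean(np.zeros((5, 5)), 4)


class TestNeutrosophicComponents:
    def test_endpoints_and_complement(self, rng):
        img = rng.random((12, 12))
        n = neutrosophic_components(img, 3)
        np.testing.assert_allclose(n.F, 1.0 - n.T)
        assert n.T.max() == pytest.approx(1.0)
        assert n.T.min() == pytest.approx(0.0)
        assert n.I.min() >= 0 and n.I.max() <= 1
        assert (n.delta >= 0).all()

    def test_matches_bruteforce_on_step_image(self):
        img = np.zeros((6, 8))
        img[:, 4:] = 1.0
        n = neutrosophic_components(img, 3)
        qhat = local_mean(img, 3)
        T = (qhat - qhat.min()) / (qhat.max() - qhat.min())
        delta = np.abs(img - qhat)
        I = (delta - delta.min()) / (delta.max() - delta.min())
        np.testing.assert_allclose(n.T, T)
        np.testing.assert_allclose(n.I, I)

    def test_constant_image_degenerate(self):
        with pytest.raises(DegenerateImageError):
            neutrosophic_components(np.full((8, 8), 0.5), 3)

    def test_delta_is_absolute_deviation(self, rng):
        img = rng.random((10, 10))
        n = neutrosophic_components(img, 3)
        np.testing.assert_allclose(n.delta, np.abs(img - n.local_mean))


class TestSFunction:
    def test_branch_endpoints(self):
        assert s_function(10.0, 10, 50, 90) == 0.0
        assert s_function(90.0, 10, 50, 90) == 1.0
        assert s_function(0.0, 10, 50, 90) == 0.0
        assert s_function(255.0, 10, 50, 90) == 1.0

    def test_hand_evaluated_midpoint(self):
        # (128-0)^2 / ((128-0)(255-0)) = 128/255
        assert s_function(128.0, 0, 128, 255) == pytest.approx(128 / 255)

    @settings(derandomize=True, max_examples=100)
    @given(st.tuples(st.floats(0, 250), st.floats(0.5, 100), st.floats(0.5, 100)))
    def test_continuity_at_b(self, abc):
        a, d1, d2 = abc
        b, c = a + d1, a + d1 + d2
        left = (b - a) ** 2 / ((b - a) * (c - a))
        right = 1 - (b - c) ** 2 / ((c - b) * (c - a))
        assert abs(left - right) < 1e-12
        assert s_function(b, a, b, c) == pytest.approx(left, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 255), min_size=2, max_size=20))
    def test_monotone(self, gs):
        vals = s_function(np.sort(np.asarray(gs)), 20.0, 100.0, 220.0)
        assert (np.diff(vals) >= -1e-15).all()

    def test_bad_ordering_rejected(self):
        with pytest.raises(ValueError):
            s_function(1.0, 50, 40, 90)


class TestEstimateAbc:
    @staticmethod
    def _image_from_histogram(counts: dict[int, int]) -> np.ndarray:
        levels = np.concatenate(
            [np.full(n, lv, dtype=float) for lv, n in counts.items()]
        )
        return (levels / 255.0).reshape(1, -1)

    def test_three_peak_hand_trace(self):
        # peaks 50 (300), 120 (80), 200 (280); mean height 220 ->
        # qualifying {50, 200}; a = 50, c = 200 (clamps inactive: B1 = 50,
        # B2 = 200 because each peak alone exceeds the 1% tail allowance)
        img = self._image_from_histogram({50: 300, 120: 80, 200: 280})
        p = estimate_abc(img)
        assert (p.g_min, p.g_max) == (50, 200)
        assert p.peak_mean == pytest.approx(220.0)
        assert p.a == pytest.approx(50.0)
        assert p.c == pytest.approx(200.0)
        assert p.B1 == 50 and p.B2 == 200

    def test_unimodal_raises(self):
        img = self._image_from_histogram({100: 500})
        with pytest.raises(EstimationError):
            estimate_abc(img)

    def test_ordering_property_on_random_multimodal(self, rng):
        # with g_1/g_n the first/last of ALL local maxima the estimate
        # satisfies g_1 <= a <= g_min < c <= g_max after clamping
        for _ in range(20):
            modes = np.sort(rng.choice(np.arange(20, 236, 5), 3, replace=False))
            counts = {}
            for m, n in zip(modes, (400, 350, 450)):
                for off in (-2, 0, 2):
                    counts[int(m) + off] = counts.get(int(m) + off, 0) + (
                        n if off == 0 else rng.integers(5, 30)
                    )
            img = self._image_from_histogram(counts)
            try:
                p = estimate_abc(img)
            except EstimationError:
                continue
            assert p.peak_levels[0] <= p.a <= p.g_min
            assert p.g_min < p.c <= p.g_max
            assert p.a < p.c


class TestMapEntropy:
    def test_half_map_is_one_bit(self):
        assert map_entropy(np.full((6, 6), 0.5)) == pytest.approx(1.0)

    def test_binary_map_is_zero(self):
        T = np.zeros((4, 4))
        T[:2] = 1.0
        assert map_entropy(T) == 0.0

    def test_constant_maps_peak_at_half(self):
        hs = [map_entropy(np.full((3, 3), t)) for t in np.linspace(0, 1, 21)]
        assert np.argmax(hs) == 10

    def test_symmetry_under_complement(self, rng):
        T = rng.random((9, 9))
        assert map_entropy(T) == pytest.approx(map_entropy(1 - T))


class TestOptimalB:
    def test_width_one_interval(self):
        g = np.linspace(0, 255, 64).reshape(8, 8)
        assert optimal_b(g, 100, 102) == 101

    def test_equals_independent_bruteforce(self, rng):
        g = rng.random((32, 32)) * 255
        a, c = 20, 200

        def sfun(x, b):  # independent re-derivation of the piecewise map
            x = np.asarray(x, float)
            y = np.where(
                x <= a, 0.0,
                np.where(
                    x <= b, (x - a) ** 2 / ((b - a) * (c - a)),
                    np.where(x <= c, 1 - (x - c) ** 2 / ((c - b) * (c - a)), 1.0),
                ),
            )
            return y

        def entropy(T):
            t = np.clip(T, 1e-300, 1)
            u = np.clip(1 - T, 1e-300, 1)
            return float(np.mean(-T * np.log2(t) - (1 - T) * np.log2(u)))

        hs = {b: entropy(sfun(g, b)) for b in range(a + 1, c)}
        expected = max(hs, key=lambda b: (hs[b], -b))
        assert optimal_b(g, a, c) == expected

    def test_result_strictly_inside(self, rng):
        g = rng.random((16, 16)) * 255
        b = optimal_b(g, 30, 220)
        assert 30 < b < 220


class TestIntensify:
    @pytest.mark.parametrize("t,expected", [(0.0, 0.0), (0.5, 0.5), (1.0, 1.0),
                                            (0.25, 0.125), (0.75, 0.875)])
    def test_values(self, t, expected):
        assert intensify(np.array([t]))[0] == pytest.approx(expected)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=30))
    def test_monotone(self, ts):
        out = intensify(np.sort(np.asarray(ts)))
        assert (np.diff(out) >= -1e-15).all()


class TestUnsharp:
    def test_zero_amount_is_identity(self, rng):
        img = rng.random((10, 10))
        np.testing.assert_allclose(unsharp_sharpen(img, 2.0, 0.0), img)

    def test_constant_unchanged(self):
        img = np.full((12, 12), 0.4)
        np.testing.assert_allclose(unsharp_sharpen(img, 2.0, 1.5), 0.4)

    def test_overshoot_localized_at_edge(self):
        # midrange step so the overshoot is not flattened by clipping
        img = np.full((20, 40), 0.3)
        img[:, 20:] = 0.7
        out = unsharp_sharpen(img, 2.0, 1.0)
        diff_col = np.abs(out - img).max(axis=0)
        assert diff_col.argmax() in range(17, 24)
        assert diff_col[:11].max() < 1e-9  # beyond the kernel: unchanged


class TestEnhance:
    def test_composed_map_preserves_rank_order(self):
        # monotone map: a bimodal image stays bimodal, separation kept
        img = np.zeros((33, 33))
        img[:, 16:] = 1.0
        rng = np.random.default_rng(0)
        img = np.clip(img * 0.6 + 0.2 + rng.normal(0, 0.05, img.shape), 0, 1)
        out, _ = enhance(GrayImage(img))
        assert out.values.min() >= 0 and out.values.max() <= 1

    def test_constant_image_survives_via_fallback(self):
        img = GrayImage(np.full((30, 30), 0.5))
        out, diag = enhance(img)
        assert diag["fallback"]
        np.testing.assert_array_equal(out.values, img.values)

    def test_lesion_contrast_not_decreased(self, small_lesion_phantom):
        img, mask = small_lesion_phantom
        out, _ = enhance(img)
        before = abs(img.values[mask == 0].mean() - img.values[mask == 1].mean())
        after = abs(out.values[mask == 0].mean() - out.values[mask == 1].mean())
        assert after >= before
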