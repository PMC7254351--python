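import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from octa_deshadow import (
    DeshadowParams,
    OctaVolume,
    ValidationError,
    deshadow_volume,
    equalize_volume,
    generate_phantom,
    match_gamma,
    mean_subtract_aline,
    step_down_aline,
)


def step_down_bruteforce(aline, gamma):
    """Literal element-by-element recursion, the independent oracle."""
    out = []
    for z, value in enumerate(aline):
        out.append(value * math.exp(-sum(out) / gamma))
    return np.array(out)


alines = st.lists(st.floats(0.0, 10.0), min_size=1, max_size=64).map(np.array)


class TestMeanSubtraction:
    def test_hand_example_with_clip(self):
        np.testing.assert_allclose(
            mean_subtract_aline([8, 4, 0, 0], w=1.0), [5.0, 1.0, 0.0, 0.0])

    def test_hand_example_raw(self):
        np.testing.assert_allclose(
            mean_subtract_aline([8, 4, 0, 0], w=1.0, clip_negative=False),
            [5.0, 1.0, -3.0, -3.0])

    def test_w_zero_is_identity(self, rng):
        a = rng.random(20)
        np.testing.assert_array_equal(mean_subtract_aline(a, w=0.0), a)

    def test_constant_aline_maps_to_zero(self):
        assert not mean_subtract_aline(np.full(8, 3.3), w=1.0).any()

    def test_longer_tail_gets_larger_subtraction(self):
        """The subtracted offset grows with the A-line's tail burden."""
        short = np.array([5.0, 1.0, 0.0, 0.0])
        long = np.array([5.0, 1.0, 2.0, 0.0])
        w = 2.0
        assert w * long.mean() > w * short.mean()
        # the shared (non-tail) pixels end up dimmer on the long-tail line
        assert mean_subtract_aline(long, w)[0] < mean_subtract_aline(short, w)[0]

    def test_not_idempotent(self):
        a = np.array([8.0, 4.0, 2.0, 0.0])
        once = mean_subtract_aline(a, w=1.0)
        twice = mean_subtract_aline(once, w=1.0)
        assert not np.allclose(once, twice)

    @settings(derandomize=True, max_examples=50)
    @given(aline=alines, w=st.floats(0.0, 5.0))
    def test_clip_bounds(self, aline, w):
        out = mean_subtract_aline(aline, w)
        assert (out >= 0).all() and (out <= aline + 1e-12).all()

    @pytest.mark.parametrize("bad", [[], [1.0, np.nan], [1.0, -2.0]])
    def test_invalid_alines_rejected(self, bad):
        with pytest.raises(ValidationError):
            mean_subtract_aline(bad, w=1.0)

    def test_negative_w_rejected(self):
        with pytest.raises(ValidationError):
            mean_subtract_aline([1.0, 2.0], w=-0.5)


class TestStepDown:
    def test_hand_example(self):
        expected = [1.0, math.exp(-1.0), math.exp(-1.0 - math.exp(-1.0))]
        np.testing.assert_allclose(step_down_aline([1, 1, 1], gamma=1.0), expected,
                                   rtol=1e-9)

    def test_all_zero_stays_zero(self):
        assert not step_down_aline(np.zeros(10), gamma=2.0).any()

    def test_huge_gamma_limit_is_identity(self, rng):
        a = rng.random(50)
        gamma = 1e12 * a.sum()
        np.testing.assert_allclose(step_down_aline(a, gamma), a, rtol=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(aline=alines, gamma=st.floats(0.1, 100.0))
    def test_matches_bruteforce_and_dominated(self, aline, gamma):
        out = step_down_aline(aline, gamma)
        np.testing.assert_allclose(out, step_down_bruteforce(aline, gamma),
                                   rtol=1e-12, atol=1e-300)
        assert (out >= 0).all() and (out <= aline + 1e-15).all()

    def test_topmost_pixel_unchanged(self, rng):
        a = rng.random(16)
        assert step_down_aline(a, gamma=0.5)[0] == a[0]

    @pytest.mark.parametrize("gamma", [0.0, -1.0])
    def test_nonpositive_gamma_rejected(self, gamma):
        with pytest.raises(ValidationError):
            step_down_aline([1.0], gamma)


class TestDeshadowVolume:
    @pytest.mark.parametrize("params", [
        DeshadowParams(method="mean_subtraction", w=1.7, normalize_output=False),
        DeshadowParams(method="step_down", gamma=3.0, normalize_output=False),
    ])
    def test_matches_per_column_loop(self, small_volume, params):
        out = deshadow_volume(small_volume, params)
        for x in range(small_volume.nx):
            for y in range(small_volume.ny):
                col = small_volume.data[:, x, y]
                if params.method == "mean_subtraction":
                    expected = mean_subtract_aline(col, params.w, params.clip_negative)
                else:
                    expected = step_down_aline(col, params.gamma)
                np.testing.assert_allclose(out.data[:, x, y], expected, rtol=1e-12)

    def test_surface_index_passthrough_above_surface(self, rng):
        """Pixels above the surface are untouched; the mean still spans all N."""
        data = rng.random((16, 3, 3)) + 0.1
        vol = OctaVolume(data=data, surface_index=4)
        out = deshadow_volume(vol, DeshadowParams(w=1.0, normalize_output=False))
        np.testing.assert_array_equal(out.data[:4], data[:4])
        expected_below = np.clip(data[4:] - data.mean(axis=0), 0, None)
        np.testing.assert_allclose(out.data[4:], expected_below)

    def test_step_down_excludes_pixels_above_surface_from_sum(self, rng):
        data = rng.random((16, 2, 2)) + 0.1
        vol = OctaVolume(data=data, surface_index=5)
        out = deshadow_volume(
            vol, DeshadowParams(method="step_down", gamma=2.0, normalize_output=False))
        np.testing.assert_array_equal(out.data[:5], data[:5])
        for x in range(2):
            for y in range(2):
                np.testing.assert_allclose(
                    out.data[5:, x, y], step_down_aline(data[5:, x, y], 2.0), rtol=1e-12)

    def test_w_zero_is_pure_normalization(self, small_volume):
        out = deshadow_volume(small_volume, DeshadowParams(w=0.0))
        np.testing.assert_allclose(
            out.data, small_volume.data / small_volume.data.max())

    def test_single_nonzero_column_locality(self):
        data = np.zeros((8, 4, 4))
        data[:, 2, 1] = np.linspace(1.0, 0.1, 8)
        vol = OctaVolume(data=data)
        out = deshadow_volume(vol, DeshadowParams(w=2.0, normalize_output=False))
        changed = np.argwhere((out.data != data).any(axis=0))
        assert changed.tolist() == [[2, 1]]

    def test_column_permutation_equivariance(self, small_volume, rng):
        perm = rng.permutation(small_volume.nx)
        out_then_perm = deshadow_volume(
            small_volume, DeshadowParams(w=2.0)).data[:, perm, :]
        perm_then_out = deshadow_volume(
            small_volume.with_data(small_volume.data[:, perm, :]),
            DeshadowParams(w=2.0)).data
        np.testing.assert_allclose(out_then_perm, perm_then_out)

    def test_all_zero_volume_skips_normalization_with_warning(self):
        vol = OctaVolume(data=np.zeros((4, 2, 2)))
        with pytest.warns(UserWarning, match="normalization skipped"):
            out = deshadow_volume(vol, DeshadowParams(w=2.0))
        assert not out.data.any()

    def test_params_validation(self):
        with pytest.raises(ValidationError):
            DeshadowParams(method="slab_subtraction")
        with pytest.raises(ValidationError):
            DeshadowParams(method="step_down", gamma=0.0)
        with pytest.raises(ValidationError):
            DeshadowParams(method="mean_subtraction", w=float("inf"))


class TestEqualize:
    def test_two_level_equal_mass_maps_to_half_and_one(self):
        data = np.zeros((2, 2, 2))
        data[1] = 1.0  # values {0, 1}, equal counts
        out = equalize_volume(OctaVolume(data=data), n_bins=16)
        levels = sorted(set(np.round(out.data.ravel(), 12)))
        np.testing.assert_allclose(levels, [0.5, 1.0])

    def test_monotone_rank_preservation(self, small_volume):
        out = equalize_volume(small_volume)
        flat_in = small_volume.data.ravel()
        flat_out = out.data.ravel()
        order = np.argsort(flat_in, kind="stable")
        assert (np.diff(flat_out[order]) >= -1e-12).all()
        assert flat_out.min() >= 0.0 and flat_out.max() <= 1.0

    def test_constant_volume_unchanged_with_warning(self):
        vol = OctaVolume(data=np.full((3, 2, 2), 4.2))
        with pytest.warns(UserWarning, match="no-op"):
            out = equalize_volume(vol)
        np.testing.assert_array_equal(out.data, vol.data)

    def test_bad_bins_rejected(self, small_volume):
        with pytest.raises(ValidationError):
            equalize_volume(small_volume, n_bins=0)


class TestMatchGamma:
    def test_agrees_with_grid_search_oracle(self, single_tail_spec):
        """Bracketed root find lands where a dense grid says the match is."""
        vol, truth = generate_phantom(single_tail_spec)
        roi = truth.tail_mask
        lo, hi = 1e-2, 1e3
        matched = match_gamma(vol, 2.0, roi, search_range=(lo, hi))

        cols = np.argwhere(roi.any(axis=0))
        sub = vol.data[:, cols[:, 0], cols[:, 1]]
        sub_roi = roi[:, cols[:, 0], cols[:, 1]]
        offset = 2.0 * sub.mean(axis=0)
        e_ms = np.clip(sub - offset, 0, None)[sub_roi].mean()

        def e_sd(gamma):
            out = np.empty_like(sub)
            acc = np.zeros(sub.shape[1])
            for z in range(sub.shape[0]):
                out[z] = sub[z] * np.exp(-acc / gamma)
                acc += out[z]
            return out[sub_roi].mean()

        grid = np.geomspace(lo, hi, 200)
        oracle = grid[np.argmin([abs(e_sd(g) - e_ms) for g in grid])]
        assert abs(e_sd(matched) - e_ms) <= 0.05 * e_ms
        assert abs(e_sd(matched) - e_ms) <= abs(e_sd(oracle) - e_ms) + 1e-12

    def test_w_zero_returns_upper_bound_with_warning(self, single_tail_spec):
        vol, truth = generate_phantom(single_tail_spec)
        with pytest.warns(UserWarning, match="boundary"):
            gamma = match_gamma(vol, 0.0, truth.tail_mask, search_range=(0.1, 50.0))
        assert gamma == 50.0

    def test_matched_gamma_monotone_nonincreasing_in_w(self, single_tail_spec):
        vol, truth = generate_phantom(single_tail_spec)
        gammas = [match_gamma(vol, w, truth.tail_mask) for w in (1.0, 2.0, 3.0)]
        assert gammas[0] >= gammas[1] >= gammas[2]

    def test_empty_roi_rejected(self, small_volume):
        with pytest.raises(ValidationError, match="no voxels"):
            match_gamma(small_volume, 2.0, np.zeros(small_volume.data.shape, dtype=bool))
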