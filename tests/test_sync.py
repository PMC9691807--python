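"""NMI, caudal scaling, grid search, and volume deformation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from breathsync import (
    PhantomSpec,
    ScalingParams,
    SearchConfig,
    SpectVolume,
    ValidationError,
    deform_spect,
    generate_phantom,
    normalized_mutual_information,
    optimize_scaling,
    scale_below_baseline,
    synchronize,
)
from breathsync.planar import coronal_reference


# ---------------------------------------------------------------------------
# Independent NMI oracle: literal histogram loops, no shared code
# ---------------------------------------------------------------------------

def nmi_bruteforce(a, b, bins):
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()

    def bin_index(x):
        lo, hi = x.min(), x.max()
        idx = np.empty(len(x), dtype=int)
        for i, v in enumerate(x):
            k = int((v - lo) / (hi - lo) * bins)
            idx[i] = min(k, bins - 1)
        return idx

    ia, ib = bin_index(a), bin_index(b)
    joint = np.zeros((bins, bins))
    for i, j in zip(ia, ib):
        joint[i, j] += 1
    joint /= joint.sum()

    def h(p):
        return -sum(v * np.log2(v) for v in p.ravel() if v > 0)

    return (h(joint.sum(axis=1)) + h(joint.sum(axis=0))) / h(joint)


class TestNmi:
    def test_self_nmi_is_two(self, rng):
        a = rng.random((16, 16))
        assert normalized_mutual_information(a, a, 32).value == pytest.approx(2.0)

    def test_hand_computed_two_by_two(self):
        """Four pixel pairs, one bit per marginal, two bits joint -> NMI = 1."""
        a = np.array([[0.0, 0.0], [1.0, 1.0]])
        b = np.array([[0.0, 1.0], [0.0, 1.0]])
        assert normalized_mutual_information(a, b, 2).value == pytest.approx(1.0)

    def test_symmetry(self, rng):
        a, b = rng.random((12, 12)), rng.random((12, 12))
        ab = normalized_mutual_information(a, b, 16).value
        ba = normalized_mutual_information(b, a, 16).value
        assert ab == pytest.approx(ba, rel=1e-12)

    def test_matches_bruteforce_on_random_images(self, rng):
        """Implementation agrees with a literal joint-histogram computation."""
        for _ in range(100):
            shape = (int(rng.integers(3, 10)), int(rng.integers(3, 10)))
            bins = int(rng.integers(2, 12))
            a = rng.random(shape) * rng.uniform(1, 500)
            b = rng.random(shape) * rng.uniform(1, 500)
            got = normalized_mutual_information(a, b, bins).value
            want = nmi_bruteforce(a, b, bins)
            assert got == pytest.approx(want, rel=1e-10)

    @given(hnp.arrays(np.float64, (8, 8), elements=st.floats(0, 100)))
    @settings(max_examples=30, deadline=None)
    def test_range_one_to_two(self, a):
        b = np.sin(a) + np.linspace(0, 1, 64).reshape(8, 8)
        if a.max() == a.min() or b.max() == b.min():
            return
        v = normalized_mutual_information(a, b, 8).value
        assert 1.0 - 1e-9 <= v <= 2.0 + 1e-9

    def test_constant_image_raises(self):
        with pytest.raises(ValidationError, match="constant"):
            normalized_mutual_information(np.ones((4, 4)), np.eye(4), 4)

    def test_bad_bins(self):
        with pytest.raises(ValidationError, match="bins"):
            normalized_mutual_information(np.eye(4), np.eye(4), 1)


# ---------------------------------------------------------------------------
# scale_below_baseline
# ---------------------------------------------------------------------------

def forward_nn_oracle(img, X, Y):
    """Brute-force forward mapping with nearest-neighbour assignment."""
    out = np.zeros_like(img)
    H = img.shape[0]
    for r in range(H):
        rp = r if r < X else X + (r - X) * Y
        rp = int(round(rp))
        if 0 <= rp < H:
            out[rp] += img[r]
    return out


class TestScaleBelowBaseline:
    def test_identity_at_unit_magnification(self, rng):
        img = rng.random((32, 8))
        out = scale_below_baseline(img, ScalingParams(10, 1.0))
        np.testing.assert_array_equal(out, img)
        assert out is not img

    def test_impulse_doubling(self):
        """Impulse at row 40 with X=0, Y=2 lands centred at row 80.

        Intensities are interpolated, not Jacobian-rescaled, so a stretch by
        Y carries total mass Y x input (each output row resamples the source
        impulse); the location, not the mass, is the contract.
        """
        img = np.zeros((128, 1))
        img[40, 0] = 1.0
        out = scale_below_baseline(img, ScalingParams(0, 2.0))
        oracle = forward_nn_oracle(img, 0, 2.0)
        assert np.argmax(oracle) == 80
        assert out[79:82].sum() == pytest.approx(2.0, abs=1e-9)
        assert out[:79].sum() == 0 and out[82:].sum() == 0
        com = (np.arange(128) * out[:, 0]).sum() / out.sum()
        assert com == pytest.approx(80, abs=1.0)

    def test_impulse_above_baseline_untouched(self):
        img = np.zeros((128, 3))
        img[10, 1] = 7.0
        out = scale_below_baseline(img, ScalingParams(60, 1.3))
        np.testing.assert_array_equal(out[:60], img[:60])
        assert out[10, 1] == 7.0

    def test_compression_zero_fills_tail(self):
        img = np.ones((20, 2))
        out = scale_below_baseline(img, ScalingParams(0, 0.5))
        # sources beyond the last row have no data -> zero rows
        assert not out[11:].any()
        np.testing.assert_allclose(out[:10], 1.0)

    def test_extent_scales_by_y(self):
        """A slab entirely below X grows in extent by the magnification."""
        img = np.zeros((128, 4))
        img[70:100] = 5.0
        out = scale_below_baseline(img, ScalingParams(60, 1.2))
        rows = np.where(out[:, 0] >= 2.5)[0]
        got_extent = rows[-1] - rows[0] + 1
        assert got_extent == pytest.approx(30 * 1.2, abs=1.5)

    def test_x_outside_image_rejected(self):
        with pytest.raises(ValidationError, match="outside"):
            scale_below_baseline(np.ones((10, 2)), ScalingParams(10, 1.1))

    def test_matches_nn_oracle_mass_location(self, rng):
        """Linear-interp inverse map agrees with the forward NN oracle on
        centre of mass for isolated impulses."""
        for _ in range(10):
            r0 = int(rng.integers(30, 90))
            X = int(rng.integers(0, 30))
            Y = float(rng.choice([1.1, 1.25, 1.5]))
            img = np.zeros((160, 1))
            img[r0, 0] = 1.0
            out = scale_below_baseline(img, ScalingParams(X, Y))
            oracle = forward_nn_oracle(img, X, Y)
            if oracle.sum() == 0 or out.sum() == 0:
                continue
            com_out = (np.arange(160) * out[:, 0]).sum() / out.sum()
            com_oracle = (np.arange(160) * oracle[:, 0]).sum() / oracle.sum()
            assert com_out == pytest.approx(com_oracle, abs=1.0)


# ---------------------------------------------------------------------------
# deform_spect
# ---------------------------------------------------------------------------

class TestDeformSpect:
    def test_identity_at_unit_magnification(self, rng):
        vol = SpectVolume(rng.random((20, 6, 6)), (1, 1, 1))
        out = deform_spect(vol, ScalingParams(5, 1.0))
        np.testing.assert_array_equal(out.voxels, vol.voxels)

    def test_projection_commutes_with_deformation(self, rng):
        """Coronal projection of the deformed volume equals the deformed
        coronal projection (axis-0 remap is linear, axis-1 sum is linear)."""
        for seed in range(20):
            r = np.random.default_rng(seed)
            vol = SpectVolume(r.random((40, 8, 10)) * 100, (1, 1, 1))
            params = ScalingParams(int(r.integers(5, 30)),
                                   float(r.choice([0.9, 1.1, 1.25, 1.4])))
            via_volume = coronal_reference(deform_spect(vol, params)).pixels
            via_projection = scale_below_baseline(
                coronal_reference(vol).pixels, params
            )
            scale = np.abs(via_projection).max()
            np.testing.assert_allclose(via_volume, via_projection,
                                       atol=1e-6 * scale)

    def test_slab_extent_grows_by_y(self):
        vox = np.zeros((128, 4, 4))
        vox[70:100] = 9.0
        out = deform_spect(SpectVolume(vox, (1, 1, 1)), ScalingParams(60, 1.2))
        rows = np.where(out.voxels[:, 2, 2] >= 4.5)[0]
        assert rows[-1] - rows[0] + 1 == pytest.approx(36, abs=1.5)

    def test_spacing_unchanged(self, rng):
        vol = SpectVolume(rng.random((16, 4, 4)), (4.42, 4.42, 4.42))
        assert deform_spect(vol, ScalingParams(4, 1.2)).voxel_spacing_mm == \
            vol.voxel_spacing_mm


# ---------------------------------------------------------------------------
# optimize_scaling
# ---------------------------------------------------------------------------

SMALL_SEARCH = SearchConfig(x_min=40, x_max=70, y_min=0.95, y_max=1.35, y_step=0.01)


def _free_planar(seed=0, **kw):
    case = generate_phantom(PhantomSpec(seed=seed, **kw))
    return case.planars[("free_breathing", "anterior")].pixels


class TestOptimizeScaling:
    def test_identical_images_return_unit_y(self):
        img = _free_planar()
        params, trace = optimize_scaling(img, img, SMALL_SEARCH)
        assert params.Y == 1.0
        assert params.X == SMALL_SEARCH.x_min  # tie-break: smallest X

    def test_noiseless_construction_recovered_exactly(self):
        img_d = _free_planar()
        truth = ScalingParams(60, 1.2)
        img_c = scale_below_baseline(img_d, truth)
        params, _ = optimize_scaling(img_c, img_d, SMALL_SEARCH)
        assert (params.X, params.Y) == (60, 1.2)

    def test_returned_params_attain_trace_maximum(self):
        img_d = _free_planar()
        img_c = scale_below_baseline(img_d, ScalingParams(55, 1.15))
        params, trace = optimize_scaling(img_c, img_d, SMALL_SEARCH)
        best_nmi = max(t[2] for t in trace)
        mine = [t for t in trace if t[0] == params.X and t[1] == params.Y]
        assert mine[0][2] == best_nmi

    def test_empty_search_space_rejected(self):
        img = _free_planar()
        with pytest.raises(ValidationError, match="empty"):
            optimize_scaling(img, img, SearchConfig(x_min=300, x_max=400))

    def test_wrong_phase_roles_rejected(self, default_case):
        from breathsync.evaluation import _aligned_pair

        img_c, img_d = _aligned_pair(default_case)
        with pytest.raises(ValidationError, match="deep"):
            optimize_scaling(img_d, img_c, SMALL_SEARCH)


# ---------------------------------------------------------------------------
# synchronize (end to end on one phantom)
# ---------------------------------------------------------------------------

class TestSynchronize:
    def test_same_phase_inputs_leave_volume_unchanged(self, default_case):
        """Feeding deep-intake planars as both phases must find Y = 1."""
        case = default_case
        deep_ant = case.planars[("deep_intake", "anterior")]
        deep_post = case.planars[("deep_intake", "posterior")]
        from breathsync import PlanarImage

        free_ant = PlanarImage(deep_ant.pixels, deep_ant.pixel_spacing_mm,
                               "anterior", "free_breathing")
        free_post = PlanarImage(deep_post.pixels, deep_post.pixel_spacing_mm,
                                "posterior", "free_breathing")
        res = synchronize(case.spect_deep_truth, deep_ant, deep_post,
                          free_ant, free_post)
        assert res.params.Y == 1.0
        np.testing.assert_allclose(
            res.scaled_spect.voxels, case.spect_deep_truth.voxels, atol=1e-9
        )

    def test_objective_not_below_unscaled_nmi(self, default_case):
        """The search includes Y=1, so the result can only improve on it."""
        case = default_case
        res = synchronize(
            case.spect_free,
            case.planars[("deep_intake", "anterior")],
            case.planars[("deep_intake", "posterior")],
            case.planars[("free_breathing", "anterior")],
            case.planars[("free_breathing", "posterior")],
        )
        unscaled = [t[2] for t in res.search_trace if t[1] == 1.0]
        assert res.objective.value >= max(unscaled) - 1e-12

    def test_objective_matches_recomputed_nmi(self, default_case):
        case = default_case
        res = synchronize(
            case.spect_free,
            case.planars[("deep_intake", "anterior")],
            case.planars[("deep_intake", "posterior")],
            case.planars[("free_breathing", "anterior")],
            case.planars[("free_breathing", "posterior")],
        )
        best = max(t[2] for t in res.search_trace)
        assert res.objective.value == pytest.approx(best, rel=1e-12)

    def test_stage_name_attached_to_errors(self, default_case):
        case = default_case
        bad = case.planars[("deep_intake", "anterior")]
        with pytest.raises(ValidationError, match=r"\[step1-sum\]"):
            synchronize(case.spect_free, bad, bad, bad, bad)
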