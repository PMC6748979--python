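import numpy as np
import pytest

from vesselmink.core_io import BinaryVolume, ZStack
from vesselmink.phantoms import (
    RenderSpec,
    make_tube,
    render_zstack,
    standard_phantom,
)
from vesselmink.segmentation import (
    FilterParams,
    adaptive_filter,
    binarise,
    clean,
    hessian_eigenvalues,
    segment,
    vesselness,
)


def dice(a, b):
    return 2 * np.sum(a & b) / (np.sum(a) + np.sum(b))


def finite_difference_hessian_eigs(img, sigma, point):
    """Independent oracle: central finite differences of the smoothed field,
    diagonalized at one voxel."""
    from scipy import ndimage

    sm = ndimage.gaussian_filter(img.astype(np.float64), sigma)
    z, y, x = point
    H = np.empty((3, 3))
    idx = [z, y, x]
    for i in range(3):
        for j in range(3):
            ei = np.zeros(3, int)
            ej = np.zeros(3, int)
            ei[i] = 1
            ej[j] = 1

            def val(off):
                q = np.array(idx) + off
                return sm[tuple(q)]

            H[i, j] = (val(ei + ej) - val(ei - ej) - val(ej - ei) + val(-ei - ej)) / 4.0
    eigs = np.linalg.eigvalsh(H * sigma**2)
    return eigs[np.argsort(np.abs(eigs))]


class TestHessian:
    def test_constant_stack_all_zero(self):
        stack = ZStack(np.full((8, 8, 8), 5.0))
        eigs = hessian_eigenvalues(stack, 1.5)
        np.testing.assert_allclose(eigs, 0.0, atol=1e-10)

    def test_bright_tube_axis_eigen_structure(self):
        vol = make_tube([(12, 12, 4), (12, 12, 20)], 3.0, (24, 24, 24))
        stack = ZStack(vol.occupancy.astype(float) * 100)
        eigs = hessian_eigenvalues(stack, 3.0)
        l1, l2, l3 = eigs[12, 12, 12]
        assert abs(l1) < 0.2 * abs(l3)     # ~0 along the axis
        assert l2 < 0 and l3 < 0
        assert abs(l2 - l3) < 0.35 * abs(l3)  # rotational symmetry

    def test_matches_finite_difference_oracle(self, rng):
        z, y, x = np.mgrid[:24, :24, :24].astype(float)
        # gentle frequencies keep the central-difference truncation error of
        # the oracle itself below the comparison tolerance
        img = np.sin(0.12 * x) * np.cos(0.1 * y) + 0.2 * (z - 12) ** 2 / 144
        stack = ZStack(img - img.min())
        sigma = 2.0
        eigs = hessian_eigenvalues(stack, sigma)
        oracle = finite_difference_hessian_eigs(stack.voxels, sigma, (12, 12, 12))
        np.testing.assert_allclose(eigs[12, 12, 12], oracle, atol=1e-4)

    def test_under_resolved_sigma_warns(self):
        stack = ZStack(np.zeros((4, 4, 4)), spacing=(1.0, 1.0, 2.0))
        with pytest.warns(UserWarning, match="under-resolved"):
            hessian_eigenvalues(stack, 0.6)


class TestVesselness:
    def test_zero_eigenvalues_zero_score(self):
        eigs = np.zeros((2, 2, 2, 3))
        assert np.all(vesselness(eigs) == 0)

    def test_ideal_tube_axis_closed_form(self):
        # lambda1 = 0, lambda2 = lambda3 = -s with s >> gamma:
        # V -> (1 - exp(-1/(2 alpha^2))); alpha = 0.5 gives 1 - e^-2 = 0.8647
        s = 100.0
        eigs = np.array([[[[0.0, -s, -s]]]])
        v = vesselness(eigs, alpha=0.5, beta=0.5, gamma=1.0)
        assert v[0, 0, 0] == pytest.approx((1 - np.exp(-2)) * 1.0, abs=1e-4)

    def test_positive_lambda_suppressed(self):
        eigs = np.array([[[[0.0, 3.0, 5.0]]]])
        assert vesselness(eigs, gamma=1.0)[0, 0, 0] == 0

    def test_on_axis_scores_beat_background(self, snr5_phantom):
        vol, truth, stack = snr5_phantom
        eigs = hessian_eigenvalues(stack, 4.0)
        v = vesselness(eigs)
        fg_scores = v[vol.occupancy]
        bg = v[~vol.occupancy]
        assert fg_scores.mean() > np.percentile(bg, 99)


class TestAdaptiveFilter:
    def test_single_scale_preserves_ranking(self, snr5_phantom):
        _, _, stack = snr5_phantom
        v = vesselness(hessian_eigenvalues(stack, 3.0))
        combined = adaptive_filter(stack, FilterParams(scales=(3.0, 3.0)))
        flat_v = np.argsort(v.ravel())
        flat_c = np.argsort(combined.ravel())
        np.testing.assert_array_equal(flat_v[-100:], flat_c[-100:])

    def test_adding_a_scale_never_decreases_scores(self, snr5_phantom):
        _, _, stack = snr5_phantom
        # compare un-rescaled maxima via the monotone log map: use raw fields
        v2 = np.maximum.reduce([
            vesselness(hessian_eigenvalues(stack, s)) for s in (2.0, 4.0)])
        v3 = np.maximum.reduce([
            vesselness(hessian_eigenvalues(stack, s)) for s in (2.0, 4.0, 6.0)])
        assert np.all(v3 >= v2 - 1e-12)

    def test_two_calibre_phantom_needs_both_scales(self):
        thin = make_tube([(16, 10, 6), (16, 10, 58)], 2.0, (32, 40, 64))
        thick = make_tube([(16, 30, 6), (16, 30, 58)], 5.0, (32, 40, 64))
        occ = thin.occupancy | thick.occupancy
        stack = render_zstack(BinaryVolume(occ),
                              RenderSpec(psf_sigma=(1, 1, 1), noise_sd=10,
                                         speckle_rate=0, background_level=5,
                                         background_gradient=0,
                                         signal_level=100, seed=3))
        p = FilterParams(scales=(1.5, 5.0))
        combined = adaptive_filter(stack, p)
        thr = binarise(combined, p).meta["threshold"]
        on_thin = combined[16, 10, 20:45]
        on_thick = combined[16, 30, 20:45]
        assert np.median(on_thin) > thr and np.median(on_thick) > thr
        # either single scale alone misses one calibre's axis response
        v_small = vesselness(hessian_eigenvalues(stack, 1.5))
        v_large = vesselness(hessian_eigenvalues(stack, 5.0))
        assert np.median(v_small[16, 30, 20:45]) < np.median(v_small[16, 10, 20:45])
        assert np.median(v_large[16, 10, 20:45]) < np.median(v_large[16, 30, 20:45])


class TestBinarise:
    def test_indicator_scores_recovered_for_any_threshold(self, rng):
        truth = rng.random((6, 6, 6)) < 0.4
        scores = truth.astype(float)
        for t in (0.2, 0.5, 0.8):
            p = FilterParams(scales=(1.0, 2.0), threshold_method="fixed",
                             fixed_threshold=t)
            out = binarise(scores, p)
            assert np.array_equal(out.occupancy, truth)

    def test_bimodal_histogram_matches_brute_force_criterion(self, rng):
        lo = np.clip(rng.normal(0.2, 0.05, 4000), 0.01, 1)
        hi = np.clip(rng.normal(0.8, 0.05, 4000), 0, 1)
        scores = np.concatenate([lo, hi]).reshape(20, 20, 20)
        p = FilterParams(scales=(1.0, 2.0))
        thr = binarise(scores, p).meta["threshold"]

        def between_class_variance(t):
            a, b = scores[scores <= t], scores[scores > t]
            if a.size == 0 or b.size == 0:
                return -np.inf
            w0, w1 = a.size / scores.size, b.size / scores.size
            return w0 * w1 * (a.mean() - b.mean()) ** 2

        sweep = np.linspace(0.05, 0.95, 400)
        brute = sweep[int(np.argmax([between_class_variance(t) for t in sweep]))]
        assert thr == pytest.approx(brute, abs=0.01)
        # the threshold separates the two modes nearly perfectly
        labels = np.concatenate([np.zeros(4000), np.ones(4000)])
        assert np.mean((scores.ravel() > thr) != labels) < 0.01

    def test_all_zero_field_raises(self):
        p = FilterParams(scales=(1.0, 2.0))
        with pytest.raises(ValueError, match="degenerate"):
            binarise(np.zeros((4, 4, 4)), p)


class TestClean:
    def test_small_components_removed(self):
        occ = np.zeros((20, 20, 20), bool)
        occ[2:10, 2:10, 2:10] = True         # 512 voxels
        occ[15:17, 15:17, 15:18] = True      # 12 voxels
        p = FilterParams(scales=(1.0, 2.0), min_cluster_voxels=100)
        out = clean(BinaryVolume(occ), p)
        assert out.count() == 512

    def test_min_cluster_one_is_identity(self, rng):
        occ = rng.random((8, 8, 8)) < 0.2
        p = FilterParams(scales=(1.0, 2.0), min_cluster_voxels=1)
        out = clean(BinaryVolume(occ), p)
        assert np.array_equal(out.occupancy, occ)

    def test_false_positive_components_removed_on_phantom(self, snr5_phantom):
        vol, truth, stack = snr5_phantom
        from scipy import ndimage

        p = FilterParams()
        mask = segment(stack, None)
        struct = np.ones((3, 3, 3), bool)
        _, n_out = ndimage.label(mask.occupancy, structure=struct)
        # all ground-truth components retained, spurious ones essentially gone
        assert n_out == truth["components"]


class TestFullPipeline:
    def test_dice_on_standard_phantom(self, snr5_phantom):
        vol, _, stack = snr5_phantom
        mask = segment(stack)
        assert dice(mask.occupancy, vol.occupancy) >= 0.90

    def test_dice_noise_free(self, snr5_phantom):
        vol, _, _ = snr5_phantom
        rs = RenderSpec(psf_sigma=(0, 0, 0), noise_sd=0, speckle_rate=0,
                        background_level=0, background_gradient=0,
                        signal_level=100, seed=0)
        mask = segment(render_zstack(vol, rs))
        assert dice(mask.occupancy, vol.occupancy) >= 0.98

    def test_affine_intensity_equivariance(self, snr5_phantom):
        _, _, stack = snr5_phantom
        params = FilterParams(scales=(2.0, 4.0, 8.0))
        m1 = segment(stack, params)
        rescaled = ZStack(stack.voxels * 3.7 + 11.0, spacing=stack.spacing)
        m2 = segment(rescaled, params)
        assert np.array_equal(m1.occupancy, m2.occupancy)

    def test_deterministic(self, snr5_phantom):
        _, _, stack = snr5_phantom
        m1 = segment(stack)
        m2 = segment(stack)
        assert np.array_equal(m1.occupancy, m2.occupancy)
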