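"""Warping, stripe composites, flicker animations, superposition plots."""

import numpy as np
import pytest

import cecalign as ca
from cecalign.errors import InvalidInputError


@pytest.fixture(scope="module")
def smooth_image():
    yy, xx = np.mgrid[0:256, 0:256]
    return ca.GrayImage((128 + 100 * np.sin(xx / 30) * np.cos(yy / 37)).astype(np.uint8))


@pytest.fixture(scope="module")
def rendered_pair(mosaic250, rendered250):
    """Fixed image plus its integer-translation twin, warped back into register."""
    t = ca.AffineTransform.translation(18.0, -11.0)
    img_m = ca.warp_image(rendered250, t.invert(), (480, 480))
    warped = ca.warp_image(img_m, t, (480, 480))
    return rendered250, warped


class TestWarpImage:
    def test_identity_is_exact(self, rendered250):
        out = ca.warp_image(rendered250, ca.AffineTransform.identity(),
                            (rendered250.height, rendered250.width))
        assert np.array_equal(out.pixels, rendered250.pixels)

    def test_integer_translation_shifts_content(self, rendered250):
        out = ca.warp_image(rendered250, ca.AffineTransform.translation(5, 0),
                            (rendered250.height, rendered250.width))
        assert np.array_equal(out.pixels[:, 5:], rendered250.pixels[:, :-5])
        assert not out.mask[:, :5].any()

    def test_roundtrip_recovers_smooth_interior(self, smooth_image):
        t = ca.AffineTransform.from_params(scale=1.02, rotation=3.0,
                                           translation=(4.0, -6.0), center=(128, 128))
        once = ca.warp_image(smooth_image, t, (256, 256))
        back = ca.warp_image(once, t.invert(), (256, 256))
        inner = (slice(40, 216),) * 2
        valid = back.mask[inner]
        diff = np.abs(
            back.pixels[inner].astype(int) - smooth_image.pixels[inner].astype(int)
        )[valid]
        assert diff.max() <= 2


class TestStripeComposite:
    def test_identical_inputs_luminance_preserved(self, rendered250):
        comp = ca.stripe_composite(rendered250, rendered250)
        assert np.array_equal(comp.max(axis=2), rendered250.pixels)

    def test_band_count_and_provenance(self):
        a = ca.GrayImage(np.full((100, 50), 200, dtype=np.uint8))
        b = ca.GrayImage(np.full((100, 50), 90, dtype=np.uint8))
        p = ca.StripeCompositeParams(stripe_width=10, orientation="horizontal")
        comp = ca.stripe_composite(a, b, p)
        bands = [comp[i * 10, 0] for i in range(10)]
        assert len(bands) == 10
        for i, px in enumerate(bands):
            if i % 2 == 0:  # fixed image, green tint
                assert px[1] == 200 and px[0] == 0
            else:  # warped image, red tint
                assert px[0] == 90 and px[1] == 0

    def test_border_continuity_when_registered(self, rendered_pair):
        img_f, warped = rendered_pair
        comp = ca.stripe_composite(img_f, warped)
        lum = comp.max(axis=2).astype(float)
        grad = np.abs(np.diff(lum, axis=0))[:, 32:448]
        rows = np.arange(grad.shape[0])
        boundary = (rows % 16) == 15
        ratio = grad[boundary].mean() / grad[~boundary].mean()
        assert abs(ratio - 1.0) <= 0.10

    def test_shape_mismatch_rejected(self, rendered250):
        other = ca.GrayImage(np.zeros((64, 64), dtype=np.uint8))
        with pytest.raises(InvalidInputError):
            ca.stripe_composite(rendered250, other)


class TestFlickerAnimation:
    def test_identical_inputs_identical_frames(self, rendered250):
        anim = ca.flicker_animation(rendered250, rendered250)
        assert np.array_equal(anim.frames[0], anim.frames[1])

    def test_two_frames_and_period(self, rendered_pair):
        img_f, warped = rendered_pair
        anim = ca.flicker_animation(img_f, warped, ca.FlickerParams(period=250))
        assert len(anim.frames) == 2
        assert anim.period == 250
        assert not np.array_equal(anim.frames[0], anim.frames[1])

    def test_registered_pair_flickers_less(self, rendered_pair, rendered250):
        img_f, warped = rendered_pair
        bad = ca.warp_image(rendered250, ca.AffineTransform.translation(20, 12),
                            (480, 480))
        d_good = np.mean(np.abs(img_f.pixels.astype(int) - warped.pixels.astype(int)))
        d_bad = np.mean(np.abs(img_f.pixels.astype(int) - bad.pixels.astype(int)))
        assert d_good < d_bad

    def test_gif_export(self, tmp_path, rendered_pair):
        img_f, warped = rendered_pair
        path = tmp_path / "flicker.gif"
        ca.flicker_animation(img_f, warped).save(path)
        import imageio.v3 as iio

        frames = iio.imread(path, index=None)
        assert frames.shape[0] == 2


class TestSuperpositionPlot:
    def test_empty_sets_give_valid_figure(self):
        empty = ca.CentroidSet(np.empty((0, 2)), 480, 480)
        fig = ca.centroid_superposition_plot(empty, empty)
        assert fig is not None

    def test_registered_pair_markers_coincide(self, spec_pair):
        res = ca.register(spec_pair.moving, spec_pair.fixed)
        moved = ca.apply_transform(res.transform, spec_pair.moving)
        cap = ca.registration.pairing_cap(spec_pair.fixed, ca.RegistrationConfig())
        s = ca.overlap_score(moved, spec_pair.fixed, cap)
        assert s.matched_pairs / len(moved) >= 0.85
        fig = ca.centroid_superposition_plot(moved, spec_pair.fixed)
        assert fig is not None
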