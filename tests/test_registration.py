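"""Registration chain: geometric normalization, warping, affine recovery."""

import numpy as np
import pytest

import popsim as ps
from popsim.registration import (
    AffineTransform2D,
    RegistrationError,
    coarse_register,
    multiscale_affine,
    register_pair,
    warp,
)


def _bead_image(n_beads=60, seed=11, grid=19200):
    ph = ps.make_bead_phantom(
        n_beads, field_size=0.7 * grid, grid_extent=grid,
        min_separation=1200, placement="disc", seed=seed,
    )
    pats = (ps.PatternParams(modulation_depth=0.0),)
    frames = ps.simulate_raw_frames(
        ph, ps.OpticalConfig(tilt_angle=0.0), pats
    )
    return frames.images[0, 0]


def _corner_error(t_est, t_true, shape):
    h, w = shape
    corners = np.array([[0, 0], [w - 1, 0], [0, h - 1], [w - 1, h - 1]], float)
    return np.linalg.norm(t_est.apply(corners) - t_true.apply(corners), axis=1).mean()


class TestAffineTransform2D:
    def test_bottom_row_enforced(self):
        m = np.eye(3)
        m[2, 0] = 0.1
        with pytest.raises(ValueError):
            AffineTransform2D(m)

    def test_singular_rejected(self):
        m = np.eye(3)
        m[0, 0] = 0.0
        with pytest.raises(ValueError):
            AffineTransform2D(m)

    def test_inverse_composition_is_identity(self):
        t = AffineTransform2D.from_params(
            translation=(3, -2), rotation_deg=10, log_scale=(0.05, -0.02),
            shear=0.1, center=(50, 50),
        )
        np.testing.assert_allclose((t @ t.inverse()).matrix, np.eye(3), atol=1e-12)

    def test_json_round_trip(self):
        t = AffineTransform2D.from_params(translation=(1.5, 2.5), rotation_deg=-3)
        t2 = AffineTransform2D.from_dict(t.to_dict())
        np.testing.assert_allclose(t.matrix, t2.matrix)


class TestWarp:
    def test_identity_is_bit_exact(self):
        rng = np.random.default_rng(0)
        img = rng.random((32, 32))
        out = warp(img, AffineTransform2D.identity())
        np.testing.assert_array_equal(out, img)

    def test_forward_then_inverse_recovers_interior(self):
        img = ps.simulate_raw_frames(
            ps.make_bead_phantom(10, field_size=5000, grid_extent=9600,
                                 min_separation=1200, placement="disc", seed=2),
            ps.OpticalConfig(tilt_angle=0.0),
            (ps.PatternParams(modulation_depth=0.0),),
        ).images[0, 0]
        t = AffineTransform2D.from_params(
            translation=(4.3, -2.7), rotation_deg=5.0, center=(47.5, 47.5)
        )
        back = warp(warp(img, t), t.inverse())
        interior = (slice(10, -10), slice(10, -10))
        err = np.abs(back[interior] - img[interior]).mean()
        assert err < 0.01 * img.max()

    def test_translation_out_of_frame_gives_zeros(self):
        img = np.ones((16, 16))
        t = AffineTransform2D.from_params(translation=(100, 0))
        assert warp(img, t).sum() == 0.0

    def test_composition_consistency(self):
        rng = np.random.default_rng(3)
        from scipy import ndimage

        img = ndimage.gaussian_filter(rng.random((64, 64)), 3.0)
        t1 = AffineTransform2D.from_params(translation=(2, 1), rotation_deg=3, center=(31.5, 31.5))
        t2 = AffineTransform2D.from_params(translation=(-1, 2), rotation_deg=-5, center=(31.5, 31.5))
        a = warp(warp(img, t1), t2)
        b = warp(img, t2 @ t1)
        interior = (slice(8, -8), slice(8, -8))
        assert np.abs(a[interior] - b[interior]).max() < 0.02 * img.max()


class TestToCommonFrame:
    def test_orientation_one_is_pure_compression(self):
        # a ruler of beads along x, spaced 2000 nm, through the 45-degree
        # projection: stretched sqrt(2) in the raw frame, isotropic after
        # the fixed compression
        import pandas as pd

        from popsim.phantom import Phantom3D, _render_emitters

        rows = [
            dict(x_nm=dx, y_nm=dy, z_nm=0.0, diameter_nm=10.0, brightness=1000.0)
            for dx in (-2000.0, 0.0, 2000.0)
            for dy in (-2000.0, 0.0, 2000.0)
        ]
        em = pd.DataFrame(rows)
        density = _render_emitters((1, 256, 256), em, 50.0, 200.0)
        ph = Phantom3D(density, 50.0, 200.0, em)
        frames = ps.simulate_raw_frames(
            ph, patterns=(ps.PatternParams(modulation_depth=0.0),)
        )
        raw = frames.images[0, 0]

        def span_ratio(img, pixel):
            pos = ps.detect_beads(img, pixel, min_separation=1000)
            assert len(pos) == 9
            return (pos[:, 1].max() - pos[:, 1].min()) / (
                pos[:, 0].max() - pos[:, 0].min()
            )

        assert span_ratio(raw, 100.0) == pytest.approx(np.sqrt(2.0), rel=0.01)
        common = ps.to_common_frame(raw, 1, 45.0)
        assert span_ratio(common, 100.0) == pytest.approx(1.0, rel=0.005)

    def test_orientations_two_three_related_by_rotation(self):
        # a rotationally symmetric phantom: after to_common_frame the three
        # orientations must coincide (up to interpolation)
        ph = ps.make_bead_phantom(
            12, field_size=9000, grid_extent=19200, min_separation=1800,
            placement="disc", seed=6,
        )
        flat = tuple(
            ps.PatternParams(azimuth=a, modulation_depth=0.0) for a in (0, 60, -60)
        )
        frames = ps.simulate_raw_frames(ph, patterns=flat)
        commons = [
            ps.to_common_frame(frames.images[i, 0], i + 1, 45.0) for i in range(3)
        ]
        for other in commons[1:]:
            num = np.abs(other - commons[0]).sum()
            assert num / commons[0].sum() < 0.05

    def test_unknown_orientation_rejected(self):
        with pytest.raises(ValueError):
            ps.to_common_frame(np.ones((8, 8)), 4)


class TestCoarseRegister:
    def test_identical_images_give_zero_shift(self):
        img = _bead_image(12, seed=1, grid=9600)
        dx, dy = coarse_register(img, img)
        assert abs(dx) < 0.05 and abs(dy) < 0.05

    def test_integer_shift_recovered(self):
        img = _bead_image(30, seed=2)
        moving = np.roll(np.roll(img, -9, axis=0), 15, axis=1)
        # moving is img shifted by (dx=+15, dy=-9): registration undoes it
        dx, dy = coarse_register(img, moving)
        assert dx == pytest.approx(-15, abs=0.1)
        assert dy == pytest.approx(9, abs=0.1)

    def test_subpixel_shift_recovered(self):
        from scipy import ndimage

        img = _bead_image(30, seed=3)
        moving = ndimage.shift(img, (-7.8, 12.3), order=3, mode="constant")
        dx, dy = coarse_register(img, moving)
        assert dx == pytest.approx(-12.3, abs=0.2)
        assert dy == pytest.approx(7.8, abs=0.2)

    def test_flat_image_rejected(self):
        with pytest.raises(RegistrationError):
            coarse_register(np.ones((32, 32)), np.ones((32, 32)))


class TestMultiscaleAffine:
    def test_identity_for_identical_images(self):
        img = _bead_image(40, seed=4)
        res = multiscale_affine(img, img, levels=(8, 4, 2, 1))
        np.testing.assert_allclose(res.transform.matrix, np.eye(3), atol=1e-3)
        assert res.converged

    def test_known_affine_recovered(self):
        img = _bead_image(60, seed=11)
        h, w = img.shape
        b = AffineTransform2D.from_params(
            translation=(8, -5), rotation_deg=2.0,
            log_scale=(np.log(1.03), 0.0), shear=0.01,
            center=((w - 1) / 2, (h - 1) / 2),
        )
        moving = warp(img, b)
        res = register_pair(img, moving)
        assert _corner_error(res.transform, b.inverse(), img.shape) < 0.5

    def test_translation_recovered_under_poisson_noise(self):
        rng = np.random.default_rng(7)
        img = _bead_image(60, seed=12)
        h, w = img.shape
        t = AffineTransform2D.from_params(
            translation=(12.3, -7.8), center=((w - 1) / 2, (h - 1) / 2)
        )
        moving = warp(img, t)
        scale = 100.0 / img.max()  # peak ~100 photons -> SNR ~ 10
        fixed_n = rng.poisson(img * scale).astype(float)
        moving_n = rng.poisson(moving * scale).astype(float)
        res = register_pair(fixed_n, moving_n)
        assert _corner_error(res.transform, t.inverse(), img.shape) < 0.5

    def test_score_trace_monotone_for_recovery(self):
        img = _bead_image(40, seed=5)
        h, w = img.shape
        t = AffineTransform2D.from_params(
            translation=(6, 3), rotation_deg=1.0, center=((w - 1) / 2, (h - 1) / 2)
        )
        res = register_pair(img, warp(img, t))
        trace = res.score_trace
        assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))

    def test_non_finite_rejected(self):
        img = np.ones((64, 64))
        bad = img.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            multiscale_affine(img, bad)


class TestEndToEndOrientations:
    def test_three_orientation_bead_discrepancy_below_half_pixel(self, resolution_run):
        """After the full chain the three orientations' bead positions agree."""
        run = resolution_run
        frames = run.registered
        pixel = frames.pixel_size
        coords = []
        for i in range(3):
            wf = frames.images[i].sum(axis=0)
            pos = ps.detect_beads(wf, pixel, min_separation=1500)
            h, w = wf.shape
            x = (pos[:, 1] - (w - 1) / 2) * pixel
            y = (pos[:, 0] - (h - 1) / 2) * pixel
            coords.append(np.column_stack([x, y]))
        from popsim.shear_calibration import _mutual_matches

        for a in range(3):
            for b in range(a + 1, 3):
                pairs, dists = _mutual_matches(coords[a], coords[b], 500.0)
                assert len(pairs) >= 20
                assert dists.mean() < 0.5 * pixel
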