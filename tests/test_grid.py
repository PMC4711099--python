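"""Geometry of the 7-line fan, bilinear sampling and the temporal median."""

import math

import numpy as np
import pytest

from lingua_rt import (
    FrameSequence,
    Kymograph,
    LandmarkPair,
    build_profile_grid,
    extract_kymograph,
    line_coordinates,
    temporal_median_filter,
)


def bilinear_oracle(img, r, c):
    """Independent brute-force bilinear interpolation at one point."""
    r0, c0 = int(np.floor(r)), int(np.floor(c))
    r1, c1 = min(r0 + 1, img.shape[0] - 1), min(c0 + 1, img.shape[1] - 1)
    fr, fc = r - r0, c - c0
    return (
        img[r0, c0] * (1 - fr) * (1 - fc)
        + img[r1, c0] * fr * (1 - fc)
        + img[r0, c1] * (1 - fr) * fc
        + img[r1, c1] * fr * fc
    )


class TestGridConstruction:
    def test_default_seven_angles(self):
        grid = build_profile_grid(LandmarkPair((40, 30), (45, 100)))
        assert grid.angles_deg == [0.0, 30.0, 60.0, 90.0, 120.0, 150.0, 180.0]

    def test_horizontal_baseline_angle_zero(self):
        grid = build_profile_grid(LandmarkPair((50, 100), (50, 180)))
        assert grid.baseline_angle == pytest.approx(0.0)
        # line 1 runs along +col, line 4 perpendicular toward +row (the cavity)
        assert grid.direction(1) == pytest.approx((0.0, 1.0))
        assert grid.direction(4) == pytest.approx((1.0, 0.0))

    def test_first_and_last_lines_collinear_opposite(self):
        grid = build_profile_grid(LandmarkPair((40, 30), (55, 95)), length_px=60)
        r1, c1, _ = line_coordinates(grid, 1)
        r7, c7, _ = line_coordinates(grid, 7)
        # independent rotation computation of the two endpoint directions
        ang = math.atan2(55 - 40, 95 - 30)
        end1 = (40 + 60 * math.sin(ang), 30 + 60 * math.cos(ang))
        assert (r1[-1], c1[-1]) == pytest.approx(end1, abs=1e-9)
        end7 = (40 - 60 * math.sin(ang), 30 - 60 * math.cos(ang))
        assert (r7[-1], c7[-1]) == pytest.approx(end7, abs=1e-9)

    def test_intermediate_line_matches_rotation_oracle(self):
        lm = LandmarkPair((40, 30), (48, 92))
        grid = build_profile_grid(lm, length_px=50)
        base = math.atan2(8, 62)
        for k, theta_deg in zip(range(1, 8), grid.angles_deg):
            # rotate the baseline direction by theta toward the +row side
            theta = math.radians(theta_deg)
            dr = math.sin(base) * math.cos(theta) + math.cos(base) * math.sin(theta)
            dc = math.cos(base) * math.cos(theta) - math.sin(base) * math.sin(theta)
            assert grid.direction(k) == pytest.approx((dr, dc), abs=1e-12)

    def test_rotation_equivariance(self):
        """Rotating image + landmarks by 90° rotates every line endpoint."""
        lm = LandmarkPair((40, 30), (47, 90))
        grid = build_profile_grid(lm, length_px=40)
        w = 128  # image width before rotation (rot90: (r, c) -> (w-1-c, r))
        lm_rot = LandmarkPair(
            incisor=(w - 1 - lm.incisor[1], lm.incisor[0]),
            disc=(w - 1 - lm.disc[1], lm.disc[0]),
        )
        grid_rot = build_profile_grid(lm_rot, length_px=40)
        for k in range(1, 8):
            r, c, _ = line_coordinates(grid, k)
            rr, cc, _ = line_coordinates(grid_rot, k)
            assert np.allclose(rr, w - 1 - c, atol=1e-9)
            assert np.allclose(cc, r, atol=1e-9)

    def test_coincident_landmarks_rejected(self):
        with pytest.raises(ValueError):
            build_profile_grid(LandmarkPair((1, 1), (1, 1.0 + 1e-30)))


class TestKymographExtraction:
    def test_constant_frame_gives_constant_rows(self):
        film = FrameSequence(np.full((4, 64, 64), 0.37, np.float32), 1 / 30)
        grid = build_profile_grid(LandmarkPair((10, 10), (14, 60)), length_px=40)
        kymo = extract_kymograph(film, grid, 2)
        assert np.allclose(kymo.values[np.isfinite(kymo.values)], 0.37, atol=1e-6)

    def test_axis_aligned_line_reproduces_linear_ramp(self):
        ramp = np.tile(np.arange(64, dtype=float) / 63.0, (64, 1))
        film = FrameSequence(ramp[None], 1 / 30)
        grid = build_profile_grid(LandmarkPair((30, 5), (30, 60)), length_px=50)
        kymo = extract_kymograph(film, grid, 1)  # along +col
        expected = (5 + kymo.positions_px) / 63.0
        assert np.allclose(kymo.values[0], expected, atol=1e-12)

    def test_oblique_line_matches_bilinear_oracle(self):
        rng = np.random.default_rng(4)
        img = rng.random((60, 60))
        film = FrameSequence(img[None], 1 / 30)
        grid = build_profile_grid(LandmarkPair((8, 6), (15, 50)), length_px=40)
        kymo = extract_kymograph(film, grid, 3)
        rows, cols, _ = line_coordinates(grid, 3)
        oracle = np.array([bilinear_oracle(img, r, c) for r, c in zip(rows, cols)])
        assert np.allclose(kymo.values[0], oracle, atol=1e-9)

    def test_out_of_bounds_marked_missing(self):
        film = FrameSequence(np.ones((2, 40, 40), np.float32), 1 / 30)
        grid = build_profile_grid(LandmarkPair((5, 5), (5, 30)), length_px=60)
        kymo = extract_kymograph(film, grid, 1)  # runs off the right edge
        assert np.isnan(kymo.values[0, -1]) and np.isfinite(kymo.values[0, 0])

    def test_fully_outside_line_rejected(self):
        film = FrameSequence(np.ones((1, 40, 40), np.float32), 1 / 30)
        # pivot below the image; line 4 heads further down, never entering it
        grid = build_profile_grid(LandmarkPair((50, 10), (50, 35)), length_px=30)
        with pytest.raises(ValueError, match="outside"):
            extract_kymograph(film, grid, 4)

    def test_commutes_with_in_bounds_cropping(self):
        rng = np.random.default_rng(5)
        frames = rng.random((3, 80, 80)).astype(np.float32)
        lm = LandmarkPair((30, 20), (34, 70))
        grid = build_profile_grid(lm, length_px=30)
        kymo = extract_kymograph(FrameSequence(frames, 1 / 30), grid, 2)
        r0, c0 = 10, 5
        lm_c = LandmarkPair(
            (lm.incisor[0] - r0, lm.incisor[1] - c0),
            (lm.disc[0] - r0, lm.disc[1] - c0),
        )
        grid_c = build_profile_grid(lm_c, length_px=30)
        kymo_c = extract_kymograph(
            FrameSequence(frames[:, r0:, c0:], 1 / 30), grid_c, 2
        )
        assert np.allclose(kymo.values, kymo_c.values, equal_nan=True, atol=1e-12)


def sliding_median_oracle(values, n):
    """Brute-force centered median with shrunken symmetric edge windows."""
    t = values.shape[0]
    out = np.empty_like(values)
    for i in range(t):
        k = min(n // 2, i, t - 1 - i)
        out[i] = np.median(values[i - k : i + k + 1], axis=0)
    return out


class TestTemporalMedianFilter:
    def _kymo(self, values):
        return Kymograph(
            line_index=2,
            values=values,
            positions_px=np.arange(values.shape[1], dtype=float),
        )

    def test_constant_signal_unchanged(self):
        kymo = self._kymo(np.full((20, 6), 0.5))
        assert np.array_equal(temporal_median_filter(kymo, 5).values, kymo.values)

    def test_single_frame_impulse_removed(self):
        values = np.full((30, 4), 0.2)
        values[13] = 0.9
        out = temporal_median_filter(self._kymo(values), 5).values
        assert np.allclose(out[2:-2], 0.2)

    def test_matches_brute_force_oracle_exactly(self):
        rng = np.random.default_rng(6)
        values = rng.random((50, 9))
        out = temporal_median_filter(self._kymo(values), 5).values
        assert np.array_equal(out, sliding_median_oracle(values, 5))

    def test_idempotent_on_long_constant_runs(self):
        values = np.repeat(np.array([[0.2], [0.8], [0.4]]), 10, axis=0)
        values = np.tile(values, (1, 3))
        once = temporal_median_filter(self._kymo(values), 5)
        twice = temporal_median_filter(once, 5)
        assert np.array_equal(once.values, twice.values)

    def test_even_width_rejected(self):
        with pytest.raises(ValueError):
            temporal_median_filter(self._kymo(np.zeros((10, 3))), 4)

    def test_width_beyond_length_rejected(self):
        with pytest.raises(ValueError):
            temporal_median_filter(self._kymo(np.zeros((3, 3))), 5)
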