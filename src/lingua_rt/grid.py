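"""Landmark-anchored line-profile grid and kymograph extraction.

Two anatomical landmarks — the lower edge of the upper incisor and the
anterior edge of the third intervertebral disc — define a baseline across the
oral cavity. Seven line profiles fan out from a common pivot at orientations
0, 30, 60, 90, 120, 150 and 180° relative to that baseline, opening into the
half-plane that contains the tongue. Luminance sampled along one line over
all frames forms a kymograph (position × time matrix), the object on which
edge tracking operates.

Where the lines are anchored is not anatomically forced; by default they all
share the incisor landmark as a common origin (``pivot="incisor"``), with
``pivot="midpoint"`` available as an alternative.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import FrameSequence, LandmarkPair

__all__ = [
    "ProfileGrid",
    "Kymograph",
    "build_profile_grid",
    "line_coordinates",
    "extract_kymograph",
    "temporal_median_filter",
]


@dataclass
class ProfileGrid:
    """Geometry of the 7-line sampling fan."""

    pivot: tuple[float, float]  # (row, col)
    baseline_angle: float  # radians, direction incisor -> disc
    angles_deg: list[float]  # orientations relative to the baseline
    length_px: float = 80.0
    step_px: float = 1.0

    def __post_init__(self) -> None:
        if self.length_px <= 0 or self.step_px <= 0:
            raise ValueError("length_px and step_px must be positive")
        if len(self.angles_deg) < 1:
            raise ValueError("at least one line required")

    @property
    def n_lines(self) -> int:
        return len(self.angles_deg)

    def direction(self, line_index: int) -> tuple[float, float]:
        """Unit direction (d_row, d_col) of a 1-based line index."""
        theta = math.radians(self.angles_deg[line_index - 1])
        ur = math.sin(self.baseline_angle)
        uc = math.cos(self.baseline_angle)
        # perpendicular with fixed chirality (rotation-equivariant); for a
        # left-to-right baseline it points toward increasing rows, i.e. into
        # the oral cavity below the incisor
        pr, pc = uc, -ur
        return (
            math.cos(theta) * ur + math.sin(theta) * pr,
            math.cos(theta) * uc + math.sin(theta) * pc,
        )


@dataclass
class Kymograph:
    """Luminance along one profile line, stacked over frames.

    ``values`` has shape (n_frames, n_positions); samples that fell outside
    the image are NaN. ``line_index`` is 1-based (line 2 crosses the anterior
    third of the tongue and is the default analysis line).
    """

    line_index: int
    values: np.ndarray
    positions_px: np.ndarray
    frame_period_s: float = 1.0 / 30.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.positions_px = np.asarray(self.positions_px, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("kymograph values must be 2-D (frame × position)")
        if self.values.shape[1] != self.positions_px.size:
            raise ValueError("positions length must match value columns")
        d = np.diff(self.positions_px)
        if self.positions_px.size and (self.positions_px[0] != 0 or np.any(d <= 0)):
            raise ValueError("positions must increase strictly from 0")

    @property
    def n_frames(self) -> int:
        return int(self.values.shape[0])


def build_profile_grid(
    landmarks: LandmarkPair,
    n_lines: int = 7,
    length_px: float = 80.0,
    step_px: float = 1.0,
    pivot: str = "incisor",
) -> ProfileGrid:
    """Construct the landmark-anchored fan of line profiles.

    Line k (k = 1..n_lines) is oriented at (k−1)·180/(n_lines−1) degrees from
    the incisor→disc baseline, so the default 7 lines sit at 0, 30, 60, 90,
    120, 150 and 180°. Lines 1 and n are collinear with the baseline, pointing
    in opposite directions.
    """
    if n_lines < 2:
        raise ValueError("need at least 2 lines")
    dr = landmarks.disc[0] - landmarks.incisor[0]
    dc = landmarks.disc[1] - landmarks.incisor[1]
    if dr == 0 and dc == 0:
        raise ValueError("landmarks are coincident")
    baseline_angle = math.atan2(dr, dc)  # angle from +col axis toward +row
    if pivot == "incisor":
        origin = landmarks.incisor
    elif pivot == "midpoint":
        origin = (
            0.5 * (landmarks.incisor[0] + landmarks.disc[0]),
            0.5 * (landmarks.incisor[1] + landmarks.disc[1]),
        )
    else:
        raise ValueError("pivot must be 'incisor' or 'midpoint'")
    angles = [k * 180.0 / (n_lines - 1) for k in range(n_lines)]
    return ProfileGrid(
        pivot=(float(origin[0]), float(origin[1])),
        baseline_angle=baseline_angle,
        angles_deg=angles,
        length_px=float(length_px),
        step_px=float(step_px),
    )


def line_coordinates(
    grid: ProfileGrid, line_index: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample coordinates of one line: ``(rows, cols, positions_px)``.

    Positions run from 0 at the pivot outward in ``step_px`` increments up to
    and including ``length_px``.
    """
    if not 1 <= line_index <= grid.n_lines:
        raise ValueError(f"line_index must be in 1..{grid.n_lines}")
    positions = np.arange(0.0, grid.length_px + 0.5 * grid.step_px, grid.step_px)
    d_row, d_col = grid.direction(line_index)
    rows = grid.pivot[0] + positions * d_row
    cols = grid.pivot[1] + positions * d_col
    return rows, cols, positions


def extract_kymograph(
    film: FrameSequence, grid: ProfileGrid, line_index: int
) -> Kymograph:
    """Sample luminance along one line in every frame (bilinear interpolation).

    Out-of-bounds samples are NaN, never extrapolated. Raises if the line lies
    entirely outside the image.
    """
    rows, cols, positions = line_coordinates(grid, line_index)
    h, w = film.shape
    inside = (rows >= 0) & (rows <= h - 1) & (cols >= 0) & (cols <= w - 1)
    if not np.any(inside):
        raise ValueError(f"line {line_index} lies entirely outside the image")
    n_frames = film.n_frames
    values = np.full((n_frames, positions.size), np.nan)
    coords = np.vstack([rows[inside], cols[inside]])
    stack = np.asarray(film.frames, dtype=float)
    for f in range(n_frames):
        values[f, inside] = ndimage.map_coordinates(
            stack[f], coords, order=1, mode="constant", cval=np.nan
        )
    return Kymograph(
        line_index=line_index,
        values=values,
        positions_px=positions,
        frame_period_s=film.frame_period_s,
    )


def temporal_median_filter(kymo: Kymograph, n: int = 5) -> Kymograph:
    """Centered running median of width ``n`` along time, per position.

    Edge frames use shrunken symmetric windows (width 1 at the first/last
    frame, 3 at the second, ...), so the output has the same shape. This is
    the post-processing step that removes single-frame streak artifacts of
    radial undersampling. NaN samples are ignored within each window.
    """
    if n % 2 == 0 or n < 1:
        raise ValueError("filter width n must be odd and ≥ 1")
    t = kymo.n_frames
    if n > t:
        raise ValueError("filter width exceeds frame count")
    half = n // 2
    out = np.empty_like(kymo.values)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows stay NaN
        for i in range(t):
            k = min(half, i, t - 1 - i)
            out[i] = np.nanmedian(kymo.values[i - k : i + k + 1], axis=0)
    return Kymograph(
        line_index=kymo.line_index,
        values=out,
        positions_px=kymo.positions_px.copy(),
        frame_period_s=kymo.frame_period_s,
    )
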