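"""Sub-pixel tongue-edge tracking and per-note summarization.

Along a profile line crossing the tongue, luminance steps up from the dark
oral cavity (air) to the bright soft tissue of the tongue. The edge of the
anterior-dorsal tongue surface is located per frame as the maximum *positive*
luminance gradient within a search window, refined to sub-pixel precision by
a parabolic fit over the gradient's 3-point neighborhood. Positions are
measured in pixels from the line's pivot (position 0), so larger values mean
a lower tongue and a larger oral cavity ("oral cavitation").

Per-note averaging over the duration of each note — onset transients
included — yields the quantity compared between groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .audio import NoteSegmentation
from .grid import Kymograph

__all__ = [
    "EdgeTrace",
    "detect_edge_profile",
    "track_edge",
    "summarize_per_note",
]


@dataclass
class EdgeTrace:
    """Per-frame sub-pixel edge position along one line (NaN = missing)."""

    line_index: int
    positions_px: np.ndarray
    quality: np.ndarray  # gradient magnitude at the detected edge

    def __post_init__(self) -> None:
        self.positions_px = np.asarray(self.positions_px, dtype=float)
        self.quality = np.asarray(self.quality, dtype=float)
        if self.positions_px.shape != self.quality.shape:
            raise ValueError("positions and quality must have equal length")

    @property
    def n_frames(self) -> int:
        return int(self.positions_px.size)

    @property
    def n_missing(self) -> int:
        return int(np.sum(~np.isfinite(self.positions_px)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(self.n_frames),
                "position_px": self.positions_px,
                "quality": self.quality,
            }
        )


def detect_edge_profile(
    values: np.ndarray,
    positions: np.ndarray,
    search_window: tuple[float, float] | None = None,
    min_gradient: float = 1e-6,
) -> tuple[float, float]:
    """Locate the cavity→tissue transition in one luminance profile.

    Returns ``(position_px, quality)``; ``(nan, 0)`` when no positive
    luminance gradient above ``min_gradient`` exists in the window (flat or
    monotonically darkening profiles have no cavity→tissue transition).

    The estimate is invariant to affine luminance rescaling a·L + b (a > 0),
    since scaling the gradient moves neither its argmax nor the parabolic
    vertex.
    """
    values = np.asarray(values, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if values.shape != positions.shape:
        raise ValueError("values and positions must have equal length")
    if search_window is None:
        lo, hi = positions[0], positions[-1]
    else:
        lo, hi = search_window
    window = (positions >= lo) & (positions <= hi) & np.isfinite(values)
    if window.sum() < 5:
        raise ValueError("search window holds fewer than 5 usable samples")

    grad = np.gradient(values, positions)
    grad_w = np.where(window, grad, -np.inf)
    grad_w = np.where(np.isfinite(grad_w), grad_w, -np.inf)
    i = int(np.argmax(grad_w))
    peak = grad_w[i]
    if not np.isfinite(peak) or peak <= min_gradient:
        return float("nan"), 0.0

    # gradient plateaus (e.g. linearly blurred steps sampled on the grid)
    # have no unique maximum: take the plateau midpoint; otherwise refine
    # the strict maximum with a parabolic fit
    tol = 1e-9 * max(abs(peak), 1e-300)
    lo_i = hi_i = i
    while lo_i > 0 and window[lo_i - 1] and abs(grad[lo_i - 1] - peak) <= tol:
        lo_i -= 1
    while hi_i < positions.size - 1 and window[hi_i + 1] and abs(grad[hi_i + 1] - peak) <= tol:
        hi_i += 1
    if hi_i > lo_i:
        pos = 0.5 * (positions[lo_i] + positions[hi_i])
    else:
        pos = positions[i]
        if 0 < i < positions.size - 1 and np.isfinite(grad[i - 1]) and np.isfinite(grad[i + 1]):
            denom = grad[i - 1] - 2.0 * grad[i] + grad[i + 1]
            if denom < 0:  # genuine local maximum
                delta = 0.5 * (grad[i - 1] - grad[i + 1]) / denom
                delta = float(np.clip(delta, -0.5, 0.5))
                pos = positions[i] + delta * (
                    positions[min(i + 1, positions.size - 1)] - positions[i]
                )
    return float(pos), float(peak)


def track_edge(
    kymo: Kymograph,
    search_window: tuple[float, float] | None = None,
    max_jump_px: float = 10.0,
    min_gradient: float = 1e-6,
    max_missing_frac: float = 0.5,
) -> EdgeTrace:
    """Track the tongue edge through a (filtered) kymograph.

    Each frame runs the profile detector; a detection jumping more than
    ``max_jump_px`` from the previous accepted position is re-tried in a
    window re-centered on that position (± ``max_jump_px``); frames that
    still fail are marked missing. More than ``max_missing_frac`` missing
    frames is a hard error — the trace is unusable.
    """
    if search_window is None:
        # default: stay clear of boundary gradient artifacts
        search_window = (
            float(kymo.positions_px[0] + 5.0),
            float(kymo.positions_px[-1] - 5.0),
        )
    n = kymo.n_frames
    pos = np.full(n, np.nan)
    qual = np.zeros(n)
    prev: float | None = None
    for f in range(n):
        try:
            p, q = detect_edge_profile(
                kymo.values[f], kymo.positions_px, search_window, min_gradient
            )
        except ValueError:
            p, q = float("nan"), 0.0
        if prev is not None and np.isfinite(p) and abs(p - prev) > max_jump_px:
            local = (
                max(search_window[0], prev - max_jump_px),
                min(search_window[1], prev + max_jump_px),
            )
            try:
                p, q = detect_edge_profile(
                    kymo.values[f], kymo.positions_px, local, min_gradient
                )
            except ValueError:
                p, q = float("nan"), 0.0
            if np.isfinite(p) and abs(p - prev) > max_jump_px:
                p, q = float("nan"), 0.0
        pos[f] = p
        qual[f] = q
        if np.isfinite(p):
            prev = p
    missing = np.sum(~np.isfinite(pos)) / n
    if missing > max_missing_frac:
        raise ValueError(
            f"{missing:.0%} of frames have no detectable edge; trace unusable"
        )
    return EdgeTrace(line_index=kymo.line_index, positions_px=pos, quality=qual)


def summarize_per_note(
    trace: EdgeTrace,
    seg: NoteSegmentation,
    subject_id: str = "",
    group: str = "",
    task: str = "slurred",
    last_note_end_frame: int | None = None,
) -> pd.DataFrame:
    """Mean edge position per note ("oral cavitation").

    Note k spans frames [onset_k, onset_{k+1}); the final note ends at
    ``last_note_end_frame`` (default: the end of the trace; callers that know
    the acoustic offset pass the corresponding frame). Missing frames are
    dropped from the
    means; ``n_frames`` counts the frames actually averaged.
    """
    onset_frames = np.asarray(seg.onset_frames, dtype=int)
    if np.any(onset_frames < 0) or np.any(np.diff(onset_frames) <= 0):
        raise ValueError("onset frames must be non-negative and strictly increasing")
    if last_note_end_frame is None:
        last_note_end_frame = trace.n_frames
    if last_note_end_frame <= onset_frames[-1]:
        raise ValueError("last note interval is empty")
    if onset_frames[-1] >= trace.n_frames:
        raise ValueError("segmentation extends beyond the trace")
    ends = np.append(onset_frames[1:], min(last_note_end_frame, trace.n_frames))
    rows = []
    for k, (a, b) in enumerate(zip(onset_frames, ends), start=1):
        chunk = trace.positions_px[a:b]
        usable = chunk[np.isfinite(chunk)]
        if usable.size == 0:
            raise ValueError(f"note {k} (frames {a}..{b}) has no usable frames")
        rows.append(
            {
                "subject_id": subject_id,
                "group": group,
                "task": task,
                "harmonic": k,
                "mean_edge_px": float(usable.mean()),
                "n_frames": int(usable.size),
            }
        )
    return pd.DataFrame(rows)
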