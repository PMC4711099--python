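"""Readers and writers for films, audio, annotations and result tables.

Conventions used by every public table and array in the package:

* pixel coordinates are 0-based ``(row, col)`` with the origin at the
  top-left of the image;
* frame indices are 0-based internally (display-side conversion to 1-based
  counting is a CLI concern);
* film luminance is min–max normalized to [0, 1] over the whole stack, never
  per frame, so temporal luminance comparisons in kymographs stay meaningful.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .audio import NoteSegmentation

logger = logging.getLogger("lingua_rt")

__all__ = [
    "FrameSequence",
    "AcquisitionMeta",
    "LandmarkPair",
    "normalize_stack",
    "read_frame_sequence",
    "write_frame_sequence",
    "read_audio",
    "write_audio",
    "read_onset_annotations",
    "write_onset_annotations",
    "write_summary_table",
    "read_summary_table",
    "write_stats_json",
]


@dataclass
class FrameSequence:
    """An ordered stack of luminance frames with acquisition metadata."""

    frames: np.ndarray  # (n_frames, height, width), float in [0, 1]
    frame_period_s: float
    subject_id: str = ""
    task_label: str = "slurred"  # {"slurred", "tongued"}

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (n_frames, H, W) array with ≥ 1 frame")
        if self.frame_period_s <= 0:
            raise ValueError("frame_period_s must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def shape(self) -> tuple[int, int]:
        return tuple(self.frames.shape[1:])  # type: ignore[return-value]

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_period_s


@dataclass
class AcquisitionMeta:
    """Acquisition parameters of a real-time FLASH film.

    ``te_ms`` and ``flip_angle_deg`` are carried as inert metadata; the two
    consistency invariants (frame time = TR × spokes, base matrix = FOV /
    resolution) are enforced at construction.
    """

    tr_ms: float
    spokes_per_image: int
    fps: float
    duration_s: float
    in_plane_resolution_mm: float
    fov_mm: float
    base_matrix: int
    te_ms: float | None = None
    flip_angle_deg: float | None = None

    def __post_init__(self) -> None:
        frame_ms = self.tr_ms * self.spokes_per_image
        if abs(frame_ms - 1000.0 / self.fps) > 0.01 * (1000.0 / self.fps):
            raise ValueError(
                f"TR × spokes = {frame_ms:.2f} ms inconsistent with "
                f"1000/fps = {1000.0 / self.fps:.2f} ms (>1%)"
            )
        if abs(self.base_matrix - self.fov_mm / self.in_plane_resolution_mm) > 0.5:
            raise ValueError("base_matrix inconsistent with FOV / resolution")

    @property
    def frame_time_ms(self) -> float:
        return self.tr_ms * self.spokes_per_image

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))


@dataclass
class LandmarkPair:
    """The two anatomical anchors of the profile grid.

    ``incisor``: lower edge of the upper incisor. ``disc``: anterior edge of
    the third intervertebral disc. Both are 0-based ``(row, col)`` pixels.
    """

    incisor: tuple[float, float]
    disc: tuple[float, float]

    def __post_init__(self) -> None:
        self.incisor = (float(self.incisor[0]), float(self.incisor[1]))
        self.disc = (float(self.disc[0]), float(self.disc[1]))
        if self.incisor == self.disc:
            raise ValueError("landmarks must be distinct points")

    def validate_inside(self, shape: tuple[int, int]) -> None:
        for name, (r, c) in (("incisor", self.incisor), ("disc", self.disc)):
            if not (0 <= r < shape[0] and 0 <= c < shape[1]):
                raise ValueError(f"landmark {name} {r, c} outside image {shape}")


# ---------------------------------------------------------------------------
# films
# ---------------------------------------------------------------------------

def normalize_stack(frames: np.ndarray) -> np.ndarray:
    """Min–max normalize a stack to [0, 1] over the whole stack.

    Idempotent; a constant stack maps to all zeros.
    """
    frames = np.asarray(frames, dtype=np.float32)
    lo = float(np.nanmin(frames))
    hi = float(np.nanmax(frames))
    if hi <= lo:
        return np.zeros_like(frames)
    return (frames - lo) / (hi - lo)


def write_frame_sequence(path, film: FrameSequence) -> Path:
    """Write a film as multi-page TIFF (``.tif``) or NIfTI (``.nii``/``.nii.gz``)."""
    path = Path(path)
    data = np.asarray(film.frames, dtype=np.float32)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, data, photometric="minisblack")
    elif path.name.lower().endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.Nifti1Image(np.transpose(data, (1, 2, 0)), affine=np.eye(4))
        img.header.set_zooms((1.0, 1.0, float(film.frame_period_s)))
        nib.save(img, str(path))
    else:
        raise ValueError(f"unsupported film format: {path.name}")
    return path


def read_frame_sequence(
    path,
    frame_period_s: float,
    subject_id: str = "",
    task_label: str = "slurred",
) -> FrameSequence:
    """Read a film stack and min–max normalize its luminance to [0, 1]."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        data = tifffile.imread(path)
    elif path.name.lower().endswith((".nii", ".nii.gz")):
        import nibabel as nib

        data = np.transpose(np.asanyarray(nib.load(str(path)).dataobj), (2, 0, 1))
    else:
        raise ValueError(f"unsupported film format: {path.name}")
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D stack, got shape {data.shape}")
    return FrameSequence(
        frames=normalize_stack(data),
        frame_period_s=frame_period_s,
        subject_id=subject_id,
        task_label=task_label,
    )


# ---------------------------------------------------------------------------
# audio
# ---------------------------------------------------------------------------

def write_audio(path, waveform: np.ndarray, sr: int) -> Path:
    """Write a waveform in [-1, 1] as 16-bit PCM WAV."""
    from scipy.io import wavfile

    path = Path(path)
    x = np.clip(np.asarray(waveform, dtype=float), -1.0, 1.0)
    wavfile.write(path, int(sr), (x * 32767.0).astype(np.int16))
    return path


def read_audio(path) -> tuple[np.ndarray, int]:
    """Read a WAV file; returns ``(waveform in [-1, 1], sr)``.

    Stereo files are reduced to their first channel with a logged warning.
    """
    from scipy.io import wavfile

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sr, data = wavfile.read(path)
    if data.size == 0:
        raise ValueError(f"empty audio file: {path}")
    if data.ndim == 2:
        logger.warning("stereo audio %s: using first channel only", path.name)
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max)
        wave = data.astype(float) / scale
    else:
        wave = data.astype(float)
    return np.clip(wave, -1.0, 1.0), int(sr)


# ---------------------------------------------------------------------------
# annotations and tables
# ---------------------------------------------------------------------------

def write_onset_annotations(path, seg: NoteSegmentation) -> Path:
    path = Path(path)
    labels = seg.labels if seg.labels else [""] * seg.n_notes
    pd.DataFrame({"onset_s": seg.onsets_s, "label": labels}).to_csv(path, index=False)
    return path


def read_onset_annotations(path, frame_period_s: float = 1.0 / 30.0) -> NoteSegmentation:
    """Parse a manual-annotation CSV with header ``onset_s,label``."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty annotation file: {path}") from exc
    if "onset_s" not in df.columns:
        raise ValueError(f"{path}: missing required column 'onset_s'")
    if len(df) == 0:
        raise ValueError(f"{path}: no annotation rows")
    onsets = pd.to_numeric(df["onset_s"], errors="raise").to_numpy(dtype=float)
    bad = np.flatnonzero(np.diff(onsets) <= 0)
    if bad.size:
        # +3: 1-based file lines, header line, and the offender is the
        # second element of the out-of-order pair
        raise ValueError(
            f"{path}: onset times not strictly increasing at row {int(bad[0]) + 3}"
        )
    labels = df["label"].astype(str).tolist() if "label" in df.columns else []
    return NoteSegmentation.from_times(
        onsets, frame_period_s, labels=labels, source="manual"
    )


SUMMARY_COLUMNS = ["subject_id", "group", "task", "harmonic", "mean_edge_px", "n_frames"]


def write_summary_table(path, table: pd.DataFrame) -> Path:
    path = Path(path)
    missing = [c for c in SUMMARY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"summary table missing columns: {missing}")
    table[SUMMARY_COLUMNS].to_csv(path, index=False, float_format="%.6f")
    return path


def read_summary_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary table missing columns: {missing}")
    return df


def write_stats_json(path, payload: dict) -> Path:
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path
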