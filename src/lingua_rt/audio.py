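"""Audio-synchronized note segmentation.

The MRI scanner triggers the sound recording, so audio time 0 coincides with
frame 0 of the film. Note boundaries found in the audio are therefore mapped
directly to frame indices (0-based internally; display conversion to the
1-based convention happens at the CLI).

The exercise analyzed throughout the package is an ascending 11-note harmonic
series on an Eb horn, from concert Eb2 to concert C5. Played slurred, the only
acoustic cue for a note change is the pitch step, so segmentation is driven by
a short-time fundamental-frequency (f0) track rather than by energy onsets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NoteSegmentation",
    "HARMONIC_SERIES_NOTES",
    "equal_tempered_frequency",
    "harmonic_series_freqs",
    "estimate_f0_autocorr",
    "track_f0",
    "detect_note_changes",
    "acoustic_offset",
    "map_time_to_frame",
    "note_durations",
    "segment_exercise",
]

#: Note names of the 11-note harmonic series on the valveless Eb horn
#: (concert pitch), Eb2 up to C5.
HARMONIC_SERIES_NOTES = (
    "Eb2", "Bb2", "Eb3", "G3", "Bb3", "Db4", "Eb4", "F4", "G4", "A4", "C5",
)

_PITCH_CLASS_SEMITONES = {
    "C": -9, "D": -7, "E": -5, "F": -4, "G": -2, "A": 0, "B": 2,
}


def equal_tempered_frequency(note: str, a4_hz: float = 440.0) -> float:
    """Equal-tempered frequency of a note name such as ``"Eb2"`` or ``"A4"``.

    Parameters
    ----------
    note
        Pitch class (A–G) with optional accidental (``#``/``b``) followed by
        the octave number, scientific pitch notation.
    a4_hz
        Reference tuning of A4 in Hz.

    Returns
    -------
    float
        ``a4_hz * 2**(s/12)`` with ``s`` the signed semitone distance from
        A4, rounded to two decimals for display parity with printed tables.
    """
    note = note.strip()
    if len(note) < 2:
        raise ValueError(f"malformed note name: {note!r}")
    pc = note[0].upper()
    if pc not in _PITCH_CLASS_SEMITONES:
        raise ValueError(f"unknown pitch class: {note!r}")
    rest = note[1:]
    accidental = 0
    while rest and rest[0] in "#b":
        accidental += 1 if rest[0] == "#" else -1
        rest = rest[1:]
    try:
        octave = int(rest)
    except ValueError as exc:
        raise ValueError(f"malformed octave in note name: {note!r}") from exc
    semitones = _PITCH_CLASS_SEMITONES[pc] + accidental + 12 * (octave - 4)
    return round(a4_hz * 2.0 ** (semitones / 12.0), 2)


def harmonic_series_freqs(a4_hz: float = 440.0) -> list[float]:
    """Frequencies (Hz) of the 11 exercise notes, Eb2 .. C5."""
    return [equal_tempered_frequency(n, a4_hz) for n in HARMONIC_SERIES_NOTES]


@dataclass
class NoteSegmentation:
    """Onset times/frames and labels delimiting the notes of one trial."""

    onsets_s: list[float]
    onset_frames: list[int]
    labels: list[str] = field(default_factory=list)
    freqs_hz: list[float] = field(default_factory=list)
    source: str = "automatic"  # {"manual", "automatic"}
    #: End of the final note in seconds (acoustic offset or recording end).
    end_s: float | None = None

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets_s, dtype=float)
        if onsets.size == 0:
            raise ValueError("segmentation must contain at least one onset")
        if np.any(np.diff(onsets) <= 0):
            bad = int(np.flatnonzero(np.diff(onsets) <= 0)[0]) + 1
            raise ValueError(f"onset times must be strictly increasing (row {bad})")
        if len(self.onset_frames) != len(self.onsets_s):
            raise ValueError("onset_frames and onsets_s must have equal length")
        if self.labels and len(self.labels) != len(self.onsets_s):
            raise ValueError("labels length mismatch")
        if self.freqs_hz and len(self.freqs_hz) != len(self.onsets_s):
            raise ValueError("freqs_hz length mismatch")

    @property
    def n_notes(self) -> int:
        return len(self.onsets_s)

    @classmethod
    def from_times(
        cls,
        onsets_s,
        frame_period_s: float,
        labels=None,
        freqs_hz=None,
        source: str = "automatic",
        end_s: float | None = None,
    ) -> "NoteSegmentation":
        frames = [map_time_to_frame(t, frame_period_s) for t in onsets_s]
        return cls(
            onsets_s=list(map(float, onsets_s)),
            onset_frames=frames,
            labels=list(labels) if labels is not None else [],
            freqs_hz=list(freqs_hz) if freqs_hz is not None else [],
            source=source,
            end_s=end_s,
        )


def map_time_to_frame(t_s: float, frame_period_s: float) -> int:
    """Map an audio time to the 0-based frame during which it falls (floor).

    A relative tolerance of 1e-9 absorbs float representation error at exact
    frame boundaries (e.g. 2.3 s at 30 fps is frame 69, not 68).
    """
    if frame_period_s <= 0:
        raise ValueError("frame period must be positive")
    if t_s < 0:
        raise ValueError("time must be non-negative")
    return int(math.floor(t_s / frame_period_s + 1e-9))


def note_durations(seg: NoteSegmentation, last_note_end_frame: int) -> list[int]:
    """Per-note duration in frames; the final note ends at ``last_note_end_frame``."""
    frames = np.asarray(seg.onset_frames, dtype=int)
    if np.any(np.diff(frames) <= 0):
        raise ValueError("onset frames must be strictly increasing")
    if last_note_end_frame <= frames[-1]:
        raise ValueError("last_note_end_frame must lie after the final onset frame")
    ends = np.append(frames[1:], last_note_end_frame)
    return list((ends - frames).astype(int))


# ---------------------------------------------------------------------------
# short-time f0 tracking
# ---------------------------------------------------------------------------

def estimate_f0_autocorr(
    window: np.ndarray,
    sr: int,
    fmin: float = 60.0,
    fmax: float = 700.0,
) -> float:
    """Fundamental frequency of a short window by normalized autocorrelation.

    Among autocorrelation local maxima in the admissible lag range, the
    smallest lag whose value reaches 80% of the strongest peak wins; this
    avoids octave-down errors on near-periodic tones, where every integer
    multiple of the period correlates equally well. The winning lag is refined
    by parabolic interpolation. Returns NaN when no periodicity is found.
    """
    x = np.asarray(window, dtype=float)
    x = x - x.mean()
    if x.size < 8 or not np.any(x):
        return float("nan")
    # FFT-based full autocorrelation, biased normalization
    nfft = int(2 ** np.ceil(np.log2(2 * x.size)))
    spec = np.fft.rfft(x, nfft)
    ac = np.fft.irfft(spec * np.conj(spec))[: x.size]
    if ac[0] <= 0:
        return float("nan")
    ac = ac / ac[0]
    lag_min = max(2, int(np.floor(sr / fmax)))
    lag_max = min(x.size - 2, int(np.ceil(sr / fmin)))
    if lag_max <= lag_min:
        return float("nan")
    seg = ac[lag_min : lag_max + 1]
    # local maxima
    interior = (seg[1:-1] >= seg[:-2]) & (seg[1:-1] >= seg[2:])
    peaks = np.flatnonzero(interior) + 1
    if peaks.size == 0:
        return float("nan")
    best = seg[peaks].max()
    if best < 0.3:  # no credible periodicity
        return float("nan")
    lag_rel = peaks[np.flatnonzero(seg[peaks] >= 0.8 * best)[0]]
    lag = lag_rel + lag_min
    # parabolic refinement on the autocorrelation peak
    y0, y1, y2 = ac[lag - 1], ac[lag], ac[lag + 1]
    denom = y0 - 2 * y1 + y2
    delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
    return float(sr / (lag + delta))


def track_f0(
    waveform: np.ndarray,
    sr: int,
    window_s: float = 0.046,
    overlap: float = 0.75,
    fmin: float = 60.0,
    fmax: float = 700.0,
    energy_rel_threshold: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Short-time f0 track.

    Returns ``(times, f0)`` where ``times`` are window start times. Windows
    whose RMS is below ``energy_rel_threshold`` times the global maximum RMS
    are marked silent (NaN f0).
    """
    x = np.asarray(waveform, dtype=float)
    win = int(round(window_s * sr))
    hop = max(1, int(round(win * (1.0 - overlap))))
    if x.size < win:
        raise ValueError("waveform shorter than one analysis window")
    starts = np.arange(0, x.size - win + 1, hop)
    rms = np.sqrt(np.array([np.mean(x[s : s + win] ** 2) for s in starts]))
    thresh = energy_rel_threshold * (rms.max() if rms.size else 0.0)
    f0 = np.full(starts.size, np.nan)
    for i, s in enumerate(starts):
        if rms[i] >= thresh and rms[i] > 0:
            f0[i] = estimate_f0_autocorr(x[s : s + win], sr, fmin, fmax)
    return starts / sr, f0


def detect_note_changes(
    waveform: np.ndarray,
    sr: int,
    min_note_s: float = 0.2,
    rel_f0_change: float = 0.03,
    window_s: float = 0.046,
    overlap: float = 0.75,
    min_consecutive: int = 3,
) -> list[float]:
    """Detect note-change moments in a monophonic recording.

    The short-time fundamental is tracked by autocorrelation (46 ms windows,
    75% overlap by default). A change is declared at the first window whose f0
    deviates by more than ``rel_f0_change`` from the running median of the
    current note, sustained for ``min_consecutive`` consecutive windows;
    changes closer than ``min_note_s`` are merged. The returned list starts
    with the initial sound onset (energy threshold crossing), so its length is
    the number of note segments.
    """
    if sr < 8000:
        raise ValueError("sample rate must be at least 8000 Hz")
    x = np.asarray(waveform, dtype=float)
    if x.size < sr:
        raise ValueError("waveform must be at least 1 s long")
    times, f0 = track_f0(x, sr, window_s=window_s, overlap=overlap)
    voiced = np.flatnonzero(np.isfinite(f0))
    if voiced.size == 0:
        raise ValueError("no stable fundamental found (silent input?)")

    half_win = 0.5 * window_s
    onsets = [float(times[voiced[0]] + half_win)]
    current: list[float] = []
    deviant_run = 0
    deviant_start_t = 0.0
    for i in voiced:
        if not current:
            current = [f0[i]]
            continue
        med = float(np.median(current))
        if abs(f0[i] - med) / med > rel_f0_change:
            if deviant_run == 0:
                deviant_start_t = float(times[i] + half_win)
            deviant_run += 1
            if deviant_run >= min_consecutive:
                onsets.append(deviant_start_t)
                current = [f0[i]]
                deviant_run = 0
        else:
            deviant_run = 0
            current.append(f0[i])
    # merge changes closer than min_note_s
    merged = [onsets[0]]
    for t in onsets[1:]:
        if t - merged[-1] >= min_note_s:
            merged.append(t)
    return merged


def acoustic_offset(
    waveform: np.ndarray,
    sr: int,
    window_s: float = 0.046,
    overlap: float = 0.75,
    energy_rel_threshold: float = 0.05,
) -> float:
    """Time at which the sound ends (last window above the energy gate)."""
    x = np.asarray(waveform, dtype=float)
    win = int(round(window_s * sr))
    hop = max(1, int(round(win * (1.0 - overlap))))
    starts = np.arange(0, x.size - win + 1, hop)
    rms = np.array([np.sqrt(np.mean(x[s : s + win] ** 2)) for s in starts])
    gate = energy_rel_threshold * rms.max()
    above = np.flatnonzero(rms >= gate)
    if above.size == 0:
        raise ValueError("silent input")
    return float((starts[above[-1]] + win) / sr)


def segment_exercise(
    waveform: np.ndarray,
    sr: int,
    frame_period_s: float,
    expected_notes: int | None = 11,
    last_note_end: str = "acoustic_offset",
    **detector_kwargs,
) -> NoteSegmentation:
    """Segment a recorded harmonic-series trial into notes, mapped to frames.

    ``last_note_end`` chooses how the final note ends: ``"acoustic_offset"``
    (default; the energy gate closing) or ``"recording_end"``.
    """
    onsets = detect_note_changes(waveform, sr, **detector_kwargs)
    if expected_notes is not None and len(onsets) != expected_notes:
        warnings.warn(
            f"detected {len(onsets)} note segments, expected {expected_notes}",
            stacklevel=2,
        )
    if last_note_end == "acoustic_offset":
        end_s = acoustic_offset(waveform, sr)
    elif last_note_end == "recording_end":
        end_s = len(waveform) / sr
    else:
        raise ValueError("last_note_end must be 'acoustic_offset' or 'recording_end'")
    labels = list(HARMONIC_SERIES_NOTES) if len(onsets) == 11 else []
    freqs = harmonic_series_freqs() if len(onsets) == 11 else []
    return NoteSegmentation.from_times(
        onsets, frame_period_s, labels=labels, freqs_hz=freqs,
        source="automatic", end_s=end_s,
    )
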