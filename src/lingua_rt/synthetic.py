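"""Synthetic phantom films, cohorts and exercise audio with known ground truth.

The analysis pipeline only ever reads luminance along straight lines, so the
phantom is deliberately non-anatomical: a dark oral cavity (a disk of
time-varying radius around the grid pivot) inside bright soft tissue. Along
every grid line the luminance profile is then an exact two-level step at the
ground-truth edge position — the idealized version of the cavity→tongue
transition the tracker estimates. On top of that clean geometry the generator
adds the phenomena the real films show:

* a piecewise-constant edge trajectory, one level per note of the 11-note
  harmonic series, with a brief "undulation" transient after each note onset
  (the tongue flick visible at note changes);
* Gaussian per-pixel frame noise;
* sporadic single-frame full-frame streak artifacts (luminance offsets),
  exactly the disturbance the 5-frame temporal median filter is meant to
  remove.

Defaults reproduce the acquisition geometry of a 30 s real-time MRI film:
900 frames of 128×128 pixels at 33.3 ms per frame, with the exercise's 11
notes of 0.9 s starting at t = 0.5 s. Group-level cohort defaults encode the
divergent elite/dystonic per-harmonic cavitation profiles (steep vs shallow
decline over harmonics 6–9, grand means 30.3 and 20.9 px).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .audio import harmonic_series_freqs
from .grid import build_profile_grid
from .io import FrameSequence, LandmarkPair

__all__ = [
    "PhantomConfig",
    "CohortConfig",
    "GroundTruth",
    "default_note_onsets",
    "elite_profile",
    "dystonic_profile",
    "fig2_like_config",
    "generate_phantom",
    "sample_cohort_profiles",
    "generate_cohort",
    "render_exercise_audio",
]

#: Default note schedule: 11 notes × 0.9 s starting at t = 0.5 s.
DEFAULT_NOTE_DURATION_S = 0.9
DEFAULT_FIRST_ONSET_S = 0.5


def default_note_onsets(
    first_onset_s: float = DEFAULT_FIRST_ONSET_S,
    note_duration_s: float = DEFAULT_NOTE_DURATION_S,
) -> list[float]:
    return [first_onset_s + k * note_duration_s for k in range(11)]


def elite_profile() -> list[float]:
    """Default elite per-harmonic cavitation means (px), grand mean 30.3.

    Large cavity on the low notes, steep monotone decline over harmonics
    6–9 (tongue moves up and forward), little change after — roughly halving
    cavitation between the low and high register.
    """
    return [38.1, 38.1, 37.6, 37.1, 36.6, 34.3, 29.3, 24.3, 19.8, 19.3, 18.8]


def dystonic_profile() -> list[float]:
    """Default dystonic per-harmonic cavitation means (px), grand mean 20.9.

    Smaller cavity on the low notes and a shallow decline (~one third) toward
    the high register.
    """
    return [24.0, 24.0, 23.7, 23.4, 23.1, 22.0, 20.4, 18.8, 17.2, 16.6, 16.7]


@dataclass
class PhantomConfig:
    """Everything needed to render one synthetic film.

    ``per_note_edge_px`` holds the 11 ground-truth edge positions (pixels
    from the pivot along the analysis line); ``rest_edge_px`` is the edge
    position before the first note (defaults to the first note's value).
    """

    image_height_px: int = 128
    image_width_px: int = 128
    n_frames: int = 900
    frame_period_s: float = 1.0 / 30.0
    tissue_level: float = 0.85
    cavity_level: float = 0.15
    noise_sd: float = 0.03
    streak_rate: float = 0.02
    streak_amplitude: float = 0.3
    per_note_edge_px: list[float] = field(default_factory=elite_profile)
    rest_edge_px: float | None = None
    transient_px: float = 2.0
    transient_frames: int = 5
    note_onsets_s: list[float] = field(default_factory=default_note_onsets)
    note_duration_s: float = DEFAULT_NOTE_DURATION_S
    landmark_incisor: tuple[float, float] = (44.0, 48.0)
    landmark_disc: tuple[float, float] = (50.0, 108.0)
    line_length_px: float = 80.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.cavity_level < self.tissue_level:
            raise ValueError("cavity_level must be below tissue_level")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.streak_rate <= 1:
            raise ValueError("streak_rate must be a probability")
        if len(self.per_note_edge_px) != len(self.note_onsets_s):
            raise ValueError("one edge position required per note")
        edges = list(self.per_note_edge_px) + (
            [self.rest_edge_px] if self.rest_edge_px is not None else []
        )
        if any(not 1.0 <= e <= self.line_length_px - 1.0 for e in edges):
            raise ValueError("edge positions must lie within the analysis line")
        if max(edges) > self.max_edge_radius_px:
            raise ValueError("cavity would leave the image for some edge position")
        last_end = self.note_onsets_s[-1] + self.note_duration_s
        if self.n_frames * self.frame_period_s < last_end:
            raise ValueError("n_frames does not cover the full note schedule")

    @property
    def landmarks(self) -> LandmarkPair:
        return LandmarkPair(incisor=self.landmark_incisor, disc=self.landmark_disc)

    @property
    def max_edge_radius_px(self) -> float:
        """Largest cavity radius whose edge stays measurable on all 7 lines.

        For each grid line, the distance from the pivot to the image boundary
        along that line bounds the usable edge position; the cavity top may
        clip above the baseline, which no line samples.
        """
        grid = build_profile_grid(self.landmarks, length_px=self.line_length_px)
        pr, pc = grid.pivot
        h, w = self.image_height_px, self.image_width_px
        radius = self.line_length_px - 1.0
        for k in range(1, grid.n_lines + 1):
            dr, dc = grid.direction(k)
            t = np.inf
            for d, p, hi in ((dr, pr, h - 1), (dc, pc, w - 1)):
                if d > 1e-12:
                    t = min(t, (hi - p) / d)
                elif d < -1e-12:
                    t = min(t, -p / d)
            radius = min(radius, t - 1.0)
        return float(radius)

    @property
    def onset_frames(self) -> list[int]:
        return [int(math.floor(t / self.frame_period_s)) for t in self.note_onsets_s]

    @property
    def last_note_end_frame(self) -> int:
        return int(
            math.floor((self.note_onsets_s[-1] + self.note_duration_s) / self.frame_period_s)
        )


@dataclass
class GroundTruth:
    """Realized truth for one phantom film (testing plumbing)."""

    edge_px_per_frame: np.ndarray
    note_onsets_s: list[float]
    per_note_mean_px: list[float]
    streak_frames: list[int] = field(default_factory=list)
    seed: int = 0


@dataclass
class CohortConfig:
    """Group-level sampling model for synthetic subjects.

    Subject i's true per-note edge profile is
    ``group_mean + offset_i + noise_ik`` with ``offset_i ~ N(0,
    between_subject_sd²)`` shared across notes and ``noise_ik ~ N(0,
    within_subject_sd²)`` independent per note.
    """

    group_label: str = "elite"
    n_subjects: int = 6
    group_mean_edge_px: list[float] = field(default_factory=elite_profile)
    between_subject_sd: float = 3.0
    within_subject_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.between_subject_sd < 0 or self.within_subject_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if len(self.group_mean_edge_px) != 11:
            raise ValueError("exactly 11 per-harmonic group means required")

    @classmethod
    def elite(cls, **kw) -> "CohortConfig":
        kw.setdefault("group_label", "elite")
        kw.setdefault("n_subjects", 6)
        kw.setdefault("group_mean_edge_px", elite_profile())
        return cls(**kw)

    @classmethod
    def dystonic(cls, **kw) -> "CohortConfig":
        kw.setdefault("group_label", "dystonic")
        kw.setdefault("n_subjects", 5)
        kw.setdefault("group_mean_edge_px", dystonic_profile())
        return cls(**kw)


def fig2_like_config(**overrides) -> PhantomConfig:
    """Packaged fixture echoing the worked single-subject film description.

    Onset frames for harmonics 1, 4, 5, 6, 7 and 9 sit at the printed 1-based
    film indices 31, 97, 124, 154, 184 and 268 (0-based 30, 96, 123, 153, 183
    and 267); the remaining onsets are interpolated between them. The resting
    edge sits at 25 px so frame 1 shows the cavity/tongue edge near the
    25-pixel mark, dropping slightly (cavitation grows) at the first note and
    then rising faster over harmonics 6–9.
    """
    period = 1.0 / 30.0
    # 0-based anchor frames for harmonics 1, 4, 5, 6, 7, 9
    anchors = {0: 30, 3: 96, 4: 123, 5: 153, 6: 183, 8: 267}
    frames = np.interp(np.arange(11), list(anchors), list(anchors.values()))
    # extrapolate harmonics 10 and 11 with the harmonic 7→9 spacing
    spacing = (anchors[8] - anchors[6]) / 2.0
    frames[9] = anchors[8] + spacing
    frames[10] = anchors[8] + 2 * spacing
    onsets = [(f + 0.5) * period for f in frames]  # mid-frame times
    edges = [27.0, 26.5, 26.0, 25.5, 25.0, 24.0, 21.0, 18.0, 14.0, 13.5, 13.0]
    cfg = dict(
        per_note_edge_px=edges,
        rest_edge_px=25.0,
        note_onsets_s=onsets,
        noise_sd=0.0,
        streak_rate=0.0,
        transient_px=1.5,
        transient_frames=5,
    )
    cfg.update(overrides)
    return PhantomConfig(**cfg)


def _edge_trajectory(config: PhantomConfig) -> np.ndarray:
    """Per-frame ground-truth edge positions (transients included)."""
    edge = np.empty(config.n_frames)
    rest = (
        config.rest_edge_px
        if config.rest_edge_px is not None
        else config.per_note_edge_px[0]
    )
    onset_frames = config.onset_frames
    bounds = onset_frames + [config.n_frames]
    edge[: onset_frames[0]] = rest
    for k in range(11):
        a, b = bounds[k], bounds[k + 1]
        edge[a:b] = config.per_note_edge_px[k]
        # half-sine undulation (brief tongue flick toward the palate)
        m = min(config.transient_frames, b - a)
        j = np.arange(m)
        edge[a : a + m] -= config.transient_px * np.sin(
            np.pi * (j + 1) / (config.transient_frames + 1)
        )
    return edge


def generate_phantom(config: PhantomConfig) -> tuple[FrameSequence, GroundTruth]:
    """Render one synthetic film; bit-reproducible for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    edge = _edge_trajectory(config)

    rr, cc = np.mgrid[0 : config.image_height_px, 0 : config.image_width_px]
    pr, pc = config.landmark_incisor
    dist = np.hypot(rr - pr, cc - pc).astype(np.float32)

    cavity = (dist[None, :, :] < edge[:, None, None]).astype(np.float32)
    frames = config.tissue_level + (config.cavity_level - config.tissue_level) * cavity

    streak_frames: list[int] = []
    if config.streak_rate > 0:
        hit = rng.random(config.n_frames) < config.streak_rate
        streak_frames = [int(i) for i in np.flatnonzero(hit)]
        frames[hit] += config.streak_amplitude
    if config.noise_sd > 0:
        frames += rng.normal(0.0, config.noise_sd, frames.shape).astype(np.float32)
    if config.noise_sd > 0 or streak_frames:
        np.clip(frames, 0.0, 1.0, out=frames)

    film = FrameSequence(
        frames=frames,
        frame_period_s=config.frame_period_s,
        task_label="slurred",
    )

    onset_frames = config.onset_frames
    bounds = onset_frames + [config.last_note_end_frame]
    per_note_mean = [
        float(edge[bounds[k] : bounds[k + 1]].mean()) for k in range(11)
    ]
    truth = GroundTruth(
        edge_px_per_frame=edge,
        note_onsets_s=list(config.note_onsets_s),
        per_note_mean_px=per_note_mean,
        streak_frames=streak_frames,
        seed=config.seed,
    )
    return film, truth


def sample_cohort_profiles(cohort: CohortConfig, rng=None) -> np.ndarray:
    """Sample per-subject true per-note edge profiles, shape (n_subjects, 11).

    This is the distributional layer of the cohort model; it is also used
    directly (without film rendering) for statistical calibration studies.
    """
    if rng is None:
        rng = np.random.default_rng(cohort.seed)
    mean = np.asarray(cohort.group_mean_edge_px, dtype=float)
    offsets = rng.normal(0.0, cohort.between_subject_sd, size=(cohort.n_subjects, 1))
    noise = rng.normal(0.0, cohort.within_subject_sd, size=(cohort.n_subjects, 11))
    return mean[None, :] + offsets + noise


def generate_cohort(
    cohort: CohortConfig, phantom_template: PhantomConfig | None = None
) -> list[tuple[FrameSequence, GroundTruth]]:
    """Generate one film + ground truth per subject of a group.

    Per-subject profiles come from :func:`sample_cohort_profiles`; each film
    is rendered from the template config with its own derived seed and the
    subject's profile, and carries ``subject_id`` like ``"elite01"``.
    """
    if phantom_template is None:
        phantom_template = PhantomConfig()
    rng = np.random.default_rng(cohort.seed)
    profiles = sample_cohort_profiles(cohort, rng)
    lo = 1.0
    hi = phantom_template.max_edge_radius_px
    out = []
    for i in range(cohort.n_subjects):
        profile = np.clip(profiles[i], lo, hi)
        cfg = replace(
            phantom_template,
            per_note_edge_px=list(profile),
            rest_edge_px=float(profile[0]),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        film, truth = generate_phantom(cfg)
        film.subject_id = f"{cohort.group_label}{i + 1:02d}"
        out.append((film, truth))
    return out


def render_exercise_audio(
    onsets_s,
    freqs_hz=None,
    sr: int = 22050,
    tongued: bool = False,
    last_note_end_s: float | None = None,
    total_duration_s: float | None = None,
    partial_amps=(1.0, 0.5, 0.25),
) -> np.ndarray:
    """Render the 11-note exercise as phase-continuous harmonic-rich tones.

    Each note is a sum of the fundamental plus low-order partials
    (``partial_amps``), with 10 ms attack/release ramps at the start and end
    of the sounding span. The ``tongued`` variant inserts a 20 ms amplitude
    dip at every note onset (the articulation). Output is normalized to
    [-1, 1]; leading silence before the first onset and trailing silence up
    to ``total_duration_s`` are preserved.
    """
    onsets = [float(t) for t in onsets_s]
    if freqs_hz is None:
        freqs_hz = harmonic_series_freqs()
    freqs = [float(f) for f in freqs_hz]
    if len(onsets) != len(freqs):
        raise ValueError("onsets and frequencies must have the same length")
    if any(b <= a for a, b in zip(onsets, onsets[1:])):
        raise ValueError("onsets must be strictly increasing")
    if last_note_end_s is None:
        last_note_end_s = onsets[-1] + DEFAULT_NOTE_DURATION_S
    if last_note_end_s <= onsets[-1]:
        raise ValueError("last note must have positive duration")
    if total_duration_s is None:
        total_duration_s = last_note_end_s + 0.2
    n = int(round(total_duration_s * sr))
    t_step = 1.0 / sr

    # instantaneous frequency per sample; phase-continuous integration
    freq = np.zeros(n)
    bounds = [int(round(t * sr)) for t in onsets] + [
        min(n, int(round(last_note_end_s * sr)))
    ]
    for k, f in enumerate(freqs):
        freq[bounds[k] : bounds[k + 1]] = f
    phase = 2.0 * np.pi * np.cumsum(freq) * t_step

    wave = np.zeros(n)
    sounding = freq > 0
    for h, amp in enumerate(partial_amps, start=1):
        wave[sounding] += amp * np.sin(h * phase[sounding])

    env = sounding.astype(float)
    ramp = max(1, int(0.010 * sr))
    a, b = bounds[0], bounds[-1]
    env[a : a + ramp] *= np.linspace(0.0, 1.0, ramp)
    env[max(a, b - ramp) : b] *= np.linspace(1.0, 0.0, min(ramp, b - a))
    if tongued:
        dip = max(1, int(0.020 * sr))
        for s in bounds[:-1]:
            stop = min(s + dip, n)
            env[s:stop] *= np.linspace(0.0, 1.0, stop - s) ** 2
    wave *= env
    peak = np.abs(wave).max()
    if peak > 0:
        wave /= peak
    return wave
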