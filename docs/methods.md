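# Methods

This note documents the models, conventions and numerical choices behind
`lingua-rt`, and what its synthetic validation does and does not establish.

## Coordinate and indexing conventions

Pixels are 0-based `(row, col)` with the origin at the image's top-left;
frame indices are 0-based internally (the CLI's `--one-based-frames` flag
covers viewers that count films from 1). Film luminance is min–max
normalized to [0, 1] over the whole stack, never per frame: per-frame
scaling would distort temporal luminance comparisons inside kymographs.
Audio time 0 coincides with frame 0 (the recording is trigger-synchronized
to acquisition); no additional latency is modelled.

## Profile grid

The incisor→disc landmark pair defines the baseline direction
`atan2(Δrow, Δcol)`. Line k of an n-line grid (default n = 7) is oriented at
(k−1)·180/(n−1) degrees from the baseline, rotated with a fixed chirality so
the fan opens into the half-plane containing the tongue (toward increasing
rows for a left-to-right baseline). The fixed chirality — rather than an
"always toward +row" rule — makes grid construction equivariant under image
rotation. Where the lines are anchored is anatomically under-determined; the
default pivots all lines on the incisor landmark (so line 2 traverses the
anterior tongue), with `pivot="midpoint"` available. Lines are 80 px long,
sampled every 1 px by bilinear interpolation; samples outside the image are
missing (NaN), never extrapolated.

## Temporal median filter

Each kymograph position's time series is replaced by its centered running
median of width n = 5 (odd n enforced). Edge frames use shrunken symmetric
windows, so the first and last frames pass through unchanged; this keeps the
output length equal to the input and is idempotent on piecewise-constant
signals with runs ≥ n. The filter is applied to kymographs rather than whole
frames — equivalent along the analyzed lines and far cheaper. It exists to
remove single-frame streak artifacts (modelled in the phantom as full-frame
luminance offsets).

## Edge detection and tracking

The tongue surface is the dark-to-bright (cavity→tissue) transition, located
as the maximum positive luminance gradient (`np.gradient`) within a search
window (default 5 px in from both line ends, avoiding boundary gradient
artifacts). Sub-pixel refinement: a parabolic fit over the gradient's
3-point neighborhood when the maximum is strict; when the maximal gradient
forms a plateau (as on a linearly blurred step sampled on the grid), the
plateau midpoint is used. A profile with no strictly positive gradient above
`min_gradient = 1e-6` has no transition and yields a missing value rather
than an arbitrary position. The estimate is invariant to affine luminance
rescaling `a·L + b, a > 0`.

Tracking applies the detector frame by frame; a detection jumping more than
`max_jump_px = 10` from the last accepted position is re-tried in a window
re-centered on that position, and frames that still fail are missing. A
trace with more than 50 % missing frames is a hard error.

Per-note summaries average the non-missing positions over
`[onset_frame, next_onset_frame)`; the 11th note ends at the acoustic offset
(energy gate closing) by default, configurably at the recording end. Onset
transients are *included* in the means — notes are averaged over their full
duration — with `skip_onset_frames` available for sensitivity analysis.
Larger mean position = tongue farther from the pivot = larger oral cavity;
this sign convention is stated here once and carried by every table.

## Audio segmentation

Short-time f0 is estimated by normalized autocorrelation (46 ms windows,
75 % overlap, 60–700 Hz search band). Among autocorrelation peaks, the
smallest lag reaching 80 % of the strongest peak wins, suppressing
octave-down errors on near-periodic tones; the winning lag is refined
parabolically. Windows below 5 % of the maximum RMS are silent. A note
change is declared when f0 deviates > 3 % from the running median of the
current note for ≥ 3 consecutive windows; changes closer than 0.2 s merge.
Change times are attributed to window centers (the time an f0 estimate
refers to), which keeps automatic onsets within one frame (33 ms) of the
true change on rendered exercises. The first onset is the energy-gate
crossing, not t = 0, since films begin with silent rest frames. Manual
annotations, when supplied, override automatic detection. Frame mapping is
`floor(t / frame_period + 1e-9)` — the frame during which the change occurs,
with a relative tolerance absorbing float error at exact frame boundaries.

## Mixed repeated-measures ANOVA

The classical split-plot partition (between: group, g = 2; within: harmonic,
k = 11; one observation per subject × harmonic) is computed from cell means;
with unequal group sizes the weighted (Type II) partition is used, matching
`pingouin.mixed_anova`, which serves as an independent cross-check oracle in
the tests (never as the implementation). Sphericity diagnostics use the
pooled within-group covariance (df-weighted average of per-group
covariances, df = N − g):

* Greenhouse–Geisser ε̂ = trace(S̃)² / ((k−1)·ΣS̃²), S̃ the double-centered
  covariance, clipped to [1/(k−1), 1];
* Mauchly's W = det(T) / (trace(T)/(k−1))^(k−1) on an orthonormal-contrast
  transform T, with the first-order Box chi-square approximation
  (χ² = −ρ·d·ln W, df = k(k−1)/2 − 1). With d = N − g < k − 1 the contrast
  covariance is singular, W = 0 and sphericity is reported as violated —
  the correct degenerate behavior for 11 subjects × 11 levels.

GG correction multiplies both within-test dfs by ε̂ and is *applied*
(reported as the headline p) when Mauchly rejects at α; corrected and
uncorrected p are always both computed. Huynh–Feldt is deliberately not
implemented. Observed power follows the convention of mainstream commercial
statistics software: λ = F·df1, power = P(F′(df1, df2, λ) > F_crit), with
GG-adjusted dfs whenever the corrected test is the one reported; other λ
conventions exist, so this one is stated prominently. Estimated marginal
means are unweighted means over harmonics of per-harmonic group means
(equal to group grand means for complete data). Degenerate inputs: missing
cells are an error (no silent listwise deletion); a zero error variance
yields an infinite F with a warning, not a crash; tiny negative SS residues
from floating-point cancellation are clamped to zero.

## Synthetic phantom

The phantom is deliberately non-anatomical: the analysis only ever reads
luminance along lines, so a dark disk (cavity, level 0.15) of time-varying
radius around the grid pivot inside bright tissue (level 0.85) exercises
every code path while keeping ground truth exact. The edge trajectory is
piecewise-constant per note with a half-sine "undulation" transient
(default 2 px over 5 frames) after each onset, Gaussian per-pixel noise
(SD 0.03) and, with probability 0.02 per frame, a single-frame full-frame
luminance offset (+0.3) standing in for streak artifacts. Defaults mirror
the acquisition geometry: 900 frames of 128×128 px at 33.3 ms, 11 notes of
0.9 s starting at t = 0.5 s (the source material does not state the
exercise tempo; 0.9 s per note is declared, not inferred). A packaged
`fig2_like_config()` fixture pins onset frames 30, 96, 123, 153, 183, 267
(0-based) for harmonics 1, 4, 5, 6, 7, 9 and a 25-px resting edge, echoing
a worked single-subject film description.

Cohorts sample subject i's true per-note profile as group mean + subject
offset (between-subject SD 3 px) + per-note noise (within-subject SD
1.5 px). The default group profiles encode the divergent motor strategies:
elite declining steeply from ≈38 px to ≈19 px over harmonics 6–9 (grand
mean exactly 30.3 px), dystonic declining by about a third, 24 → 16.6 px
(grand mean exactly 20.9 px). Exercise audio is rendered as
phase-continuous tones (fundamental + 2 partials at −6/−12 dB) at the 11
equal-tempered frequencies, with a 20 ms amplitude dip per onset in the
tongued variant.

**Quantization limit.** A hard two-level step sampled at pixel centers only
localizes the edge to the midpoint between the last cavity and first tissue
sample; any detector therefore carries up to ±0.5 px error per frame on
noiseless phantoms. Per-note and cohort-level means do better (fractional
edge positions dither the bias toward zero — recovered noise-free EMMs land
within ~0.05 px of the configured 30.3/20.9), but noiseless "exactness"
claims are bounded by this ±0.5 px, and the tests assert accordingly.

**What the phantom does not emulate:** anatomical tissue texture and
intensity inhomogeneity, through-plane motion, reconstruction-specific
artifact structure (streaks are luminance offsets, not oriented streaks),
breathing or swallowing events, and pitch instability or missed notes in
the audio. Passing tests therefore demonstrate correctness of the
measurement chain and calibration of the statistics under the stated model,
not robustness to every failure mode of real scanner data.

## Validation problem sizes

The test suite validates tracking on full-size 900-frame films; cohort
recovery runs the complete imaging pipeline for 6 + 5 subjects at full film
size, twice (noise-free and noisy). Statistical calibration uses 500
replicates each for the null (both groups share one profile; subject
intercept SD 2 px plus AR(1) ρ = 0.7, SD 1.5 px note-to-note errors — a
serially correlated, hence non-spherical, structure) and for power (the
default divergent cohort configs), at the value level without film
rendering. Observed type-I error of the GG-corrected interaction test sits
at the nominal 0.05 while the uncorrected test inflates to ≈0.10 on the
same draws; power on the divergent profiles is ≈1.

## Known limitations

* The split-plot ANOVA assumes multivariate normality of within-subject
  vectors; no robust/rank alternative is provided.
* Landmarks are manual inputs; no automatic landmark detection.
* The detector tracks a single monotone cavity→tissue transition per line;
  multiple tissue interfaces along a line (possible on posterior lines)
  would need the search-window machinery rather than working out of the box.
* Pitch tracking assumes a monophonic, reasonably stable tone; heavily
  unstable dystonic audio may require the manual-annotation path, as in
  practice.
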