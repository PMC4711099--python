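# lingua-rt

Quantifying tongue motion in real-time MRI films of the oral cavity during
brass playing.

When a horn player ascends a harmonic series on a valveless instrument, every
note change is produced by lip tension, air speed and — crucially — the shape
of the oral cavity. Real-time MRI (radial FLASH at ~30 frames/s) makes the
tongue visible throughout a performance, and the question this package
addresses is whether elite players and players with embouchure dystonia shape
the oral cavity differently across an ascending 11-note harmonic series
(concert Eb2 → C5, slurred or tongued).

`lingua-rt` implements the full measurement and inference chain:

1. **Profile grid** — two anatomical landmarks (lower edge of the upper
   incisor, anterior edge of the third intervertebral disc) define a
   baseline; seven 80-px line profiles fan from the incisor at 0, 30, 60, 90,
   120, 150 and 180° into the oral cavity. Line 2 crosses the anterior third
   of the tongue and is the default analysis line.
2. **Kymographs** — luminance is sampled bilinearly along each line in every
   frame (position × time matrix), then temporally median-filtered over
   n = 5 frames to remove single-frame streak artifacts of radial
   undersampling.
3. **Edge tracking** — the cavity→tissue transition (the anterior-dorsal
   tongue surface) is located per frame as the maximum positive luminance
   gradient, refined to sub-pixel precision. Its distance from the pivot is
   the *oral cavitation* measure: larger = lower tongue = bigger cavity.
4. **Note segmentation** — the scanner-triggered audio track is segmented
   into the 11 notes by short-time autocorrelation pitch tracking (46 ms
   windows, 75 % overlap; a note change = a sustained f0 shift > 3 %), and
   onsets are mapped to frame indices. Manual onset annotations, when
   provided, take precedence.
5. **Statistics** — per-note mean edge positions enter a mixed
   repeated-measures ANOVA (between: group; within: harmonic, 11 levels)
   with Mauchly's sphericity test, Greenhouse–Geisser-corrected degrees of
   freedom, estimated marginal means and observed (noncentral-F, λ = F·df1)
   power.

Because raw scanner data of this kind are not public, the package ships a
first-class synthetic phantom generator (`lingua_rt.synthetic`) producing
MRI-like films, synchronized exercise audio and exact ground truth, so every
stage — and the pipeline end to end — is validated against known answers.

## Worked example

Simulate a study of 6 elite and 5 dystonic synthetic subjects (30 s films,
900 frames of 128×128 px at 33.3 ms/frame) and analyze it:

```bash
lingua-rt simulate --out demo --seed 1
lingua-rt analyze --config demo/study.yaml
```

which prints (output of the run above):

```
per-note table: demo/results/per_note_summary.csv
Mauchly's test indicated a violation of sphericity (W = 0.000, p = 0); Greenhouse-Geisser epsilon = 0.519.
Group main effect: F(1, 9) = 27.802, p = 0.000512, observed power = 0.996.
Harmonic main effect: F(10, 90) = 144.166, p = 1.82e-27 after Greenhouse-Geisser adjustment of the degrees of freedom, observed power = 1.000.
Group x harmonic interaction: F(10, 90) = 35.080, p = 6.18e-15 after Greenhouse-Geisser adjustment of the degrees of freedom, observed power = 1.000.
Estimated marginal means: dystonic: 19.6 px, elite: 29.9 px.
```

Reading the output: sphericity of the 11-level within-subject covariance is
strongly violated (the note-to-note positions are serially correlated), so
the within-subject tests use Greenhouse–Geisser-adjusted degrees of freedom.
The significant group × harmonic interaction says the two groups move the
tongue *differently* across the series — the simulated elite profile narrows
the cavity steeply over harmonics 6–9 while the dystonic profile declines
shallowly, which is exactly what the generator encoded (group profiles
averaging 30.3 px and 20.9 px; the recovered estimated marginal means are
29.9 and 19.6 px, within sampling error of 6 and 5 subjects). Artifacts land
in `demo/results/`: the per-note CSV, `rm_anova.json`, a text report, per-
subject edge traces and a per-group mean ± SE profile figure.

The same machinery is available as a library:

```python
import lingua_rt as lr

cfg = lr.PhantomConfig()                 # 900 frames @ 33.3 ms, 128×128
film, truth = lr.generate_phantom(cfg)
grid = lr.build_profile_grid(cfg.landmarks)
kymo = lr.extract_kymograph(film, grid, line_index=2)
trace = lr.track_edge(lr.temporal_median_filter(kymo, n=5))
```

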