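# dualtrace

Two-channel TIRF puncta **event-timing analysis**: when do two fluorescent
signals at the same diffraction-limited spot peak relative to each other?

The package was built for the question of whether dynamin's GTP-hydrolysis
activity (reported by a conformation-specific fluorescent nanobody, "dynab")
is temporally coupled to dynamin assembly at clathrin-coated pits. Given a
pair of time-lapse stacks (channel 1: dynamin, channel 2: the activity
reporter; typically 2 s/frame), it

1. detects diffraction-limited punctae in every frame (Laplacian-of-Gaussian
   band-pass, sub-pixel 2-D Gaussian refinement, background-subtracted
   circular-aperture photometry),
2. links spots over time into candidate events, tolerating up to two
   consecutive missing frames,
3. labels each candidate with five validation criteria — spatial coherence,
   minimum duration (10 frames), relative peak intensity (≥ 40% of the
   sequence maximum), inter-channel profile correlation (r > 0.45) and
   mixture-fit quality (R² > 0.6) — keeping every candidate with its flags,
4. processes each event's paired intensity traces: shift to zero minimum,
   cubic-spline upsampling to 0.25-frame resolution, and a four-Gaussian
   mixture fit per channel from which the principal (signal) component gives
   the peak value *p*, peak time *t* and duration *d* = 4σ,
5. computes the peak delay Δt = t(ch2) − t(ch1), its normalization
   Δt/d(ch1) in percent, 5%-cluster histograms, the
   before / simultaneous / after classification (cutoff ±10%, inclusive),
   double-peak rates, duration ratios, peak-intensity correlations and
   peak-aligned average curves.

Because such data sets are rarely shareable, the package ships a first-class
synthetic-movie generator (`dualtrace.simulate`) that plants events with
known positions, amplitudes, peak times, widths and channel-2 offsets under
a realistic camera noise model (Poisson + Gaussian read noise), so every
stage of the analysis is testable against ground truth.

## Model

Each event contributes a separable space-time Gaussian to its channel:

    I(x, y, t) = Σ_k a_k · exp(−(t − t_k)² / 2σ_k²) · exp(−r² / 2σ_psf²)

The per-event temporal trace of each channel is fitted with a mixture of
four Gaussians; the principal component yields (p, t, d = 4σ), and the
analysis statistic is the normalized delay

    Δt_norm = 100 · (t_dynab − t_dynamin) / d_dynamin   [%]

with Δt_norm < −10% classified *before*, |Δt_norm| ≤ 10% *simultaneous*,
and Δt_norm > +10% *after* (negative values mean the reporter peaks before
dynamin).

## Worked example

```python
from dualtrace import (SimulationConfig, generate_movie, TwoChannelEventModel)

config = SimulationConfig(n_events=12, n_frames=100, seed=8)
movie = generate_movie(config)                      # two stacks + ground truth
results = TwoChannelEventModel.from_movie(movie).fit()
print(results.summary())
```

prints

```
Two-channel event-timing analysis
================================================
Frames: 100   frame interval: 2.0 s   image: 64x64 px
Candidate events (ch1-anchored): 176
Validated events:                12
Events entering timing:          12
------------------------------------------------
Events analyzed:            12
Before / simultaneous / after (%):  8.3 / 66.7 / 25.0
Negative delta_t (%):       41.7
Double dynab peaks (%):     0.0
Double dynamin peaks (%):   0.0
Duration dynamin (s):       30.61 +/- 1.86 (SEM)
Duration dynab (s):         22.96 +/- 1.47 (SEM)
Duration ratio dynab/dynamin (%): 75.0
Peak-intensity correlation: 0.995
```

All 12 planted events are recovered and validated; the 164 other candidates
are transient noise detections, correctly rejected by the five criteria
(none validates). The recovered mean-duration ratio (75.0%) matches the
generator's channel-2 width scale (0.75), and the per-event delays are in
`results.timing_table` (columns include `delta_t_s`, `delta_t_norm_pct`,
`timing_class`):

```
 event_id  delta_t_s  delta_t_norm_pct timing_class
       17   2.960827          7.830064 simultaneous
       29  -1.315038         -5.904959 simultaneous
       40  -1.576049         -5.553599 simultaneous
       50  -9.843987        -25.438614       before
       53   0.836819          2.489312 simultaneous
```

`results.plot_delta_t_histogram()` and `results.plot_curve_average()` draw
the 5%-cluster delay histogram and the peak-aligned mean curves;
`evaluate_against_truth(results, movie)` scores recall, spurious rate and
per-event delay errors against the planted truth.

A command line mirrors the library: `dualtrace simulate / detect / events /
fit / stats / run / evaluate` (see `dualtrace --help`); `run` executes the
whole pipeline from a YAML config and writes all tables plus a manifest with
SHA-256 digests of every input and output.

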