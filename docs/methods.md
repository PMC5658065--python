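# Methods

This note documents the models, algorithms and numerical choices behind
`dualtrace`, in the order the pipeline applies them, together with the
assumptions and known limitations a user should weigh before trusting the
output on their own data.

## Scope and data model

The package analyzes paired time-lapse fluorescence stacks of
diffraction-limited, quasi-stationary punctae — the regime of dynamin
recruitment at clathrin-coated pits imaged by TIRF at ~2 s/frame, with a
second spectrally separated channel reporting a related signal (here a
conformation-specific nanobody that lights up during dynamin's GTP-hydrolysis
transition state). The scientific output is the distribution of peak delays
between the two channels across events, normalized per event by the duration
of the reference (dynamin) channel.

Events are modelled as separable space × time Gaussians: a fixed sub-pixel
position blurred by a Gaussian PSF (σ_psf, default 1.5 px), with a Gaussian
temporal envelope per channel (amplitude a, peak time t, width σ).
Quasi-stationarity is an assumption of the analysis, not merely of the
simulator: spot motion beyond the link radius (default 2 px) splits or
invalidates events by design.

## Synthetic movies

`simulate.generate_movie` renders planted events on a constant background,
applies Poisson noise to (signal + background) and adds zero-mean Gaussian
camera read noise, clipping at zero — the standard CCD/EMCCD approximation.
Defaults describe the study conditions the analysis was designed around:

| parameter | default | meaning |
|---|---|---|
| frame_interval_s | 2.0 | acquisition interval (s) |
| psf_sigma_px | 1.5 | PSF Gaussian sigma (px) |
| image, frames, events | 64×64, 150, 30 | benchmark movie size |
| amplitude_range | (300, 600) photons | peak amplitude, channel 1 |
| channel2_amplitude_scale | 0.8 | reporter is dimmer |
| channel2_sigma_scale | 0.75 | reporter events are shorter (duration ratio 70–80%) |
| temporal_sigma_range_frames | (2, 5) | event width; duration d = 4σ = 8–20 frames |
| delta_t_spec | categorical (0.29, 0.47, 0.24) | before/simultaneous/after probabilities |
| class offset ranges | (−35,−12) / (−8,8) / (12,35) % | channel-2 peak offset as % of d₁ |
| double_peak_fraction | 0.08 | probability of two reporter bursts |
| background_level / camera_noise_sd | 20 / 2 photons | noise floor |
| min_event_separation_px | 9 (= 6·σ_psf) | spatial separation of events |

Channel-2 offsets may instead be a point mass (for exact-delay tests) or a
Gaussian mixture. Double-peak events place one burst before and one after
the channel-1 peak, amplitude ratio 0.8, mirroring the reported phenomenology
of early abortive plus late productive hydrolysis bursts.

Event positions are drawn on a jittered square lattice sampled without
replacement, which guarantees the pairwise separation constraint by
construction; plain rejection sampling stalls far below the packing limit at
benchmark densities. Peak times are kept ≥ 3σ + 2 frames from both movie
ends so no planted event is truncated. Per-frame positional jitter is
available (default 0) for robustness experiments.

What the simulator deliberately does **not** emulate: photobleaching, lateral
drift, CCP maturation kinetics (intensity plateaus, scission dips), motion of
pits, non-uniform illumination, or correlated camera noise. Passing tests on
synthetic movies therefore demonstrate the correctness of the *computation*,
not robustness to every real-microscope artefact.

## Spot detection and photometry

Per frame: the image is band-passed with a negated Laplacian-of-Gaussian at
σ_psf; candidate spots are 8-neighbourhood local maxima exceeding the
response median by 3 robust standard deviations (MAD × 1.4826). Plateau ties
keep the smallest (row, col). Each candidate is refined by least-squares
fitting a symmetric 2-D Gaussian plus constant in a (4σ_psf + 1)² window.

Intensity follows the integrated-circle definition: the sum over pixels whose
centres lie within the aperture radius (default 3σ_psf, capturing ≈ 99% of
the flux) minus the annulus-median local background (annulus radii
aperture + 1.5 to + 4.5 px; the median is robust to neighbouring spots). The
intensity is therefore invariant under adding a constant to the frame and
linear in the signal amplitude; it may legitimately be negative over empty
regions.

Significance: a spot is flagged significant when the lower (1 − α)
confidence bound of its fitted amplitude (standard error from the fit
Jacobian, noise from the annulus MAD) exceeds the α-quantile of the local
pixel noise; α defaults to 0.05. With this test a planted spot whose
amplitude equals one noise standard deviation is flagged in ≤ 5% of
realizations, while the detection significance does not gate linking — the
five validation criteria are the arbiter of what counts as an event.

## Event assembly and the five criteria

Linking is greedy: within each frame, spots (brightest first) extend the
open candidate whose running intensity-weighted anchor is nearest within the
link radius; otherwise they seed a new candidate. A candidate may be missing
for up to two consecutive frames; at three missing frames it is closed.
Anchors are frozen after assembly and used to measure both channels' traces
over the event span plus a margin (default 10 frames per side — enough
baseline for the mixture fit and the profile correlation, comparable to how
such traces are usually displayed). Events touching the first or last movie
frame are flagged truncated and excluded from timing statistics; events
whose aperture does not fit in the frame are flagged unmeasurable.

The five criteria (evaluated on raw, pre-spline traces; every candidate is
retained with its flags, `valid` is their conjunction):

1. **spatial** — every consecutive spot displacement ≤ link radius;
2. **duration** — frame span ≥ 10 frames;
3. **intensity** — raw trace peak ≥ 40% of the largest event peak in the
   sequence, per channel, inclusive at the threshold; both channels must
   pass (which channel the criterion applies to is a genuine ambiguity —
   requiring both is the stricter reading);
4. **correlation** — Pearson r between the two traces > 0.45, strict; a
   zero-variance trace fails;
5. **goodness of fit** — both channels' mixture fits converged with a
   principal component and R² > 0.6.

Note a structural property of criterion 4: for Gaussian-shaped events the
windowed Pearson correlation of the two traces falls below 0.45 once the
normalized peak offset exceeds roughly ±30% of the reference duration, so
strongly shifted events are rejected by construction. This is faithful to
the published procedure; it implies measured "before/after" fractions are
conditioned on events surviving the correlation gate. The recovery
benchmark therefore plants offsets within ±28% — it measures losses from
detection, linking and fitting, not the criterion's intended rejections.

Colocalization between two event lists is the fraction of A-events with a
B-event anchor within a radius (default 3 px) and ≥ 3 frames of temporal
overlap; an empty A list is an undefined fraction and raises.

## Trace processing and the four-Gaussian fit

Each trace is shifted so its minimum is exactly zero and upsampled fourfold
with an interpolating cubic spline (node values preserved to machine
precision; resolution 0.25 frames). The mixture of four Gaussians is then
fitted in normalized intensity units (values divided by their maximum, so
the fit is exactly equivariant under intensity scaling).

Fitting is a deterministic block-coordinate scheme rather than a free joint
least squares:

1. the trace maximum seeds one peak component (width from the local
   half-maximum extent), fitted **jointly** with one broad background
   component — a Gaussian constrained to σ ∈ [2, 3] × span with centre in
   the span, i.e. near-flat over the window — which absorbs the positive
   noise floor that zero-minimum shifting leaves behind;
2. each remaining component is fitted alone to the frozen residual, seeded
   on the residual maximum.

The rationale: a free joint fit of four Gaussians to a single noisy peak is
unidentifiable — it can split the peak across two components with identical
residual, or broaden it into the baseline — corrupting exactly the centre
and width the analysis reports. The staged fit keeps the principal
component in the well-behaved single-peak basin (empirically matching a
constrained Gaussian + offset reference fit: median peak-time error ≈ 0.2
frames and duration error ≈ 11% at SNR 5) while still returning a full
four-component mixture and recovering genuinely double-peaked traces
exactly in the noiseless limit. Bounds: amplitudes ≥ 0, centres within one
span of the window, peak widths in [0.25 samples, span]. Goodness of fit is
R² = 1 − SS_res/SS_tot over the fitted (upsampled) samples — the only
common bounded-near-1 statistic for which a 0.6 threshold is meaningful.

**Principal selection.** A component qualifies as signal if its amplitude
reaches 50% of the largest amplitude among components centred **inside** the
time span (components parked outside the span are background by definition
and must not set the reference), its width lies in [1 frame, span], and its
centre is inside the span. The top qualifier is always principal; a second
becomes principal — a double peak — only when separated from the first by
more than ¼(d₁ + d₂) = σ₁ + σ₂. At most two components are principal. When
two are, the higher-amplitude one enters the delay statistic and both are
recorded. From the principal component: p = amplitude, t = centre,
d = 4σ (an exact identity, asserted in tests).

Degenerate inputs: traces shorter than 12 upsampled samples, all-constant
traces, or non-converging fits yield a failed fit (criterion 5 false); the
event is kept with its flags. Candidates already failing the duration
criterion are not fitted at all — they can never validate, and skipping them
removes a few hundred pointless fits per movie.

## Timing statistics

Δt = t(channel 2) − t(channel 1) in seconds (negative: the reporter peaks
first), also reported in frames and quantized to 0.25 frames for display —
the fitted centres themselves are continuous, and the quarter frame is the
claimed *accuracy*, which the tests verify end-to-end (recovered Δt within
0.25 frames of truth for sub-frame offsets at high SNR).

Δt_norm = 100·Δt/d₁ is binned in 5% clusters, [k·5, (k+1)·5) left-inclusive
and symmetric about zero; values beyond ±100% land in their own overflow
bins and remain counted. Classification: before (< −10%), simultaneous
(−10% to +10%, inclusive both sides), after (> +10%); the cutoff is
configurable. Cohort summaries report class fractions, the fraction of
raw-negative Δt (a distinct statistic from the "before" fraction — both are
emitted because both readings of "peaks before" are in circulation),
double-peak rates per channel, duration means ± SEM and their ratio, and
the Pearson correlation of peak intensities. Curve averaging evaluates each
event's *fitted principal* curves (not the sampled data) on a grid of time
relative to the channel-1 peak, divides both channels by that event's
channel-1 peak value, and averages pointwise with SEM; grid step defaults
to 0.25 frames. `duration_comparison` reports the ratio of group means with
a Welch t statistic — descriptive only; no inferential claims are made on
synthetic cohorts.

## Orchestration and reproducibility

`run_pipeline` executes simulate/read → detect → assemble → extract → fit →
label → timing → summarize with a fixed stage order, persists every
intermediate table as CSV (fixed column order, six-decimal seconds), and
writes a JSON manifest (config snapshot, seed, version, SHA-256 digest of
every input and output, timestamps) atomically at the end. All randomness
in the package flows from the single configured seed; the analysis itself
is deterministic, so reruns are byte-identical — a property the test suite
asserts. The frame interval always comes from configuration, never from
TIFF metadata. The CLI subcommands (`simulate`, `detect`, `events`, `fit`,
`stats`, `run`, `evaluate`) are thin wrappers over the same library calls.

## Problem sizes used in tests

The standard recovery benchmark is one 64×64 px movie pair of 150 frames
with 30 events (≈ 10 s of analysis on one CPU); Monte-Carlo checks use
100–500 repetitions of frame-sized or trace-sized problems; the
classification cohort uses 1000 sampled events. These sizes give binomial
standard errors comfortably inside the asserted tolerances while keeping
the full suite fast.

## Known limitations

- Overlapping events closer than ~6σ_psf are not deconvolved (dense fields
  are out of scope); linking has no motion model or merge/split handling.
- The correlation criterion's offset ceiling (above) biases validated
  cohorts against |Δt_norm| ≳ 30%; interpret class fractions accordingly.
- The mixture fit reports no parameter uncertainties; K is fixed at four.
- The manual event-validation step of interactive workflows is replaced by
  automatic flags; a reviewer can still overrule any
  event via `apply_review_overrides` (an event-id → keep mapping, e.g. read
  from a review CSV), which takes precedence over the automatic flags.
- Durations are definitionally d = 4σ of a Gaussian envelope; asymmetric
  recruitment profiles (fast assembly, slow disassembly) will be summarized
  by an effective width.
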