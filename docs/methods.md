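# Methods

This note documents the models, conventions and numerical choices behind
`rattlekit`, and what the synthetic-data tests do and do not establish about
real recordings.

## Signal model and preprocessing

Each wrist sensor yields tri-axial acceleration on a uniform 60 Hz grid.
The pipeline is unit-agnostic (g or m/s²): all detection thresholds are
relative. Preprocessing order is fixed — interpolate, collapse, smooth:

1. **Missing samples** are filled per axis by cubic-spline interpolation
   through the known samples; known samples pass through bit-for-bit.
   Leading/trailing missing runs are filled by nearest-known-value extension
   rather than spline extrapolation, which diverges; session endpoints are
   never analyzed (claps and episodes are interior), so this choice has no
   analytic effect. At least 4 known samples per axis are required.
2. **Magnitude**: `Acc(t) = √(ax² + ay² + az²)`. Interpolation happens on
   the axes *before* the norm (interpolating the norm instead was
   considered and rejected: the norm of interpolated axes is the quantity a
   spline on the rectified signal cannot reproduce).
3. **Median smoothing**: third-order median filter (each value replaced by
   the median of its 3-sample neighborhood) with zero-padded edges, the
   convention of the common reference implementation, so endpoint behavior
   is reproducible.

## Event detection and the merge rule

Within an analysis window (the clap window, or one rattling episode), the
threshold is the window mean plus one **population** standard deviation
(`ddof=0`; a fixed convention documented for bit-reproducibility — the
difference from the sample SD is negligible at these window lengths).
Samples strictly above threshold are 1; maximal 1-runs separated by 50 ms
or less (≤ 3 samples at 60 Hz, boundary inclusive) merge into one event.
Detection is invariant to affine rescaling of the magnitude.

For movement counting, thresholds are computed **per episode segment**
rather than from the whole joined series, making counts robust to baseline
drift between episodes; the whole-series scope is available as
`threshold_scope="joined"`. The merge rule is never applied across the
artificial joins between episodes. The two arms are combined by **union**
of their supra-threshold binaries on the time axis, so a bimanual shake
counts as one movement; `combine="per-arm"` sums the arms instead. Rattling
frequency is movements divided by total *annotated* episode duration, and a
visit above 2.5 Hz is flagged as an outlier (`excluded`).

Re-coding control analyses are reproduced by configuration, not separate
code: `min_episodes_per_visit` (pipeline) and a `min_duration_s` episode
filter (segmentation), rather than re-implementations.

## Sensor↔video synchronization

The mother's claps anchor the two clocks. The clap window is an explicit
configuration value (replacing interactive selection). Sensor claps are
binarized by the event detector; video clap intervals are rasterized
half-open (`[onset, offset)`, sample *i* inside iff `i/fs` is covered — the
convention used everywhere intervals meet the sample grid, preventing
double counting at shared boundaries).

The lag is estimated from the **diagonal cross-recurrence profile**: for
every integer-sample shift within ±6 s, the number of co-occurring ones,
normalized by the smaller count of ones inside the shifted overlap, so the
profile value is the matched-clap fraction in [0, 1] (for 0/1 series a
binary match *is* a recurrence; no radius or embedding is involved). A true
alignment scores near 1; a false peak — one clap landing on a *different*
clap — scores at most ~1/n_claps. The confidence floor is therefore 0.5
("majority of claps matched"): below it the search automatically widens to
±15 s, mirroring the two-stage short/long-window procedure; if the widened
peak is still weak the estimate carries `low_confidence=True`.

Because the true lag is generally a non-integer number of samples, the
match profile peaks as a short tent with a near-tied plateau whose ends
depend on rasterization phase. The returned lag is the match-weighted
centroid of the contiguous half-maximum region around the argmax, rounded
to an integer sample — this removes the systematic half-sample skew a bare
argmax-with-tie-break exhibits. Output stays on the integer sample grid; no
sub-sample refinement is attempted. Residual error is bounded by the
quantization of the binarized representations (about half a sample of
irreducible phase noise per session with four claps).

**Sign convention**: `lag_s` is the video clock minus the sensor clock — an
event at sensor time `t` appears in the annotations at `t + lag_s` — and
`align` subtracts it from annotation times. Annotation times are converted
to sensor time in exactly one place (`sync.align`); everything downstream
assumes sensor-clock annotations. Intervals that leave the sensor extent
after shifting are clipped, and fully-outside intervals dropped with a
logged count.

## Wavelet coherence

The continuous wavelet transform uses the analytic Morlet wavelet with
center frequency ω₀ = 6 on a dyadic grid of 12 voices per octave spanning
0.25–5 Hz (the 0.5–2.5 Hz rattling band with an octave of margin on each
side); frequency and scale are related by the standard Fourier factor
λ = 4π/(ω₀ + √(2 + ω₀²)) ≈ 1.033. The transform is FFT-based with
zero-padding past the longest wavelet's support; the cone of influence uses
the √2·scale e-folding convention and is stored as the lowest
edge-reliable frequency per time point.

Wavelet coherence is the smoothed cross-spectrum magnitude squared over the
product of smoothed auto-spectra. The smoothing operator follows the
Grinsted convention: a Gaussian in time with SD equal to the scale
(truncated at 4 SD and normalized), a 0.6-octave boxcar across scales
(rounded to an odd 7 rows at 12 voices, truncated and renormalized at the
grid edges), with each field divided by its scale before smoothing. Because
the weights are non-negative and identical across numerator and
denominator, the Cauchy–Schwarz inequality bounds WC in [0, 1] up to float
rounding; values are clipped within a 1e-6 tolerance and anything beyond
raises (it would indicate a smoothing bug). With smoothing disabled the
ratio is identically 1 — the test suite asserts this degeneracy as a
negative control against silently disabled smoothing.

Two numerical guards: (i) smoothed auto-spectra are floored at 1e-7 of
their maximum, because FFT-based smoothing carries absolute rounding error
of order 1e-14 × the field maximum, which would otherwise dominate the
ratio at cells with essentially no power (coherence is reported ≈ 0 where
there is no power); (ii) constant inputs are rejected (zero denominator).

The band average is the unweighted mean over scale rows with
0.5 ≤ f ≤ 2.5 Hz and **all** time columns (the cone of influence is not
excluded by default, matching the full-time band averaging of the original
analysis; `coi_exclude=True` gives the conservative variant). Coherence is
computed on the joined episode series, accepting join artifacts, as the
original analysis does.

**Surrogate null**: each of 1000 iterations independently permutes the
samples of both series and records the band mean. Full permutation destroys
*all* temporal structure — the surrogates are white — which is the
appropriate null for "is there any structure at all", and it is what plain
shuffling of a time series means. A spectrum-preserving alternative
(`method="phase"`, Fourier phase randomization) is provided for the
sharper question "is there cross-arm phase coupling beyond what two
independent signals with these spectra would show"; see *Limitations*.
Group-level inference is a paired two-sided t-test of per-visit observed
band means against per-visit null means.

The single-hand spectrum is the time-averaged wavelet power per frequency
row of one arm's series.

## Synthetic sessions

The generator emulates the statistical structure of a ~5 min dyadic
recording, not its biomechanics (no joint models or orientations):

* per-axis white Gaussian noise (default SD 0.5) plus a constant gravity
  offset (default 9.81) on one axis;
* **movement packets**: each rattling movement is one period-scale burst —
  a Hann-windowed cosine, window 1.25 carrier periods, carrier peak at the
  window center — added to the gravity axis with default amplitude 5.0
  (SNR ≈ 10, plausible for wrist-worn IMUs during vigorous shaking, where
  the effective noise is baseline movement rather than sensor noise). The
  single-lobe-above-baseline shape is what makes "one packet = one
  movement" hold exactly under the mean + 1 SD threshold: a multi-cycle
  carrier would produce several supra-threshold lobes separated by more
  than the 50 ms merge gap and be counted as several events;
* **coupling** c ∈ [0, 1]: right-arm packets are the left-arm packets
  shifted in time by a placement jitter (1 − c)·U(−L/2, L/2) wrapped into
  the episode plus a sub-period circular jitter with SD π(1 − c) on the
  carrier clock. c = 1 gives phase-locked identical arm signals (up to
  independent sensor noise); c = 0 gives uniformly, independently placed
  and phased packets. An alternative — drawing the c = 0 right arm as an
  independent realization of the left arm's evenly-spaced placement law —
  was evaluated and rejected: two near-commensurate packet trains hold an
  almost constant relative phase and are *more* coherent than uniformly
  placed ones;
* **claps**: half-sine transients (width 0.1 s, amplitude 30 ≥ 5× noise SD)
  at jittered-grid times inside the clap window, identical on both arms;
* **video track**: the true clap/episode intervals shifted by the
  configured lag (video = sensor + lag, up to ±15 s), with per-episode
  condition labels;
* **default layout** (`default_session_config`): 300 s sessions, 12
  episodes of 1.5–4.5 s separated by 8–20 s gaps, burst frequency 1.2 Hz,
  ~0.8 movements per carrier period capped so packet centers stay ≥ 0.7
  periods apart (keeping movements temporally distinct); the implied
  rattling frequency is 0.78–0.90 Hz and episode counts/durations match the
  reported descriptive ranges for this kind of play. A ~70/30
  condition split mirrors the observed proportion of solo rattling.
  All randomness flows from one seed through deterministic per-component
  substreams, so identical configs are bit-reproducible.

What passing tests on these sessions show: the pipeline recovers planted
lags, counts, frequencies and coupling ordering under realistic noise. What
they do not show: robustness to broadband, jerky real movements, posture
changes, sensor drift or coder error — none of which the generator
emulates.

## Longitudinal statistics

Visit metrics are assembled into a long-format table (subject × timepoint
T1–T4 × condition × metric, at most one value per cell). Models are GEEs
with subject clusters and an exchangeable working correlation
(independence and AR(1) are config switches), counts under Poisson/log and
durations/frequencies/coherence under Gaussian/identity; factors are tested
with robust Wald χ² statistics, and all pairwise level contrasts are
Bonferroni-adjusted (p·m capped at 1). No small-sample corrections are
applied; the robust Wald test is known to be mildly anti-conservative below
~40 clusters (measured ≈ 7% empirical size at 40 clusters, ≈ 5% at 80).

Cohen's κ compares two coders' tracks frame-by-frame (default 25 fps,
mirroring overlap-based computation at video rate):
κ = (p_o − p_e)/(1 − p_e) with chance agreement from the marginal label
frequencies; κ is undefined (NaN with a warning) when both raters are
constant with the same label.

## Problem sizes in the test suite

Simulations are sized for a desk machine: coupling-discrimination runs use
the default layout scaled to 6 episodes (~18 s of joined rattling) with
1000-draw nulls over 20 seeds per coupling level; lag recovery uses 60
sessions with 2 episodes each; count recovery uses 20 full default
sessions; the bound checks use 200 pairs of 60 s noise series. The
coherence engine is fully vectorized (batched FFTs over scales, cached
kernels per input length), and surrogate nulls run on a reduced scale grid
covering the band plus the scale-smoothing margin, which leaves the in-band
values identical to the full-grid computation.

## Limitations

* **Permutation nulls and narrowband signals.** Full-permutation surrogates
  are white, while any oscillatory signal is not. Smoothed coherence
  between two *independent* narrowband signals at a common carrier
  frequency is biased upward (the smoothing span covers only ~1–2
  independent phase segments at the carrier scale), so uncoupled
  same-frequency packet trains sit at or above the upper tail of their
  permutation null even with zero cross-arm coupling. This is a property of
  the estimator/null pair, not of the generator: it persists when the two
  arms come from entirely different sessions. Interpreting a permutation
  null as evidence *about coupling* therefore requires the observed signals
  to be near-white, as broadband real movement data may be; for narrowband
  data the phase-randomized surrogate is the valid coupling null.
* **Integer-sample lags.** The lag estimator quantizes to the 60 Hz grid;
  binarization phase noise adds up to ~half a sample of session-level bias
  on top, so accuracy is ±1 sample on the discrete grid, not below.
* **GEE small samples** as noted above.
* The ELAN dialect supported is the tab-delimited export, not `.eaf` XML.
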