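# Methods

## Problem and signal model

Cortical networks in slice preparations (and in vivo under some states)
alternate between silent periods and epochs of persistent, synchronized
activity (Up states).  In a local field potential (LFP) recording these
events appear as irregular high-amplitude, multi-frequency bursts,
0.3–8 s long, separated by noisy baseline whose statistics can drift
over the course of a recording.  The quantity of scientific interest is
the event list — onset, offset, and per-event amplitude and spectral
properties — and the analysis must not depend on a user-chosen
threshold, because both event occurrence and baseline level vary across
preparations and over time.

`lfpevents` treats the trace as locally stationary: within an 11-s
window the baseline statistics are constant, and a window is long
enough to contain baseline even when it also contains an event (events
are empirically at most ~8 s).  All decisions are made per window from
the data in that window.

## Pipeline

1. **Preprocessing.** The channel mean (DC offset from the acquisition
   chain) is subtracted and the trace is low-pass filtered with a
   3rd-order Butterworth at 200 Hz — the LFP band.  Filtering is
   zero-phase (forward–backward, reflect padding) by default because
   event timing is the primary output and a causal pass would delay
   onsets by the filter's group delay; `zero_phase=False` restores the
   single-pass variant.  The two-pass magnitude response is |H(f)|²
   with |H(f)| = (1 + (f/200)⁶)^(−1/2).

2. **Feature signals.** Two complementary non-negative sequences are
   derived on the same per-sample time base:
   * the *Hilbert envelope* |H(u(t))|, the modulus of the analytic
     signal, computed on the whole trace at once to avoid segment-edge
     artifacts;
   * the *short-time energy* E(i) = (1/N) Σₙ |uᵢ(n)|², the mean squared
     amplitude over consecutive non-overlapping windows (default
     50 ms; the final partial window is averaged over its own length),
     step-expanded back to per-sample resolution.  Step expansion
     rather than interpolation keeps thresholding order-preserving.

   The envelope underestimates low-amplitude stretches inside events;
   the energy feature over-segments at brief pauses.  Their masks are
   fused downstream precisely so each covers the other's failure mode.

3. **Adaptive thresholds.** Each feature trace is cut into 11-s
   segments (a trailing piece ≥ 2 s stands alone; shorter tails merge
   backward, since a tiny tail cannot support a two-component fit).
   Per segment, a 1-D Gaussian mixture is fitted to the feature values
   by EM, with the number of components (1 or 2) chosen by a
   minimum-message-length criterion: starting from the maximum count,
   components whose estimated support cannot pay for their parameter
   cost are annihilated (weight update max(0, nₘ − P/2), P = 2
   parameters per univariate component), and the candidate minimizing

       L = (P/2) Σₘ log(n wₘ/12) + (k/2) log(n/12) + k(P+1)/2 − loglik

   over all surviving counts k is kept.  EM is initialized at
   deterministic sample quantiles with shared variance, so a fit is a
   pure function of the data; convergence is a relative log-likelihood
   change < 1e-7 or 500 iterations.  Segments longer than 20 000
   samples are stride-decimated before the fit (deterministic, and
   immaterial for a density estimate).

   A segment is declared **event-free** when any of these hold:
   * the winning model has one component;
   * the winning two-component model's *summed density has no interior
     local minimum*.  Feature values of pure noise are skewed (the
     envelope is Rayleigh-like, window energies chi-square-like), and
     a two-Gaussian fit will happily spend its second component on the
     skew; the baseline/event reading of the fit is only meaningful
     when the density genuinely shows two peaks, which is the
     criterion applied;
   * the threshold would exceed the segment maximum;
   * the segment has fewer than 50 usable values or zero variance.

   Otherwise the threshold is the **Bayes decision boundary**: the
   root of w₁g(x|μ₁,Σ₁) = w₂g(x|μ₂,Σ₂) in (μ₁, μ₂), obtained from the
   closed-form quadratic in x (smaller admissible root on ties), with
   a posterior scan at 1e-4·(μ₂−μ₁) resolution as fallback when no
   real root lies between the means.  Event-free segments carry an
   infinite threshold so that the strict `feature > threshold`
   comparison yields an all-zero mask without special-casing; an
   exactly-at-threshold plateau is baseline by the same strictness.

4. **Masks, fusion, events.** Each feature/threshold pair gives a
   boolean mask; the two masks are fused with a logical OR; maximal
   runs of ones become candidate events (half-open sample intervals,
   so runs crossing segment boundaries are naturally contiguous).
   Candidates shorter than `min_event_s` (default 0.2 s) are dropped:
   the events the method targets last 0.3–8 s, while threshold
   crossings of a few milliseconds are noise-tail excursions — their
   local SD is of the order of the threshold itself, which defeats the
   SD artifact filter below, and no event of scientific interest is
   that short.  A `merge_gap_s` hook exists (default 0 = off).

5. **Artifact rejection and baseline.** A surviving candidate is kept
   only if the SD of the preprocessed signal over the candidate is at
   least the SD of the whole preprocessed trace — genuine network
   events raise local variance above that of a trace dominated by
   quiet baseline, while electrical/mechanical glitches of comparable
   amplitude but low internal variability do not.  The longest
   event-free stretch (earliest on ties) is kept as the baseline
   window for spectral referencing.

6. **Quantification.** Per event: onset, offset, duration,
   inter-event interval (offset to next onset; absent for the last
   event), first-occurrence extrema with times, rectified area
   Σ|v|·Δt (V·s).  Spectra per event from two estimators — plain
   periodogram and a DPSS multitaper average (default NW = 3, 5
   tapers, clamped for very short events) — integrated over delta
   (1–4), theta (4–8), alpha (8–12), beta (12–30), gamma (30–100) and
   wide gamma (30–120 Hz), half-open bands so a shared edge belongs to
   the upper band.  Each band power is reported absolute, normalized
   to the event's total power, and normalized to the largest band;
   each also in a baseline-subtracted variant where the baseline
   window's PSD is interpolated onto the event's frequency grid and
   the difference floored at 0 before integration (subtraction can go
   negative; flooring keeps the result interpretable as a power).
   Amplitudes are reported in µV, times in seconds; internal units are
   volts and seconds throughout.

## Parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| `lowpass_cutoff` | 200 | Hz | upper edge of LFP-related content |
| `filter_order` | 3 | — | gentle roll-off, low distortion |
| `segment_len_s` | 11 | s | ≥ one max-length event plus baseline |
| `ste_window_s` | 0.05 | s | speech practice 10–50 ms; resolves sub-second events, smooths passband content |
| `max_components` | 2 | — | baseline vs event is the natural split |
| `min_event_s` | 0.2 | s | below the 0.3-s floor of targeted events; removes sub-resolution noise excursions |
| `multitaper_nw`, `multitaper_k` | 3, 5 | — | standard variance/resolution trade-off |

## Synthetic generator

The generator emulates the regime the detector is built for: Gaussian
white noise low-passed at 200 Hz (so baseline statistics match the
analysis passband) at 25 µV SD, optionally with a slow sinusoidal
drift or a piecewise SD profile; events are bundles of band-limited
oscillations (2, 15, 40 Hz by default — slow, beta and gamma content)
scaled to a target RMS (default 100 µV, i.e. SNR 4 relative to
baseline) under a Tukey taper with fixed 0.1-s edge ramps, since state
transitions are fast relative to state duration.  Durations are
log-normal (median ≈ 1.3 s, σ_log = 0.45) clipped to [0.3, 8] s —
mimicking the right-skewed, short/long-population structure of real
event-duration samples — with starts placed uniformly under a minimum
1-s gap.  Default trace: 120 s at 1 kHz with 8 events.

What it deliberately does **not** emulate: line noise and sharp
electrical artifacts, 1/f background structure, amplitude
non-stationarity *within* an event, correlated multi-channel activity,
and electrode drift faster than the drift term.  Tests passing on this
generator therefore demonstrate the pipeline's logic and its local
adaptation, not robustness to every failure mode of real recordings —
the SD artifact filter in particular is exercised only against the
generator's noise, not against genuine mechanical glitches.

## Evaluation utilities

Method-vs-method comparisons use summary statistics (mean, SD, SEM,
CV = SD/mean), a least-absolute-residuals line fit f(x) = αx + b
computed by iteratively reweighted least squares on centered/scaled
data and reported on the original scale (gradient α near 1 with a
nonzero bias reads as a consistent offset between methods), a paired
two-sided t-test (zero-variance differences flagged, not silently
given a p-value), and a fixed-M Gaussian mixture for bimodal duration
samples (reusing the same EM core with selection disabled).  R² under
an L1 fit has no canonical definition; the conventional
1 − SSres/SStot on the fitted line is used.

## Numerical choices and degenerate inputs

* Variance floor 1e-10 × sample variance prevents component collapse.
* Quantile initialization plus a deterministic tie-break jitter makes
  fits reproducible bit-for-bit for identical input.
* Empty/NaN traces, cutoffs at or above Nyquist, coverage gaps in
  thresholds, empty event intervals and zero-variance regression
  inputs all fail fast with messages naming the offending quantity.
* Events covering the entire trace leave the baseline undefined
  (recorded as absent) rather than inventing one.

## Problem sizes

The test suite and the reproduction script run the standard suite at
120 s × 1 kHz × 8 events (10–20 seeds), the model-selection battery at
n = 5 000 × 50–100 replicates, and the local-vs-global comparison on
60-s two-regime traces × 50–100 replicates — sizes at which every
statistical assertion is stable from seed to seed.

## Known limitations

* Thresholds assume the feature histogram of an event-containing
  segment is genuinely two-peaked; events filling an entire segment
  (> 11 s of continuous activity) would read as baseline.
* The SD artifact filter compares against the whole-trace SD and so
  becomes conservative when events occupy a large fraction of the
  recording.
* Channels are processed independently; no cross-channel consistency
  is exploited.
* Detection is offline; the per-segment fits need the full segment.
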