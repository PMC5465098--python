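# lfpevents

Automatic, data-driven detection and quantification of spontaneous
network events — Up states and similar activity bursts — in local
field potential (LFP) recordings.

LFP traces from cortical slices (or chronic in-vivo preparations)
alternate between noisy baseline and irregular high-amplitude bursts
0.3–8 s long.  Quantifying these events usually means hand-tuning a
global voltage threshold, which is slow, subjective, and breaks down
whenever the baseline drifts or the event rate changes.  `lfpevents`
removes the user from that loop: every threshold is estimated locally
from the data, so two people analyzing the same file get the same
event list.

## Method in brief

For each channel, after DC removal and a zero-phase 3rd-order
Butterworth low-pass at 200 Hz, two feature sequences are computed:
the Hilbert envelope |H(u(t))| and the short-time energy
E(i) = (1/N) Σₙ|uᵢ(n)|² over 50-ms windows.  Each feature trace is cut
into 11-s segments and, per segment, a 1-D Gaussian mixture

p(x | λ) = Σᵢ wᵢ g(x | μᵢ, Σᵢ)

is fitted by EM with the component count (1 or 2) selected by a
minimum-message-length criterion (component annihilation).  A
two-peaked segment yields the Bayes decision boundary
w₁g(x|μ₁,Σ₁) = w₂g(x|μ₂,Σ₂) as its threshold; a one-peaked segment is
baseline throughout.  The two per-feature masks are fused with a
logical OR, runs of ones become candidate events, candidates whose
standard deviation falls below the whole-trace SD are rejected as
artifacts, and the longest event-free stretch becomes the baseline
window.  Every surviving event is quantified: onset, offset, duration,
inter-event interval, extrema, rectified area, and band powers (delta
through wide gamma, periodogram and multitaper, absolute/normalized,
raw and baseline-subtracted).

A synthetic-LFP generator with exact ground truth (`lfpevents.generate`)
makes the whole pipeline testable without any recording data, and an
evaluation module provides the comparison statistics used to benchmark
detectors against each other (CV, robust LAR regression, paired
t-test, duration mixtures).

## Worked example

```python
import numpy as np
import lfpevents as lfp

spec = lfp.SynthSpec(seed=42)            # 120 s, 1 kHz, 8 events, SNR 4
rec, truth = lfp.generate(spec)

cfg = lfp.RunConfig(fs=rec.fs, rng_seed=42)
result = lfp.analyze_channel(rec, 0, cfg)

score = lfp.score_detection(truth, result.detection)
print(f"events detected: {len(result.events)} (true: {len(truth)})")
print(f"recall {score.recall:.2f}, precision {score.precision:.2f}")
print(f"median |onset error|: "
      f"{1e3 * np.median(np.abs(score.onset_errors_s)):.0f} ms")
cols = ["onset_s", "offset_s", "duration_s", "v_max_uV", "rect_area_Vs"]
print(result.table[cols].head(3).round(4))
```

prints

```
events detected: 8 (true: 8)
recall 1.00, precision 1.00
median |onset error|: 33 ms
   onset_s  offset_s  duration_s  v_max_uV  rect_area_Vs
0    18.60      20.7        2.10  300.9480        0.0002
1    27.35      28.2        0.85  246.0585        0.0001
2    46.05      47.1        1.05  260.6575        0.0001
```

All eight planted bursts are recovered with no false positives; onsets
are located to a few tens of milliseconds.  `v_max_uV` is the event's
peak amplitude in microvolts and `rect_area_Vs` the integral of the
absolute voltage over the event (volt-seconds); the full table also
carries the inter-event intervals and 72 band-power columns (6 bands ×
2 estimators × raw/baseline-subtracted × 3 normalizations).

## Command line

```sh
lfpevents synth --out trace.csv --truth truth.csv --seed 3
lfpevents run --input trace.csv --fs 1000 --out results/ [--xlsx]
lfpevents compare --truth truth.csv --detected results/events_synth.csv \
    --report report.csv
```

`run` writes one `events_<channel>.csv` per channel (CSV is the
canonical artifact; `--xlsx` adds a spreadsheet with a metadata
sheet), `baseline_<channel>.csv`, and `run_meta.csv`.  Input may be
delimited text (one column per channel) or raw little-endian float
binary with `--n-channels`; a `key = value` config file can replace
the flags.

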