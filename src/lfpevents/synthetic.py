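"""Synthetic LFP traces with known ground truth.

Emulates the regime of slice recordings of spontaneous network events:
long stretches of noisy baseline -- white Gaussian noise low-passed at
200 Hz so its statistics match the preprocessing passband, optionally
with slow drift or a piecewise SD change -- interrupted by
high-amplitude multi-frequency bursts 0.3-8 s long at variable
intervals.  Each burst is a bundle of band-limited oscillations (2, 15
and 40 Hz by default, spanning the slow, beta and gamma ranges an Up
state engages) under a Tukey taper, so onsets and offsets are sharp
enough to locate but not discontinuous.

Every planted interval is returned as ground truth, which makes
recall/precision and onset/offset timing errors measurable exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .detect import DetectionResult
from .io_core import Recording

__all__ = ["SynthSpec", "GroundTruth", "DetectionScore", "generate",
           "score_detection"]


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic trace.

    Amplitude and noise SD are in volts.  ``event_amplitude_v`` is the
    RMS of the oscillation bundle before tapering, so the per-event
    signal-to-noise ratio is amplitude/baseline_sd: the defaults
    (100 uV RMS events over 25 uV RMS baseline) give SNR 4, a clean but
    realistic slice recording.  Durations are drawn log-normally
    (median ~1.3 s, spread mimicking the strong right skew of real
    event-duration samples) and clipped to [0.3, 8] s.
    """

    fs: float = 1_000.0
    duration_s: float = 120.0
    n_events: int = 8
    event_amplitude_v: float = 100e-6
    baseline_sd_v: float = 25e-6
    event_freqs_hz: tuple[float, ...] = (2.0, 15.0, 40.0)
    duration_lognorm: tuple[float, float] = (np.log(1.3), 0.45)
    duration_bounds_s: tuple[float, float] = (0.3, 8.0)
    min_gap_s: float = 1.0
    drift_amp_v: float = 0.0          # slow (<0.5 Hz) sinusoidal drift
    drift_freq_hz: float = 0.1
    sd_profile: tuple[float, ...] = ()   # piecewise SD multipliers
    edge_ramp_s: float = 0.1          # Tukey taper length per event edge
    dc_offset_v: float = 0.0
    seed: int = 0


@dataclass
class GroundTruth:
    """Planted events: half-open (onset_s, offset_s) plus realized SNR."""

    events: list[tuple[float, float]] = field(default_factory=list)
    amplitudes_v: list[float] = field(default_factory=list)
    snr: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.events)


@dataclass
class DetectionScore:
    recall: float
    precision: float
    onset_errors_s: list[float]    # detected minus true, matched pairs
    offset_errors_s: list[float]
    n_matched: int


def _place_events(rng: np.random.Generator, spec: SynthSpec
                  ) -> list[tuple[float, float]]:
    """Draw durations then scatter non-overlapping start times."""
    lo, hi = spec.duration_bounds_s
    mu, sigma = spec.duration_lognorm
    durations = np.clip(rng.lognormal(mu, sigma, spec.n_events), lo, hi)
    gap = spec.min_gap_s
    needed = durations.sum() + gap * (spec.n_events + 1)
    if needed > spec.duration_s:
        raise ValueError(
            f"cannot pack {spec.n_events} events totalling "
            f"{durations.sum():.1f} s plus gaps into {spec.duration_s} s"
        )
    # distribute the slack among the n+1 gaps (Dirichlet-uniform)
    slack = spec.duration_s - needed
    cuts = np.sort(rng.uniform(0.0, slack, spec.n_events))
    extra = np.diff(np.concatenate(([0.0], cuts)))
    events = []
    t = gap
    for d, e in zip(durations, extra):
        t += e
        events.append((t, t + d))
        t += d + gap
    return events


def generate(spec: SynthSpec) -> tuple[Recording, GroundTruth]:
    """Build one trace and its ground truth; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs))
    t = np.arange(n) / spec.fs

    # baseline: white noise shaped to the 200 Hz analysis passband
    noise = rng.normal(0.0, 1.0, n)
    if spec.fs > 500.0:
        sos = sps.butter(3, 200.0, btype="low", fs=spec.fs, output="sos")
        noise = sps.sosfiltfilt(sos, noise)
    noise *= spec.baseline_sd_v / noise.std()
    if spec.sd_profile:
        k = len(spec.sd_profile)
        edges = np.linspace(0, n, k + 1).astype(int)
        for m, (a, b) in zip(spec.sd_profile, zip(edges[:-1], edges[1:])):
            noise[a:b] *= m
    trace = noise.copy()
    if spec.drift_amp_v:
        trace += spec.drift_amp_v * np.sin(2 * np.pi * spec.drift_freq_hz * t)
    trace += spec.dc_offset_v

    truth = GroundTruth()
    if spec.n_events:
        placed = _place_events(rng, spec)
        for onset, offset in placed:
            a = int(round(onset * spec.fs))
            b = int(round(offset * spec.fs))
            m = b - a
            tt = np.arange(m) / spec.fs
            burst = np.zeros(m)
            for f in spec.event_freqs_hz:
                phase = rng.uniform(0, 2 * np.pi)
                burst += np.sin(2 * np.pi * f * tt + phase)
            rms = burst.std()
            if rms > 0:
                burst *= spec.event_amplitude_v / rms
            # fixed-length edge ramps: state transitions are fast
            # relative to state duration
            alpha = min(1.0, 2.0 * spec.edge_ramp_s * spec.fs / max(m, 1))
            burst *= sps.windows.tukey(m, alpha)
            trace[a:b] += burst
            truth.events.append((a / spec.fs, b / spec.fs))
            truth.amplitudes_v.append(spec.event_amplitude_v)
            truth.snr.append(float(burst.std() / spec.baseline_sd_v))

    rec = Recording(samples=trace[None, :], fs=spec.fs, channel_ids=["synth"])
    return rec, truth


def score_detection(
    truth: GroundTruth,
    result: DetectionResult | list[tuple[float, float]],
    match_tol_s: float = 0.5,
) -> DetectionScore:
    """Greedy one-to-one matching of detected against planted events.

    A detected event matches a true one when their intervals overlap
    (or their boundary gap is within ``match_tol_s``); each true event
    is consumed by at most one detection, best-overlap first.  Signed
    onset/offset errors are detected-minus-true for the matched pairs.
    """
    if isinstance(result, DetectionResult):
        detected = result.event_times_s
    else:
        detected = list(result)
    true = list(truth.events)
    pairs = []
    for di, (da, db) in enumerate(detected):
        for ti, (ta, tb) in enumerate(true):
            overlap = min(db, tb) - max(da, ta)
            if overlap > -match_tol_s:
                pairs.append((overlap, di, ti))
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
    used_d: set[int] = set()
    used_t: set[int] = set()
    onset_err, offset_err = [], []
    for _, di, ti in pairs:
        if di in used_d or ti in used_t:
            continue
        used_d.add(di)
        used_t.add(ti)
        onset_err.append(detected[di][0] - true[ti][0])
        offset_err.append(detected[di][1] - true[ti][1])
    n_match = len(used_t)
    recall = n_match / len(true) if true else 1.0
    precision = n_match / len(detected) if detected else \
        (1.0 if not true else 0.0)
    return DetectionScore(
        recall=recall, precision=precision,
        onset_errors_s=onset_err, offset_errors_s=offset_err,
        n_matched=n_match,
    )
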