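"""Mask derivation, OR fusion, artifact rejection and baseline selection.

Each per-segment threshold is applied to its feature signal to build a
boolean mask (1 = prospective event).  The Hilbert-envelope and
short-time-energy masks are fused with a logical OR: the envelope misses
low-amplitude stretches inside events while the energy feature is
over-sensitive to brief pauses, and the union covers for both.  Runs of
ones become candidate events; candidates whose standard deviation falls
below the whole-trace SD are discarded as mechanical/electrical
artifacts, and the longest event-free stretch is kept as the baseline
window for spectral referencing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import FeatureSignal, hilbert_envelope, short_time_energy
from .gmm import SegmentThreshold, segment_thresholds
from .io_core import RunConfig
from .preprocess import PreprocessedSignal

__all__ = [
    "Mask",
    "DetectionResult",
    "apply_thresholds",
    "fuse_masks",
    "mask_to_events",
    "reject_artifacts",
    "select_baseline",
    "detect_events",
]


@dataclass
class Mask:
    values: np.ndarray   # per-sample booleans
    source: str          # "hilbert_env" | "short_time_energy" | "fused"


@dataclass
class DetectionResult:
    events: list[tuple[int, int]]            # half-open sample intervals
    masks: dict[str, Mask]
    thresholds: dict[str, list[SegmentThreshold]]
    baseline: tuple[int, int] | None
    fs: float
    rejected: list[tuple[int, int]]          # SD-filter casualties

    @property
    def event_times_s(self) -> list[tuple[float, float]]:
        return [(a / self.fs, b / self.fs) for a, b in self.events]


def apply_thresholds(
    feature: FeatureSignal, thresholds: list[SegmentThreshold]
) -> Mask:
    """Per-sample boolean mask: feature strictly above its segment's
    threshold.  Event-free segments carry an infinite threshold, so
    they come out all-zero without special-casing; the strict >
    comparison makes an exactly-at-threshold plateau baseline."""
    values = np.asarray(feature.values, dtype=float)
    mask = np.zeros(values.size, dtype=bool)
    covered = np.zeros(values.size, dtype=bool)
    for st in thresholds:
        if st.feature_kind != feature.kind:
            raise ValueError(
                f"threshold for {st.feature_kind!r} applied to "
                f"{feature.kind!r} feature"
            )
        mask[st.start:st.stop] = values[st.start:st.stop] > st.threshold
        covered[st.start:st.stop] = True
    if not covered.all():
        gap = int(np.argmin(covered))
        raise ValueError(f"thresholds do not cover sample {gap}")
    return Mask(values=mask, source=feature.kind)


def fuse_masks(a: Mask, b: Mask) -> Mask:
    if a.values.size != b.values.size:
        raise ValueError(
            f"mask length mismatch: {a.values.size} vs {b.values.size}"
        )
    return Mask(values=a.values | b.values, source="fused")


def mask_to_events(mask: Mask) -> list[tuple[int, int]]:
    """Maximal runs of ones as half-open (onset, offset) sample pairs."""
    v = np.asarray(mask.values, dtype=bool)
    if v.size == 0:
        return []
    padded = np.concatenate(([False], v, [False]))
    diff = np.diff(padded.astype(np.int8))
    onsets = np.nonzero(diff == 1)[0]
    offsets = np.nonzero(diff == -1)[0]
    return list(zip(onsets.tolist(), offsets.tolist()))


def reject_artifacts(
    events: list[tuple[int, int]], signal: PreprocessedSignal
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Keep events whose SD reaches the whole-trace SD.

    Genuine network events raise the local variance above that of a
    trace dominated by quiet baseline; brief noise blips do not.  The
    comparison uses the preprocessed signal on both sides.  Returns
    (kept, rejected).
    """
    whole_sd = float(np.std(signal.samples))
    kept, rejected = [], []
    for a, b in events:
        if float(np.std(signal.samples[a:b])) >= whole_sd:
            kept.append((a, b))
        else:
            rejected.append((a, b))
    return kept, rejected


def select_baseline(
    events: list[tuple[int, int]], trace_len: int
) -> tuple[int, int]:
    """Longest event-free stretch (earliest on ties)."""
    edges = [0] + [e for ev in events for e in ev] + [trace_len]
    best: tuple[int, int] | None = None
    for i in range(0, len(edges), 2):
        a, b = edges[i], edges[i + 1]
        if b > a and (best is None or b - a > best[1] - best[0]):
            best = (a, b)
    if best is None:
        raise ValueError("no baseline found: events cover the whole trace")
    return best


def _merge_and_filter(
    events: list[tuple[int, int]], fs: float, cfg: RunConfig
) -> list[tuple[int, int]]:
    """Optional gap-merging and minimum-duration hooks (default off)."""
    if cfg.merge_gap_s > 0 and len(events) > 1:
        gap = cfg.merge_gap_s * fs
        merged = [events[0]]
        for a, b in events[1:]:
            if a - merged[-1][1] <= gap:
                merged[-1] = (merged[-1][0], b)
            else:
                merged.append((a, b))
        events = merged
    if cfg.min_event_s > 0:
        events = [(a, b) for a, b in events if b - a >= cfg.min_event_s * fs]
    return events


def detect_events_global(x: PreprocessedSignal,
                         cfg: RunConfig) -> DetectionResult:
    """Reference scheme: one whole-trace threshold per feature.

    Identical pipeline except the mixture is fitted once on the full
    trace instead of per 11-s segment, i.e. the classic global
    data-driven threshold.  Exists to demonstrate what segment-local
    adaptation buys on traces with non-stationary baseline.
    """
    trace_s = x.samples.size / x.fs
    return detect_events(x, cfg.replace(segment_len_s=trace_s + 1.0))


def detect_events(x: PreprocessedSignal, cfg: RunConfig) -> DetectionResult:
    """Full detection chain on one preprocessed channel."""
    env = hilbert_envelope(x.samples, x.fs)
    ste = short_time_energy(x.samples, x.fs, cfg.ste_window_s)

    thresholds: dict[str, list[SegmentThreshold]] = {}
    masks: dict[str, Mask] = {}
    for feat in (env, ste):
        try:
            thr = segment_thresholds(
                feat, cfg.segment_len_s, cfg.max_components, cfg.rng_seed
            )
        except ValueError as err:
            raise ValueError(f"thresholding ({feat.kind}): {err}") from err
        thresholds[feat.kind] = thr
        masks[feat.kind] = apply_thresholds(feat, thr)

    fused = fuse_masks(masks[env.kind], masks[ste.kind])
    masks["fused"] = fused

    candidates = mask_to_events(fused)
    candidates = _merge_and_filter(candidates, x.fs, cfg)
    kept, rejected = reject_artifacts(candidates, x)
    baseline = None
    try:
        baseline = select_baseline(kept, x.samples.size)
    except ValueError:
        pass  # pathological all-event trace; recorded as no baseline
    return DetectionResult(
        events=kept, masks=masks, thresholds=thresholds,
        baseline=baseline, fs=x.fs, rejected=rejected,
    )
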