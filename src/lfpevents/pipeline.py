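"""End-to-end per-channel analysis: preprocess, detect, quantify."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .detect import DetectionResult, detect_events
from .io_core import Recording, RunConfig
from .preprocess import PreprocessedSignal, preprocess
from .quantify import Event, build_event_table, quantify_events

__all__ = ["ChannelResult", "analyze_channel", "analyze_recording"]


@dataclass
class ChannelResult:
    channel_id: str
    signal: PreprocessedSignal
    detection: DetectionResult
    events: list[Event]
    table: pd.DataFrame


def analyze_channel(
    recording: Recording, channel: int, cfg: RunConfig,
    *, keep_psd: bool = False,
) -> ChannelResult:
    sig = preprocess(
        recording.channel(channel), recording.fs,
        cfg.lowpass_cutoff, cfg.filter_order, cfg.zero_phase,
    )
    det = detect_events(sig, cfg)
    events = quantify_events(
        sig, det, cfg.band_edges, nw=cfg.multitaper_nw,
        n_tapers=cfg.multitaper_k, keep_psd=keep_psd,
    )
    return ChannelResult(
        channel_id=str(recording.channel_ids[channel]),
        signal=sig, detection=det, events=events,
        table=build_event_table(events),
    )


def analyze_recording(
    recording: Recording, cfg: RunConfig,
    channels: list[int] | None = None,
    *, keep_psd: bool = False,
) -> list[ChannelResult]:
    if channels is None:
        channels = list(range(recording.n_channels))
    return [analyze_channel(recording, ch, cfg, keep_psd=keep_psd)
            for ch in channels]
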