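"""Recording input, run configuration and event-table output.

Recordings enter the pipeline either as delimited text (one column per
channel, optional header row) or as raw little-endian float binary with
the channel count supplied in the config.  Everything downstream works
in volts and seconds; amplitudes in the output tables are reported in
microvolts, the conventional unit for slice LFP work.
"""

from __future__ import annotations

import dataclasses
import datetime
import io
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "RunConfig",
    "DEFAULT_BANDS",
    "read_recording",
    "write_event_table",
    "read_event_table",
    "load_config",
    "EVENT_TABLE_COLUMNS",
]

#: Canonical frequency bands (Hz), half-open [lo, hi).  The two gamma
#: definitions overlap on purpose; both are always reported.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 100.0),
    "gamma_wide": (30.0, 120.0),
}

#: Bands used for the norm_total denominator sanity property (the five
#: canonical non-overlapping bands; gamma_wide overlaps gamma).
CANONICAL_BANDS = ("delta", "theta", "alpha", "beta", "gamma")


@dataclass(frozen=True)
class RunConfig:
    """Parameters steering one analysis run.

    All durations are seconds and converted to samples per trace, so 5 kHz
    and 10 kHz recordings are handled identically at native rate.
    """

    fs: float = 10_000.0
    lowpass_cutoff: float = 200.0
    filter_order: int = 3
    segment_len_s: float = 11.0
    ste_window_s: float = 0.05
    max_components: int = 2
    rng_seed: int = 0
    band_edges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )
    units_scale: float = 1.0
    zero_phase: bool = True
    #: Events the method targets last 0.3-8 s; threshold crossings much
    #: shorter than the short-time-energy window are noise-tail
    #: excursions whose local SD the artifact filter cannot separate
    #: from genuine events, so a floor below the physiological minimum
    #: removes them without touching anything in scope.
    min_event_s: float = 0.2
    merge_gap_s: float = 0.0
    multitaper_nw: float = 3.0
    multitaper_k: int = 5

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.lowpass_cutoff < self.fs / 2:
            raise ValueError(
                f"lowpass cutoff {self.lowpass_cutoff} Hz must be below the "
                f"Nyquist frequency {self.fs / 2} Hz"
            )
        if self.segment_len_s <= 0:
            raise ValueError("segment_len_s must be positive")
        if self.ste_window_s <= 0:
            raise ValueError("ste_window_s must be positive")
        if self.max_components < 1:
            raise ValueError("max_components must be >= 1")
        for name, (lo, hi) in self.band_edges.items():
            if not lo < hi:
                raise ValueError(f"band {name!r}: lo {lo} must be < hi {hi}")

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class Recording:
    """A multichannel voltage trace in volts.

    samples has shape (n_channels, n_samples); fs is in Hz.
    """

    samples: np.ndarray
    fs: float
    channel_ids: Sequence[str]
    units_scale: float = 1.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.size == 0:
            raise ValueError("no samples")
        bad = ~np.isfinite(self.samples)
        if bad.any():
            ch, idx = np.argwhere(bad)[0]
            raise ValueError(
                f"non-finite sample in channel {ch} at index {idx}"
            )
        if len(self.channel_ids) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_ids)} channel ids for "
                f"{self.samples.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, i: int) -> np.ndarray:
        return self.samples[i]


def read_recording(
    path: str | os.PathLike,
    config: RunConfig,
    *,
    n_channels: int | None = None,
    dtype: str = "float32",
) -> Recording:
    """Load a recording from delimited text or raw binary floats.

    Text files hold one column per channel, with an optional header row of
    channel names.  Binary files are flat little-endian float32/float64
    arrays; ``n_channels`` gives the reshape (sample-major: the file is
    read as ``n_channels`` equal consecutive blocks, one per channel).
    Samples are multiplied by ``config.units_scale`` to reach volts.
    """
    path = os.fspath(path)
    if path.endswith((".bin", ".raw", ".dat")):
        if n_channels is None:
            n_channels = 1
        raw = np.fromfile(path, dtype=np.dtype(dtype).newbyteorder("<"))
        if raw.size == 0:
            raise ValueError(f"{path}: no samples")
        if raw.size % n_channels:
            raise ValueError(
                f"{path}: {raw.size} values not divisible by "
                f"{n_channels} channels"
            )
        samples = raw.reshape(n_channels, -1).astype(float)
        ids = [str(i) for i in range(n_channels)]
    else:
        samples, ids = _read_delimited(path)
    samples = samples * config.units_scale
    return Recording(
        samples=samples, fs=config.fs, channel_ids=ids,
        units_scale=config.units_scale,
    )


def _read_delimited(path: str) -> tuple[np.ndarray, list[str]]:
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise ValueError(f"{path}: no samples")
    sep = None
    for cand in (",", "\t", ";"):
        if cand in first:
            sep = cand
            break
    header = 0
    try:
        [float(tok) for tok in first.strip().split(sep) if tok != ""]
        header = None
    except ValueError:
        header = 0
    df = pd.read_csv(path, sep=sep if sep else r"\s+", header=header,
                     engine="python")
    if df.empty:
        raise ValueError(f"{path}: no samples")
    arr = df.to_numpy(dtype=float).T
    bad = ~np.isfinite(arr)
    if bad.any():
        ch, idx = np.argwhere(bad)[0]
        raise ValueError(f"{path}: non-finite sample in channel "
                         f"{df.columns[ch]!r} at row {idx}")
    ids = [str(c) for c in df.columns]
    return arr, ids


# --- event table ---------------------------------------------------------

_BASE_COLUMNS = [
    "onset_s", "offset_s", "duration_s", "iei_s",
    "t_max_s", "v_max_uV", "t_min_s", "v_min_uV", "rect_area_Vs",
]


def _band_power_columns(bands: Sequence[str]) -> list[str]:
    cols = []
    for est in ("fourier", "multitaper"):
        for variant in ("raw", "bsub"):
            for norm in ("abs", "norm_total", "norm_max"):
                for b in bands:
                    cols.append(f"bp_{est}_{variant}_{norm}_{b}")
    return cols


EVENT_TABLE_COLUMNS = _BASE_COLUMNS + _band_power_columns(list(DEFAULT_BANDS))


def _validate_event_table(events: pd.DataFrame) -> None:
    if len(events) == 0:
        return
    on = events["onset_s"].to_numpy()
    off = events["offset_s"].to_numpy()
    if not (off > on).all():
        raise ValueError("event table has offset <= onset")
    if not (np.diff(on) >= 0).all():
        raise ValueError("event table rows not sorted by onset")
    if (on[1:] < off[:-1]).any():
        raise ValueError("event table has overlapping events")


def write_event_table(
    events: pd.DataFrame,
    path: str | os.PathLike,
    fmt: str = "csv",
    *,
    meta: Mapping[str, object] | None = None,
) -> None:
    """Write the per-event property table.

    CSV is the canonical artifact and preserves 12 significant digits so
    that a read-back reproduces every numeric field.  xlsx additionally
    carries a metadata sheet echoing the run configuration.
    """
    _validate_event_table(events)
    path = os.fspath(path)
    if fmt == "csv":
        events.to_csv(path, index=False, float_format="%.12g",
                      lineterminator="\n")
    elif fmt == "xlsx":
        with pd.ExcelWriter(path, engine="openpyxl") as xl:
            events.to_excel(xl, sheet_name="events", index=False)
            meta = dict(meta or {})
            meta.setdefault("written_utc",
                            datetime.datetime.now(datetime.UTC).isoformat())
            md = pd.DataFrame(
                {"key": list(meta), "value": [str(v) for v in meta.values()]}
            )
            md.to_excel(xl, sheet_name="metadata", index=False)
    else:
        raise ValueError(f"unknown format {fmt!r} (expected csv or xlsx)")


def read_event_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path)


def load_config(path: str | os.PathLike, **overrides) -> RunConfig:
    """Parse a flat ``key = value`` config file into a RunConfig.

    Band edges use keys like ``band.theta = 4,8``.  Keyword overrides win
    over file values (the CLI maps flags through here).
    """
    values: dict[str, object] = {}
    bands: dict[str, tuple[float, float]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, val = (s.strip() for s in line.split("=", 1))
            if key.startswith("band."):
                lo, hi = (float(x) for x in val.split(","))
                bands[key[5:]] = (lo, hi)
            else:
                values[key] = val
    kwargs: dict[str, object] = {}
    hints = {f.name: f.type for f in dataclasses.fields(RunConfig)}
    for key, val in values.items():
        if key not in hints:
            raise ValueError(f"unknown config key {key!r}")
        hint = str(hints[key])
        if "bool" in hint:
            kwargs[key] = str(val).strip().lower() in ("1", "true", "yes")
        elif "int" in hint:
            kwargs[key] = int(val)
        else:
            kwargs[key] = float(val)
    if bands:
        kwargs["band_edges"] = bands
    kwargs.update(overrides)
    return RunConfig(**kwargs)
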