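"""Per-event properties and band-limited spectral quantification.

For every detected event the table carries onset/offset/duration,
inter-event interval, extrema with their times, rectified area, and
band powers in the delta (1-4), theta (4-8), alpha (8-12), beta
(12-30), gamma (30-100) and wide-gamma (30-120 Hz) bands.  Spectra come
from two estimators -- a plain periodogram and a DPSS multitaper
average -- and each band power is reported raw and after subtraction of
the baseline-window spectrum, in three scalings: absolute (V^2),
normalized to the event's total power, and normalized to the largest
band.  Normalized variants make events of very different size and
duration directly comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import signal as sps

from .detect import DetectionResult
from .io_core import DEFAULT_BANDS, EVENT_TABLE_COLUMNS
from .preprocess import PreprocessedSignal

__all__ = [
    "Event",
    "basic_properties",
    "power_spectrum",
    "band_powers",
    "quantify_events",
    "build_event_table",
]

V_TO_UV = 1e6


@dataclass
class Event:
    onset_s: float
    offset_s: float
    duration_s: float
    t_max_s: float
    v_max_uV: float
    t_min_s: float
    v_min_uV: float
    rect_area_Vs: float
    iei_s: float = np.nan                # set across the event list
    band_powers: dict[str, float] = field(default_factory=dict)
    psd: dict[str, tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict)


def basic_properties(
    signal: PreprocessedSignal, interval: tuple[int, int]
) -> Event:
    """Amplitude/timing properties of one event (spectra added later).

    Extremum times are the first occurrence; the rectified area is
    sum(|v|) * dt, i.e. the discrete integral of the absolute voltage
    in V*s.
    """
    a, b = interval
    if b <= a:
        raise ValueError(f"empty event interval ({a}, {b})")
    seg = signal.samples[a:b]
    fs = signal.fs
    i_max = int(np.argmax(seg))
    i_min = int(np.argmin(seg))
    return Event(
        onset_s=a / fs,
        offset_s=b / fs,
        duration_s=(b - a) / fs,
        t_max_s=(a + i_max) / fs,
        v_max_uV=float(seg[i_max]) * V_TO_UV,
        t_min_s=(a + i_min) / fs,
        v_min_uV=float(seg[i_min]) * V_TO_UV,
        rect_area_Vs=float(np.abs(seg).sum()) / fs,
    )


def power_spectrum(
    segment: np.ndarray,
    fs: float,
    estimator: str = "fourier",
    *,
    nw: float = 3.0,
    n_tapers: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided PSD of a signal slice (V^2/Hz against Hz).

    ``fourier`` is the plain periodogram; ``multitaper`` averages
    eigenspectra over ``n_tapers`` discrete prolate spheroidal tapers
    of time-bandwidth ``nw``.  Detrending is mean removal only -- the
    input is already low-passed and globally zero-mean.  Both satisfy
    Parseval: integrating the PSD recovers the segment variance.
    """
    segment = np.asarray(segment, dtype=float)
    n = segment.size
    if n == 0:
        raise ValueError("zero-length segment")
    if n < 2 * fs:
        warnings.warn(
            f"segment of {n / fs:.3f} s gives coarse spectral resolution",
            stacklevel=2,
        )
    if estimator == "fourier":
        freqs, psd = sps.periodogram(segment, fs=fs, detrend="constant")
        return freqs, psd
    if estimator == "multitaper":
        x = segment - segment.mean()
        # dpss needs NW < n/2; clamp for very short events so the
        # estimator degrades gracefully instead of failing
        nw_eff = min(nw, max(0.5, (n - 1) / 2.0 - 1e-9))
        k = max(1, min(n_tapers, int(2 * nw_eff) - 1, n - 1))
        tapers = np.atleast_2d(sps.windows.dpss(n, nw_eff, Kmax=k))
        k = tapers.shape[0]
        freqs = np.fft.rfftfreq(n, d=1.0 / fs)
        psd = np.zeros(freqs.size)
        for t in tapers:
            spec = np.fft.rfft(t * x)
            # taper is unit-energy, so |X|^2/fs is a proper PSD estimate
            psd += (np.abs(spec) ** 2) / fs
        psd /= k
        # fold negative frequencies into the one-sided estimate
        psd[1:] *= 2.0
        if n % 2 == 0:
            psd[-1] /= 2.0
        return freqs, psd
    raise ValueError(f"unknown estimator {estimator!r}")


def _integrate_band(
    freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float
) -> float:
    """Integral of the PSD over [lo, hi) by the trapezoidal rule on the
    in-band grid points (half-open so a shared edge is counted once)."""
    sel = (freqs >= lo) & (freqs < hi)
    if sel.sum() < 2:
        # band narrower than the grid spacing: rectangle on what's there
        return float(psd[sel].sum() * (freqs[1] - freqs[0])) if sel.any() \
            else 0.0
    return float(np.trapezoid(psd[sel], freqs[sel]))


def band_powers(
    freqs: np.ndarray,
    psd: np.ndarray,
    bands: Mapping[str, tuple[float, float]] = DEFAULT_BANDS,
    baseline_psd: tuple[np.ndarray, np.ndarray] | None = None,
) -> dict[str, dict[str, float]]:
    """Band-power table for one PSD.

    Returns ``{"raw": {...}, "bsub": {...}}``; each inner dict maps
    ``"abs_<band>"``, ``"norm_total_<band>"`` and ``"norm_max_<band>"``
    to numbers.  For the baseline-subtracted (``bsub``) variant the
    baseline PSD is interpolated onto the event's frequency grid and
    the difference floored at zero before integration, keeping the
    result interpretable as a power.
    """
    out: dict[str, dict[str, float]] = {}
    variants: dict[str, np.ndarray] = {"raw": psd}
    if baseline_psd is not None:
        bfreqs, bpsd = baseline_psd
        interp = np.interp(freqs, bfreqs, bpsd, left=0.0, right=0.0)
        variants["bsub"] = np.maximum(psd - interp, 0.0)
    for name, p in variants.items():
        absolute = {b: _integrate_band(freqs, p, lo, hi)
                    for b, (lo, hi) in bands.items()}
        total = _integrate_band(freqs, p, 0.0, np.inf)
        peak = max(absolute.values()) if absolute else 0.0
        table: dict[str, float] = {}
        for b, val in absolute.items():
            table[f"abs_{b}"] = val
            table[f"norm_total_{b}"] = val / total if total > 0 else np.nan
            table[f"norm_max_{b}"] = val / peak if peak > 0 else np.nan
        out[name] = table
    return out


def quantify_events(
    signal: PreprocessedSignal,
    result: DetectionResult,
    bands: Mapping[str, tuple[float, float]] = DEFAULT_BANDS,
    *,
    nw: float = 3.0,
    n_tapers: int = 5,
    keep_psd: bool = False,
) -> list[Event]:
    """Full property set for every detected event.

    The inter-event interval is the gap from one event's offset to the
    next event's onset; the last event has none (NaN).  Baseline
    spectra come from the detection result's baseline window.
    """
    events = [basic_properties(signal, iv) for iv in result.events]
    for i in range(len(events) - 1):
        events[i].iei_s = events[i + 1].onset_s - events[i].offset_s

    baselines: dict[str, tuple[np.ndarray, np.ndarray] | None] = {}
    for est in ("fourier", "multitaper"):
        if result.baseline is not None:
            a, b = result.baseline
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                baselines[est] = power_spectrum(
                    signal.samples[a:b], signal.fs, est,
                    nw=nw, n_tapers=n_tapers)
        else:
            baselines[est] = None

    for ev, (a, b) in zip(events, result.events):
        seg = signal.samples[a:b]
        for est in ("fourier", "multitaper"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                freqs, psd = power_spectrum(seg, signal.fs, est,
                                            nw=nw, n_tapers=n_tapers)
            if keep_psd:
                ev.psd[est] = (freqs, psd)
            table = band_powers(freqs, psd, bands, baselines[est])
            for variant, cols in table.items():
                for key, val in cols.items():
                    # column name: bp_<est>_<variant>_<norm>_<band>
                    if key.startswith("abs_"):
                        col = f"bp_{est}_{variant}_abs_{key[4:]}"
                    elif key.startswith("norm_total_"):
                        col = f"bp_{est}_{variant}_norm_total_{key[11:]}"
                    else:
                        col = f"bp_{est}_{variant}_norm_max_{key[9:]}"
                    ev.band_powers[col] = val
    return events


def build_event_table(events: list[Event]) -> pd.DataFrame:
    """Assemble the canonical per-event DataFrame, one row per event."""
    rows = []
    for ev in events:
        row = {
            "onset_s": ev.onset_s,
            "offset_s": ev.offset_s,
            "duration_s": ev.duration_s,
            "iei_s": ev.iei_s,
            "t_max_s": ev.t_max_s,
            "v_max_uV": ev.v_max_uV,
            "t_min_s": ev.t_min_s,
            "v_min_uV": ev.v_min_uV,
            "rect_area_Vs": ev.rect_area_Vs,
        }
        row.update(ev.band_powers)
        rows.append(row)
    df = pd.DataFrame(rows, columns=EVENT_TABLE_COLUMNS if rows else
                      EVENT_TABLE_COLUMNS)
    return df
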