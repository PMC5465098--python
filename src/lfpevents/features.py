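"""The two feature sequences: Hilbert envelope and short-time energy.

Both transforms map the preprocessed trace onto non-negative per-sample
sequences on the same time base, so the downstream per-segment
thresholding can build one boolean mask per feature and fuse them.

The Hilbert envelope |H(u(t))| tracks the slow-varying amplitude of a
narrow-band signal and is computed over the whole trace at once (only
the thresholding is segment-local) to avoid boundary artifacts.

Short-time energy is the speech-processing activity feature

    E(i) = (1/N) * sum_n |u_i(n)|^2

over consecutive non-overlapping windows of N samples; the final
partial window is averaged over its own length.  The piecewise-constant
energy sequence is expanded back to per-sample resolution by step
repetition (not interpolation), which preserves threshold ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = ["FeatureSignal", "hilbert_envelope", "short_time_energy"]

HILBERT_ENV = "hilbert_env"
SHORT_TIME_ENERGY = "short_time_energy"


@dataclass
class FeatureSignal:
    kind: str                 # "hilbert_env" | "short_time_energy"
    values: np.ndarray        # per-sample, >= 0, same length as input
    fs: float                 # Hz of the per-sample grid
    window_s: float | None = None   # STE only


def hilbert_envelope(x: np.ndarray, fs: float) -> FeatureSignal:
    """Modulus of the analytic signal of ``x``."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("trace too short for the Hilbert transform")
    env = np.abs(sps.hilbert(x))
    return FeatureSignal(kind=HILBERT_ENV, values=env, fs=fs)


def short_time_energy(
    x: np.ndarray, fs: float, window_s: float = 0.05
) -> FeatureSignal:
    """Mean squared amplitude per non-overlapping window, step-expanded.

    ``window_s`` is not fixed by the method itself; 50 ms (speech
    practice uses 10-50 ms) resolves sub-second events while smoothing
    content up to the 200 Hz passband edge.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 1:
        raise ValueError("empty trace")
    n_win = int(round(window_s * fs))
    if n_win < 1:
        raise ValueError(
            f"window of {window_s} s spans no samples at fs={fs} Hz"
        )
    if n_win > x.size:
        n_win = x.size  # single-window degenerate case
    n_full = x.size // n_win
    sq = x * x
    values = np.empty_like(x)
    if n_full:
        e_full = sq[: n_full * n_win].reshape(n_full, n_win).mean(axis=1)
        values[: n_full * n_win] = np.repeat(e_full, n_win)
    rem = x.size - n_full * n_win
    if rem:
        values[n_full * n_win:] = sq[n_full * n_win:].mean()
    return FeatureSignal(kind=SHORT_TIME_ENERGY, values=values, fs=fs,
                         window_s=n_win / fs)
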