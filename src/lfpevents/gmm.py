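"""Unsupervised 1-D Gaussian mixtures with MML model selection.

Per 11-s segment of each feature signal we fit a Gaussian mixture

    p(x | lambda) = sum_i w_i g(x | mu_i, sigma2_i)

by expectation-maximization, letting a minimum-message-length (MML)
criterion choose the number of components: EM starts from the maximum
allowed count and annihilates components whose estimated support cannot
pay for their parameter cost, in the Figueiredo-Jain fashion.  The
message length minimized is

    L = (P/2) * sum_m log(n w_m / 12)
        + (k/2) * log(n / 12) + k (P + 1) / 2 - loglik

with P = 2 free parameters per univariate component and k the number of
surviving components.  After convergence at each surviving count the
candidate is scored, the lightest component is then forcibly removed,
and the minimum-L candidate over all counts is returned.  With a
two-component winner the baseline/event decision boundary is the Bayes
threshold: the root of w_1 g_1(x) = w_2 g_2(x) between the two means.

A one-component winner means the segment is baseline throughout; the
segment is then flagged event-free (sentinel: an infinite threshold, so
a strict > comparison yields an all-zero mask with no special-casing).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .features import FeatureSignal

__all__ = [
    "GmmFit",
    "SegmentThreshold",
    "EVENT_FREE",
    "fit_gmm_mml",
    "bayes_threshold",
    "segment_thresholds",
    "segment_bounds",
]

#: Sentinel threshold for a segment declared baseline throughout.
EVENT_FREE = math.inf

_LOG_2PI = math.log(2.0 * math.pi)
_N_PARAMS = 2  # mean + variance per univariate component


@dataclass
class GmmFit:
    """A fitted 1-D Gaussian mixture, components sorted by mean."""

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    message_length: float
    converged: bool
    n_iter: int
    loglik: float

    @property
    def M(self) -> int:
        return len(self.weights)


@dataclass
class SegmentThreshold:
    segment_index: int
    feature_kind: str
    threshold: float          # EVENT_FREE when no event/baseline split
    start: int                # sample index, inclusive
    stop: int                 # sample index, exclusive
    fit: GmmFit | None

    @property
    def event_free(self) -> bool:
        return not math.isfinite(self.threshold)


def _log_gauss(x: np.ndarray, mean: float, var: float) -> np.ndarray:
    return -0.5 * (_LOG_2PI + math.log(var) + (x - mean) ** 2 / var)


def _em(
    x: np.ndarray,
    obs_w: np.ndarray,
    w: np.ndarray,
    mu: np.ndarray,
    var: np.ndarray,
    *,
    annihilate: bool,
    var_floor: float,
    tol: float = 1e-7,
    max_iter: int = 500,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, bool, int, list[float]]:
    """EM loop; with ``annihilate`` the Figueiredo-Jain weight update
    max(0, n_m - P/2) kills unsupported components in place."""
    n_eff = obs_w.sum()
    prev_ll = -np.inf
    ll = -np.inf
    ll_path: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step
        logp = np.stack([
            math.log(w[m]) + _log_gauss(x, mu[m], var[m])
            for m in range(len(w))
        ])
        mx = logp.max(axis=0)
        lse = mx + np.log(np.exp(logp - mx).sum(axis=0))
        ll = float((obs_w * lse).sum())
        ll_path.append(ll)
        resp = np.exp(logp - lse)

        # M-step
        n_m = (resp * obs_w).sum(axis=1)
        if annihilate:
            support = np.maximum(0.0, n_m - _N_PARAMS / 2.0)
            if support.sum() <= 0:
                support = n_m  # all components starving: keep the plain EM step
            keep = support > 0
            if not keep.all():
                w, mu, var = w[keep], mu[keep], var[keep]
                resp, n_m, support = resp[keep], n_m[keep], support[keep]
                prev_ll = -np.inf  # model changed; restart convergence check
            w = support / support.sum()
        else:
            w = n_m / n_eff
        n_m = np.maximum(n_m, 1e-300)
        mu = (resp * obs_w * x).sum(axis=1) / n_m
        var = (resp * obs_w * (x - mu[:, None]) ** 2).sum(axis=1) / n_m
        var = np.maximum(var, var_floor)

        if prev_ll > -np.inf and abs(ll - prev_ll) <= tol * abs(prev_ll):
            converged = True
            break
        prev_ll = ll
    return w, mu, var, ll, converged, it, ll_path


def _message_length(w: np.ndarray, n_eff: float, ll: float) -> float:
    k = len(w)
    return (
        (_N_PARAMS / 2.0) * float(np.log(n_eff * w / 12.0).sum())
        + (k / 2.0) * math.log(n_eff / 12.0)
        + k * (_N_PARAMS + 1) / 2.0
        - ll
    )


def _sorted_fit(w, mu, var, ml, converged, it, ll) -> GmmFit:
    order = np.argsort(mu)
    return GmmFit(
        weights=np.asarray(w, dtype=float)[order],
        means=np.asarray(mu, dtype=float)[order],
        variances=np.asarray(var, dtype=float)[order],
        message_length=float(ml),
        converged=bool(converged),
        n_iter=int(it),
        loglik=float(ll),
    )


def fit_gmm_mml(
    values: np.ndarray,
    max_components: int = 2,
    seed: int = 0,
    *,
    force_m: int | None = None,
    weights: np.ndarray | None = None,
    return_ll_path: bool = False,
):
    """Fit a 1-D Gaussian mixture, selecting the component count by MML.

    Parameters
    ----------
    values
        1-D sample (feature values of one segment, or e.g. event
        durations).  Must be finite.
    max_components
        Upper bound on the component count; the MML annihilation loop
        reduces it.
    seed
        Accepted for interface stability; the quantile-based
        initialization is already deterministic, so the result depends
        only on the data.
    force_m
        Fit exactly this many components (plain EM, no selection); used
        when a distribution is known to be bimodal.
    weights
        Optional per-observation weights (e.g. histogram counts when
        fitting bin centers instead of raw samples).
    """
    x = np.asarray(values, dtype=float).ravel()
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in GMM input")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if weights is None:
        obs_w = np.ones_like(x)
    else:
        obs_w = np.asarray(weights, dtype=float).ravel()
        if obs_w.shape != x.shape or (obs_w < 0).any():
            raise ValueError("weights must be non-negative, same shape")
    n_eff = float(obs_w.sum())
    gvar = float(np.average((x - np.average(x, weights=obs_w)) ** 2,
                            weights=obs_w))
    if gvar <= 0:
        raise ValueError("degenerate sample: zero variance")
    var_floor = max(gvar * 1e-10, 1e-300)

    m0 = int(force_m) if force_m is not None else int(max_components)
    if m0 < 1:
        raise ValueError("component count must be >= 1")

    # Quantile initialization: deterministic, robust in 1-D.
    qs = (np.arange(m0) + 0.5) / m0
    mu = np.quantile(x, qs) if weights is None else _weighted_quantile(
        x, obs_w, qs)
    mu = mu + np.linspace(0, 1e-6 * math.sqrt(gvar), m0)  # break exact ties
    var = np.full(m0, gvar / max(m0, 1))
    w = np.full(m0, 1.0 / m0)

    if force_m is not None:
        w, mu, var, ll, conv, it, path = _em(
            x, obs_w, w, mu, var, annihilate=False, var_floor=var_floor)
        fit = _sorted_fit(w, mu, var, _message_length(w, n_eff, ll),
                          conv, it, ll)
        return (fit, path) if return_ll_path else fit

    best: GmmFit | None = None
    full_path: list[float] = []
    while True:
        w, mu, var, ll, conv, it, path = _em(
            x, obs_w, w, mu, var, annihilate=True, var_floor=var_floor)
        full_path.extend(path)
        cand = _sorted_fit(w, mu, var, _message_length(w, n_eff, ll),
                           conv, it, ll)
        if best is None or cand.message_length < best.message_length:
            best = cand
        if len(w) <= 1:
            break
        # force-annihilate the lightest component, re-converge smaller model
        drop = int(np.argmin(w))
        keep = np.ones(len(w), dtype=bool)
        keep[drop] = False
        w, mu, var = w[keep], mu[keep], var[keep]
        w = w / w.sum()
    if not best.converged:
        warnings.warn("GMM EM hit the iteration cap; returning best fit",
                      stacklevel=2)
    return (best, full_path) if return_ll_path else best


def mixture_is_bimodal(fit: GmmFit, n_grid: int = 4001) -> bool:
    """Whether the fitted mixture density itself shows two peaks.

    A two-component fit can merely be describing the skew of a
    unimodal sample (the envelope of pure noise is Rayleigh-like, and
    window energies are chi-square-like): the components then overlap
    so much that the summed density has no interior dip.  Only a
    density with a genuine local minimum between the component means
    supports a baseline/event split, so this check backs the
    one-peak-means-event-free rule.
    """
    if fit.M < 2:
        return False
    lo = fit.means[0] - 3 * math.sqrt(fit.variances[0])
    hi = fit.means[-1] + 3 * math.sqrt(fit.variances[-1])
    grid = np.linspace(lo, hi, n_grid)
    pdf = np.zeros(n_grid)
    for w, m, v in zip(fit.weights, fit.means, fit.variances):
        pdf += w * np.exp(_log_gauss(grid, m, v))
    d = np.diff(np.sign(np.diff(pdf)))
    return int((d > 0).sum()) >= 1   # at least one interior local minimum


def _weighted_quantile(x: np.ndarray, w: np.ndarray,
                       qs: np.ndarray) -> np.ndarray:
    order = np.argsort(x)
    xs, ws = x[order], w[order]
    cum = np.cumsum(ws) - 0.5 * ws
    cum /= ws.sum()
    return np.interp(qs, cum, xs)


def bayes_threshold(fit: GmmFit) -> float:
    """Decision boundary between the two components of a fitted mixture.

    Solves w1*g(x|mu1,v1) = w2*g(x|mu2,v2), a quadratic in x; among real
    roots the one inside (mu1, mu2) is preferred (smaller root on ties).
    If no root lands in that interval -- extreme weight or variance
    imbalance -- a posterior scan at 1e-4*(mu2-mu1) resolution finds the
    point where the two weighted densities are closest.
    """
    if fit.M != 2:
        raise ValueError(f"Bayes threshold needs M=2, got M={fit.M}")
    (w1, w2) = fit.weights
    (m1, m2) = fit.means
    (v1, v2) = fit.variances
    if not m1 < m2:
        raise ValueError("component means must be distinct and sorted")

    # log(w1 g1) - log(w2 g2) = a x^2 + b x + c
    a = 0.5 * (1.0 / v2 - 1.0 / v1)
    b = m1 / v1 - m2 / v2
    c = (
        0.5 * (m2 ** 2 / v2 - m1 ** 2 / v1)
        + math.log(w1) - math.log(w2)
        + 0.5 * math.log(v2 / v1)
    )
    roots: list[float] = []
    if abs(a) < 1e-300:
        if b != 0.0:
            roots = [-c / b]
    else:
        disc = b * b - 4 * a * c
        if disc >= 0:
            sq = math.sqrt(disc)
            roots = sorted([(-b - sq) / (2 * a), (-b + sq) / (2 * a)])
    inside = [r for r in roots if m1 < r < m2]
    if inside:
        return float(min(inside))

    # fallback: scan the posterior for the closest-to-equal point
    grid = np.linspace(m1, m2, 10_001)[1:-1]
    diff = (
        math.log(w1) + _log_gauss(grid, m1, v1)
        - math.log(w2) - _log_gauss(grid, m2, v2)
    )
    sign_change = np.nonzero(np.diff(np.sign(diff)) != 0)[0]
    if sign_change.size:
        i = int(sign_change[0])
        # linear interpolation of the zero crossing
        x0, x1 = grid[i], grid[i + 1]
        y0, y1 = diff[i], diff[i + 1]
        return float(x0 - y0 * (x1 - x0) / (y1 - y0))
    return float(grid[int(np.argmin(np.abs(diff)))])


def segment_bounds(
    n_samples: int, fs: float, segment_len_s: float = 11.0,
    min_tail_s: float = 2.0,
) -> list[tuple[int, int]]:
    """Half-open sample bounds of the analysis segments.

    Segments are non-overlapping and ``segment_len_s`` long; a trailing
    partial segment of at least ``min_tail_s`` stands alone, a shorter
    tail is merged into the previous segment (a tiny tail cannot
    support a two-component fit).
    """
    seg = int(round(segment_len_s * fs))
    if seg < 1:
        raise ValueError("segment shorter than one sample")
    if n_samples <= seg:
        return [(0, n_samples)]
    bounds = [(s, min(s + seg, n_samples)) for s in range(0, n_samples, seg)]
    tail = bounds[-1][1] - bounds[-1][0]
    if len(bounds) > 1 and tail < min_tail_s * fs:
        bounds[-2] = (bounds[-2][0], bounds[-1][1])
        bounds.pop()
    return bounds


def segment_thresholds(
    feature: FeatureSignal,
    segment_len_s: float = 11.0,
    max_components: int = 2,
    seed: int = 0,
    *,
    max_points_per_segment: int = 20_000,
) -> list[SegmentThreshold]:
    """One adaptive threshold per segment of a feature signal.

    Each segment's feature values are fitted with the MML mixture; a
    one-component winner, a degenerate segment, or a threshold above
    the segment maximum all mark the segment event-free.  Long segments
    are stride-decimated to at most ``max_points_per_segment`` values
    before the fit (deterministic, order-preserving).
    """
    values = np.asarray(feature.values, dtype=float)
    out: list[SegmentThreshold] = []
    for si, (start, stop) in enumerate(
        segment_bounds(values.size, feature.fs, segment_len_s)
    ):
        seg = values[start:stop]
        step = max(1, int(np.ceil(seg.size / max_points_per_segment)))
        sub = seg[::step]
        thr = EVENT_FREE
        fit: GmmFit | None = None
        if sub.size >= 50 and np.ptp(sub) > 0 and float(np.var(sub)) > 0:
            try:
                fit = fit_gmm_mml(sub, max_components, seed)
            except ValueError as err:
                raise ValueError(f"segment {si}: {err}") from err
            if fit.M >= 2 and mixture_is_bimodal(fit):
                t = bayes_threshold(_top_two(fit))
                if t <= seg.max():
                    thr = t
        elif sub.size < 50:
            warnings.warn(
                f"segment {si}: fewer than 50 samples, declared event-free",
                stacklevel=2,
            )
        out.append(SegmentThreshold(
            segment_index=si, feature_kind=feature.kind, threshold=thr,
            start=start, stop=stop, fit=fit,
        ))
    return out


def _top_two(fit: GmmFit) -> GmmFit:
    """Reduce a fit to its lowest- and highest-mean components
    (max_components is 2 in the detection pipeline, so this is almost
    always the identity)."""
    if fit.M == 2:
        return fit
    idx = [0, fit.M - 1]
    w = fit.weights[idx]
    return GmmFit(
        weights=w / w.sum(), means=fit.means[idx],
        variances=fit.variances[idx],
        message_length=fit.message_length, converged=fit.converged,
        n_iter=fit.n_iter, loglik=fit.loglik,
    )
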