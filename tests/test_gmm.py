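"""Mixture fitting, MML model selection and the Bayes threshold."""

import math

import numpy as np
import pytest

import lfpevents as lfp
from lfpevents.features import FeatureSignal
from lfpevents.gmm import (GmmFit, bayes_threshold, fit_gmm_mml,
                           mixture_is_bimodal, segment_bounds,
                           segment_thresholds)


def make_fit(w, mu, var):
    return GmmFit(weights=np.asarray(w, float), means=np.asarray(mu, float),
                  variances=np.asarray(var, float), message_length=0.0,
                  converged=True, n_iter=1, loglik=0.0)


def scan_threshold(w, mu, var, resolution=1e-6):
    """Brute-force root of w1 g1 = w2 g2 on a dense grid in (mu1, mu2)."""
    grid = np.arange(mu[0], mu[1], resolution * (mu[1] - mu[0]) * 1e4)
    # refine around the coarse sign change with the requested resolution
    def diff(x):
        return (math.log(w[0]) - 0.5 * math.log(var[0])
                - (x - mu[0]) ** 2 / (2 * var[0])
                - math.log(w[1]) + 0.5 * math.log(var[1])
                + (x - mu[1]) ** 2 / (2 * var[1]))
    d = np.array([diff(x) for x in grid])
    sc = np.nonzero(np.diff(np.sign(d)))[0]
    assert sc.size, "no sign change on coarse grid"
    lo, hi = grid[sc[0]], grid[sc[0] + 1]
    fine = np.arange(lo, hi, resolution)
    df = np.array([diff(x) for x in fine])
    i = int(np.argmin(np.abs(df)))
    return float(fine[i])


class TestFitGmmMml:
    def test_single_gaussian_recovers_m1(self):
        x = np.random.default_rng(0).normal(0.0, 1.0, 5000)
        fit = fit_gmm_mml(x, max_components=2, seed=0)
        assert fit.M == 1
        assert abs(fit.means[0]) < 0.05
        assert abs(fit.variances[0] - 1.0) < 0.05

    def test_two_component_recovery(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(0, 1, 2000), rng.normal(6, 1, 3000)])
        fit = fit_gmm_mml(x, max_components=2, seed=0)
        assert fit.M == 2
        np.testing.assert_allclose(fit.weights, [0.4, 0.6], atol=0.03)
        np.testing.assert_allclose(fit.means, [0.0, 6.0], atol=0.1)

    def test_constant_sample_rejected_as_degenerate(self):
        with pytest.raises(ValueError, match="zero variance"):
            fit_gmm_mml(np.full(100, 3.0), 2, 0)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            fit_gmm_mml(np.array([1.0, np.nan, 2.0] * 30), 2, 0)

    def test_loglik_monotone_within_em(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(0, 1, 500), rng.normal(5, 1, 500)])
        _, path = fit_gmm_mml(x, 2, 0, force_m=2, return_ll_path=True)
        diffs = np.diff(path)
        assert (diffs >= -1e-8 * np.abs(path[:-1])).all()

    def test_deterministic_given_data(self):
        x = np.random.default_rng(3).normal(size=2000)
        a = fit_gmm_mml(x, 2, seed=0)
        b = fit_gmm_mml(x, 2, seed=0)
        assert np.array_equal(a.weights, b.weights)
        assert np.array_equal(a.means, b.means)
        assert np.array_equal(a.variances, b.variances)
        assert a.message_length == b.message_length

    def test_weights_sum_to_one_and_sorted_means(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(-2, 0.5, 1000),
                            rng.normal(3, 1.0, 1000)])
        fit = fit_gmm_mml(x, 2, 0)
        assert abs(fit.weights.sum() - 1.0) < 1e-9
        assert (np.diff(fit.means) >= 0).all()
        assert (fit.variances > 0).all()
        assert math.isfinite(fit.message_length)

    def test_histogram_weighted_fit_agrees_on_threshold(self):
        """Binned EM (counts as weights) lands within 2% of the raw fit."""
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(0, 1, 4000), rng.normal(6, 1, 2000)])
        raw = fit_gmm_mml(x, 2, 0)
        counts, edges = np.histogram(x, bins=256)
        centers = (edges[:-1] + edges[1:]) / 2
        keep = counts > 0
        binned = fit_gmm_mml(centers[keep], 2, 0, weights=counts[keep])
        assert raw.M == binned.M == 2
        t_raw = bayes_threshold(raw)
        t_bin = bayes_threshold(binned)
        assert t_bin == pytest.approx(t_raw, rel=0.02)


class TestBayesThreshold:
    def test_symmetric_midpoint(self):
        fit = make_fit([0.5, 0.5], [0.0, 6.0], [1.0, 1.0])
        assert bayes_threshold(fit) == pytest.approx(3.0, abs=1e-12)

    @pytest.mark.parametrize("w, mu, var", [
        ((0.9, 0.1), (0.0, 6.0), (1.0, 1.0)),
        ((0.5, 0.5), (0.0, 6.0), (1.0, 4.0)),
        ((0.7, 0.3), (-1.0, 4.0), (0.5, 2.0)),
    ])
    def test_matches_posterior_scan_oracle(self, w, mu, var):
        fit = make_fit(w, mu, var)
        got = bayes_threshold(fit)
        expect = scan_threshold(w, mu, var)
        assert abs(got - expect) <= 1e-4 * (mu[1] - mu[0])
        assert mu[0] < got < mu[1]

    def test_rejects_single_component(self):
        fit = make_fit([1.0], [0.0], [1.0])
        with pytest.raises(ValueError, match="M=2"):
            bayes_threshold(fit)


class TestModelSelectionRates:
    """Selection must be nearly always right at generous separation."""

    def test_rates_over_replicates(self):
        n_rep = 30
        m1_hits = 0
        m2_hits = 0
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            if fit_gmm_mml(rng.normal(0, 1, 5000), 2, seed).M == 1:
                m1_hits += 1
            x = np.concatenate([rng.normal(0, 1, 2000),
                                rng.normal(6, 1, 3000)])
            if fit_gmm_mml(x, 2, seed).M == 2:
                m2_hits += 1
        assert m1_hits >= math.ceil(0.95 * n_rep)
        assert m2_hits >= math.ceil(0.95 * n_rep)


class TestSegmentThresholds:
    def test_33s_trace_gives_three_segments(self):
        bounds = segment_bounds(33_000, fs=1000.0, segment_len_s=11.0)
        assert bounds == [(0, 11_000), (11_000, 22_000), (22_000, 33_000)]

    def test_short_tail_merges_backward(self):
        bounds = segment_bounds(23_000, fs=1000.0, segment_len_s=11.0)
        assert bounds == [(0, 11_000), (11_000, 23_000)]

    def test_long_tail_stands_alone(self):
        bounds = segment_bounds(25_000, fs=1000.0, segment_len_s=11.0)
        assert bounds[-1] == (22_000, 25_000)

    def test_pure_noise_every_segment_event_free(self):
        rec, _ = lfp.generate(lfp.SynthSpec(seed=11, duration_s=60.0,
                                            n_events=0))
        sig = lfp.preprocess(rec.channel(0), rec.fs)
        env = lfp.hilbert_envelope(sig.samples, sig.fs)
        thrs = segment_thresholds(env)
        assert all(t.event_free for t in thrs)

    def test_burst_segment_gets_threshold_between_modes(self, synth_run):
        sig = synth_run["sig"]
        env = lfp.hilbert_envelope(sig.samples, sig.fs)
        thrs = segment_thresholds(env)
        finite = [t for t in thrs if not t.event_free]
        assert finite, "no segment produced a threshold"
        for t in finite:
            assert t.fit.means[0] < t.threshold < t.fit.means[-1]

    def test_unimodal_two_component_fit_is_not_bimodal(self):
        fit = make_fit([0.5, 0.5], [0.0, 1.0], [1.0, 1.0])
        assert not mixture_is_bimodal(fit)
        fit2 = make_fit([0.5, 0.5], [0.0, 6.0], [1.0, 1.0])
        assert mixture_is_bimodal(fit2)

    def test_tiny_segment_declared_event_free(self):
        feat = FeatureSignal(kind="hilbert_env",
                             values=np.abs(np.random.default_rng(0)
                                           .normal(size=40)),
                             fs=4.0)
        with pytest.warns(UserWarning, match="fewer than 50"):
            thrs = segment_thresholds(feat, segment_len_s=11.0)
        assert all(t.event_free for t in thrs)
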