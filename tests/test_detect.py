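"""Mask logic, artifact rejection, baseline selection, end-to-end."""

import numpy as np
import pytest

import lfpevents as lfp
from lfpevents.detect import (Mask, apply_thresholds, detect_events,
                              fuse_masks, mask_to_events, reject_artifacts,
                              select_baseline)
from lfpevents.features import FeatureSignal
from lfpevents.gmm import EVENT_FREE, SegmentThreshold

from conftest import make_signal


def _feat(values, kind="hilbert_env", fs=1.0):
    return FeatureSignal(kind=kind, values=np.asarray(values, float), fs=fs)


def _thr(value, start, stop, kind="hilbert_env", idx=0):
    return SegmentThreshold(segment_index=idx, feature_kind=kind,
                            threshold=value, start=start, stop=stop,
                            fit=None)


class TestApplyThresholds:
    def test_event_free_segments_give_zero_mask(self):
        feat = _feat([5.0] * 10)
        mask = apply_thresholds(feat, [_thr(EVENT_FREE, 0, 10)])
        assert not mask.values.any()

    def test_constant_above_threshold_all_ones(self):
        feat = _feat([5.0] * 10)
        mask = apply_thresholds(feat, [_thr(3.0, 0, 10)])
        assert mask.values.all()

    def test_step_flips_exactly_at_step(self):
        feat = _feat([0.0] * 5 + [10.0] * 5)
        mask = apply_thresholds(feat, [_thr(5.0, 0, 10)])
        np.testing.assert_array_equal(mask.values,
                                      [False] * 5 + [True] * 5)

    def test_strict_comparison_keeps_plateau_as_baseline(self):
        feat = _feat([3.0] * 4)
        mask = apply_thresholds(feat, [_thr(3.0, 0, 4)])
        assert not mask.values.any()

    def test_coverage_gap_rejected(self):
        feat = _feat([1.0] * 10)
        with pytest.raises(ValueError, match="cover"):
            apply_thresholds(feat, [_thr(0.5, 0, 5)])


class TestFuseMasks:
    def test_or_with_zero_is_identity(self):
        a = Mask(np.array([1, 0, 1, 0], bool), "hilbert_env")
        z = Mask(np.zeros(4, bool), "short_time_energy")
        np.testing.assert_array_equal(fuse_masks(a, z).values, a.values)

    def test_idempotent(self):
        a = Mask(np.array([1, 0, 1, 1], bool), "hilbert_env")
        np.testing.assert_array_equal(fuse_masks(a, a).values, a.values)

    def test_disjoint_runs_union(self):
        a = Mask(np.array([1, 1, 0, 0, 0], bool), "hilbert_env")
        b = Mask(np.array([0, 0, 0, 1, 1], bool), "short_time_energy")
        fused = fuse_masks(a, b)
        assert fused.source == "fused"
        assert mask_to_events(fused) == [(0, 2), (3, 5)]

    def test_length_mismatch_rejected(self):
        a = Mask(np.zeros(4, bool), "hilbert_env")
        b = Mask(np.zeros(5, bool), "short_time_energy")
        with pytest.raises(ValueError, match="mismatch"):
            fuse_masks(a, b)


@pytest.mark.parametrize("bits, expected", [
    ([0, 0, 0, 1, 1, 1, 0], [(3, 6)]),
    ([0, 0, 0, 0], []),
    ([1, 1, 1, 1, 1], [(0, 5)]),
    ([1, 0, 1], [(0, 1), (2, 3)]),
])
def test_mask_to_events_runs(bits, expected):
    mask = Mask(np.array(bits, bool), "fused")
    assert mask_to_events(mask) == expected


class TestRejectArtifacts:
    def test_constant_event_excluded(self, rng):
        x = rng.normal(size=1000)
        x[100:200] = 5.0  # flat plateau: SD 0
        kept, rejected = reject_artifacts([(100, 200)], make_signal(x, 1000))
        assert kept == [] and rejected == [(100, 200)]

    def test_large_burst_kept(self, rng):
        x = rng.normal(0, 1.0, 10_000)
        x[4000:5000] += 10.0 * np.sin(np.linspace(0, 60, 1000))
        kept, _ = reject_artifacts([(4000, 5000)], make_signal(x, 1000))
        assert kept == [(4000, 5000)]

    def test_empty_list(self, rng):
        kept, rejected = reject_artifacts([], make_signal(rng.normal(size=10),
                                                          10))
        assert kept == [] and rejected == []


class TestSelectBaseline:
    def test_no_events_full_trace(self):
        assert select_baseline([], 1000) == (0, 1000)

    def test_earliest_longest_gap_wins(self):
        # gaps are (0,10)=10, (20,25)=5, (100,110)=10 -> earliest tie
        assert select_baseline([(10, 20), (25, 100)], 110) == (0, 10)

    def test_event_covering_trace_is_an_error(self):
        with pytest.raises(ValueError, match="no baseline"):
            select_baseline([(0, 50)], 50)


class TestDetectEvents:
    def test_pure_noise_no_events_baseline_full(self):
        rec, _ = lfp.generate(lfp.SynthSpec(seed=5, duration_s=60.0,
                                            n_events=0))
        sig = lfp.preprocess(rec.channel(0), rec.fs)
        res = detect_events(sig, lfp.RunConfig(fs=rec.fs))
        assert res.events == []
        assert res.baseline == (0, sig.samples.size)

    def test_constant_zero_trace_no_events(self):
        sig = make_signal(np.zeros(30_000), 1000.0)
        res = detect_events(sig, lfp.RunConfig(fs=1000.0))
        assert res.events == []

    def test_all_planted_bursts_recovered(self, synth_run):
        score = lfp.score_detection(synth_run["truth"], synth_run["det"])
        assert score.recall == 1.0
        assert score.precision == 1.0
        assert np.median(np.abs(score.onset_errors_s)) <= 0.05

    def test_planted_events_pass_sd_filter(self, synth_run):
        sig, det = synth_run["sig"], synth_run["det"]
        whole_sd = sig.samples.std()
        for a, b in det.events:
            assert sig.samples[a:b].std() >= whole_sd

    def test_fused_mask_superset_of_parts(self, synth_run):
        masks = synth_run["det"].masks
        fused = masks["fused"].values
        assert (fused | masks["hilbert_env"].values == fused).all()
        assert (fused | masks["short_time_energy"].values == fused).all()

    def test_events_interior_within_fused_mask(self, synth_run):
        det = synth_run["det"]
        fused = det.masks["fused"].values
        for a, b in det.events:
            assert fused[a:b].all()

    def test_events_sorted_disjoint_inside_trace(self, synth_run):
        det = synth_run["det"]
        n = synth_run["sig"].samples.size
        prev_end = 0
        for a, b in det.events:
            assert 0 <= a < b <= n
            assert a >= prev_end
            prev_end = b

    def test_baseline_intersects_no_event(self, synth_run):
        det = synth_run["det"]
        a, b = det.baseline
        for ea, eb in det.events:
            assert eb <= a or ea >= b

    def test_recall_monotone_in_snr(self):
        """Recall is non-decreasing along a 3-point amplitude ladder."""
        recalls = []
        for amp in (30e-6, 60e-6, 120e-6):
            spec = lfp.SynthSpec(seed=21, duration_s=60.0, n_events=4,
                                 event_amplitude_v=amp)
            rec, truth = lfp.generate(spec)
            sig = lfp.preprocess(rec.channel(0), rec.fs)
            res = detect_events(sig, lfp.RunConfig(fs=rec.fs, rng_seed=21))
            recalls.append(lfp.score_detection(truth, res).recall)
        assert recalls == sorted(recalls)

    def test_deterministic(self, synth_run):
        sig, cfg = synth_run["sig"], synth_run["cfg"]
        again = detect_events(sig, cfg)
        assert again.events == synth_run["det"].events
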