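import numpy as np
import pytest

import lfpevents as lfp


@pytest.fixture(scope="session")
def synth_run():
    """One standard synthetic trace analyzed end to end (shared)."""
    spec = lfp.SynthSpec(seed=7)
    rec, truth = lfp.generate(spec)
    cfg = lfp.RunConfig(fs=spec.fs, rng_seed=7)
    sig = lfp.preprocess(rec.channel(0), rec.fs)
    det = lfp.detect_events(sig, cfg)
    events = lfp.quantify_events(sig, det)
    table = lfp.build_event_table(events)
    return {"spec": spec, "rec": rec, "truth": truth, "cfg": cfg,
            "sig": sig, "det": det, "events": events, "table": table}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_signal(samples, fs):
    """Wrap raw samples as a PreprocessedSignal without filtering."""
    x = np.asarray(samples, dtype=float)
    return lfp.PreprocessedSignal(samples=x, fs=fs, dc_offset_removed=0.0)
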