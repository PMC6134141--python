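import numpy as np
import pytest

import boutmap as bm


@pytest.fixture(scope="session")
def default_schedule():
    """The standard 315 s trial: 10 s motion / 5 s static cycles."""
    return bm.make_schedule(315.0, 10.0, 5.0)


@pytest.fixture(scope="session")
def small_scene():
    """A compact scene with a few ROIs of each archetype."""
    return bm.make_scene(
        {"swim_locked": 3, "stim_on": 3, "mixed": 3, "stim_suppressed": 3, "silent": 2},
        frame_shape=(64, 48),
        bleed_factor=0.2,
        seed=1,
    )


@pytest.fixture(scope="session")
def small_trial(default_schedule, small_scene):
    """Tail trace, planted bouts and noise-free ground-truth dF/F."""
    from boutmap.synthetic import ground_truth_dff

    trace, planted = bm.generate_tail_trace(default_schedule, 250.0, seed=1)
    dff, frame_times = ground_truth_dff(
        small_scene, default_schedule, planted, gain_jitter_sd=0.0
    )
    return trace, planted, dff, frame_times


def pearson_oracle(x, y):
    """Direct-summation Pearson correlation, independent of numpy.corrcoef."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx = x - x.sum() / x.size
    dy = y - y.sum() / y.size
    num = float((dx * dy).sum())
    den = float(np.sqrt((dx * dx).sum()) * np.sqrt((dy * dy).sum()))
    return num / den
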