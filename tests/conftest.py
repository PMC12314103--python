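import numpy as np
import pytest

from microskill import SyntheticConfig, TipTrack, VASeries, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_track(x, y, valid=None, fps=30.0, trial_id="t", hand="right"):
    x = np.asarray(x, dtype=float)
    if valid is None:
        valid = np.ones(len(x), dtype=bool)
    return TipTrack(
        trial_id=trial_id, hand=hand,
        frame_index=np.arange(len(x)),
        x_px=x, y_px=np.asarray(y, dtype=float),
        valid=np.asarray(valid, dtype=bool), fps=fps,
    )


def make_va(va, fps=30.0, trial_id="t"):
    va = np.asarray(va, dtype=float)
    return VASeries(trial_id=trial_id, frame_index=np.arange(len(va)),
                    va_px=va, fps=fps)


@pytest.fixture(scope="session")
def default_cohort_dir(tmp_path_factory):
    """Default synthetic cohort (14 surgeons, 2 trials, seed 0) shared by
    the end-to-end tests."""
    out = tmp_path_factory.mktemp("cohort") / "default"
    generate_cohort(SyntheticConfig(seed=0), out)
    return out
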