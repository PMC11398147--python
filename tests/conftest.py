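import numpy as np
import pytest

from accelsleep import simulate as sim


@pytest.fixture(scope="session")
def quiet_phys():
    """Physiology without movements: the clean beat-detection condition."""
    return sim.PhysiologyParams(movement_rate={s: 0.0 for s in "WLDR"})


@pytest.fixture(scope="session")
def short_recording():
    """A 10-min default-physiology recording with raw acceleration (100 Hz)."""
    arch = sim.SleepArchitecture(n_epochs=20)
    return sim.simulate_recording(arch, seed=11, fs=100.0)


@pytest.fixture(scope="session")
def hour_beats():
    """Ground-truth beats of a 1-h recording (no acceleration synthesis)."""
    arch = sim.SleepArchitecture(n_epochs=120)
    rec = sim.simulate_recording(arch, seed=5, fs=100.0, synthesize=False)
    return rec.true_beats


def random_stage_labels(rng, n):
    return np.array(list(rng.choice(list("WLDR"), size=n)), dtype=object)
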