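import numpy as np
import pytest

from nirsgait import synthdata
from nirsgait.optics import OpticalParams
from nirsgait.preprocess import TaskEpoch

ZERO_NOISE = dict(
    hbo2_noise_sd={c: 0.0 for c in synthdata.CONDITIONS},
    hb_noise_sd={c: 0.0 for c in synthdata.CONDITIONS},
    rest_noise_sd=0.0, drift_amp=0.0, mayer_amp=0.0, resp_amp=0.0,
    cardiac_amp=0.0, shot_noise_frac=0.0, spike_rate=0.0,
    saturation_prob=0.0, dark_prob=0.0, missing_prob=0.0,
    voxel_gain_sd=0.0, subject_gain_log_sd=0.0, subject_pace_log_sd=0.0,
)


@pytest.fixture
def quiet_config():
    """All nuisance processes switched off; deterministic response only."""
    return synthdata.SynthConfig(**ZERO_NOISE)


@pytest.fixture
def quiet_recording(quiet_config):
    return synthdata.make_recording(quiet_config, seed=0)


@pytest.fixture(scope="session")
def small_cohort():
    """12 subjects under the default (noisy) study conditions."""
    return synthdata.make_cohort(synthdata.SynthConfig(n_subjects=12), seed=5)


@pytest.fixture
def default_optics():
    return OpticalParams(i0=(1000.0, 1000.0), age=76.0)


def make_epoch(hbo2, hb, condition="STW", voxels=None, missing=(), fs=2.0):
    """Assemble a TaskEpoch directly from arrays (test helper)."""
    hbo2 = np.asarray(hbo2, dtype=float)
    hb = np.asarray(hb, dtype=float)
    if voxels is None:
        voxels = tuple(range(1, hbo2.shape[0] + 1))
    return TaskEpoch(
        condition=condition, hbo2=hbo2, hb=hb, voxels=tuple(voxels),
        missing_voxels=frozenset(missing), fs=fs,
        duration=hbo2.shape[1] / fs, baseline_start=0.0, task_start=10.0,
    )


@pytest.fixture
def epoch_factory():
    return make_epoch
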