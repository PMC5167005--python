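import numpy as np
import pytest

import backnirs as bn
from backnirs.simulate import SimulationParams, simulate_recording


@pytest.fixture(scope="session")
def layout():
    return bn.build_default_probe()


@pytest.fixture(scope="session")
def study_protocol():
    """Full 20-min study protocol: 15 events/condition, 5 s + 15 s ISI."""
    return bn.generate_protocol(seed=42)


@pytest.fixture(scope="session")
def small_protocol():
    """Scaled-down protocol for fast pipeline tests (recording still longer
    than the 80 s SG trend window)."""
    return bn.generate_protocol(n_per_condition=6, baseline_s=100.0, seed=7)


@pytest.fixture(scope="session")
def clean_params():
    """Evoked responses only - every noise source switched off."""
    return SimulationParams(
        seed=5, noise_sd_od=0.0, drift_slope_od_per_s=0.0, drift_walk_od=0.0,
        oscillators=[], scalp_amplitude={c: 0.0 for c in bn.CONDITIONS},
        scalp_background_um=0.0)


@pytest.fixture(scope="session")
def default_recording(layout, study_protocol):
    params = SimulationParams(seed=9)
    od, truth = simulate_recording(layout, study_protocol, params)
    return od, truth, params


@pytest.fixture(scope="session")
def preprocessed_tensor(layout, study_protocol, default_recording):
    od, _truth, params = default_recording
    return bn.preprocess_recording(od, layout, params.subject_age_years,
                                   study_protocol, subject="s1")


def make_tensor(arrays: dict, fs=7.81, pre=30, stim=39, post=30):
    """Hand-built TrialTensor from {(ch, cond, chrom): trials x samples}."""
    from backnirs.preprocess import TrialTensor
    return TrialTensor({k: np.asarray(v, dtype=float) for k, v in arrays.items()},
                       fs, pre, stim, post)
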