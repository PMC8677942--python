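import numpy as np
import pytest

from phnrlab.simulate import CohortSpec, WaveformParams, simulate_cohort, simulate_waveform
from phnrlab.waveform import ERGRecording


def make_recording(samples, subject_id="S0", eye="OD", visit=0, recording=0,
                   label="ON_NEG", eye_class="control_healthy", **kwargs):
    return ERGRecording(subject_id=subject_id, eye=eye, visit_index=visit,
                        recording_index=recording, samples=tuple(samples),
                        label=label, eye_class=eye_class, **kwargs)


def synthetic_recording(phnr=-3.7, noise_sd=0.0, drift=0.0, seed=0, **param_kwargs):
    """One default-morphology recording with a planted PhNR amplitude."""
    params = WaveformParams(phnr_true=phnr, noise_sd_uv=noise_sd,
                            drift_slope_uv_per_ms=drift, **param_kwargs)
    rng = np.random.default_rng(seed)
    return make_recording(simulate_waveform(params, rng)), params


@pytest.fixture(scope="session")
def small_cohort():
    """30-subject default-calibration cohort shared across tests."""
    return simulate_cohort(CohortSpec(n_subjects=30, seed=42))


@pytest.fixture(scope="session")
def separated_cohort():
    """Well-separated cohort: 3 uV group gap, tight groups, noise SD 0.5 uV."""
    spec = CohortSpec(n_subjects=40, phnr_mean_on=-1.0, phnr_mean_control=-4.0,
                      phnr_sd_on=0.3, phnr_sd_control=0.3, noise_sd_uv=0.5, seed=7)
    return simulate_cohort(spec)
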