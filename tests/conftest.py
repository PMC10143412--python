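import numpy as np
import pytest

from bpfusion.io_formats import SignalRecord, SubjectInfo
from bpfusion.synthetic import GeneratorConfig, generate_record


@pytest.fixture
def subject():
    return SubjectInfo(subject_id="S000", gender=1, age=30, weight=72.5)


@pytest.fixture
def clean_config():
    """Noise- and drift-free generator settings."""
    return GeneratorConfig(
        ecg_noise_sd=0.0, ppg_noise_sd=0.0,
        ecg_drift_amp=0.0, ppg_drift_amp=0.0, seed=1,
    )


@pytest.fixture
def clean_record(clean_config):
    record, truth = generate_record(clean_config)
    return record, truth


@pytest.fixture
def noisy_record():
    record, truth = generate_record(GeneratorConfig(ecg_snr_db=20, ppg_snr_db=20, seed=3))
    return record, truth


def make_record(ecg, ppg, fs=125.0, abp=None, subject=None, **kw):
    if subject is None:
        subject = SubjectInfo(subject_id="T", gender=0, age=25)
    return SignalRecord(ecg=np.asarray(ecg, float), ppg=np.asarray(ppg, float),
                        abp=abp, fs=fs, subject=subject, **kw)
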