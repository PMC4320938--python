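"""Shared fixtures: small synthetic records with exact ground truth."""

import numpy as np
import pytest

from raad import bandpass_filter, inject_anomaly, synthesize_record


@pytest.fixture(scope="session")
def normal_record():
    """One seeded 2-lead, 10 s, 257 Hz all-normal record with truth."""
    return synthesize_record(n_leads=2, duration_s=10.0, sampling_rate=257.0,
                             seed=7)


@pytest.fixture(scope="session")
def pvc_record(normal_record):
    """Same record with beat 5 replaced by a PVC."""
    record, truth = normal_record
    return inject_anomaly(record, truth, 5)


@pytest.fixture(scope="session")
def filtered_lead(normal_record):
    """Band-passed lead 0 of the normal record."""
    record, truth = normal_record
    return bandpass_filter(record).lead(0), truth


@pytest.fixture(scope="session")
def filtered_pvc_lead(pvc_record):
    record, truth = pvc_record
    return bandpass_filter(record).lead(0), truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
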