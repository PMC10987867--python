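import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from otva import SyntheticCohortConfig, generate_cohort, patient_context
from otva.qrs import LEADS, QrsSegment


def make_segment(n: int = 40, fs: float = 500.0, beat_type: str = "pvc", **leads) -> QrsSegment:
    """Build a baseline-corrected segment with explicit per-lead waveforms."""
    signal = np.zeros((n, 12))
    for name, values in leads.items():
        values = np.asarray(values, dtype=float)
        signal[: len(values), LEADS.index(name)] = values
    signal -= signal[0]
    return QrsSegment(signal, fs=fs, beat_type=beat_type)


def rs_segment(r_amps, s_amps, n: int = 12) -> QrsSegment:
    """Segment whose V1..V6 leads have exact max=+r and min=-s deflections."""
    leads = {}
    for k, (r, s) in enumerate(zip(r_amps, s_amps), start=1):
        wave = np.zeros(n)
        wave[n // 3] = r
        wave[2 * n // 3] = -s
        leads[f"V{k}"] = wave
    return make_segment(n=n, **leads)


@pytest.fixture(scope="session")
def small_cohort():
    """60-patient default-condition cohort shared across test modules."""
    return generate_cohort(SyntheticCohortConfig(n_patients=60, seed=11))


@pytest.fixture(scope="session")
def small_contexts(small_cohort):
    return [patient_context(s) for s in small_cohort]
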