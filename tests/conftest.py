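"""Shared fixtures: small synthetic recordings and cohorts.

Everything is generated programmatically at session scope; no data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from amyeeg import synth
from amyeeg.preprocess import PreprocessConfig
from amyeeg.recording import SubjectProfile


@pytest.fixture(scope="session")
def clean_profile() -> SubjectProfile:
    return SubjectProfile("CLEAN-1", 72, "M", "SCD", "NEG", seed=11)


@pytest.fixture(scope="session")
def clean_spectral() -> synth.SpectralProfile:
    # jitter-free so expected band structure is deterministic
    return synth.default_spectral_profile(72, "M", np.random.default_rng(3),
                                          jitter_sigma=0.0)


@pytest.fixture(scope="session")
def clean_recording(clean_profile, clean_spectral):
    """60 s artifact-free recording (no blinks/EMG/line noise)."""
    return synth.synthesize_recording(
        clean_profile, clean_spectral, duration=60.0, fs=250.0, seed=11,
        blink_rate_per_min=0.0, emg_rate_per_min=0.0, line_noise_uv=0.0,
    )


@pytest.fixture(scope="session")
def default_recording(clean_profile, clean_spectral):
    """60 s recording with the default artifact schedule."""
    return synth.synthesize_recording(
        clean_profile, clean_spectral, duration=60.0, fs=250.0, seed=12,
    )


@pytest.fixture(scope="session")
def prep_no_ocular() -> PreprocessConfig:
    return PreprocessConfig(ocular_mode="none")


@pytest.fixture(scope="session")
def tiny_cohort_spec() -> synth.CohortSpec:
    """Small four-stratum cohort for structural tests."""
    return synth.CohortSpec(
        n_scd_pos=3, n_scd_neg=5, n_mci_pos=3, n_mci_neg=3,
        duration=60.0, seed=21,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_cohort_spec):
    return synth.generate_study_cohort(tiny_cohort_spec)
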