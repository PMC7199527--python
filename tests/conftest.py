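import numpy as np
import pytest

from fpvs.design import make_design
from fpvs.montage import biosemi64
from fpvs.pipeline import roi_montage, subject_spectra
from fpvs.simulate import SubjectSpec, simulate_subject_eeg


@pytest.fixture(scope="session")
def design():
    return make_design()


@pytest.fixture(scope="session")
def montage():
    return biosemi64()


@pytest.fixture(scope="session")
def sub_montage(montage):
    return roi_montage(montage)


@pytest.fixture(scope="session")
def noiseless_subject(design, montage):
    """One noiseless TD-default subject at 256 Hz, generator-level spectra
    (no filtering/resampling so amplitudes are exact)."""
    spec = SubjectSpec("clean01", noise_scale=0.0, blink_rate=0.0, seed=7)
    rec, gt = simulate_subject_eeg(spec, design, montage, fs=256.0)
    spectra = subject_spectra(rec, design, apply_preprocessing=False)
    return spec, rec, gt, spectra


@pytest.fixture(scope="session")
def noisy_subject(design, montage):
    """One default (noisy) TD subject at 256 Hz, generator-level spectra."""
    spec = SubjectSpec("noisy01", seed=11)
    rec, gt = simulate_subject_eeg(spec, design, montage, fs=256.0)
    spectra = subject_spectra(rec, design, apply_preprocessing=False)
    return spec, rec, gt, spectra
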