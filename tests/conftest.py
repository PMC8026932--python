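"""Shared fixtures: simulated acquisitions are expensive, so the heavy
RF simulations and extractions are session-scoped and reused across tests."""

import numpy as np
import pytest

from qusrecur import features, simulate, spectra


@pytest.fixture(scope="session")
def acq():
    return simulate.AcquisitionSpec()


@pytest.fixture(scope="session")
def phantom(acq):
    return simulate.simulate_phantom(acq, seed=123)


@pytest.fixture(scope="session")
def phantom_ref(phantom):
    return spectra.PhantomReference(phantom.slices)


@pytest.fixture(scope="session")
def structured_exam(acq):
    """Tissue with every estimable property: 25 um radius, 1.0 mm spacing,
    0.5 dB/cm/MHz attenuation -- the parameter-recovery workhorse."""
    tissue = simulate.TissueSpec(
        effective_scatterer_radius=25e-6,
        mean_regular_spacing=1.0e-3,
        spacing_jitter=0.05,
        attenuation_coeff=0.5,
    )
    return simulate.simulate_exam(acq, tissue, n_slices=3, seed=11)


@pytest.fixture(scope="session")
def structured_extraction(structured_exam, phantom_ref):
    return features.extract_patient_features(structured_exam, phantom_ref)


@pytest.fixture(scope="session")
def flat_exam(acq):
    """Point scatterers, no attenuation, no spacing: the flat-spectrum limit."""
    tissue = simulate.TissueSpec(
        effective_scatterer_radius=0.0,
        mean_regular_spacing=0.0,
        attenuation_coeff=0.0,
    )
    return simulate.simulate_exam(acq, tissue, n_slices=1, seed=3)


@pytest.fixture(scope="session")
def flat_slice(flat_exam, phantom_ref, acq):
    return spectra.extract_slice(flat_exam.slices[0], flat_exam.masks[0],
                                 phantom_ref, acq)


@pytest.fixture(scope="session")
def separated_table():
    """Feature-level cohort with a true inter-class margin (classifier
    validation conditions)."""
    return features.synthetic_feature_table(seed=0)


def toy_acquisition(window_px=10, pitch_mm=0.2):
    """Acquisition whose 2 mm window is exactly ``window_px`` pixels on both
    axes (axial interval = lateral pitch = 2 mm / window_px)."""
    interval = 2e-3 / window_px
    fs = 1540.0 / (2.0 * interval)
    return simulate.AcquisitionSpec(
        sampling_frequency=fs, center_frequency=fs / 4,
        band_low=fs / 8, band_high=3 * fs / 8,
        lateral_pitch=interval, n_axial_samples=64, n_lines=64)
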