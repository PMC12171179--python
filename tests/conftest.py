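"""Shared fixtures: small synthetic cohorts and trained models.

Everything is generated programmatically at test time; session scope keeps
the expensive artifacts (cohort directories, trained classifiers) shared
across test modules.
"""

import numpy as np
import pytest

from awcop.simulate import CohortSpec, generate_cohort
from awcop.train import TrainSpec, assemble_dataset, train


@pytest.fixture(scope="session")
def tiny_cohort(tmp_path_factory):
    """24 patients, 16x16 images, default (study-condition) effects."""
    out = tmp_path_factory.mktemp("cohort_tiny")
    spec = CohortSpec(n_patients=24, prevalence=0.5, seed=7, image_size=(16, 16))
    manifest, truth = generate_cohort(spec, out)
    return spec, manifest, truth


@pytest.fixture(scope="session")
def tiny_dataset(tiny_cohort):
    _, manifest, _ = tiny_cohort
    return assemble_dataset(manifest, image_size=(16, 16), seed=0)


@pytest.fixture(scope="session")
def noiseless_cohort(tmp_path_factory):
    """Clean waveforms for exact fiducial-recovery checks."""
    out = tmp_path_factory.mktemp("cohort_clean")
    spec = CohortSpec(n_patients=10, prevalence=0.5, seed=5, image_size=(16, 16),
                      pulse_noise=0.0, drift_amp=0.0)
    manifest, truth = generate_cohort(spec, out)
    return spec, manifest, truth


@pytest.fixture(scope="session")
def pulse_signal_cohort(tmp_path_factory):
    """Signal only in the pulse h3/h1 ratio; other modalities pure noise."""
    out = tmp_path_factory.mktemp("cohort_pulse")
    spec = CohortSpec(n_patients=100, prevalence=0.5, seed=13, image_size=(16, 16),
                      tongue_effect=0.0, face_effect=0.0, pulse_effect=0.25,
                      clinical_effects={})
    manifest, truth = generate_cohort(spec, out)
    return spec, manifest, truth


@pytest.fixture(scope="session")
def pulse_lstm_clf(pulse_signal_cohort):
    """LSTM-only pulse model trained on the pulse-signal cohort."""
    _, manifest, _ = pulse_signal_cohort
    ds = assemble_dataset(manifest, image_size=(16, 16), seed=0)
    clf = train(ds, TrainSpec(epochs=15, batch_size=32, seed=0),
                modalities=("pulse",), fusion="concat", validate=False)
    return clf, ds


@pytest.fixture(scope="session")
def tongue_signal_cohort(tmp_path_factory):
    """Signal only in the tongue-coating hue; used for Grad-CAM checks.

    32x32 images: the class activation map lives at half resolution, and
    localization checks need a feature map larger than the coating patch.
    """
    out = tmp_path_factory.mktemp("cohort_tongue")
    spec = CohortSpec(n_patients=80, prevalence=0.5, seed=17, image_size=(32, 32),
                      face_effect=0.0, pulse_effect=0.0, clinical_effects={})
    manifest, truth = generate_cohort(spec, out)
    return spec, manifest, truth


@pytest.fixture(scope="session")
def tongue_clf(tongue_signal_cohort):
    """Tongue-only image model trained on the tongue-signal cohort."""
    _, manifest, _ = tongue_signal_cohort
    ds = assemble_dataset(manifest, image_size=(32, 32), seed=0)
    clf = train(ds, TrainSpec(epochs=8, batch_size=16, seed=0),
                modalities=("tongue",), fusion="concat", validate=False)
    return clf, ds


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
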