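import numpy as np
import pytest

from serslda import (
    BandSpec,
    ClassProfile,
    PreprocessParams,
    SpectraMatrix,
    WavenumberAxis,
    generate_dataset,
    preprocess_pipeline,
)


def make_matrix(X, labels):
    """SpectraMatrix on an integer wavenumber axis, for toy examples."""
    X = np.asarray(X, dtype=float)
    return SpectraMatrix(
        X=X,
        axis=WavenumberAxis(np.arange(X.shape[1], dtype=float)),
        labels=np.asarray(labels, dtype=object),
    )


def simple_profiles(exclusive_amplitude=0.3, noise_sd=0.05):
    """Three classes sharing three major bands, one exclusive band each.

    A minimal, well-separated configuration for fast pipeline tests and
    for planted-band recovery checks (one known exclusive centre per
    class).
    """
    shared_centers = (600.0, 900.0, 1200.0)
    exclusive = {"seminal": 450.0, "lung": 1050.0, "heart": 1500.0}

    def band(center, amplitude):
        return BandSpec(
            center=center,
            width=6.0,
            amplitude=amplitude,
            jitter_center=0.5,
            jitter_amplitude=0.05,
        )

    profiles = []
    for name, center in exclusive.items():
        bands = tuple(band(c, 1.0) for c in shared_centers) + (
            band(center, exclusive_amplitude),
        )
        profiles.append(
            ClassProfile(
                name=name,
                bands=bands,
                baseline_coeffs=(0.5, 0.3, -0.2),
                noise_sd=noise_sd,
                baseline_jitter=0.03,
            )
        )
    return profiles


@pytest.fixture(scope="session")
def small_axis():
    return WavenumberAxis.uniform(512, 250.0, 1900.0)


@pytest.fixture(scope="session")
def simple_matrix(small_axis):
    """Preprocessed matrix from the simple three-class generator."""
    sset = generate_dataset(simple_profiles(), (16, 16, 16), seed=11, axis=small_axis)
    return preprocess_pipeline(sset, PreprocessParams())
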