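"""Shared fixtures: small sensors, phantoms, captures and surrogate windows.

Everything is generated programmatically; expensive fixtures are module- or
session-scoped so the suite stays within a desk-scale CPU budget.
"""

import numpy as np
import pytest

from hsiderm import mlprep, model as model_mod, photometric, synthdata


@pytest.fixture(scope="session")
def lights():
    return synthdata.LightGeometry()


@pytest.fixture(scope="session")
def small_sensor():
    return synthdata.SensorConfig(height_px=128, width_px=128)


@pytest.fixture(scope="session")
def phantom(small_sensor):
    return synthdata.make_phantom(small_sensor, "MM", 30, seed=11, healthy_annulus_px=20)


@pytest.fixture(scope="session")
def capture(phantom, lights, small_sensor):
    return synthdata.render_capture(phantom, lights, small_sensor, seed=12)


@pytest.fixture(scope="session")
def processed(capture):
    return photometric.preprocess_capture(capture, sigma=2.0)


@pytest.fixture(scope="session")
def feature_cube(processed, phantom):
    return mlprep.prepare_features(processed, phantom.fov_mask)


def surrogate_windows(classes, n_per_class, seed, separation=1.0, noise_sd=0.02,
                      side="train"):
    """Windows built directly from class spectra plus pixel noise — a cheap
    stand-in for the full pipeline when only the classifier is under test."""
    rng = np.random.default_rng(seed)
    params = synthdata.SpectrumParams(separation=separation)
    wl = synthdata.default_wavelengths()
    samples = []
    for label in classes:
        spec = synthdata.class_spectrum(label, wl, params, seed=0).astype(np.float32)
        for _ in range(n_per_class):
            patch = np.empty((30, 30, 34), dtype=np.float32)
            patch[..., :33] = spec + rng.normal(0.0, noise_sd, size=(30, 30, 33))
            patch[..., 33] = 0.5 + rng.normal(0.0, noise_sd, size=(30, 30))
            samples.append(
                mlprep.WindowSample(patch=np.clip(patch, 0, 1), label=label,
                                    center=(15, 15), side=side)
            )
    return samples


@pytest.fixture(scope="session")
def tiny_model_config():
    return model_mod.small_config(3, max_epochs=2, patience=2)


@pytest.fixture(scope="session")
def trained_tiny_model(tiny_model_config):
    classes = ["MM", "PN", "healthy"]
    train = surrogate_windows(classes, 60, seed=21)
    val = surrogate_windows(classes, 15, seed=22, side="test")
    net = model_mod.build_model(tiny_model_config)
    return model_mod.train(net, train, val, tiny_model_config,
                           class_order=sorted(classes))
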