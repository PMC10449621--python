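import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from guvquant import (
    SimImageConfig,
    detect_vesicles,
    estimate_background,
    normalize_experiment,
    quantify_image_set,
    simulate_field,
)
from guvquant.synthetic_microscopy import TXR

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_field():
    """A small default-SNR field with truth: (config, images, truths)."""
    cfg = SimImageConfig(field_size_px=(384, 384), n_vesicles=12, rng_seed=7)
    images, truths = simulate_field(cfg)
    return cfg, images, truths


@pytest.fixture(scope="session")
def small_field_analyzed(small_field):
    """Normalized images, detections, background and records for the small field."""
    cfg, images, truths = small_field
    normalized, model = normalize_experiment(images)
    norm = normalized[0]
    detections = detect_vesicles(norm[TXR])
    bg = estimate_background(norm, (slice(0, 30), slice(0, 30)))
    records = quantify_image_set(norm, detections, bg)
    return {
        "config": cfg,
        "truths": truths,
        "normalized": norm,
        "model": model,
        "detections": detections,
        "background": bg,
        "records": records,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
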