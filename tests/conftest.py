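import numpy as np
import pytest

from scribepd.dynamic_features import (
    IN_AIR,
    ON_SURFACE,
    kinematic_features,
    pressure_features,
    segment,
)
from scribepd.image_branch import CNNConfig, make_pretrain_corpus, pretrain_cnn
from scribepd.io_formats import TabletRecording
from scribepd.synthetic_data import (
    SubjectProfile,
    default_glyph_bank,
    synthesize_recording,
)


@pytest.fixture(scope="session")
def glyph_bank():
    return default_glyph_bank()


@pytest.fixture(scope="session")
def hc_recording(glyph_bank):
    """One healthy-control-like recording shared by read-only tests."""
    return synthesize_recording(SubjectProfile(seed=11), glyph_bank,
                                subject_id="HC_fixture")


@pytest.fixture(scope="session")
def hc_mask(hc_recording):
    return segment(hc_recording)


@pytest.fixture(scope="session")
def pressure_fm(hc_recording, hc_mask):
    return pressure_features(hc_recording, hc_mask)


@pytest.fixture(scope="session")
def kin_on_fm(hc_recording, hc_mask):
    return kinematic_features(hc_recording, hc_mask, ON_SURFACE)


@pytest.fixture(scope="session")
def kin_air_fm(hc_recording, hc_mask):
    return kinematic_features(hc_recording, hc_mask, IN_AIR)


@pytest.fixture(scope="session")
def pretrained_model():
    """Small pre-trained micrographia network shared across CNN tests."""
    corpus = make_pretrain_corpus(120, seed=5)
    config = CNNConfig(seed=5, epochs=3, patience=2)
    model, test_acc = pretrain_cnn(corpus, config)
    return model, test_acc, corpus


@pytest.fixture
def make_recording():
    """Factory for small hand-built recordings with valid side channels."""

    def _make(pressure, x=None, y=None, z=None, fs=180.0, subject_id="toy"):
        pressure = np.asarray(pressure, dtype=float)
        n = len(pressure)
        x = np.arange(n, dtype=float) if x is None else np.asarray(x, dtype=float)
        y = np.zeros(n) if y is None else np.asarray(y, dtype=float)
        if z is None:
            z = np.where(pressure > 0, 0.0, 10.0)
        return TabletRecording(
            subject_id=subject_id,
            x=x, y=y, z=np.asarray(z, dtype=float),
            azimuth=np.full(n, 250.0),
            altitude=np.full(n, 60.0),
            pressure=pressure,
            fs=fs,
        )

    return _make
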