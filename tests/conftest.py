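import numpy as np
import pytest

from mstate_ri.montage import standard_montage
from mstate_ri.synthetic import (
    GenConfig,
    generate_templates,
    sample_state_sequence,
    render_eeg,
)


@pytest.fixture(scope="session")
def montage60():
    return standard_montage(60)


@pytest.fixture(scope="session")
def montage19():
    return standard_montage(19)


@pytest.fixture(scope="session")
def templates4(montage60):
    return generate_templates(montage60, 4, seed=1)


@pytest.fixture(scope="session")
def clean_render(montage60, templates4):
    """Noise-free 10-s render with its ground truth."""
    cfg = GenConfig(noise_sd_uv=0.0, fs_hz=512.0, length_s=10.0, seed=7)
    labels, runs = sample_state_sequence(cfg)
    return render_eeg(labels, runs, templates4, cfg), cfg


@pytest.fixture(scope="session")
def noisy_render(montage60, templates4):
    """SNR ~ 4 60-s render (noise 2.5 uV vs 10 uV envelope)."""
    cfg = GenConfig(noise_sd_uv=2.5, fs_hz=512.0, length_s=60.0, seed=3)
    labels, runs = sample_state_sequence(cfg)
    return render_eeg(labels, runs, templates4, cfg), cfg


def unit_maps(maps: np.ndarray) -> np.ndarray:
    maps = np.atleast_2d(np.asarray(maps, float))
    maps = maps - maps.mean(axis=1, keepdims=True)
    return maps / np.linalg.norm(maps, axis=1, keepdims=True)
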