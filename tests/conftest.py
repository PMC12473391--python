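import numpy as np
import pytest

from semscan.labeling import complement_intervals, extract_windows
from semscan.preprocess import preprocess_recording
from semscan.simulate import SimConfig, generate_recording

# Small model configuration used wherever a test only needs *a* working
# network, not the full-size one.
TINY_MODEL = dict(
    kernel_sizes=(7, 7, 7, 7),
    d_model=8,
    n_heads=2,
    n_encoder_layers=2,
    d_ff=16,
    pool_sizes=(4, 5),
    fc_units=8,
    lstm_units=6,
)


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(duration_s=120.0, n_sem_events=6, n_saccades=10, seed=42)


@pytest.fixture(scope="session")
def recording_and_truth(sim_config):
    return generate_recording(sim_config)


@pytest.fixture(scope="session")
def clean_recording(recording_and_truth):
    recording, _ = recording_and_truth
    return preprocess_recording(recording, "heog+hsum")


@pytest.fixture(scope="session")
def window_dataset(sim_config, recording_and_truth, clean_recording):
    _, truth = recording_and_truth
    intervals = sorted(
        truth.intervals + complement_intervals(truth.intervals, sim_config.duration_s),
        key=lambda iv: iv.start_s,
    )
    return extract_windows(clean_recording, intervals)


@pytest.fixture(scope="session")
def toy_windows():
    """Tiny linearly separable bimodal windows: class 1 carries a slow
    oscillation on modality 1, class 0 is noise only."""
    rng = np.random.default_rng(7)
    n, win = 120, 100
    t = np.arange(win) / 100.0
    X = rng.standard_normal((n, 2, win)).astype(np.float32)
    y = (np.arange(n) % 3 == 0).astype(int)
    X[y == 1, 0] += 8.0 * np.sin(2 * np.pi * 1.5 * t).astype(np.float32)
    return X, y
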