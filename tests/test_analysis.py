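"""Alpha-band wavelet energy curves, O2/HSUM correlation, attention maps."""

import numpy as np
import pytest

from semscan.analysis import (
    class_average_attention,
    cwt_alpha_energy,
    energy_correlation,
    extract_attention,
)
from semscan.architectures import ModelConfig, build_model
from semscan.io import Recording, WindowDataset

FS = 500.0


class TestCWTEnergy:
    def test_stationary_tone_gives_flat_curve(self):
        t = np.arange(int(6 * FS)) / FS
        x = np.sin(2 * np.pi * 10.0 * t)
        curve = cwt_alpha_energy(x, FS).values
        n = len(curve)
        central = curve[int(0.2 * n) : int(0.8 * n)]
        assert np.std(central) / np.mean(central) < 0.10

    def test_linearity_in_amplitude(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(int(3 * FS))
        c1 = cwt_alpha_energy(x, FS).values
        c2 = cwt_alpha_energy(2 * x, FS).values
        assert np.allclose(c2, 2 * c1, rtol=1e-9)

    def test_out_of_band_rejection(self):
        t = np.arange(int(6 * FS)) / FS
        slow = np.sin(2 * np.pi * 0.3 * t)
        alpha = np.sin(2 * np.pi * 10.0 * t)
        n = len(t)
        mid = slice(int(0.2 * n), int(0.8 * n))
        c_slow = cwt_alpha_energy(slow, FS).values[mid]
        c_alpha = cwt_alpha_energy(alpha, FS).values[mid]
        assert np.max(c_slow) < 0.05 * np.mean(c_alpha)

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError, match="band"):
            cwt_alpha_energy(np.zeros(1000), FS, band=(6.0, 300.0))


def _two_channel_recording(o2, hsum):
    zeros = np.zeros_like(o2)
    return Recording(
        {"Hl": zeros, "Hr": zeros, "O2": o2, "HSUM": hsum}, fs=FS
    )


class TestEnergyCorrelation:
    def test_identical_channels_perfect_correlation(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(int(12 * FS))
        rs, summary = energy_correlation(_two_channel_recording(x, x.copy()))
        assert np.allclose(rs, 1.0)
        assert summary["median_r"] == pytest.approx(1.0)

    def test_negated_curve_anticorrelates(self):
        # energy curves are magnitudes, so anti-correlation needs opposed
        # envelopes rather than a sign flip: alternate bursts
        t = np.arange(int(12 * FS)) / FS
        env_a = 0.5 * (1 + np.sin(2 * np.pi * t / 6))
        carrier = np.sin(2 * np.pi * 10 * t)
        rs, _ = energy_correlation(
            _two_channel_recording(env_a * carrier, (1 - env_a) * carrier)
        )
        assert np.median(rs) < -0.8

    def test_shared_envelope_high_correlation(self, recording_and_truth):
        from semscan.preprocess import preprocess_recording

        recording, _ = recording_and_truth
        clean = preprocess_recording(recording, "heog+hsum")
        rs, summary = energy_correlation(clean)
        assert summary["n_windows"] >= 30
        assert summary["median_r"] > 0.7

    def test_positive_rescaling_invariance(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal(int(12 * FS))
        b = rng.standard_normal(int(12 * FS))
        rs1, _ = energy_correlation(_two_channel_recording(a, b))
        rs2, _ = energy_correlation(_two_channel_recording(3.7 * a, 0.2 * b))
        assert np.allclose(rs1, rs2, atol=1e-9)

    def test_outlier_removal_single_pass(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal(int(30 * FS))
        b = a + 0.3 * rng.standard_normal(len(a))
        rs, summary = energy_correlation(_two_channel_recording(a, b))
        # removed points are exactly those beyond 2 SD of the raw r set
        assert summary["n_removed"] <= summary["n_windows"]
        assert np.all(np.abs(rs - rs.mean()) <= 4 * rs.std() + 1e-12)

    def test_too_few_windows_rejected(self):
        x = np.zeros(int(4 * FS))
        with pytest.raises(ValueError, match="at least 3"):
            energy_correlation(_two_channel_recording(x, x))


@pytest.fixture(scope="module")
def tiny_pmmct():
    cfg = ModelConfig(
        variant="pmmct", kernel_sizes=(7, 7, 7, 7), d_model=8, n_heads=2,
        n_encoder_layers=2, d_ff=16, pool_sizes=(4, 5), fc_units=8,
    )
    return build_model(cfg, np.random.default_rng(0))


class TestAttention:
    def test_rows_stochastic_and_shape(self, tiny_pmmct):
        rng = np.random.default_rng(0)
        x1, x2 = rng.standard_normal((2, 100)).astype(np.float32)
        maps = extract_attention(tiny_pmmct, x1, x2)
        assert len(maps.maps) == 2  # branches
        for branch in maps.maps:
            assert len(branch) == 2  # encoder layers
            for m in branch:
                assert m.shape == (2, 5, 5)  # heads, l_enc, l_enc
                assert np.allclose(m.sum(axis=-1), 1.0, atol=1e-6)

    def test_instrumentation_does_not_change_output(self, tiny_pmmct):
        rng = np.random.default_rng(1)
        x1, x2 = rng.standard_normal((2, 100)).astype(np.float32)
        plain = tiny_pmmct.predict_proba(x1[None], x2[None])
        maps = extract_attention(tiny_pmmct, x1, x2)
        assert np.allclose(maps.probabilities, plain, atol=0)

    def test_non_transformer_variant_rejected(self):
        cfg = ModelConfig(variant="cnn", kernel_sizes=(7, 7, 7, 7), d_model=8,
                          pool_sizes=(4, 5))
        net = build_model(cfg, np.random.default_rng(0))
        with pytest.raises(ValueError, match="no encoder"):
            extract_attention(net, np.zeros(100, np.float32), np.zeros(100, np.float32))

    def _dataset(self, n=8, win=100):
        rng = np.random.default_rng(2)
        return WindowDataset(
            X=rng.standard_normal((n, 2, win)).astype(np.float32),
            y=np.arange(n) % 2,
            t_start=np.arange(n, dtype=float),
            fs=FS / 3,
            modalities=("HEOG", "HSUM"),
        )

    def test_class_averages_row_stochastic(self, tiny_pmmct):
        maps = class_average_attention(tiny_pmmct, self._dataset())
        for c in (0, 1):
            for branch_map in maps[c]:
                assert np.allclose(branch_map.sum(axis=-1), 1.0, atol=1e-5)

    def test_single_sample_class_average_is_that_sample(self, tiny_pmmct):
        ds = self._dataset(n=3)
        ds.y = np.array([0, 0, 1])
        maps = class_average_attention(tiny_pmmct, ds)
        single = extract_attention(tiny_pmmct, ds.X[2, 0], ds.X[2, 1])
        for b in (0, 1):
            assert np.allclose(maps[1][b], single.maps[b][-1], atol=1e-6)

    def test_trained_model_class_maps_differ(self, toy_windows):
        from semscan.classifiers import PMMCTClassifier
        from conftest import TINY_MODEL
        from semscan.io import WindowDataset

        X, y = toy_windows
        clf = PMMCTClassifier(**TINY_MODEL, dropout=0.0, max_epochs=2,
                              batch_size=32, random_state=0).fit(X, y)
        ds = WindowDataset(X=X[:40], y=y[:40], t_start=np.arange(40, dtype=float),
                           fs=FS / 3, modalities=("HEOG", "HSUM"))
        maps = class_average_attention(clf.network_, ds)
        for b in (0, 1):
            assert np.linalg.norm(maps[1][b] - maps[0][b]) > 0

    def test_missing_class_rejected(self, tiny_pmmct):
        ds = self._dataset()
        ds.y = np.zeros(len(ds), dtype=int)
        with pytest.raises(ValueError, match="both classes"):
            class_average_attention(tiny_pmmct, ds)
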