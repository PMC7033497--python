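"""Synthetic sEMG generator: determinism, separability structure, and the
generator/feature spectral round trip."""

import json
import os

import numpy as np
import pytest

from emgid.config import IdftConfig, PopulationConfig
from emgid.features import extract_dataset_features, idft_feature
from emgid.synthetic import (
    SpectralSignature,
    draw_population,
    generate_dataset,
    load_dataset,
    synthesize_recording,
)

FCOLS = [f"f{i:02d}" for i in range(48)]


def _mean_feature_by_segment(rec, n_channels=8):
    """Mean extracted feature over all windows, reshaped (segments x channels)."""
    feats = extract_dataset_features([rec])
    f = feats[[c for c in feats.columns if c.startswith("f")]].to_numpy()
    return f.mean(axis=0).reshape(n_channels, 6).T


class TestDrawPopulation:
    def test_seeded_determinism(self):
        cfg = PopulationConfig(n_subjects=3, n_gestures=2, seed=9)
        a = draw_population(cfg)
        b = draw_population(cfg)
        for key in a:
            assert np.array_equal(a[key].log_band_gains, b[key].log_band_gains)

    def test_zero_separability_collapses_classes(self):
        cfg = PopulationConfig(
            n_subjects=3, n_gestures=2, subject_separability=0.0, gesture_separability=0.0
        )
        sigs = draw_population(cfg)
        ref = sigs[(1, 1)].log_band_gains
        assert all(np.array_equal(s.log_band_gains, ref) for s in sigs.values())

    def test_between_subject_variance_matches_configured_std(self):
        cfg = PopulationConfig(
            n_subjects=100, n_gestures=1, subject_separability=2.0,
            gesture_separability=0.0, channel_gain_spread=0.0, seed=4,
        )
        gains = np.stack([draw_population(cfg)[(s, 1)].log_band_gains for s in range(1, 101)])
        var = gains.var(axis=0, ddof=1)  # elementwise across subjects
        assert abs(var.mean() - 4.0) < 0.3

    def test_invalid_config_names_field(self):
        with pytest.raises(ValueError, match="n_subjects"):
            PopulationConfig(n_subjects=0)
        with pytest.raises(ValueError, match="band"):
            PopulationConfig(band=(10.0, 600.0))  # beyond Nyquist
        with pytest.raises(ValueError, match="within_class_variability"):
            PopulationConfig(within_class_variability=-0.1)


class TestSynthesizeRecording:
    def test_flat_signature_gives_flat_feature(self):
        cfg = PopulationConfig(n_subjects=1, n_gestures=1, within_class_variability=0.0)
        sig = SpectralSignature(1, 1, np.zeros((6, 8)))
        rec = synthesize_recording(sig, cfg, 77)
        mean = _mean_feature_by_segment(rec)
        assert np.abs(mean).max() < 0.1

    def test_doubling_gains_shifts_feature_by_ln2(self):
        cfg = PopulationConfig(n_subjects=1, n_gestures=1)
        rng_gains = np.random.default_rng(3).normal(0, 0.5, (6, 8))
        rec1 = synthesize_recording(SpectralSignature(1, 1, rng_gains), cfg, 5)
        rec2 = synthesize_recording(SpectralSignature(1, 1, rng_gains + np.log(2)), cfg, 5)
        f1 = extract_dataset_features([rec1])[FCOLS].to_numpy()
        f2 = extract_dataset_features([rec2])[FCOLS].to_numpy()
        assert np.abs(f2 - f1 - np.log(2)).max() < 0.05

    def test_boosted_segment_dominates_windows(self):
        """Segment 3 at 10x the others wins the per-window argmax >= 95% of
        the time over 100 windows."""
        cfg = PopulationConfig(
            n_subjects=1, n_gestures=1, n_channels=1, duration=5.2,
            within_class_variability=0.0,
        )
        gains = np.zeros((6, 1))
        gains[2, 0] = np.log(10.0)
        rec = synthesize_recording(SpectralSignature(1, 1, gains), cfg, 11)
        feats = extract_dataset_features([rec])
        f = feats[[f"f{i:02d}" for i in range(6)]].to_numpy()
        assert f.shape[0] >= 100
        wins = (np.argmax(f, axis=1) == 2).mean()
        assert wins >= 0.95

    def test_out_of_band_power_suppressed(self):
        cfg = PopulationConfig(n_subjects=1, n_gestures=1, n_channels=1)
        rec = synthesize_recording(SpectralSignature(1, 1, np.zeros((6, 1))), cfg, 2)
        spec = np.abs(np.fft.rfft(rec.signal[0])) ** 2
        freqs = np.fft.rfftfreq(rec.n_samples, 1 / cfg.sampling_rate)
        out_band = spec[(freqs < 10.0) | (freqs > 500.0)].sum()
        assert out_band / spec.sum() < 1e-20

    def test_band_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError, match="band"):
            PopulationConfig(sampling_rate=512.0, band=(10.0, 500.0))


class TestGenerateDataset:
    def test_counts(self):
        cfg = PopulationConfig(n_subjects=2, n_gestures=1, n_repetitions=7, duration=1.0)
        assert len(generate_dataset(cfg).recordings) == 14
        assert PopulationConfig().n_recordings == 24 * 16 * 7 == 2688

    def test_seeded_determinism_byte_identical_on_disk(self, tmp_path):
        cfg = PopulationConfig(n_subjects=1, n_gestures=2, n_repetitions=2, duration=1.0, seed=5)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_dataset(cfg, out_dir=str(d1))
        generate_dataset(cfg, out_dir=str(d2))
        m1 = (d1 / "manifest.json").read_bytes()
        m2 = (d2 / "manifest.json").read_bytes()
        assert m1 == m2
        for root, _, files in os.walk(d1):
            for f in files:
                rel = os.path.relpath(os.path.join(root, f), d1)
                assert (d2 / rel).read_bytes() == (d1 / rel).read_bytes()

    def test_disk_round_trip(self, tmp_path):
        cfg = PopulationConfig(n_subjects=1, n_gestures=1, n_repetitions=2, duration=1.0, seed=6)
        ds = generate_dataset(cfg, out_dir=str(tmp_path / "ds"))
        loaded = load_dataset(str(tmp_path / "ds"))
        assert loaded.config == cfg
        for a, b in zip(ds.recordings, loaded.recordings):
            assert (a.subject_id, a.gesture_id, a.repetition_id) == (
                b.subject_id, b.gesture_id, b.repetition_id)
            assert np.allclose(a.signal, b.signal, atol=1e-6)
        manifest = json.loads((tmp_path / "ds" / "manifest.json").read_text())
        assert len(manifest["checksums"]) == 2

    def test_generator_feature_round_trip(self):
        """With zero repetition jitter the mean extracted feature of each
        class recovers its spectral signature to within 0.1."""
        cfg = PopulationConfig(n_subjects=2, n_gestures=2, within_class_variability=0.0, seed=3)
        ds = generate_dataset(cfg)
        feats = extract_dataset_features(ds)
        for (s, g), grp in feats.groupby(["subject", "gesture"]):
            mean_feat = grp[FCOLS].to_numpy().mean(axis=0).reshape(8, 6).T
            err = np.abs(mean_feat - ds.signatures[(s, g)].log_band_gains).max()
            assert err < 0.1
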