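"""Sliding-window segmentation and the six-segment band-power (iDFT) feature.

For each 200-ms analysis window and each channel the feature is the
(natural) log of the mean DFT magnitude within each of six equal-width
frequency segments spanning the analysis band:

    DFT_i = ln( (1/N_i) * sum_j |X(f_{i,j})| ),   i = 1..6

where f_{i,j} runs over the N_i discrete window frequencies falling in
segment i.  The per-channel six-vectors are concatenated channel-major
(channel 1 segments 1-6, then channel 2, ...) into the feature vector.

The logarithm makes the feature equivariant under amplitude scaling:
feature(c*x) = feature(x) + ln(c).
"""

from __future__ import annotations

from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import IdftConfig, WindowingConfig, segment_of_frequencies
from .synthetic import Recording, SyntheticDataset, load_dataset

__all__ = [
    "segment_of_frequencies",
    "segment_windows",
    "idft_feature",
    "extract_dataset_features",
    "feature_columns",
    "write_feature_table",
    "read_feature_table",
]


@lru_cache(maxsize=64)
def _segment_bins(window_samples: int, sampling_rate: float, cfg: IdftConfig):
    """Per-segment rfft bin indices for a window, cached by geometry.

    Raises if any segment contains no bin (window too short for the band).
    """
    freqs = np.fft.rfftfreq(window_samples, d=1.0 / sampling_rate)
    seg = segment_of_frequencies(freqs, cfg)
    bins = []
    for i in range(cfg.n_segments):
        b = np.flatnonzero(seg == i)
        if b.size == 0:
            raise ValueError(
                f"frequency segment {i + 1} of band {cfg.band} contains no DFT bin for a "
                f"{window_samples}-sample window at {sampling_rate} Hz; use a longer "
                "window or a narrower band"
            )
        bins.append(b)
    # indicator matrix (n_segments x n_bins) averaging magnitudes per segment
    ind = np.zeros((cfg.n_segments, freqs.size))
    for i, b in enumerate(bins):
        ind[i, b] = 1.0 / b.size
    return tuple(bins), ind


def segment_windows(rec: Recording, cfg: WindowingConfig) -> list[tuple[int, np.ndarray]]:
    """Cut a recording into overlapping windows.

    Windows start at sample 0 and advance by ``increment_samples``; a
    trailing partial window is discarded.  Returns ``(window_index,
    channels x window_samples)`` pairs in stream order.
    """
    n = rec.n_samples
    w, inc = cfg.window_samples, cfg.increment_samples
    if n < w:
        raise ValueError(
            f"recording (subject={rec.subject_id}, gesture={rec.gesture_id}, "
            f"repetition={rec.repetition_id}) has {n} samples, shorter than one "
            f"{w}-sample window"
        )
    count = (n - w) // inc + 1
    return [(k, rec.signal[:, k * inc : k * inc + w]) for k in range(count)]


def idft_feature(
    window: np.ndarray, cfg: IdftConfig, sampling_rate: float
) -> np.ndarray:
    """Band-power feature of one window: length n_segments * n_channels.

    Element order is channel-major (all segments of channel 1 first).
    """
    window = np.asarray(window, dtype=float)
    if window.ndim == 1:
        window = window[None, :]
    if not np.all(np.isfinite(window)):
        raise ValueError("window contains non-finite values")
    _, ind = _segment_bins(window.shape[1], float(sampling_rate), cfg)
    mags = np.abs(np.fft.rfft(window, axis=1))  # (C, bins)
    means = mags @ ind.T  # (C, n_segments)
    return np.log(np.maximum(means, cfg.log_floor)).ravel()


def _windows_view(signal: np.ndarray, w: int, inc: int) -> np.ndarray:
    """(n_windows, C, w) strided view of all full windows."""
    view = np.lib.stride_tricks.sliding_window_view(signal, w, axis=1)
    count = (signal.shape[1] - w) // inc + 1
    return view[:, : count * inc : inc].transpose(1, 0, 2)


def feature_columns(n_channels: int, n_segments: int = 6) -> list[str]:
    return [f"f{i:02d}" for i in range(n_segments * n_channels)]


def extract_dataset_features(
    dataset: SyntheticDataset | Iterable[Recording] | str,
    wcfg: WindowingConfig | None = None,
    icfg: IdftConfig | None = None,
) -> pd.DataFrame:
    """Window every recording and extract the band-power feature per window.

    Returns a tidy table with one row per window: ``subject``, ``gesture``,
    ``repetition``, ``window`` and the feature columns ``f00``..; rows keep
    stream order within each repetition (required by the vote / moving-
    average postprocessing downstream).
    """
    if isinstance(dataset, str):
        dataset = load_dataset(dataset)
    recordings: Sequence[Recording]
    if isinstance(dataset, SyntheticDataset):
        recordings = dataset.recordings
    else:
        recordings = list(dataset)
    if not recordings:
        return pd.DataFrame(columns=["subject", "gesture", "repetition", "window"])

    fs = recordings[0].sampling_rate
    wcfg = wcfg or WindowingConfig(sampling_rate=fs)
    icfg = icfg or IdftConfig()

    frames = []
    for rec in recordings:
        n = rec.n_samples
        w, inc = wcfg.window_samples, wcfg.increment_samples
        if n < w:
            raise ValueError(
                f"recording (subject={rec.subject_id}, gesture={rec.gesture_id}, "
                f"repetition={rec.repetition_id}) is shorter than one window"
            )
        wins = _windows_view(rec.signal, w, inc)  # (W, C, w)
        _, ind = _segment_bins(w, float(rec.sampling_rate), icfg)
        mags = np.abs(np.fft.rfft(wins, axis=2))
        means = mags @ ind.T  # (W, C, S)
        feats = np.log(np.maximum(means, icfg.log_floor)).reshape(wins.shape[0], -1)
        df = pd.DataFrame(feats, columns=feature_columns(rec.signal.shape[0], icfg.n_segments))
        df.insert(0, "window", np.arange(wins.shape[0]))
        df.insert(0, "repetition", rec.repetition_id)
        df.insert(0, "gesture", rec.gesture_id)
        df.insert(0, "subject", rec.subject_id)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def write_feature_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, index=False)


def read_feature_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path)
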