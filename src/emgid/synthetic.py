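"""Synthetic multi-subject sEMG generator.

Every downstream stage of the pipeline (band log-power features,
Mahalanobis matching, DET/CMC evaluation) sees only the second-order
spectral content of the signal, so the generator produces band-limited,
spectrally shaped Gaussian noise rather than a physiological motor-unit
model.  Each (subject, gesture) class owns a spectral signature -- a
6-segment x channel matrix of log band gains built additively from

    base spectrum + subject offset + gesture offset + channel offset,

with offsets drawn once per entity from zero-mean normals whose standard
deviations are the separability parameters of ``PopulationConfig``.
Each repetition adds per-(segment, channel) jitter
(``within_class_variability``), so repetitions differ while windows
within a repetition share one spectrum -- the structure leave-one-
repetition-out cross-validation assumes.

Shaping is calibrated so that the mean windowed DFT magnitude within
segment i equals exp(log_band_gains[i, c]): the band log-power feature
extracted downstream recovers the signature up to finite-window spectral
leakage.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .config import IdftConfig, PopulationConfig, WindowingConfig, segment_of_frequencies

__all__ = [
    "BASE_LOG_GAINS",
    "SpectralSignature",
    "Recording",
    "SyntheticDataset",
    "draw_population",
    "synthesize_recording",
    "generate_dataset",
    "write_dataset",
    "load_dataset",
]

# Population-level mean log band gain per segment: a broadly sEMG-like
# spectrum, rising to a peak in the second segment (~90-170 Hz over the
# default 10-500 Hz band) and rolling off toward 500 Hz.
BASE_LOG_GAINS = np.array([0.0, 0.3, 0.1, -0.3, -0.8, -1.4])


@dataclass(frozen=True)
class SpectralSignature:
    """Per-(subject, gesture) target spectrum on the log band-gain scale."""

    subject_id: int
    gesture_id: int
    log_band_gains: np.ndarray  # (n_segments, n_channels)

    def __post_init__(self) -> None:
        g = np.asarray(self.log_band_gains, dtype=float)
        if not np.all(np.isfinite(g)):
            raise ValueError("log_band_gains must be finite")
        object.__setattr__(self, "log_band_gains", g)


@dataclass(frozen=True)
class Recording:
    """One steady 5-s contraction: channels x samples, with identity tags."""

    subject_id: int
    gesture_id: int
    repetition_id: int
    signal: np.ndarray  # (n_channels, n_samples)
    sampling_rate: float

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


@dataclass
class SyntheticDataset:
    config: PopulationConfig
    signatures: dict[tuple[int, int], SpectralSignature]
    recordings: list[Recording] = field(default_factory=list)

    @property
    def subjects(self) -> list[int]:
        return list(range(1, self.config.n_subjects + 1))

    @property
    def gestures(self) -> list[int]:
        return list(range(1, self.config.n_gestures + 1))


def draw_population(
    config: PopulationConfig, icfg: IdftConfig | None = None
) -> dict[tuple[int, int], SpectralSignature]:
    """Draw the spectral signature of every (subject, gesture) class.

    Deterministic given ``config.seed``; with both separability parameters
    at zero all classes share one signature per channel.
    """
    icfg = icfg or IdftConfig(band=config.band)
    S, G, C = config.n_subjects, config.n_gestures, config.n_channels
    n_seg = icfg.n_segments
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    channel_off = rng.normal(0.0, config.channel_gain_spread, size=C)
    subject_off = rng.normal(0.0, config.subject_separability, size=(S, n_seg, C))
    gesture_off = rng.normal(0.0, config.gesture_separability, size=(G, n_seg, C))
    base = BASE_LOG_GAINS[:n_seg, None]
    out: dict[tuple[int, int], SpectralSignature] = {}
    for s in range(S):
        for g in range(G):
            gains = base + channel_off[None, :] + subject_off[s] + gesture_off[g]
            out[(s + 1, g + 1)] = SpectralSignature(s + 1, g + 1, gains)
    return out


@lru_cache(maxsize=16)
def _shaping_system(n_samples: int, window_samples: int, sampling_rate: float, icfg: IdftConfig):
    """Linear map from per-segment full-length bin powers to expected
    windowed DFT bin powers, plus the segment-averaging matrix.

    A length-L analysis window cut from a stationary signal sees each
    full-length spectral line through the Fejer (squared Dirichlet)
    kernel; with a rectangular window the sidelobes leak appreciable
    power across segment boundaries, so the shaping gains are solved
    from this system rather than read off the flat-spectrum formula.

    Returns ``(full_seg, M, A)``: segment index per full-length rfft bin
    (-1 out of band), M (in-band window bins x n_segments) mapping
    per-segment full-bin power to expected window-bin power, and A
    (n_segments x in-band window bins) averaging window bins per segment.
    """
    N, L, fs = n_samples, window_samples, sampling_rate
    full_freqs = np.fft.rfftfreq(N, d=1.0 / fs)
    full_seg = segment_of_frequencies(full_freqs, icfg)
    win_freqs = np.fft.rfftfreq(L, d=1.0 / fs)
    win_seg = segment_of_frequencies(win_freqs, icfg)
    jbins = np.flatnonzero(win_seg >= 0)

    k = np.arange(1, (N - 1) // 2 + 1 if N % 2 else N // 2)  # strictly inside (0, N/2)
    delta = k[None, :] / N - jbins[:, None] / L  # (J, K)

    def fejer(d):
        num = np.sin(np.pi * L * d)
        den = np.sin(np.pi * d)
        out = np.where(np.abs(den) < 1e-15, float(L), num / np.where(den == 0, 1.0, den))
        return out ** 2

    F = fejer(delta) + fejer(k[None, :] / N + jbins[:, None] / L)  # +k and N-k lines
    seg_of_k = full_seg[k]
    M = np.zeros((jbins.size, icfg.n_segments))
    for i in range(icfg.n_segments):
        sel = seg_of_k == i
        if sel.any():
            M[:, i] = F[:, sel].sum(axis=1) / N**2
    A = np.zeros((icfg.n_segments, jbins.size))
    for i in range(icfg.n_segments):
        sel = win_seg[jbins] == i
        A[i, sel] = 1.0 / max(sel.sum(), 1)
    return full_seg, M, A


def _solve_band_powers(targets: np.ndarray, M: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Per-segment full-bin powers whose expected windowed segment-mean
    magnitudes equal ``targets`` (one column per channel).

    E|X_w[j]| = (sqrt(pi)/2) sqrt(M a) for circular complex Gaussian
    bins; solves A (sqrt(pi)/2) sqrt(M a) = targets by damped Newton with
    a positivity floor (the floor only binds for pathological contrasts
    where sidelobe leakage alone exceeds a segment's target).
    """
    c = np.sqrt(np.pi) / 2.0
    n_seg, C = targets.shape
    out = np.empty((n_seg, C))
    floor = 1e-30
    for ch in range(C):
        t = targets[:, ch]
        a = np.maximum((t / c) ** 2 / M.sum(axis=1).mean(), floor)
        for _ in range(25):
            p = M @ a
            root = np.sqrt(np.maximum(p, 1e-300))
            r = A @ (c * root) - t
            J = A @ (c * 0.5 / root[:, None] * M)
            try:
                step = np.linalg.solve(J, r)
            except np.linalg.LinAlgError:
                break
            a_new = a - step
            # damp into the feasible region
            lam = 1.0
            while np.any(a - lam * step < 0) and lam > 1e-6:
                lam *= 0.5
            a = np.maximum(a - lam * step, floor)
            if np.max(np.abs(r)) < 1e-12 * max(t.max(), 1e-30):
                break
        out[:, ch] = a
    return out


def _recording_seed(config: PopulationConfig, s: int, g: int, r: int):
    # one spawn-key path per recording: deterministic and collision-free
    return np.random.SeedSequence(config.seed, spawn_key=(1, s, g, r))


def synthesize_recording(
    signature: SpectralSignature,
    config: PopulationConfig,
    repetition_jitter_seed,
    repetition_id: int = 1,
    icfg: IdftConfig | None = None,
    wcfg: WindowingConfig | None = None,
) -> Recording:
    """Render one repetition of a class signature as shaped Gaussian noise.

    The full-length spectrum of each channel is complex Gaussian with a
    piecewise-constant power per frequency segment, zero outside the
    analysis band, then inverse-transformed.  The per-segment powers are
    solved (through the Fejer kernel of the analysis window, see
    :func:`_shaping_system`) so that the expected windowed DFT magnitude
    averaged over segment i equals exp(g_i) -- i.e. the downstream band
    log-power feature recovers g in expectation, including rectangular-
    window leakage across segment boundaries.  Per-repetition jitter
    (within_class_variability) is added to g per (segment, channel)
    before shaping.
    """
    icfg = icfg or IdftConfig(band=config.band)
    wcfg = wcfg or WindowingConfig(sampling_rate=config.sampling_rate)
    gains = np.asarray(signature.log_band_gains, dtype=float)
    n_seg, C = gains.shape
    if C != config.n_channels or n_seg != icfg.n_segments:
        raise ValueError(
            f"signature shape {gains.shape} does not match config "
            f"({icfg.n_segments} segments x {config.n_channels} channels)"
        )
    if config.band[1] > config.sampling_rate / 2.0:
        raise ValueError("band.high exceeds the Nyquist frequency")

    rng = np.random.default_rng(repetition_jitter_seed)
    jitter = rng.normal(0.0, config.within_class_variability, size=(n_seg, C))
    g = gains + jitter

    N = config.n_samples
    L = wcfg.window_samples
    full_seg, M, A = _shaping_system(N, L, config.sampling_rate, icfg)
    a = _solve_band_powers(np.exp(g), M, A)  # (n_seg, C) full-bin powers

    n_bins = N // 2 + 1
    v = np.zeros((C, n_bins))
    in_band = full_seg >= 0
    v[:, in_band] = a[full_seg[in_band], :].T
    v[:, 0] = 0.0  # DC
    if N % 2 == 0:
        v[:, -1] = 0.0  # Nyquist

    re = rng.standard_normal((C, n_bins))
    im = rng.standard_normal((C, n_bins))
    spectrum = np.sqrt(v / 2.0) * (re + 1j * im)
    signal = np.fft.irfft(spectrum, n=N, axis=1)
    return Recording(
        subject_id=signature.subject_id,
        gesture_id=signature.gesture_id,
        repetition_id=repetition_id,
        signal=signal,
        sampling_rate=config.sampling_rate,
    )


def generate_dataset(
    config: PopulationConfig,
    out_dir: str | None = None,
    icfg: IdftConfig | None = None,
    wcfg: WindowingConfig | None = None,
) -> SyntheticDataset:
    """Generate the full subject x gesture x repetition grid of recordings.

    Fully deterministic given ``config.seed``.  When ``out_dir`` is given
    the dataset is also written to disk in the documented layout.
    """
    signatures = draw_population(config, icfg)
    recordings: list[Recording] = []
    for s in range(1, config.n_subjects + 1):
        for g in range(1, config.n_gestures + 1):
            sig = signatures[(s, g)]
            for r in range(1, config.n_repetitions + 1):
                rec = synthesize_recording(
                    sig,
                    config,
                    _recording_seed(config, s, g, r),
                    repetition_id=r,
                    icfg=icfg,
                    wcfg=wcfg,
                )
                recordings.append(rec)
    ds = SyntheticDataset(config=config, signatures=signatures, recordings=recordings)
    if out_dir is not None:
        write_dataset(ds, out_dir)
    return ds


def _rec_relpath(rec: Recording) -> str:
    return os.path.join(f"s{rec.subject_id:02d}", f"g{rec.gesture_id:02d}", f"r{rec.repetition_id}.csv")


def write_dataset(ds: SyntheticDataset, root: str) -> None:
    """Write recordings as headerless per-sample CSV plus a JSON manifest."""
    os.makedirs(root, exist_ok=True)
    checksums = {}
    for rec in ds.recordings:
        rel = _rec_relpath(rec)
        path = os.path.join(root, rel)
        os.makedirs(os.path.dirname(path), exist_ok=True)
        np.savetxt(path, rec.signal.T, fmt="%.8e", delimiter=",")
        with open(path, "rb") as fh:
            checksums[rel.replace(os.sep, "/")] = hashlib.sha256(fh.read()).hexdigest()
    manifest = {
        "format": "emgid-dataset-v1",
        "config": ds.config.to_dict(),
        "seed": ds.config.seed,
        "sampling_rate": ds.config.sampling_rate,
        "checksums": checksums,
    }
    with open(os.path.join(root, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def load_dataset(root: str) -> SyntheticDataset:
    """Read a dataset written by :func:`write_dataset`."""
    with open(os.path.join(root, "manifest.json")) as fh:
        manifest = json.load(fh)
    config = PopulationConfig.from_dict(manifest["config"])
    signatures = draw_population(config)
    recordings = []
    for s in range(1, config.n_subjects + 1):
        for g in range(1, config.n_gestures + 1):
            for r in range(1, config.n_repetitions + 1):
                path = os.path.join(root, f"s{s:02d}", f"g{g:02d}", f"r{r}.csv")
                if not os.path.exists(path):
                    raise FileNotFoundError(f"dataset recording missing: {path}")
                signal = np.loadtxt(path, delimiter=",").T
                if signal.ndim == 1:
                    signal = signal[None, :]
                recordings.append(
                    Recording(s, g, r, signal, manifest["sampling_rate"])
                )
    return SyntheticDataset(config=config, signatures=signatures, recordings=recordings)
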