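"""MFCC feature extraction for percussion traces.

Chain per frame: Hann window -> power spectrum (512-point FFT) -> 40-band
triangular mel filterbank (HTK mel scale) -> natural log with a small floor
-> orthonormal DCT-II -> first 13 coefficients (index 0 retained).  The
per-frame coefficients are then averaged over time to give one fixed-length
13-dimensional vector per signal.  No pre-emphasis, liftering or delta
features; the chain is the simplest standard MFCC pipeline and is fully
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import dct
from scipy.signal import get_window

from .signal_chain import PercussionSignal


@dataclass(frozen=True)
class FeatureConfig:
    n_mfcc: int = 13
    n_fft: int = 512
    n_mels: int = 40
    frame_length: int = 512
    hop_length: int = 256
    window: str = "hann"
    fmin: float = 0.0
    fmax: float | None = None  # None -> Nyquist
    log_floor: float = 1e-10

    def __post_init__(self) -> None:
        if self.n_mfcc > self.n_mels:
            raise ValueError("n_mfcc cannot exceed n_mels")
        if self.frame_length > self.n_fft:
            raise ValueError("frame_length cannot exceed n_fft")
        if self.hop_length <= 0 or self.frame_length <= 0:
            raise ValueError("frame_length and hop_length must be positive")
        if self.log_floor <= 0.0:
            raise ValueError("log_floor must be positive")


@dataclass(frozen=True)
class FeatureVector:
    """Time-averaged MFCCs of one signal."""

    values: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite values")


def hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    """HTK mel scale: mel = 2595 log10(1 + f/700)."""
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(cfg: FeatureConfig, sample_rate: float) -> np.ndarray:
    """Triangular mel filterbank, shape (n_mels, n_fft//2 + 1).

    Centers are equally spaced on the mel scale between fmin and fmax; each
    filter is a unit-peak triangle over the FFT bin frequencies.
    """
    nyquist = sample_rate / 2.0
    fmax = nyquist if cfg.fmax is None else cfg.fmax
    if fmax > nyquist:
        raise ValueError(f"fmax={fmax} exceeds Nyquist {nyquist}")
    if not (0.0 <= cfg.fmin < fmax):
        raise ValueError("need 0 <= fmin < fmax")
    freqs = np.linspace(0.0, nyquist, cfg.n_fft // 2 + 1)
    band_edges = mel_to_hz(
        np.linspace(hz_to_mel(cfg.fmin), hz_to_mel(fmax), cfg.n_mels + 2)
    )
    fb = np.zeros((cfg.n_mels, freqs.size))
    for i in range(cfg.n_mels):
        lo, center, hi = band_edges[i], band_edges[i + 1], band_edges[i + 2]
        rising = (freqs - lo) / (center - lo)
        falling = (hi - freqs) / (hi - center)
        fb[i] = np.clip(np.minimum(rising, falling), 0.0, None)
    return fb


def filterbank_centers(cfg: FeatureConfig, sample_rate: float) -> np.ndarray:
    """Center frequencies (Hz) of the mel filters."""
    nyquist = sample_rate / 2.0
    fmax = nyquist if cfg.fmax is None else cfg.fmax
    return mel_to_hz(
        np.linspace(hz_to_mel(cfg.fmin), hz_to_mel(fmax), cfg.n_mels + 2)
    )[1:-1]


def _frame(x: np.ndarray, frame_length: int, hop_length: int) -> np.ndarray:
    n_frames = 1 + (len(x) - frame_length) // hop_length
    idx = np.arange(frame_length)[None, :] + hop_length * np.arange(n_frames)[:, None]
    return x[idx]


def compute_mfcc(s: PercussionSignal, cfg: FeatureConfig = FeatureConfig()) -> np.ndarray:
    """Frame-wise MFCCs, shape (n_frames, n_mfcc).

    Only full frames are used (no padding); with the default 512/256
    framing a 2205-sample trace yields 7 frames.
    """
    x = np.asarray(s.samples, dtype=float)
    if len(x) < cfg.frame_length:
        raise ValueError(
            f"signal length {len(x)} shorter than one frame ({cfg.frame_length})"
        )
    frames = _frame(x, cfg.frame_length, cfg.hop_length)
    win = get_window(cfg.window, cfg.frame_length, fftbins=True)
    power = np.abs(np.fft.rfft(frames * win, n=cfg.n_fft, axis=1)) ** 2
    fb = mel_filterbank(cfg, s.sample_rate)
    mel_energy = power @ fb.T
    log_energy = np.log(np.maximum(mel_energy, cfg.log_floor))
    coeffs = dct(log_energy, type=2, norm="ortho", axis=1)
    return coeffs[:, : cfg.n_mfcc]


def summarize_features(mfcc_matrix: np.ndarray, sample_id: str = "") -> FeatureVector:
    """Collapse frame-wise MFCCs to their arithmetic time average."""
    m = np.asarray(mfcc_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] == 0:
        raise ValueError("need a non-empty (frames x coefficients) matrix")
    return FeatureVector(values=m.mean(axis=0), sample_id=sample_id)


def extract_features(
    s: PercussionSignal, cfg: FeatureConfig = FeatureConfig(), sample_id: str = ""
) -> FeatureVector:
    """Convenience: compute frame MFCCs and average them."""
    return summarize_features(compute_mfcc(s, cfg), sample_id=sample_id)
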