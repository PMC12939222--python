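"""From raw enamel displacement to the persisted percussion signal.

Each simulated trace is normalized per sample by its peak absolute
displacement, ``s(t) = x1(t) / max_t |x1(t)|``, then corrupted with
independent zero-mean Gaussian measurement noise of standard deviation
``sigma`` (no renormalization afterwards, so the noisy signal may exceed
[-1, 1] -- hence float WAV encoding).  Both operations are strictly
per-sample: no dataset-level statistics leak across samples.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.io import wavfile

DEFAULT_SAMPLE_RATE = 44100


@dataclass(frozen=True)
class PercussionSignal:
    """A sampled percussion trace plus its normalization/noise provenance."""

    samples: np.ndarray
    sample_rate: int = DEFAULT_SAMPLE_RATE
    sigma: float = 0.0
    normalized: bool = False

    def __len__(self) -> int:
        return len(self.samples)


def normalize_signal(
    x1: np.ndarray, sample_rate: int = DEFAULT_SAMPLE_RATE
) -> PercussionSignal:
    """Scale a displacement trace to unit peak absolute amplitude.

    The denominator is ``max |x1|`` (not the signed max), so the output is
    polarity-stable and has peak magnitude exactly 1.  An all-zero trace has
    no meaningful scale and raises.
    """
    x1 = np.asarray(x1, dtype=float)
    if x1.size == 0:
        raise ValueError("cannot normalize an empty trace")
    peak = np.max(np.abs(x1))
    if peak == 0.0:
        raise ValueError("degenerate signal: trace is identically zero")
    return PercussionSignal(samples=x1 / peak, sample_rate=sample_rate, normalized=True)


def add_measurement_noise(
    s: PercussionSignal, sigma: float, rng: np.random.Generator
) -> PercussionSignal:
    """Add i.i.d. N(0, sigma^2) measurement noise per sample."""
    if sigma < 0.0:
        raise ValueError(f"noise SD must be >= 0, got {sigma}")
    if sigma == 0.0:
        return replace(s, sigma=0.0)
    noisy = s.samples + rng.normal(0.0, sigma, size=len(s.samples))
    return replace(s, samples=noisy, sigma=sigma)


def write_wav(s: PercussionSignal, path: Path | str) -> Path:
    """Persist as mono IEEE-float32 WAV (lossless for out-of-range samples).

    Samples are stored as float32; re-reading reproduces the float32 values
    exactly.
    """
    path = Path(path)
    samples = np.asarray(s.samples, dtype=np.float64)
    if not np.all(np.isfinite(samples)):
        raise ValueError("refusing to write non-finite samples")
    wavfile.write(path, int(s.sample_rate), samples.astype(np.float32))
    return path


def read_wav(path: Path | str) -> PercussionSignal:
    """Read a WAV written by :func:`write_wav`.

    Normalization/noise provenance is not stored in the WAV container; it
    lives in the dataset metadata CSV, so the returned flags are neutral.
    """
    path = Path(path)
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"{path} is not mono")
    if data.dtype != np.float32:
        raise ValueError(f"{path} is not float32-encoded (got {data.dtype})")
    return PercussionSignal(samples=data.astype(np.float64), sample_rate=int(rate))


def compute_spectrum(
    s: PercussionSignal, n_fft: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided magnitude spectrum (freqs in Hz, |X_k|), length nfft//2 + 1."""
    x = np.asarray(s.samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    if n_fft is None:
        n_fft = x.size
    mag = np.abs(np.fft.rfft(x, n=n_fft))
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / s.sample_rate)
    return freqs, mag


def dominant_frequency(s: PercussionSignal, skip_dc: bool = True) -> float:
    """Frequency (Hz) of the largest magnitude-spectrum bin."""
    freqs, mag = compute_spectrum(s)
    start = 1 if skip_dc else 0
    return float(freqs[start + int(np.argmax(mag[start:]))])
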