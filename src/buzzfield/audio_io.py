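"""Audio ingestion, spectrograms, noise profiles and spectral smoothing.

Field recordings of foraging bees are long, noisy mono tracks. Everything
downstream of this module works on one of two substrates:

* :class:`Recording` — mono samples at a known rate, nominally in [-1, 1];
* :class:`Spectrogram` — STFT magnitudes on a (frame, frequency-bin) grid.

Noise handling follows the classic spectral-subtraction recipe: estimate a
per-bin noise magnitude profile from a stretch of pure noise, subtract it
from every frame and floor at zero. Harmonic peaks are then sharpened with
a centred 3-bin sliding average before peak picking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile

__all__ = [
    "Recording",
    "Spectrogram",
    "NoiseProfile",
    "load_audio",
    "save_audio",
    "stft_spectrogram",
    "estimate_noise_profile",
    "subtract_noise",
    "smooth_spectrum",
]

# integer PCM full-scale divisors, keyed by numpy kind/itemsize
_PCM_SCALE = {("i", 2): 2 ** 15, ("i", 4): 2 ** 31, ("u", 1): 2 ** 7}


@dataclass
class Recording:
    """Mono audio: samples (nominally in [-1, 1]) plus a sample rate in Hz."""

    samples: np.ndarray
    sample_rate: float
    source_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("Recording samples must be one-dimensional (mono)")
        if len(self.samples) < 1:
            raise ValueError("Recording must contain at least one sample")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return len(self.samples) / self.sample_rate


@dataclass
class Spectrogram:
    """Nonnegative STFT magnitudes, frames x bins, with axis coordinates.

    ``frame_times`` are window centres in seconds; ``bin_freqs`` are bin
    centres in Hz with spacing ``sample_rate / fft_size``.
    """

    magnitudes: np.ndarray
    frame_times: np.ndarray
    bin_freqs: np.ndarray
    window: str = "hamming"
    fft_size: int = 0
    hop: int = 0

    def __post_init__(self) -> None:
        self.magnitudes = np.asarray(self.magnitudes, dtype=np.float64)
        self.frame_times = np.asarray(self.frame_times, dtype=np.float64)
        self.bin_freqs = np.asarray(self.bin_freqs, dtype=np.float64)
        if self.magnitudes.ndim != 2:
            raise ValueError("magnitudes must be a 2-D [frame, bin] matrix")
        if self.magnitudes.shape != (len(self.frame_times), len(self.bin_freqs)):
            raise ValueError("axis coordinates do not match magnitude shape")
        if np.any(self.magnitudes < 0):
            raise ValueError("magnitudes must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.magnitudes.shape[0]

    @property
    def n_bins(self) -> int:
        return self.magnitudes.shape[1]

    @property
    def bin_width(self) -> float:
        return float(self.bin_freqs[1] - self.bin_freqs[0]) if self.n_bins > 1 else 0.0

    def to_frame(self):
        """Long-format DataFrame (frame_time, bin_freq, magnitude) for export."""
        import pandas as pd

        tt, ff = np.meshgrid(self.frame_times, self.bin_freqs, indexing="ij")
        return pd.DataFrame(
            {
                "frame_time": tt.ravel(),
                "bin_freq": ff.ravel(),
                "magnitude": self.magnitudes.ravel(),
            }
        )


@dataclass
class NoiseProfile:
    """Per-bin noise magnitude aligned with a spectrogram's ``bin_freqs``."""

    magnitudes: np.ndarray
    bin_freqs: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.magnitudes = np.asarray(self.magnitudes, dtype=np.float64)
        if self.magnitudes.ndim != 1:
            raise ValueError("noise profile must be one-dimensional")
        if np.any(self.magnitudes < 0):
            raise ValueError("noise profile must be nonnegative")
        if self.bin_freqs is not None:
            self.bin_freqs = np.asarray(self.bin_freqs, dtype=np.float64)
            if len(self.bin_freqs) != len(self.magnitudes):
                raise ValueError("bin_freqs must align with profile length")


def load_audio(path, channel_policy: str = "mix") -> Recording:
    """Read a WAV file into a mono :class:`Recording`.

    Integer PCM is rescaled to [-1, 1]; float WAV is passed through. Stereo
    files are reduced per ``channel_policy``: ``"mix"`` averages channels,
    ``"first"`` keeps channel 0.
    """
    if channel_policy not in ("mix", "first"):
        raise ValueError(f"unknown channel_policy {channel_policy!r}")
    try:
        rate, data = wavfile.read(str(path))
    except FileNotFoundError:
        raise
    except ValueError as exc:
        raise ValueError(f"codec unsupported or unreadable WAV: {path} ({exc})") from exc
    if data.size == 0:
        raise ValueError(f"zero-length audio file: {path}")
    if data.dtype.kind in "iu":
        scale = _PCM_SCALE.get((data.dtype.kind, data.dtype.itemsize))
        if scale is None:
            raise ValueError(f"codec unsupported: {data.dtype} PCM in {path}")
        samples = data.astype(np.float64) / scale
        if data.dtype.kind == "u":  # 8-bit WAV is unsigned, offset binary
            samples -= 1.0
    else:
        samples = data.astype(np.float64)
    if samples.ndim == 2:
        samples = samples.mean(axis=1) if channel_policy == "mix" else samples[:, 0]
    return Recording(samples, float(rate), source_id=str(path))


def save_audio(path, rec: Recording) -> None:
    """Write a Recording as 16-bit PCM WAV (clipped to full scale)."""
    clipped = np.clip(rec.samples, -1.0, 1.0)
    wavfile.write(str(path), int(round(rec.sample_rate)), (clipped * 32767).astype(np.int16))


def stft_spectrogram(
    rec: Recording,
    fft_size: int = 1024,
    hop: int = 256,
    window: str = "hamming",
) -> Spectrogram:
    """Short-time magnitude spectrogram with explicit frame geometry.

    Frames start at multiples of ``hop``; there are
    ``floor((len - fft_size)/hop) + 1`` of them (no padding), each windowed
    and transformed with a real FFT. Frame times are window centres.
    """
    if fft_size < 2:
        raise ValueError("fft_size must be >= 2")
    if hop < 1:
        raise ValueError("hop must be >= 1")
    n = len(rec.samples)
    if n < fft_size:
        raise ValueError(
            f"recording too short for one window ({n} samples < fft_size {fft_size})"
        )
    n_frames = (n - fft_size) // hop + 1
    win = _get_window(window, fft_size)
    idx = np.arange(fft_size)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = rec.samples[idx] * win[None, :]
    mags = np.abs(np.fft.rfft(frames, axis=1))
    freqs = np.fft.rfftfreq(fft_size, d=1.0 / rec.sample_rate)
    times = (hop * np.arange(n_frames) + fft_size / 2.0) / rec.sample_rate
    return Spectrogram(mags, times, freqs, window=window, fft_size=fft_size, hop=hop)


def _get_window(name: str, size: int) -> np.ndarray:
    if name == "hamming":
        return np.hamming(size)
    if name == "hann":
        return np.hanning(size)
    if name in ("rect", "boxcar", "none"):
        return np.ones(size)
    raise ValueError(f"unknown window {name!r}")


def estimate_noise_profile(spec: Spectrogram, t0: float, t1: float) -> NoiseProfile:
    """Per-bin mean magnitude over frames with t0 <= frame_time < t1.

    Mirrors the field workflow of designating a stretch of pure noise
    (typically one second) as the noise reference for a track.
    """
    mask = (spec.frame_times >= t0) & (spec.frame_times < t1)
    if not mask.any():
        raise ValueError(
            f"noise interval [{t0}, {t1}) covers no frames "
            f"(recording frames span {spec.frame_times[0]:.3f}-{spec.frame_times[-1]:.3f} s)"
        )
    return NoiseProfile(spec.magnitudes[mask].mean(axis=0), spec.bin_freqs)


def subtract_noise(spec: Spectrogram, profile: NoiseProfile) -> Spectrogram:
    """Magnitude spectral subtraction, floored at zero."""
    if len(profile.magnitudes) != spec.n_bins:
        raise ValueError(
            f"noise profile length {len(profile.magnitudes)} does not match "
            f"{spec.n_bins} spectrogram bins"
        )
    cleaned = np.maximum(spec.magnitudes - profile.magnitudes[None, :], 0.0)
    return Spectrogram(
        cleaned,
        spec.frame_times,
        spec.bin_freqs,
        window=spec.window,
        fft_size=spec.fft_size,
        hop=spec.hop,
    )


def smooth_spectrum(spectrum) -> np.ndarray:
    """Centred 3-bin sliding average over a magnitude spectrum.

    Edge bins average only their available neighbours (window shrinks to 2
    bins at the ends) so edge amplitudes are not biased downward by implicit
    zero padding. Length is preserved; constants are fixed points.
    """
    x = np.asarray(spectrum, dtype=np.float64)
    if x.ndim != 1 or len(x) == 0:
        raise ValueError("spectrum must be a non-empty 1-D sequence")
    if len(x) == 1:
        return x.copy()
    sums = np.convolve(x, np.ones(3), mode="same")
    counts = np.convolve(np.ones_like(x), np.ones(3), mode="same")
    return sums / counts
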