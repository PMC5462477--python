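"""Characteristic (first-harmonic) frequency extraction.

A bee's flight buzz is a harmonic series whose fundamental equals the
wingbeat frequency — roughly 120-400 Hz for bumble bees, lower for large
queens than for small workers. The "characteristic frequency" of a buzz is
the frequency of that first harmonic, read off a noise-subtracted, smoothed
power spectrum as the strongest peak inside the search band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .audio_io import (
    NoiseProfile,
    Recording,
    estimate_noise_profile,
    smooth_spectrum,
    stft_spectrogram,
    subtract_noise,
)

__all__ = ["CharacteristicFrequency", "power_spectrum", "characteristic_frequency", "extract_char_freq"]

#: first-harmonic range for bumble bee flight buzzes, Hz
DEFAULT_BAND = (120.0, 400.0)
#: FFT length used for frequency read-off (Hamming window)
DEFAULT_FFT = 8192


@dataclass
class CharacteristicFrequency:
    f0: float  # Hz; the wingbeat (first-harmonic) frequency
    band: tuple  # (lo, hi) Hz searched
    peak_magnitude: float

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not (lo <= self.f0 <= hi):
            raise ValueError("f0 must lie inside the searched band")
        if self.peak_magnitude < 0:
            raise ValueError("peak magnitude must be nonnegative")


def power_spectrum(
    rec: Recording,
    segment: tuple | None = None,
    fft_size: int = DEFAULT_FFT,
    window: str = "hamming",
    hop: int | None = None,
):
    """Average magnitude spectrum of a recording segment.

    The segment is framed (Hamming window, ``fft_size`` points, half-window
    hop by default) and per-frame magnitudes are averaged, mirroring a
    spectrum read-off over a marked buzz. Returns ``(magnitudes, bin_freqs)``.

    Raises if the segment is shorter than one window; zero-padding is not
    applied implicitly — pass a smaller ``fft_size`` instead.
    """
    if segment is not None:
        t0, t1 = segment
        i0 = max(int(np.floor(t0 * rec.sample_rate)), 0)
        i1 = min(int(np.ceil(t1 * rec.sample_rate)), len(rec.samples))
        samples = rec.samples[i0:i1]
    else:
        samples = rec.samples
    if len(samples) < fft_size:
        raise ValueError(
            f"segment has {len(samples)} samples, fewer than fft_size={fft_size}; "
            "choose a smaller FFT size (implicit zero-padding is off)"
        )
    seg = Recording(samples, rec.sample_rate, source_id=rec.source_id)
    spec = stft_spectrogram(seg, fft_size=fft_size, hop=hop or fft_size // 2, window=window)
    return spec.magnitudes.mean(axis=0), spec.bin_freqs


def characteristic_frequency(
    spectrum,
    bin_freqs,
    band: tuple = DEFAULT_BAND,
    octave_guard: float = 0.5,
) -> CharacteristicFrequency | None:
    """Pick the characteristic frequency from a (smoothed) spectrum.

    f0 is the bin-centre frequency of the maximal magnitude within ``band``;
    exact ties break toward the lower frequency. Returns ``None`` ("no peak")
    when the band is all-zero — distinct from a misuse error.

    Octave-error guard: harmonic series sometimes carry a weak fundamental,
    so if the magnitude at f0/2 (when itself inside the band) exceeds
    ``octave_guard`` x the peak, f0/2 is reported instead. Set
    ``octave_guard=None`` to disable.
    """
    x = np.asarray(spectrum, dtype=np.float64)
    freqs = np.asarray(bin_freqs, dtype=np.float64)
    if x.shape != freqs.shape:
        raise ValueError("spectrum and bin_freqs must align")
    lo, hi = band
    in_band = np.nonzero((freqs >= lo) & (freqs <= hi))[0]
    if len(in_band) == 0:
        raise ValueError(f"band {band} does not intersect bin frequencies")
    mags = x[in_band]
    if np.all(mags == 0):
        return None
    best = in_band[int(np.argmax(mags))]  # argmax takes the first = lowest-frequency tie
    f0 = float(freqs[best])
    peak = float(x[best])
    if octave_guard is not None:
        half_bin = int(round(best / 2))
        if freqs[half_bin] >= lo and x[half_bin] > octave_guard * peak:
            best, f0, peak = half_bin, float(freqs[half_bin]), float(x[half_bin])
    return CharacteristicFrequency(f0=f0, band=(float(lo), float(hi)), peak_magnitude=peak)


def extract_char_freq(
    rec: Recording,
    segment: tuple | None = None,
    noise_interval: tuple | None = None,
    band: tuple = DEFAULT_BAND,
    fft_size: int = DEFAULT_FFT,
) -> CharacteristicFrequency | None:
    """Full read-off pipeline: spectrum -> noise subtraction -> smoothing -> peak.

    ``noise_interval`` marks a stretch of pure noise (seconds) used as the
    per-bin noise reference; omit it for clean recordings.
    """
    spec = stft_spectrogram(
        rec if segment is None else _slice(rec, segment),
        fft_size=fft_size,
        hop=fft_size // 2,
        window="hamming",
    )
    if noise_interval is not None:
        profile = estimate_noise_profile(spec, *noise_interval)
        spec = subtract_noise(spec, profile)
    mean_spectrum = spec.magnitudes.mean(axis=0)
    return characteristic_frequency(smooth_spectrum(mean_spectrum), spec.bin_freqs, band=band)


def _slice(rec: Recording, segment: tuple) -> Recording:
    t0, t1 = segment
    i0 = max(int(np.floor(t0 * rec.sample_rate)), 0)
    i1 = min(int(np.ceil(t1 * rec.sample_rate)), len(rec.samples))
    return Recording(rec.samples[i0:i1], rec.sample_rate, source_id=rec.source_id)
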