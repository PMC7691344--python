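"""FFT-based breaths-per-minute estimation.

The respiratory rate is read off the magnitude spectrum of the two band
signals: each channel is mean-subtracted, transformed with an FFT (zero
padded to the next power of two, rectangular window), and the two magnitude
spectra are averaged per bin. Within a physiological band the largest
magnitude is found, every bin within 20% of it is kept, and the rate is the
amplitude-weighted mean of the selected bin frequencies times 60.

The default band [0.3, 3.0] Hz (18–180 breaths/min) excludes baseline
drift below and motion harmonics above the plausible rodent breathing
range; both edges are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import RipRecording
from .errors import NoSpectralContentError

__all__ = [
    "SpectrumEstimate",
    "BpmEstimate",
    "DEFAULT_BAND_HZ",
    "magnitude_spectrum",
    "bpm_from_spectrum",
    "breaths_per_minute",
]

DEFAULT_BAND_HZ: tuple[float, float] = (0.3, 3.0)

#: A spectral line must stand at least this many times above the in-band
#: median magnitude, otherwise the record is treated as having no dominant
#: breathing frequency (noise guard).
NOISE_FLOOR_RATIO = 3.0


@dataclass(frozen=True)
class SpectrumEstimate:
    """In-band average magnitude spectrum of the two channels."""

    freqs_hz: np.ndarray
    mag: np.ndarray
    nfft: int
    fs: float

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs_hz, dtype=float)
        mag = np.asarray(self.mag, dtype=float)
        if freqs.shape != mag.shape:
            raise ValueError("freqs_hz and mag must have equal length")
        if len(freqs) and (freqs[0] < 0 or np.any(np.diff(freqs) <= 0)):
            raise ValueError("freqs_hz must be nonnegative and ascending")
        if np.any(mag < 0):
            raise ValueError("magnitudes must be nonnegative")
        object.__setattr__(self, "freqs_hz", freqs)
        object.__setattr__(self, "mag", mag)

    @property
    def bin_hz(self) -> float:
        """Frequency resolution of the transform."""
        return self.fs / self.nfft


@dataclass(frozen=True)
class BpmEstimate:
    """Weighted-average breathing rate derived from a magnitude spectrum.

    ``valid`` is False when no spectral line stands clearly above the noise
    floor; ``bpm`` then still carries the (untrustworthy) weighted average
    for inspection.
    """

    bpm: float
    peak_hz: float
    n_bins_used: int
    bin_hz: float
    valid: bool = True


def _next_pow2(n: int) -> int:
    return 1 << max(0, (n - 1)).bit_length()


def magnitude_spectrum(
    recording: RipRecording,
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
) -> SpectrumEstimate:
    """Per-bin magnitudes averaged across the RC and AB channels.

    Both channels are mean-subtracted, zero-padded to the next power of two
    and transformed; the result is restricted to ``band_hz`` with the DC
    bin excluded. Deterministic for fixed input.
    """
    lo, hi = band_hz
    nyquist = recording.fs / 2.0
    if not (0 <= lo < hi <= nyquist):
        raise ValueError(
            f"band [{lo}, {hi}] must satisfy 0 <= lo < hi <= fs/2 ({nyquist})"
        )
    if recording.n_samples < 2 * recording.fs:
        raise ValueError(
            f"recording of {recording.n_samples} samples is shorter than 2 s "
            f"at fs={recording.fs}"
        )
    nfft = _next_pow2(recording.n_samples)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / recording.fs)
    mag_rc = np.abs(np.fft.rfft(recording.rc - recording.rc.mean(), nfft))
    mag_ab = np.abs(np.fft.rfft(recording.ab - recording.ab.mean(), nfft))
    mag = 0.5 * (mag_rc + mag_ab)
    keep = (freqs >= lo) & (freqs <= hi) & (freqs > 0)
    if not np.any(keep):
        raise NoSpectralContentError(
            f"no FFT bins inside [{lo}, {hi}] Hz at resolution {recording.fs / nfft:.4g} Hz"
        )
    return SpectrumEstimate(
        freqs_hz=freqs[keep], mag=mag[keep], nfft=nfft, fs=recording.fs
    )


def bpm_from_spectrum(
    spec: SpectrumEstimate, noise_floor_ratio: float = NOISE_FLOOR_RATIO
) -> BpmEstimate:
    """Amplitude-weighted dominant frequency, in breaths per minute.

    Let M be the maximum in-band magnitude; every bin with magnitude
    ≥ 0.8·M is selected and the estimate is
    ``60 · Σ(f_i · m_i) / Σ(m_i)`` over the selected bins — the reading of
    the 20%-band weighted average that reduces to the peak frequency for a
    single spectral line.
    """
    mag = spec.mag
    if len(mag) == 0 or float(mag.max()) <= 0.0:
        raise NoSpectralContentError("all in-band magnitudes are zero")
    m_max = float(mag.max())
    peak_hz = float(spec.freqs_hz[int(np.argmax(mag))])
    selected = mag >= 0.8 * m_max
    f_sel = spec.freqs_hz[selected]
    m_sel = mag[selected]
    bpm = 60.0 * float(np.sum(f_sel * m_sel) / np.sum(m_sel))
    valid = m_max >= noise_floor_ratio * float(np.median(mag))
    return BpmEstimate(
        bpm=bpm,
        peak_hz=peak_hz,
        n_bins_used=int(selected.sum()),
        bin_hz=spec.bin_hz,
        valid=valid,
    )


def breaths_per_minute(
    recording: RipRecording,
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
) -> BpmEstimate:
    """Whole-record breathing rate: spectrum estimation then weighted peak."""
    return bpm_from_spectrum(magnitude_spectrum(recording, band_hz))
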