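"""Domain types and per-window work-of-breathing indices.

Respiratory inductance plethysmography (RIP) records thoracoabdominal
motion with two elastic bands: one around the rib cage (RC) and one around
the abdomen (AB). Under the classical Konno–Mead two-compartment model the
band excursions approximate compartmental volume changes, and three indices
summarise breathing effort and synchrony within a short analysis window:

* **RC%** — the rib-cage contribution to tidal volume,
  ``100 * A_rc / (A_rc + A_ab)`` where ``A_c`` is the compartment's
  excursion (peak-to-peak of the linearly detrended window).
* **LBI** (labored breathing index) — the ratio of the maximal compartmental
  amplitude (the tidal excursion the compartments would produce in unison,
  ``A_rc + A_ab``) to the excursion of the recorded sum ``rc + ab`` (the
  tidal-volume proxy). LBI is 1 for perfectly synchronous breathing and
  grows with asynchrony.
* **Phase angle (Φ)** — the angle whose cosine is the normalized inner
  product of the mean-subtracted channels,
  ``arccos(Σ x·y / sqrt(Σx² · Σy²))``, in degrees. 0° is perfect synchrony,
  180° is paradoxical (opposed) motion. The angle is unsigned: the formula
  cannot distinguish RC-leads from AB-leads.

All three are computed on the same N-sample window (default 20; at a 10 Hz
output cadence that covers roughly two rat breaths).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import DegenerateWindowError

__all__ = [
    "RipRecording",
    "AnalysisWindow",
    "WobSample",
    "SynchronyThresholds",
    "SynchronyLabel",
    "DEFAULT_WINDOW_N",
    "excursion",
    "rc_percent",
    "phase_angle",
    "lbi",
    "classify_synchrony",
]

#: Default analysis-window length in samples, applied to all three indices.
DEFAULT_WINDOW_N = 20

#: Minimum meaningful window length; below this, amplitude and phase
#: estimates are rejected outright.
MIN_WINDOW_N = 4


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class RipRecording:
    """A two-channel uncalibrated band-displacement recording.

    Parameters
    ----------
    subject_id:
        Identifier of the recorded subject.
    fs:
        Sampling rate in Hz; must be positive and finite.
    rc, ab:
        Rib-cage and abdomen band amplitudes in arbitrary units; equal
        length, at least 2 samples, all finite.
    metadata:
        Optional pass-through annotations (e.g. ``weight_g``, ``hr_bpm``,
        ``spo2_pct``, ``etco2_mmHg``, anesthesia notes). Never computed on.
    """

    subject_id: str
    fs: float
    rc: np.ndarray
    ab: np.ndarray
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        rc = _as_float_array(self.rc, "rc")
        ab = _as_float_array(self.ab, "ab")
        if len(rc) != len(ab):
            raise ValueError(
                f"rc and ab must have equal length, got {len(rc)} and {len(ab)}"
            )
        if len(rc) < 2:
            raise ValueError("recording must hold at least 2 samples per channel")
        if not (math.isfinite(self.fs) and self.fs > 0):
            raise ValueError(f"fs must be positive and finite, got {self.fs}")
        if not np.all(np.isfinite(rc)):
            raise ValueError("rc contains non-finite samples")
        if not np.all(np.isfinite(ab)):
            raise ValueError("ab contains non-finite samples")
        rc.setflags(write=False)
        ab.setflags(write=False)
        object.__setattr__(self, "rc", rc)
        object.__setattr__(self, "ab", ab)
        object.__setattr__(self, "metadata", dict(self.metadata))

    @property
    def n_samples(self) -> int:
        return len(self.rc)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


@dataclass(frozen=True)
class AnalysisWindow:
    """A contiguous N-sample slice of both channels.

    ``t_index`` is the index of the window's *last* sample in the parent
    recording (right-aligned, causal windows: a real-time instrument only
    has past samples).
    """

    rc_w: np.ndarray
    ab_w: np.ndarray
    t_index: int = 0

    def __post_init__(self) -> None:
        rc_w = _as_float_array(self.rc_w, "rc_w")
        ab_w = _as_float_array(self.ab_w, "ab_w")
        if len(rc_w) != len(ab_w):
            raise ValueError(
                f"window channels must match in length, got {len(rc_w)} and {len(ab_w)}"
            )
        if len(rc_w) < MIN_WINDOW_N:
            raise ValueError(
                f"window length {len(rc_w)} below minimum {MIN_WINDOW_N}"
            )
        object.__setattr__(self, "rc_w", rc_w)
        object.__setattr__(self, "ab_w", ab_w)

    @property
    def n(self) -> int:
        return len(self.rc_w)

    @classmethod
    def from_recording(
        cls, recording: RipRecording, t_index: int, n: int = DEFAULT_WINDOW_N
    ) -> "AnalysisWindow":
        """Right-aligned window ending at ``t_index`` (inclusive)."""
        start = t_index - n + 1
        if start < 0 or t_index >= recording.n_samples:
            raise ValueError(
                f"window [{start}, {t_index}] out of bounds for "
                f"{recording.n_samples}-sample recording"
            )
        return cls(
            rc_w=recording.rc[start : t_index + 1],
            ab_w=recording.ab[start : t_index + 1],
            t_index=t_index,
        )


def _nan_eq(a: float, b: float) -> bool:
    return (a == b) or (math.isnan(a) and math.isnan(b))


@dataclass(frozen=True)
class WobSample:
    """Per-window index values emitted at the output cadence.

    ``valid`` is False when any estimate was degenerate (flat window,
    zero-variance channel, vanishing summed excursion); the numeric fields
    are then NaN for the estimates that failed.
    """

    t_index: int
    phase_deg: float
    lbi: float
    rc_percent: float
    valid: bool

    def __eq__(self, other: object) -> bool:  # NaN-tolerant field equality
        if not isinstance(other, WobSample):
            return NotImplemented
        return (
            self.t_index == other.t_index
            and self.valid == other.valid
            and _nan_eq(self.phase_deg, other.phase_deg)
            and _nan_eq(self.lbi, other.lbi)
            and _nan_eq(self.rc_percent, other.rc_percent)
        )


@dataclass(frozen=True)
class SynchronyThresholds:
    """Decision thresholds for breathing-pattern classification.

    Normal synchronous breathing in humans and most mammals is seen at
    Φ < 30° together with LBI < 1.05. Strictly, only Φ = 180° is
    paradoxical; under measurement noise that class would be empty, so a
    configurable band Φ ≥ ``phase_paradox_deg`` (default 150°) is labelled
    paradoxical instead — an extension of the strict definition.
    """

    phase_sync_deg: float = 30.0
    lbi_sync: float = 1.05
    phase_paradox_deg: float = 150.0


DEFAULT_THRESHOLDS = SynchronyThresholds()


@dataclass(frozen=True)
class SynchronyLabel:
    """Classification outcome; a pure function of (Φ, LBI, thresholds)."""

    label: str  # one of {"synchronous", "asynchronous", "paradoxical"}
    phase_deg: float
    lbi: float


def excursion(x: np.ndarray) -> float:
    """Peak-to-peak amplitude of a window after linear detrend.

    The detrend removes the straight line through the window's first and
    last samples. This removes any baseline drift shared by the channels
    exactly (band tension creep, posture shifts) while leaving a
    whole-period oscillation untouched — a least-squares line, by contrast,
    fits a substantial spurious slope to a pure sinusoid and biases its
    peak-to-peak by several percent. Operates on a copy; the input is
    untouched.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    line = x[0] + (x[-1] - x[0]) * np.arange(n) / (n - 1)
    resid = x - line
    return float(resid.max() - resid.min())


def rc_percent(window: AnalysisWindow, eps: float = 1e-12) -> float:
    """Rib-cage contribution to tidal volume, in percent.

    Returns ``100 * A_rc / (A_rc + A_ab)`` with ``A_c`` the detrended
    peak-to-peak excursion of each compartment.

    Raises
    ------
    DegenerateWindowError
        If both excursions are below ``eps`` (flat window).
    """
    a_rc = excursion(window.rc_w)
    a_ab = excursion(window.ab_w)
    total = a_rc + a_ab
    if total < eps:
        raise DegenerateWindowError(
            f"flat window at t_index={window.t_index}: combined excursion {total:.3g}"
        )
    return 100.0 * a_rc / total


def phase_angle(window: AnalysisWindow) -> float:
    """Thoracoabdominal phase angle Φ in degrees, range [0, 180].

    Both channels are mean-subtracted over the window (normalisation), then
    Φ = arccos of their normalized inner product. The arccos argument is
    clamped to [-1, 1] to absorb floating-point rounding. Symmetric under
    channel swap and invariant to positive rescaling of either channel.

    Raises
    ------
    DegenerateWindowError
        If either channel has zero variance within the window (phase
        undefined).
    """
    x = window.rc_w - window.rc_w.mean()
    y = window.ab_w - window.ab_w.mean()
    xx = float(np.dot(x, x))
    yy = float(np.dot(y, y))
    if xx == 0.0 or yy == 0.0:
        raise DegenerateWindowError(
            f"zero-variance channel at t_index={window.t_index}: phase undefined"
        )
    c = float(np.dot(x, y)) / math.sqrt(xx * yy)
    c = min(1.0, max(-1.0, c))
    return math.degrees(math.acos(c))


def lbi(
    window: AnalysisWindow, eps: float = 1e-12, eps_rel: float = 1e-6
) -> float:
    """Labored breathing index: (A_rc + A_ab) / A_sum, ≥ 1 up to rounding.

    The numerator is the maximal compartmental amplitude — the tidal
    excursion the two compartments would produce breathing in unison. The
    denominator is the excursion of the sample-wise sum ``rc + ab``, the
    uncalibrated tidal-volume proxy. Peak-to-peak is sub-additive, so the
    ratio is ≥ 1, reaching 1 at perfect synchrony and diverging toward
    total paradox.

    Raises
    ------
    DegenerateWindowError
        If the window is flat, or if the summed excursion falls below
        ``eps_rel`` times the combined compartmental excursion (near-total
        paradox with equal amplitudes) — an invalid sample is preferable to
        an unbounded index.
    """
    a_rc = excursion(window.rc_w)
    a_ab = excursion(window.ab_w)
    total = a_rc + a_ab
    if total < eps:
        raise DegenerateWindowError(
            f"flat window at t_index={window.t_index}: combined excursion {total:.3g}"
        )
    a_sum = excursion(window.rc_w + window.ab_w)
    if a_sum < eps_rel * total:
        raise DegenerateWindowError(
            f"vanishing tidal excursion at t_index={window.t_index}: "
            f"A_sum={a_sum:.3g} vs A_rc+A_ab={total:.3g}"
        )
    return total / a_sum


def classify_synchrony(
    phase_deg: float,
    lbi_value: float,
    thresholds: SynchronyThresholds = DEFAULT_THRESHOLDS,
) -> SynchronyLabel:
    """Classify a (Φ, LBI) pair as synchronous, asynchronous or paradoxical.

    Synchronous requires both Φ below the synchrony threshold and LBI below
    its threshold; paradoxical is Φ at or above the paradox threshold;
    everything else is asynchronous.
    """
    if not (0.0 <= phase_deg <= 180.0):
        raise ValueError(f"phase_deg must be in [0, 180], got {phase_deg}")
    if lbi_value < 1.0 - 1e-9:
        raise ValueError(f"lbi must be >= 1, got {lbi_value}")
    if phase_deg >= thresholds.phase_paradox_deg:
        label = "paradoxical"
    elif phase_deg < thresholds.phase_sync_deg and lbi_value < thresholds.lbi_sync:
        label = "synchronous"
    else:
        label = "asynchronous"
    return SynchronyLabel(label=label, phase_deg=phase_deg, lbi=lbi_value)
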