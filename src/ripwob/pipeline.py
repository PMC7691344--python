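"""Sliding-window analysis and cohort summarisation.

``analyze_recording`` slides a right-aligned window across a recording and
emits one work-of-breathing sample per position — with a 10 Hz recording,
window 20 and stride 1 this reproduces the instrument's cadence of ten
index measurements per second. ``summarize_cohort`` builds mean ± SEM rows
per variable with subjects (not pooled windows) as the unit of replication,
``histogram`` pools valid samples across subjects into fixed-width bins
with a percent-in-range statistic, and ``tam_trace`` exports the paired
mean-removed thoracoabdominal motion traces for plotting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import core
from .core import AnalysisWindow, RipRecording, WobSample
from .errors import DegenerateWindowError, InsufficientDataError
from .rate import BpmEstimate

__all__ = [
    "WobSeries",
    "SummaryRow",
    "CohortSummary",
    "HistogramResult",
    "DEFAULT_BIN_WIDTHS",
    "analyze_recording",
    "summarize_cohort",
    "histogram",
    "tam_trace",
    "TamTrace",
]

#: Default histogram bin widths per variable.
DEFAULT_BIN_WIDTHS = {"phase_deg": 2.0, "lbi": 0.01, "rc_percent": 2.0}

#: Metadata keys passed through from acquisition into the cohort summary.
METADATA_VARIABLES = ("weight_g", "hr_bpm", "spo2_pct", "etco2_mmHg")


@dataclass(frozen=True)
class WobSeries:
    """Ordered per-window index samples for one recording."""

    samples: tuple[WobSample, ...]
    window_n: int
    stride: int
    fs: float
    source_id: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", tuple(self.samples))
        idx = [s.t_index for s in self.samples]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("samples must be strictly increasing in t_index")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def cadence_hz(self) -> float:
        """Emission rate of index samples per second (fs / stride)."""
        return self.fs / self.stride

    @property
    def n_valid(self) -> int:
        return sum(s.valid for s in self.samples)

    @property
    def valid_fraction(self) -> float:
        return self.n_valid / len(self.samples) if self.samples else float("nan")

    def values(self, variable: str, valid_only: bool = True) -> np.ndarray:
        """Array of one index variable across samples."""
        if variable not in ("phase_deg", "lbi", "rc_percent"):
            raise ValueError(f"unknown series variable {variable!r}")
        samples = [s for s in self.samples if s.valid] if valid_only else self.samples
        return np.array([getattr(s, variable) for s in samples], dtype=float)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_index": [s.t_index for s in self.samples],
                "time_s": [s.t_index / self.fs for s in self.samples],
                "phase_deg": [s.phase_deg for s in self.samples],
                "lbi": [s.lbi for s in self.samples],
                "rc_percent": [s.rc_percent for s in self.samples],
                "valid": [int(s.valid) for s in self.samples],
            }
        )


def analyze_recording(
    recording: RipRecording,
    window_n: int = core.DEFAULT_WINDOW_N,
    stride: int = 1,
) -> WobSeries:
    """Emit one WobSample per window position across the recording.

    Windows are right-aligned (causal): the first window ends at sample
    ``window_n - 1``, successive windows advance by ``stride``. A window on
    which any index is degenerate yields a sample with ``valid=False`` and
    NaN for the failed estimates rather than aborting the run.
    """
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    if recording.n_samples < window_n:
        raise InsufficientDataError(
            f"recording of {recording.n_samples} samples is shorter than one "
            f"{window_n}-sample window"
        )
    samples = []
    for end in range(window_n - 1, recording.n_samples, stride):
        window = AnalysisWindow.from_recording(recording, end, window_n)
        phase = lbi_v = rcp = float("nan")
        ok = True
        try:
            phase = core.phase_angle(window)
        except DegenerateWindowError:
            ok = False
        try:
            lbi_v = core.lbi(window)
        except DegenerateWindowError:
            ok = False
        try:
            rcp = core.rc_percent(window)
        except DegenerateWindowError:
            ok = False
        samples.append(
            WobSample(t_index=end, phase_deg=phase, lbi=lbi_v, rc_percent=rcp, valid=ok)
        )
    return WobSeries(
        samples=tuple(samples),
        window_n=window_n,
        stride=stride,
        fs=recording.fs,
        source_id=recording.subject_id,
    )


@dataclass(frozen=True)
class SummaryRow:
    """Mean ± SEM of one variable across subjects.

    ``sem`` is the sample standard deviation over subject-level values
    divided by sqrt(n); NaN when only one subject contributes.
    """

    name: str
    mean: float
    sem: float
    n: int


@dataclass(frozen=True)
class CohortSummary:
    """Mean ± SEM table across subjects plus per-subject valid fractions."""

    rows: dict[str, SummaryRow]
    n_subjects: int
    valid_fractions: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, name: str) -> SummaryRow:
        return self.rows[name]


def _mean_sem(values: Sequence[float]) -> tuple[float, float, int]:
    arr = np.asarray(values, dtype=float)
    n = len(arr)
    mean = float(arr.mean())
    sem = float(arr.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
    return mean, sem, n


def summarize_cohort(
    series_list: Sequence[WobSeries],
    metadata: Sequence[Mapping[str, object]] | None = None,
    bpm_estimates: Sequence[BpmEstimate | None] | None = None,
) -> CohortSummary:
    """Cohort mean ± SEM table over subjects.

    Subject-level means are computed first (one value per subject per index
    variable, over that subject's valid samples), then the cohort mean and
    SEM are taken across subjects — so a long recording cannot dominate the
    table. Physiological annotations (weight, heart rate, SpO2, ETCO2) and
    per-subject BPM estimates are summarised the same way when supplied.
    """
    if not series_list:
        raise ValueError("summarize_cohort requires at least one series")
    for s in series_list:
        if s.n_valid == 0:
            raise ValueError(f"series {s.source_id!r} has no valid samples")
    if metadata is not None and len(metadata) != len(series_list):
        raise ValueError("metadata list must align with series list")
    if bpm_estimates is not None and len(bpm_estimates) != len(series_list):
        raise ValueError("bpm_estimates list must align with series list")

    rows: dict[str, SummaryRow] = {}
    if metadata is not None:
        for var in METADATA_VARIABLES:
            vals = [
                float(m[var])  # type: ignore[arg-type]
                for m in metadata
                if m is not None and m.get(var) is not None
            ]
            if vals:
                mean, sem, n = _mean_sem(vals)
                rows[var] = SummaryRow(name=var, mean=mean, sem=sem, n=n)
    if bpm_estimates is not None:
        vals = [b.bpm for b in bpm_estimates if b is not None and b.valid]
        if vals:
            mean, sem, n = _mean_sem(vals)
            rows["bpm"] = SummaryRow(name="bpm", mean=mean, sem=sem, n=n)
    for var in ("phase_deg", "rc_percent", "lbi"):
        per_subject = [float(s.values(var).mean()) for s in series_list]
        mean, sem, n = _mean_sem(per_subject)
        rows[var] = SummaryRow(name=var, mean=mean, sem=sem, n=n)

    return CohortSummary(
        rows=rows,
        n_subjects=len(series_list),
        valid_fractions={s.source_id: s.valid_fraction for s in series_list},
    )


@dataclass(frozen=True)
class HistogramResult:
    """Fixed-width histogram of pooled valid samples.

    Bin edges start on the bin-width grid at or below the data minimum;
    counting and ``pct_in_range`` both use inclusive-low / exclusive-high
    intervals.
    """

    variable: str
    bin_edges: np.ndarray
    counts: np.ndarray
    values: np.ndarray  # pooled valid samples the histogram was built from

    def __post_init__(self) -> None:
        object.__setattr__(self, "bin_edges", np.asarray(self.bin_edges, dtype=float))
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=int))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if len(self.bin_edges) != len(self.counts) + 1:
            raise ValueError("bin_edges must be one longer than counts")
        if int(self.counts.sum()) != len(self.values):
            raise ValueError("counts must sum to the number of pooled values")

    def pct_in_range(self, lo: float, hi: float) -> float:
        """Percent of pooled values with lo <= value < hi."""
        if len(self.values) == 0:
            return float("nan")
        inside = (self.values >= lo) & (self.values < hi)
        return 100.0 * float(inside.mean())


def histogram(
    series_list: Sequence[WobSeries],
    variable: str,
    bin_width: float | None = None,
) -> HistogramResult:
    """Pool valid samples of one variable across subjects into fixed bins."""
    if bin_width is None:
        bin_width = DEFAULT_BIN_WIDTHS.get(variable, 1.0)
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    pooled = np.concatenate([s.values(variable) for s in series_list])
    if len(pooled) == 0:
        raise ValueError("no valid samples to histogram")
    start = math.floor(pooled.min() / bin_width) * bin_width
    # inclusive-lo/exclusive-hi bin assignment; a value landing exactly on
    # the top edge opens one more bin
    idx = np.floor((pooled - start) / bin_width).astype(int)
    n_bins = int(idx.max()) + 1
    counts = np.bincount(idx, minlength=n_bins)
    edges = start + bin_width * np.arange(n_bins + 1)
    return HistogramResult(
        variable=variable, bin_edges=edges, counts=counts, values=pooled
    )


@dataclass(frozen=True)
class TamTrace:
    """Time-aligned mean-removed RC/AB traces for TAM plotting or export."""

    time_s: np.ndarray
    rc: np.ndarray
    ab: np.ndarray
    source_id: str


def tam_trace(
    recording: RipRecording,
    sample_range: tuple[int, int] | None = None,
) -> TamTrace:
    """Paired mean-removed thoracoabdominal motion traces, no resampling.

    ``sample_range`` is a half-open (start, stop) selection in sample
    indices; the mean is removed over the selected span so both traces are
    centred for overlay plotting.
    """
    start, stop = sample_range if sample_range is not None else (0, recording.n_samples)
    rc = recording.rc[start:stop]
    ab = recording.ab[start:stop]
    time_s = recording.time_s[start:stop]
    if len(rc):
        rc = rc - rc.mean()
        ab = ab - ab.mean()
    return TamTrace(time_s=time_s, rc=rc, ab=ab, source_id=recording.subject_id)
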