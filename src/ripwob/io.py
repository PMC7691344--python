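"""Reading and writing recordings, index series, and summary documents.

Recordings travel as plain CSV with a ``time_s,rc,ab`` header — human
readable and diff-able, with an optional JSON sidecar for subject metadata
(``{subject_id, weight_g, hr_bpm, spo2_pct, etco2_mmHg}``). The sampling
rate is inferred from the time column (1 / median Δt) unless supplied
explicitly; timestamps must be strictly increasing and near-uniform (any
interval deviating more than 1% from the median is rejected with a
diagnostic).

Index series are CSV with columns
``t_index,time_s,phase_deg,lbi,rc_percent,valid`` preceded by ``#``
key=value comment lines carrying the windowing provenance, so a series
file round-trips to an equal in-memory object. Cohort summaries and
histograms are JSON.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import RipRecording, WobSample
from .errors import RecordingParseError
from .pipeline import CohortSummary, HistogramResult, SummaryRow, WobSeries

__all__ = [
    "read_recording",
    "write_recording",
    "write_series",
    "read_series",
    "summary_document",
    "write_summary",
    "read_summary",
]

REQUIRED_COLUMNS = ("time_s", "rc", "ab")
SERIES_COLUMNS = ("t_index", "time_s", "phase_deg", "lbi", "rc_percent", "valid")

#: Maximum tolerated deviation of any sampling interval from the median,
#: as a fraction of the median interval.
MAX_DT_DEVIATION = 0.01


def read_recording(
    path: str | Path,
    fs: float | None = None,
    sidecar: str | Path | None = None,
    subject_id: str | None = None,
) -> RipRecording:
    """Load a two-channel recording from CSV, validating the time base.

    ``fs`` overrides the rate inferred from timestamps. Metadata is merged
    from the JSON sidecar when given; an explicit ``subject_id`` argument
    wins over the sidecar, which wins over the file stem.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise RecordingParseError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise RecordingParseError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )
    if len(df) < 2:
        raise RecordingParseError(f"{path}: need at least 2 rows, got {len(df)}")
    for col in REQUIRED_COLUMNS:
        bad = np.flatnonzero(~np.isfinite(df[col].to_numpy(dtype=float)))
        if len(bad):
            # +2: one for the header line, one for 1-based numbering
            rows = ", ".join(str(i + 2) for i in bad[:5])
            raise RecordingParseError(
                f"{path}: non-finite value in column {col!r} at file row(s) {rows}"
            )
    time_s = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(time_s)
    if np.any(dt <= 0):
        row = int(np.flatnonzero(dt <= 0)[0]) + 2
        raise RecordingParseError(
            f"{path}: time_s not strictly increasing at file row {row + 1}"
        )
    median_dt = float(np.median(dt))
    deviation = np.abs(dt - median_dt)
    if np.any(deviation > MAX_DT_DEVIATION * median_dt):
        worst = int(np.argmax(deviation))
        raise RecordingParseError(
            f"{path}: irregular sampling — interval at file row {worst + 3} is "
            f"{dt[worst]:.6g} s vs median {median_dt:.6g} s "
            f"(max allowed deviation {100 * MAX_DT_DEVIATION:g}%)"
        )

    metadata: dict[str, object] = {}
    sidecar_subject = None
    if sidecar is not None:
        with open(sidecar) as fh:
            metadata = dict(json.load(fh))
        sidecar_subject = metadata.pop("subject_id", None)
    return RipRecording(
        subject_id=subject_id or sidecar_subject or path.stem,
        fs=fs if fs is not None else 1.0 / median_dt,
        rc=df["rc"].to_numpy(dtype=float),
        ab=df["ab"].to_numpy(dtype=float),
        metadata=metadata,
    )


def write_recording(
    recording: RipRecording,
    path: str | Path,
    sidecar: str | Path | None = None,
) -> None:
    """Write a recording as ``time_s,rc,ab`` CSV plus optional sidecar JSON."""
    df = pd.DataFrame(
        {"time_s": recording.time_s, "rc": recording.rc, "ab": recording.ab}
    )
    # 17 significant digits: lossless float64 round trip
    df.to_csv(path, index=False, float_format="%.17g")
    if sidecar is not None:
        doc = {"subject_id": recording.subject_id, **recording.metadata}
        with open(sidecar, "w") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
            fh.write("\n")


def write_series(series: WobSeries, path: str | Path) -> None:
    """Export a WobSeries as CSV with windowing provenance in comments."""
    header = (
        f"# source_id={series.source_id}\n"
        f"# fs={series.fs!r}\n"
        f"# window_n={series.window_n}\n"
        f"# stride={series.stride}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        series.to_dataframe().to_csv(fh, index=False, float_format="%.17g")


def read_series(path: str | Path) -> WobSeries:
    """Read back a series CSV written by :func:`write_series`."""
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line.lstrip("# ").rstrip("\n").partition("=")
            meta[key] = value
    required = {"source_id", "fs", "window_n", "stride"}
    if not required.issubset(meta):
        raise RecordingParseError(
            f"{path}: series file missing provenance comment(s) "
            f"{', '.join(sorted(required - set(meta)))}"
        )
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise RecordingParseError(
            f"{path}: series file missing column(s) {', '.join(missing)}"
        )
    samples = tuple(
        WobSample(
            t_index=int(row.t_index),
            phase_deg=float(row.phase_deg),
            lbi=float(row.lbi),
            rc_percent=float(row.rc_percent),
            valid=bool(int(row.valid)),
        )
        for row in df.itertuples()
    )
    return WobSeries(
        samples=samples,
        window_n=int(meta["window_n"]),
        stride=int(meta["stride"]),
        fs=float(meta["fs"]),
        source_id=meta["source_id"],
    )


def _row_dict(row: SummaryRow) -> dict:
    return {
        "mean": row.mean,
        "sem": None if math.isnan(row.sem) else row.sem,
        "n": row.n,
    }


def summary_document(
    summary: CohortSummary,
    histograms: Sequence[HistogramResult] = (),
) -> dict:
    """Assemble the JSON-serialisable summary document."""
    return {
        "n_subjects": summary.n_subjects,
        "rows": {name: _row_dict(row) for name, row in summary.rows.items()},
        "valid_fractions": dict(summary.valid_fractions),
        "histograms": [
            {
                "variable": h.variable,
                "bin_edges": [float(e) for e in h.bin_edges],
                "counts": [int(c) for c in h.counts],
                "n_values": int(len(h.values)),
            }
            for h in histograms
        ],
    }


def write_summary(document: Mapping[str, object], path: str | Path) -> None:
    """Write a summary document as deterministic, sorted-key JSON."""
    with open(path, "w") as fh:
        json.dump(document, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_summary(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
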