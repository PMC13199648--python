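"""Data model, validation and CSV I/O for ICP traces and outcome tables.

Intracranial pressure after decompressive craniectomy is logged by the
bedside monitor at a nominal 30-minute interval for up to 72 hours.  The
on-disk interchange formats are deliberately plain long-format CSV:

* traces:    ``patient_id,time_h,icp_mmHg``  (one row per sample)
* outcomes:  ``patient_id,mrs``              (modified Rankin Scale, 0-6)
* summaries: one row per patient of derived burden metrics

Times are hours since decompression (continuous, 0-based); pressures are
mmHg.  The 30-minute grid is nominal only: real monitors drop samples, and
monitoring is discontinued at different times per patient, so nothing here
assumes uniform spacing.  Gaps longer than a tolerance split a trace into
contiguous segments; downstream integration treats gaps as contributing
neither area nor time rather than interpolating across them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import FormatError, ParseError, UnusableTraceError

log = logging.getLogger("icpburden")

TRACE_COLUMNS = ("patient_id", "time_h", "icp_mmHg")
OUTCOME_COLUMNS = ("patient_id", "mrs")

#: Poor outcome is death: modified Rankin Scale 6 vs. anything below.
MRS_DEATH = 6


@dataclass
class IcpTrace:
    """One patient's timestamped ICP record.

    Invariants (checked on construction): at least two samples, strictly
    increasing non-negative times, finite pressures.
    """

    patient_id: str
    times_h: np.ndarray
    icp_mmHg: np.ndarray
    nominal_interval_h: float = 0.5

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.icp_mmHg = np.asarray(self.icp_mmHg, dtype=float)
        if self.times_h.ndim != 1 or self.times_h.shape != self.icp_mmHg.shape:
            raise ValueError("times_h and icp_mmHg must be 1-D and equally long")
        if self.times_h.size < 2:
            raise ValueError(f"trace {self.patient_id!r} needs >= 2 samples")
        if not np.all(np.isfinite(self.times_h)) or self.times_h[0] < 0:
            raise ValueError("times must be finite and non-negative")
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError(f"times of trace {self.patient_id!r} must be strictly increasing")
        if not np.all(np.isfinite(self.icp_mmHg)):
            raise ValueError(f"pressures of trace {self.patient_id!r} must be finite")
        if self.nominal_interval_h <= 0:
            raise ValueError("nominal_interval_h must be positive")

    @property
    def n_samples(self) -> int:
        return int(self.times_h.size)

    @property
    def span_h(self) -> float:
        """First-to-last sample span in hours (ignores interior gaps)."""
        return float(self.times_h[-1] - self.times_h[0])


@dataclass(frozen=True)
class OutcomeRecord:
    """Modified Rankin Scale at discharge and its death dichotomization."""

    patient_id: str
    mrs: int

    def __post_init__(self) -> None:
        if not (isinstance(self.mrs, (int, np.integer)) and 0 <= self.mrs <= 6):
            raise ValueError(f"mrs must be an integer in 0..6, got {self.mrs!r}")

    @property
    def poor_outcome(self) -> bool:
        """True iff the patient died (mRS = 6)."""
        return self.mrs == MRS_DEATH


@dataclass
class Cohort:
    """Traces plus outcomes, each keyed by patient id.

    The analysis subset consists only of patients present in both tables;
    patients without complete outcome data are excluded from association
    and modelling stages.
    """

    traces: dict[str, IcpTrace] = field(default_factory=dict)
    outcomes: dict[str, OutcomeRecord] = field(default_factory=dict)

    @property
    def analysis_ids(self) -> list[str]:
        """Sorted ids with both a trace and an outcome."""
        return sorted(set(self.traces) & set(self.outcomes))


# ---------------------------------------------------------------------------
# reading


def _numeric_column(df: pd.DataFrame, col: str) -> pd.Series:
    try:
        return pd.to_numeric(df[col], errors="raise")
    except (ValueError, TypeError) as exc:
        raise ParseError(f"non-numeric value in column {col!r}: {exc}") from None


def read_traces(path, window_h: float = 72.0) -> dict[str, IcpTrace]:
    """Read a long-format traces CSV into one :class:`IcpTrace` per patient.

    Rows are grouped by patient, sorted by time and truncated to
    ``time_h <= window_h``.  Duplicate timestamps within a patient are
    rejected; patients left with fewer than two samples are excluded with a
    logged warning.
    """
    if window_h <= 0:
        raise ValueError("window_h must be positive")
    df = pd.read_csv(path, dtype={"patient_id": str}, float_precision="round_trip")
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"traces file {path} lacks column(s) {missing}")
    t_all = _numeric_column(df, "time_h")
    v_all = _numeric_column(df, "icp_mmHg")
    if t_all.isna().any() or (t_all < 0).any():
        raise ParseError("time_h must be finite and non-negative")
    if not np.isfinite(v_all.to_numpy(float)).all():
        raise ParseError("icp_mmHg must be finite")
    df = df.assign(time_h=t_all, icp_mmHg=v_all)

    traces: dict[str, IcpTrace] = {}
    for pid, group in df.groupby("patient_id", sort=True):
        group = group.sort_values("time_h", kind="mergesort")
        t = group["time_h"].to_numpy(float)
        v = group["icp_mmHg"].to_numpy(float)
        if np.any(np.diff(t) == 0):
            raise FormatError(f"duplicate timestamps for patient {pid!r}")
        keep = t <= window_h
        if int(keep.sum()) < 2:
            log.warning(
                "patient %s: fewer than 2 samples within %g h window; excluded", pid, window_h
            )
            continue
        traces[str(pid)] = IcpTrace(str(pid), t[keep], v[keep])
    return traces


def read_outcomes(path) -> dict[str, OutcomeRecord]:
    """Read the outcomes CSV (``patient_id,mrs``)."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in OUTCOME_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"outcomes file {path} lacks column(s) {missing}")
    mrs = _numeric_column(df, "mrs")
    if mrs.isna().any() or (mrs != mrs.round()).any() or (mrs < 0).any() or (mrs > 6).any():
        raise ParseError("mrs must be an integer in 0..6")
    if df["patient_id"].duplicated().any():
        raise FormatError("duplicate patient ids in outcomes file")
    return {
        str(pid): OutcomeRecord(str(pid), int(m))
        for pid, m in zip(df["patient_id"], mrs)
    }


# ---------------------------------------------------------------------------
# trace validation / segmentation

Segment = tuple[int, int]  # half-open [start, stop) index range


def validate_trace(trace: IcpTrace, gap_tolerance_h: float = 1.0) -> list[Segment]:
    """Split a trace into maximal contiguous segments.

    Consecutive samples further apart than ``gap_tolerance_h`` (default 1 h
    = 2x the nominal 30-min interval) start a new segment.  Segments of a
    single sample carry neither area nor time and are dropped.  A trace with
    no segment of >= 2 samples raises :class:`UnusableTraceError`.
    """
    if gap_tolerance_h <= 0:
        raise ValueError("gap_tolerance_h must be positive")
    dt = np.diff(trace.times_h)
    breaks = np.flatnonzero(dt > gap_tolerance_h)
    starts = np.concatenate(([0], breaks + 1))
    stops = np.concatenate((breaks + 1, [trace.n_samples]))
    segments = [(int(a), int(b)) for a, b in zip(starts, stops) if b - a >= 2]
    if not segments:
        raise UnusableTraceError(
            f"trace {trace.patient_id!r} has no contiguous segment of >= 2 samples "
            f"at gap tolerance {gap_tolerance_h} h"
        )
    return segments


def monitored_duration(trace: IcpTrace, segments: Iterable[Segment]) -> float:
    """Total monitored hours: sum of segment spans (gaps contribute nothing)."""
    return float(sum(trace.times_h[b - 1] - trace.times_h[a] for a, b in segments))


# ---------------------------------------------------------------------------
# writing

def _trace_frame(traces: Mapping[str, IcpTrace] | Iterable[IcpTrace]) -> pd.DataFrame:
    seq = traces.values() if isinstance(traces, Mapping) else traces
    rows = [
        (tr.patient_id, t, v)
        for tr in seq
        for t, v in zip(tr.times_h, tr.icp_mmHg)
    ]
    return pd.DataFrame(rows, columns=list(TRACE_COLUMNS))


def write_traces(traces, path) -> None:
    """Write traces in the long-format interchange schema."""
    _trace_frame(traces).to_csv(path, index=False)


def write_outcomes(outcomes: Mapping[str, OutcomeRecord] | Iterable[OutcomeRecord], path) -> None:
    seq = outcomes.values() if isinstance(outcomes, Mapping) else outcomes
    pd.DataFrame(
        [(o.patient_id, o.mrs) for o in seq], columns=list(OUTCOME_COLUMNS)
    ).to_csv(path, index=False)


def _summary_columns(thresholds: list[float]) -> list[str]:
    cols = ["patient_id", "duration_h", "auc_mmHg_h", "normalized_auc", "max_icp", "mean_icp"]
    cols += [f"dose_above_{t:g}" for t in thresholds]
    cols += [f"frac_above_{t:g}" for t in thresholds]
    return cols


def write_summaries(summaries, path) -> None:
    """Write per-patient burden summaries, one row per patient.

    Column order is fixed; floats are written at full (round-tripping)
    precision.  Raises on an empty collection or duplicate patient ids.
    """
    if isinstance(summaries, Mapping):
        summaries = list(summaries.values())
    else:
        summaries = list(summaries)
    if not summaries:
        raise ValueError("no summaries to write")
    ids = [s.patient_id for s in summaries]
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate patient ids in summaries")
    thresholds = sorted(summaries[0].dose_above)
    rows = []
    for s in summaries:
        if sorted(s.dose_above) != thresholds or sorted(s.frac_above) != thresholds:
            raise FormatError("summaries have inconsistent threshold sets")
        row = [s.patient_id, s.duration_h, s.auc_mmHg_h, s.normalized_auc, s.max_icp, s.mean_icp]
        row += [s.dose_above[t] for t in thresholds]
        row += [s.frac_above[t] for t in thresholds]
        rows.append(row)
    pd.DataFrame(rows, columns=_summary_columns(thresholds)).to_csv(path, index=False)


def read_summaries(path) -> dict[str, "BurdenSummary"]:
    """Read a summaries CSV back into :class:`~icpburden.burden.BurdenSummary`."""
    from .burden import BurdenSummary  # deferred: burden imports this module

    # round_trip parsing: summaries must survive write/read bit-for-bit
    df = pd.read_csv(path, dtype={"patient_id": str}, float_precision="round_trip")
    base = {"patient_id", "duration_h", "auc_mmHg_h", "normalized_auc", "max_icp", "mean_icp"}
    if not base <= set(df.columns):
        raise FormatError(f"summaries file {path} lacks columns {sorted(base - set(df.columns))}")
    dose_cols = {float(c[len("dose_above_"):]): c for c in df.columns if c.startswith("dose_above_")}
    frac_cols = {float(c[len("frac_above_"):]): c for c in df.columns if c.startswith("frac_above_")}
    out: dict[str, BurdenSummary] = {}
    for _, r in df.iterrows():
        pid = str(r["patient_id"])
        if pid in out:
            raise FormatError(f"duplicate patient id {pid!r} in summaries file")
        out[pid] = BurdenSummary(
            patient_id=pid,
            duration_h=float(r["duration_h"]),
            auc_mmHg_h=float(r["auc_mmHg_h"]),
            normalized_auc=float(r["normalized_auc"]),
            max_icp=float(r["max_icp"]),
            mean_icp=float(r["mean_icp"]),
            dose_above={t: float(r[c]) for t, c in dose_cols.items()},
            frac_above={t: float(r[c]) for t, c in frac_cols.items()},
        )
    return out
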