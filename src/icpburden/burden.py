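"""Cumulative ICP-burden metrics.

The central quantity is the area under the ICP curve (ICP-AUC, mmHg*h)
over the early postoperative monitoring window, together with:

* **normalized AUC** = AUC / (max ICP x monitored time), a dimensionless
  relative burden in (0, 1]; 1 means pressure sat at its maximum for the
  whole window.
* **dose above a threshold** = integral of max(ICP(t) - theta, 0) dt, the
  pressure-time dose above theta (default thresholds 15 and 20 mmHg).
* **fraction of time above a threshold**, with crossing times located by
  linear interpolation inside each sampling interval.
* max ICP and the time-weighted mean ICP (= AUC / duration).

All integrals use the trapezoid rule on the piecewise-linear interpolant of
the samples — exact for linear segments and the standard choice for
30-min-sampled dose metrics.  Metrics are computed per contiguous segment
(see :func:`icpburden.io.validate_trace`) and summed, so monitoring gaps
contribute neither area nor time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .exceptions import UndefinedMetricError
from .io import IcpTrace, Segment, monitored_duration, validate_trace

log = logging.getLogger("icpburden")

DEFAULT_THRESHOLDS = (15.0, 20.0)


@dataclass
class BurdenSummary:
    """Per-patient derived burden feature vector."""

    patient_id: str
    duration_h: float
    auc_mmHg_h: float
    normalized_auc: float
    max_icp: float
    mean_icp: float
    dose_above: dict[float, float]
    frac_above: dict[float, float]


def _segments_or_default(trace: IcpTrace, segments, gap_tolerance_h: float):
    return validate_trace(trace, gap_tolerance_h) if segments is None else list(segments)


def _excess_and_time(t: np.ndarray, v: np.ndarray, theta: float) -> tuple[float, float]:
    """Excess area above ``theta`` and time spent above it, one segment.

    Vectorized over sampling intervals of the piecewise-linear interpolant.
    An interval lying entirely at the threshold counts as neither area nor
    time above ("above" is strict).
    """
    dt = np.diff(t)
    e0 = v[:-1] - theta
    e1 = v[1:] - theta
    pos0 = e0 > 0
    pos1 = e1 > 0

    time = np.zeros_like(dt)
    area = np.zeros_like(dt)

    both = pos0 & pos1
    time[both] = dt[both]
    area[both] = 0.5 * (e0[both] + e1[both]) * dt[both]

    # crossing intervals: the interpolant hits theta at fraction e/(e - other)
    up = ~pos0 & pos1  # rises through theta
    with np.errstate(invalid="ignore", divide="ignore"):
        f_up = np.where(up, e1 / (e1 - e0), 0.0)
    time[up] = (dt * f_up)[up]
    area[up] = (0.5 * e1 * dt * f_up)[up]

    down = pos0 & ~pos1  # falls through theta
    with np.errstate(invalid="ignore", divide="ignore"):
        f_down = np.where(down, e0 / (e0 - e1), 0.0)
    time[down] = (dt * f_down)[down]
    area[down] = (0.5 * e0 * dt * f_down)[down]

    # intervals touching theta at one endpoint but positive at the other are
    # covered by `up`/`down` with f == 1; both-at-or-below contributes zero.
    return float(area.sum()), float(time.sum())


def integrate_auc(
    trace: IcpTrace,
    segments: Sequence[Segment] | None = None,
    gap_tolerance_h: float = 1.0,
) -> float:
    """Trapezoidal area under the ICP curve in mmHg*h, summed over segments."""
    segments = _segments_or_default(trace, segments, gap_tolerance_h)
    if np.any(trace.icp_mmHg < 0):
        log.warning("trace %s contains negative pressures; integrating as-is", trace.patient_id)
    return float(
        sum(np.trapezoid(trace.icp_mmHg[a:b], trace.times_h[a:b]) for a, b in segments)
    )


def dose_above(
    trace: IcpTrace,
    threshold: float,
    segments: Sequence[Segment] | None = None,
    gap_tolerance_h: float = 1.0,
    mode: str = "excess",
) -> float:
    """Pressure-time dose above ``threshold`` in mmHg*h.

    ``mode="excess"`` (default) integrates max(ICP - theta, 0): the excess
    area only.  ``mode="epoch"`` integrates the full ICP curve during
    supra-threshold epochs, i.e. excess + theta x time-above.  Both use
    linearly interpolated crossing times.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if mode not in ("excess", "epoch"):
        raise ValueError(f"unknown dose mode {mode!r}")
    segments = _segments_or_default(trace, segments, gap_tolerance_h)
    excess = time = 0.0
    for a, b in segments:
        e, tt = _excess_and_time(trace.times_h[a:b], trace.icp_mmHg[a:b], threshold)
        excess += e
        time += tt
    return excess if mode == "excess" else excess + threshold * time


def time_above(
    trace: IcpTrace,
    threshold: float,
    segments: Sequence[Segment] | None = None,
    gap_tolerance_h: float = 1.0,
) -> float:
    """Hours the linear interpolant spends strictly above ``threshold``."""
    segments = _segments_or_default(trace, segments, gap_tolerance_h)
    return float(
        sum(
            _excess_and_time(trace.times_h[a:b], trace.icp_mmHg[a:b], threshold)[1]
            for a, b in segments
        )
    )


def frac_time_above(
    trace: IcpTrace,
    threshold: float,
    segments: Sequence[Segment] | None = None,
    gap_tolerance_h: float = 1.0,
) -> float:
    """Fraction of the monitored duration spent above ``threshold``."""
    segments = _segments_or_default(trace, segments, gap_tolerance_h)
    duration = monitored_duration(trace, segments)
    if duration <= 0:
        raise UndefinedMetricError("monitored duration is zero")
    return time_above(trace, threshold, segments) / duration


def normalized_auc(
    trace: IcpTrace,
    segments: Sequence[Segment] | None = None,
    gap_tolerance_h: float = 1.0,
    norm_mode: str = "actual",
    window_h: float = 72.0,
) -> float:
    """AUC / (max ICP x monitoring time), dimensionless relative burden.

    ``norm_mode="actual"`` (default) uses the patient's monitored duration;
    ``"fixed72"`` divides by the nominal window instead, which understates
    the burden of short records but matches a fixed-window convention.
    """
    if norm_mode not in ("actual", "fixed72"):
        raise ValueError(f"unknown normalization mode {norm_mode!r}")
    segments = _segments_or_default(trace, segments, gap_tolerance_h)
    max_icp = float(np.max(trace.icp_mmHg))
    if max_icp <= 0:
        raise UndefinedMetricError("normalized AUC undefined: max ICP <= 0")
    duration = monitored_duration(trace, segments) if norm_mode == "actual" else window_h
    if duration <= 0:
        raise UndefinedMetricError("monitoring time is zero")
    return integrate_auc(trace, segments) / (max_icp * duration)


def summarize(
    trace: IcpTrace,
    thresholds: Iterable[float] = DEFAULT_THRESHOLDS,
    gap_tolerance_h: float = 1.0,
    norm_mode: str = "actual",
    dose_mode: str = "excess",
    window_h: float = 72.0,
) -> BurdenSummary:
    """Compute the full burden feature vector for one trace.

    Propagates :class:`~icpburden.exceptions.UnusableTraceError` from
    segmentation and :class:`~icpburden.exceptions.UndefinedMetricError`
    for non-positive maxima.
    """
    thresholds = [float(t) for t in thresholds]
    segments = validate_trace(trace, gap_tolerance_h)
    duration = monitored_duration(trace, segments)
    auc = integrate_auc(trace, segments)
    nauc = normalized_auc(trace, segments, norm_mode=norm_mode, window_h=window_h)
    return BurdenSummary(
        patient_id=trace.patient_id,
        duration_h=duration,
        auc_mmHg_h=auc,
        normalized_auc=nauc,
        max_icp=float(np.max(trace.icp_mmHg)),
        mean_icp=auc / duration,
        dose_above={t: dose_above(trace, t, segments, mode=dose_mode) for t in thresholds},
        frac_above={t: frac_time_above(trace, t, segments) for t in thresholds},
    )


def summarize_cohort(traces, **kwargs) -> dict[str, BurdenSummary]:
    """Summarize a mapping of traces; returns summaries keyed by patient id."""
    return {pid: summarize(tr, **kwargs) for pid, tr in traces.items()}
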