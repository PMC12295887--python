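"""Trace metrics for pyrene polymerization assays.

Four quantities summarize a fluorescence time trace: the initial assembly
rate (slope over the first seconds), the half-maximal (log-phase) rate,
the peak intensity, and the time to reach it.  A fifth operation fits
slopes on either side of a mid-run nucleator addition.  All slopes are
ordinary least squares with the standard error taken from the residuals,
matching the "error of the linear fit" convention of assay figures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.stats import linregress

from .kinetics import FluorescenceTrace, ValidationError

__all__ = [
    "SlopeFit",
    "TraceMetrics",
    "AdditionResponse",
    "initial_rate",
    "halfmax_rate",
    "peak_metrics",
    "fold_change",
    "addition_response",
    "compute_metrics",
    "metrics_table",
]

DEFAULT_INITIAL_WINDOW = (0.0, 40.0)
DEFAULT_HALF_WIDTH = 30.0
DEFAULT_SMOOTH_WINDOW = 5
_BASELINE_SAMPLES = 3  # leading samples averaged for the half-max baseline


class MetricError(RuntimeError):
    """Raised when a metric is undefined for the given trace."""


@dataclass(frozen=True)
class SlopeFit:
    slope: float
    stderr: float
    window: tuple[float, float]
    n: int


@dataclass(frozen=True)
class TraceMetrics:
    initial_rate: SlopeFit
    halfmax_rate: SlopeFit
    peak_intensity: float
    time_to_peak: float
    condition: str = ""

    def value(self, metric: str) -> float:
        if metric in ("initial_rate", "halfmax_rate"):
            return getattr(self, metric).slope
        if metric in ("peak_intensity", "time_to_peak"):
            return getattr(self, metric)
        raise KeyError(f"unknown metric {metric!r}")


@dataclass(frozen=True)
class AdditionResponse:
    pre_slope: float
    post_slope: float
    ratio: float


def _window_fit(t: np.ndarray, F: np.ndarray, window: tuple[float, float],
                closed: str = "both") -> SlopeFit:
    lo, hi = window
    if closed == "both":
        sel = (t >= lo) & (t <= hi)
    elif closed == "left":
        sel = (t >= lo) & (t < hi)
    else:  # "right"
        sel = (t > lo) & (t <= hi)
    if sel.sum() < 3:
        raise MetricError(f"need >= 3 samples in window {window}, got {int(sel.sum())}")
    tw, Fw = t[sel], F[sel]
    if np.ptp(tw) == 0:
        raise MetricError("zero time variance in fit window")
    res = linregress(tw, Fw)
    stderr = float(res.stderr) if np.isfinite(res.stderr) else 0.0
    return SlopeFit(slope=float(res.slope), stderr=stderr,
                    window=(float(tw[0]), float(tw[-1])), n=int(sel.sum()))


def initial_rate(trace: FluorescenceTrace,
                 window: tuple[float, float] = DEFAULT_INITIAL_WINDOW) -> SlopeFit:
    """OLS slope of F vs t over the early-time window (default 0–40 s)."""
    return _window_fit(trace.t, trace.F, window)


def peak_metrics(trace: FluorescenceTrace,
                 smooth_window: int = DEFAULT_SMOOTH_WINDOW) -> tuple[float, float]:
    """Peak of the moving-average-smoothed trace and its first attainment time.

    ``smooth_window`` must be odd (1 disables smoothing).  The reported
    intensity is the smoothed value; ties in the maximum are broken by
    the earliest time.
    """
    if trace.t.size == 0:
        raise MetricError("empty trace")
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValidationError(f"smooth_window must be odd and >= 1, got {smooth_window}")
    smoothed = uniform_filter1d(trace.F, size=smooth_window, mode="nearest")
    idx = int(np.argmax(smoothed))  # argmax returns the first maximum
    return float(smoothed[idx]), float(trace.t[idx])


def halfmax_rate(
    trace: FluorescenceTrace,
    window: tuple[float, float] | None = None,
    half_width: float = DEFAULT_HALF_WIDTH,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> SlopeFit:
    """Slope in the half-maximal (log-phase) region of the rise.

    With ``window=None`` the fit window is ``t_half ± half_width`` clipped
    to the trace span, where ``t_half`` is the first (interpolated) upward
    crossing of ``baseline + (peak − baseline)/2``; the baseline is the
    mean of the first three samples.

    Raises
    ------
    MetricError
        if the trace never rises to half-maximum (e.g. monotone
        decreasing traces, for which a rise half-time is undefined).
    """
    t, F = trace.t, trace.F
    if window is not None:
        return _window_fit(t, F, window)
    if t.size < _BASELINE_SAMPLES:
        raise MetricError("trace too short for baseline estimation")
    baseline = float(F[:_BASELINE_SAMPLES].mean())
    peak, _ = peak_metrics(trace, smooth_window)
    if peak <= baseline:
        raise MetricError("trace has no rise above baseline; half-max undefined")
    level = baseline + 0.5 * (peak - baseline)
    above = F >= level
    if above[0]:
        raise MetricError("trace starts at/above half-max; rising crossing undefined")
    if not above.any():
        raise MetricError("half-maximal level never reached")
    i = int(np.argmax(above))
    # linear interpolation between the bracketing samples
    t_half = t[i - 1] + (level - F[i - 1]) / (F[i] - F[i - 1]) * (t[i] - t[i - 1])
    lo = max(float(t[0]), t_half - half_width)
    hi = min(float(t[-1]), t_half + half_width)
    return _window_fit(t, F, (lo, hi))


def fold_change(test: TraceMetrics, control: TraceMetrics, metric: str) -> float:
    """Ratio test/control of one named metric (e.g. ``"initial_rate"``)."""
    c = control.value(metric)
    if c == 0:
        raise MetricError(f"control {metric} is zero; fold change undefined")
    return test.value(metric) / c


def addition_response(trace: FluorescenceTrace, t_add: float,
                      pre_width: float, post_width: float) -> AdditionResponse:
    """Slopes immediately before and after a mid-run addition at ``t_add``.

    Fits are independent on [t_add−pre_width, t_add) and
    (t_add, t_add+post_width]; the ratio post/pre quantifies the kick the
    addition gives to the ongoing assembly.
    """
    t = trace.t
    if t_add - pre_width < t[0] or t_add + post_width > t[-1]:
        raise MetricError("addition windows extend beyond the trace")
    pre = _window_fit(t, trace.F, (t_add - pre_width, t_add), closed="left")
    post = _window_fit(t, trace.F, (t_add, t_add + post_width), closed="right")
    if pre.slope == 0:
        raise MetricError("pre-addition slope is zero; ratio undefined")
    return AdditionResponse(pre_slope=pre.slope, post_slope=post.slope,
                            ratio=post.slope / pre.slope)


def compute_metrics(
    trace: FluorescenceTrace,
    initial_window: tuple[float, float] = DEFAULT_INITIAL_WINDOW,
    halfmax_window: tuple[float, float] | None = None,
    half_width: float = DEFAULT_HALF_WIDTH,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> TraceMetrics:
    """All four trace metrics in one pass."""
    peak, t_peak = peak_metrics(trace, smooth_window)
    return TraceMetrics(
        initial_rate=initial_rate(trace, initial_window),
        halfmax_rate=halfmax_rate(trace, halfmax_window, half_width, smooth_window),
        peak_intensity=peak,
        time_to_peak=t_peak,
        condition=trace.condition,
    )


def metrics_table(metrics: list[TraceMetrics]) -> pd.DataFrame:
    """One row per trace, ready for CSV export."""
    return pd.DataFrame([
        {
            "condition": m.condition,
            "initial_rate_au_per_s": m.initial_rate.slope,
            "initial_rate_se": m.initial_rate.stderr,
            "initial_window_start_s": m.initial_rate.window[0],
            "initial_window_end_s": m.initial_rate.window[1],
            "halfmax_rate_au_per_s": m.halfmax_rate.slope,
            "halfmax_rate_se": m.halfmax_rate.stderr,
            "halfmax_window_start_s": m.halfmax_rate.window[0],
            "halfmax_window_end_s": m.halfmax_rate.window[1],
            "peak_intensity_au": m.peak_intensity,
            "time_to_peak_s": m.time_to_peak,
        }
        for m in metrics
    ])
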