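"""Kinetic statistics of fluorescence traces.

Ratiometric indicator traces are built by pointwise division of two
background-subtracted emission channels. Response kinetics are summarized by
the maximal slope of the percent-change signal (in %/s, estimated by a
sliding local linear regression for noise robustness), the response onset
(first crossing of a fraction of the trace's own maximal percent change) and
the lag time between a reference trace's onset and a target trace's maximal
slope. Stimulus-response amplitudes are plain post-minus-pre window means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .core import PipelineError, Trace

__all__ = [
    "KineticsResult",
    "ratio_trace",
    "max_slope",
    "lag_time",
    "delta_response",
    "percent_change",
]


@dataclass
class KineticsResult:
    """Summary kinetics of one trace."""

    f0: float
    max_slope_pct_per_s: float
    t_max_slope_s: float
    onset_s: Optional[float] = None
    lag_dt_s: Optional[float] = None
    delta_response: Optional[float] = None


def ratio_trace(ch_num: Trace, ch_den: Trace) -> Trace:
    """Pointwise ratio of two aligned, background-subtracted channels.

    Samples with a zero denominator are NaN and flagged in ``flags``.
    """
    if len(ch_num) != len(ch_den) or not np.allclose(ch_num.t, ch_den.t):
        raise ValueError("traces must share an aligned time base")
    den = ch_den.f
    flags = den == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(flags, np.nan, ch_num.f / np.where(flags, 1.0, den))
    return Trace(ch_num.t, ratio, ch_num.baseline_window, flags=flags)


def percent_change(trace: Trace,
                   baseline_window: Optional[Tuple[int, int]] = None) -> np.ndarray:
    """P(t) = 100 (f - f0) / f0 with f0 the baseline-window mean."""
    window = baseline_window or trace.baseline_window
    if window is None:
        raise ValueError("no baseline window given")
    a, b = window
    f0 = float(np.mean(trace.f[a:b]))
    if f0 <= 0:
        raise PipelineError("baseline mean must be positive for percent "
                            "normalization")
    return 100.0 * (trace.f - f0) / f0


def max_slope(trace: Trace,
              baseline_window: Optional[Tuple[int, int]] = None,
              slope_window_pts: int = 11,
              polyorder: int = 3,
              search_window_s: Optional[Tuple[float, float]] = None) -> Tuple[float, float]:
    """Maximal slope of the percent-change signal, in %/s, and its time.

    The derivative is estimated by sliding local polynomial regression
    (Savitzky-Golay) over ``slope_window_pts`` samples. ``polyorder`` 1 is a
    plain linear regression; the default cubic also captures the curvature of
    a sigmoidal rise, which a linear window systematically underestimates.
    ``search_window_s`` optionally restricts the maximum search to a time
    range (e.g. the response epoch — after strong bleach correction the late
    trace carries amplified noise).
    """
    from scipy.signal import savgol_filter

    if slope_window_pts < 2:
        raise ValueError("slope window must span >= 2 points")
    if slope_window_pts > len(trace):
        raise ValueError("slope window longer than the trace")
    if polyorder >= slope_window_pts:
        raise ValueError("polyorder must be smaller than the window")
    p = percent_change(trace, baseline_window)
    dt = float(np.mean(np.diff(trace.t)))
    if not np.allclose(np.diff(trace.t), dt, rtol=1e-3):
        raise ValueError("slope estimation requires uniform sampling")
    deriv = savgol_filter(p, slope_window_pts, polyorder, deriv=1, delta=dt)
    sel = np.ones(len(deriv), dtype=bool)
    if search_window_s is not None:
        sel = (trace.t >= search_window_s[0]) & (trace.t <= search_window_s[1])
        if not sel.any():
            raise ValueError("empty slope search window")
    i = int(np.flatnonzero(sel)[np.argmax(deriv[sel])])
    return float(deriv[i]), float(trace.t[i])


def onset_time(trace: Trace, onset_frac: float = 0.05,
               baseline_window: Optional[Tuple[int, int]] = None) -> float:
    """First time the percent change exceeds ``onset_frac`` of its maximum.

    The crossing is located by linear interpolation between samples.
    """
    if not (0.0 < onset_frac < 1.0):
        raise ValueError("onset_frac must be in (0, 1)")
    p = percent_change(trace, baseline_window)
    pmax = p.max()
    if pmax <= 0:
        raise PipelineError("trace never rises above its baseline")
    thr = onset_frac * pmax
    above = np.nonzero(p >= thr)[0]
    if len(above) == 0:
        raise PipelineError("reference never crosses the onset threshold")
    i = int(above[0])
    if i == 0:
        return float(trace.t[0])
    frac = (thr - p[i - 1]) / (p[i] - p[i - 1])
    return float(trace.t[i - 1] + frac * (trace.t[i] - trace.t[i - 1]))


def lag_time(reference: Trace, target: Trace, onset_frac: float = 0.05,
             slope_window_pts: int = 11) -> float:
    """Lag from the reference's response onset to the target's maximal slope."""
    onset = onset_time(reference, onset_frac)
    _, t_ms = max_slope(target, slope_window_pts=slope_window_pts)
    return float(t_ms - onset)


def delta_response(trace: Trace, event_time_s: float,
                   pre_window: Tuple[float, float],
                   post_window: Tuple[float, float]) -> float:
    """mean(post window) - mean(pre window), windows in seconds.

    The pre window must end at or before the event, the post window start at
    or after it, and both must contain samples.
    """
    if not (pre_window[0] < pre_window[1] <= event_time_s
            <= post_window[0] < post_window[1]):
        raise ValueError("windows must be disjoint around the event time")
    pre = trace.f[(trace.t >= pre_window[0]) & (trace.t < pre_window[1])]
    post = trace.f[(trace.t >= post_window[0]) & (trace.t < post_window[1])]
    if len(pre) == 0 or len(post) == 0:
        raise ValueError("empty pre/post window")
    return float(post.mean() - pre.mean())
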