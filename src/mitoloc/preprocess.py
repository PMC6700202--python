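"""Background subtraction for images and bleach correction for traces.

These corrections precede every quantification stage: smooth image background
is removed by a rolling-ball (grayscale opening with a ball structuring
element), constant offsets by a signal-free ROI/window mean, and
photobleaching by dividing the trace by a normalized exponential decay fitted
on response-free samples (bleaching acts multiplicatively on fluorescence).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence, Tuple, Union

import numpy as np
from scipy import ndimage, optimize

from .core import FitError, Image2D, Trace

__all__ = [
    "rolling_ball_background",
    "subtract_background_roi",
    "bleach_correct_exponential",
    "BleachCorrection",
]


def _ball_structure(radius_px: float) -> np.ndarray:
    """Height profile of a ball of the given radius, zero at the apex."""
    r = int(math.ceil(radius_px))
    y, x = np.mgrid[-r:r + 1, -r:r + 1]
    d2 = x.astype(float) ** 2 + y.astype(float) ** 2
    inside = d2 <= radius_px ** 2
    s = np.full(d2.shape, -np.inf)
    s[inside] = np.sqrt(radius_px ** 2 - d2[inside]) - radius_px
    # grey_opening cannot take -inf; restrict to the disk footprint instead
    return np.where(inside, s, np.nan)


def rolling_ball_background(img: Image2D, radius_px: float = 50.0) -> Image2D:
    """Subtract a smooth background estimated by a rolling-ball opening.

    The background is the grayscale opening of the image with a ball
    structuring element of the given radius; the result is clipped at zero.
    """
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    if 2 * int(math.ceil(radius_px)) + 1 > min(img.shape):
        raise ValueError("rolling-ball radius larger than the image")
    s = _ball_structure(radius_px)
    footprint = np.isfinite(s)
    heights = np.where(footprint, s, 0.0)
    background = ndimage.grey_opening(
        img.pixels, structure=heights, footprint=footprint, mode="reflect"
    )
    out = np.clip(img.pixels - background, 0.0, None)
    return Image2D(out, img.nm_per_px, img.channel_label)


def subtract_background_roi(
    x: Union[Image2D, Trace],
    roi_or_window,
) -> Union[Image2D, Trace]:
    """Subtract the mean of a signal-free ROI (image) or window (trace).

    For images the ROI is a boolean mask of the same shape; for traces the
    window is an index range ``(start, stop)``.
    """
    if isinstance(x, Image2D):
        roi = np.asarray(roi_or_window, dtype=bool)
        if roi.shape != x.pixels.shape:
            raise ValueError("ROI mask must match image shape")
        if not roi.any():
            raise ValueError("empty background ROI")
        return Image2D(x.pixels - x.pixels[roi].mean(), x.nm_per_px,
                       x.channel_label)
    if isinstance(x, Trace):
        a, b = roi_or_window
        if b <= a or len(x.f[a:b]) == 0:
            raise ValueError("empty background window")
        return Trace(x.t, x.f - x.f[a:b].mean(), x.baseline_window, x.flags)
    raise TypeError("expected Image2D or Trace")


@dataclass
class BleachCorrection:
    """Corrected trace plus the fitted exponential decay parameters."""

    trace: Trace
    amplitude: float
    tau_s: float  # math.inf when no decay was detected


def bleach_correct_exponential(
    trace: Trace,
    fit_window: Union[Tuple[int, int], Sequence[Tuple[int, int]], None] = None,
) -> BleachCorrection:
    """Correct multiplicative photobleaching with an exponential-decay fit.

    Fits ``f ~ A exp(-t / tau)`` by least squares on the response-free
    ``fit_window`` (one or several index ranges; default: the trace's
    baseline window), then divides the whole trace by the fitted decay
    normalized to 1 at the first time point.
    """
    if fit_window is None:
        if trace.baseline_window is None:
            raise ValueError("no fit window given and trace has no baseline window")
        fit_window = [trace.baseline_window]
    elif isinstance(fit_window[0], (int, np.integer)):
        fit_window = [fit_window]  # type: ignore[list-item]
    idx = np.concatenate([np.arange(a, b) for a, b in fit_window])
    if len(idx) < 5:
        raise ValueError("fit window must span >= 5 points")
    t_fit, f_fit = trace.t[idx], trace.f[idx]
    if np.any(f_fit <= 0):
        raise FitError("bleach fit requires positive intensities in the window")

    # log-linear initial guess
    coef = np.polyfit(t_fit, np.log(f_fit), 1)
    k0, a0 = -coef[0], math.exp(coef[1])

    def model(t, a, k):
        return a * np.exp(-k * t)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = optimize.curve_fit(model, t_fit, f_fit,
                                            p0=[a0, k0], maxfev=10000)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"bleach fit did not converge: {exc}") from exc
    a_fit, k_fit = (float(v) for v in popt)
    if a_fit <= 0:
        raise FitError(f"bleach fit returned non-positive amplitude A={a_fit:.3g}")
    k_sd = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else 0.0
    span = float(trace.t[-1] - trace.t[0])
    if k_fit < 0 and abs(k_fit) > 3.0 * k_sd and abs(k_fit) * span > 0.02:
        # significantly rising: a real decay cannot have tau <= 0
        raise FitError(
            f"fitted decay is rising (tau={1.0 / k_fit:.3g} s <= 0); "
            "check the fit window for response contamination"
        )
    # an insignificantly negative rate is noise, not anti-bleaching: no-op
    k_use = max(k_fit, 0.0)
    if k_use * span < 1e-9:   # numerically zero decay over the whole trace
        k_use = 0.0
    decay = np.exp(-k_use * (trace.t - trace.t[0]))
    corrected = Trace(trace.t, trace.f / decay, trace.baseline_window,
                      trace.flags)
    tau = math.inf if k_use <= 0 else 1.0 / k_use
    return BleachCorrection(trace=corrected, amplitude=a_fit, tau_s=tau)
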