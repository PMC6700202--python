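"""Bead-based two-channel chromatic-aberration calibration.

Sub-pixel bead localization (2D Gaussian fits around detected maxima), a
local lateral aberration metric, axial channel offset by 1D Gaussian fits of
per-bead z-profiles, and the half-area (AUC/2) axial position readout.

The lateral metric is deliberately *local*: for each matched bead the
channel displacement vector v_i = pos_B - pos_A is compared with that of its
nearest neighbour, |v_i - v_j| / d_ij, in percent. A rigid translation of one
channel cancels exactly, so the number reports differential (scale-like)
distortion rather than trivial misalignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import integrate, optimize, spatial
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu

from .core import FitError, Image2D, ImageStack, LineProfile, PipelineError

__all__ = [
    "SpotSet",
    "AberrationReport",
    "localize_spots",
    "lateral_aberration",
    "axial_offset_gauss",
    "z_half_auc",
]


@dataclass
class SpotSet:
    """Sub-pixel spot coordinates, (x, y) per row."""

    coordinates: np.ndarray
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.coordinates)


def _gauss2d(xy, a, x0, y0, sigma, b):
    x, y = xy
    return (a * np.exp(-((x - x0) ** 2 + (y - y0) ** 2) / (2 * sigma ** 2)) + b).ravel()


def localize_spots(img: Image2D, expected_sigma_px: float = 1.5) -> SpotSet:
    """Detect spots and refine each with a local 2D Gaussian fit.

    Candidates are local maxima above an Otsu-derived floor; each is refined
    by least squares in a window of half-size ~3 sigma. Zero candidates give
    an empty set, not an error.
    """
    px = img.pixels
    if px.max() == px.min():
        return SpotSet(np.empty((0, 2)), img.channel_label)
    floor = threshold_otsu(px, nbins=256)
    min_dist = max(2, int(round(2 * expected_sigma_px)))
    peaks = peak_local_max(px, min_distance=min_dist, threshold_abs=floor)
    half = max(3, int(round(3 * expected_sigma_px)))
    coords: List[Tuple[float, float]] = []
    h, w = px.shape
    for (r, c) in peaks:
        r0, r1 = max(0, r - half), min(h, r + half + 1)
        c0, c1 = max(0, c - half), min(w, c + half + 1)
        win = px[r0:r1, c0:c1]
        yy, xx = np.mgrid[r0:r1, c0:c1]
        p0 = [px[r, c] - win.min(), float(c), float(r), expected_sigma_px, win.min()]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = optimize.curve_fit(
                    _gauss2d, (xx.astype(float), yy.astype(float)), win.ravel(),
                    p0=p0, maxfev=5000,
                )
        except (RuntimeError, ValueError):
            continue
        x0, y0 = float(popt[1]), float(popt[2])
        if np.hypot(x0 - c, y0 - r) > 2 * half:  # wandered off: reject
            continue
        coords.append((x0, y0))
    return SpotSet(np.array(coords).reshape(-1, 2), img.channel_label)


@dataclass
class AberrationReport:
    """Per-bead displacement vectors and local relative aberrations."""

    matched_a_px: np.ndarray
    matched_b_px: np.ndarray
    displacement_px: np.ndarray        # v_i = B - A, per matched bead
    local_aberration_pct: np.ndarray   # one value per bead (vs. its nearest neighbour)
    mean_local_aberration_pct: float
    n_matched: int


def _mutual_nearest(a: np.ndarray, b: np.ndarray, gate_px: float):
    tree_a, tree_b = spatial.cKDTree(a), spatial.cKDTree(b)
    d_ab, j_ab = tree_b.query(a, distance_upper_bound=gate_px)
    d_ba, j_ba = tree_a.query(b, distance_upper_bound=gate_px)
    pairs = []
    for i, j in enumerate(j_ab):
        if j < len(b) and j_ba[j] == i:
            pairs.append((i, j))
    return pairs


def lateral_aberration(spots_a: SpotSet, spots_b: SpotSet,
                       gate_px: float = 5.0,
                       metric: str = "difference") -> AberrationReport:
    """Local relative chromatic aberration between two channels, in percent.

    Beads are paired channel A to channel B by mutual nearest neighbour
    within ``gate_px``. For each bead i and its nearest neighbouring bead j:
    ``|v_i - v_j| / d_ij * 100`` with ``v = pos_B - pos_A`` and ``d_ij`` the
    bead separation in channel A (metric="difference", the default,
    translation-invariant). ``metric="dot"`` instead reports
    ``|v_i . v_j| / d_ij * 100``, a literal inner-product reading.
    """
    pairs = _mutual_nearest(spots_a.coordinates, spots_b.coordinates, gate_px)
    if len(pairs) < 2:
        raise PipelineError("need at least 2 matched bead pairs")
    a = spots_a.coordinates[[i for i, _ in pairs]]
    b = spots_b.coordinates[[j for _, j in pairs]]
    v = b - a
    tree = spatial.cKDTree(a)
    d_nn, j_nn = tree.query(a, k=2)
    d_nn, j_nn = d_nn[:, 1], j_nn[:, 1]
    if metric == "difference":
        num = np.hypot(*(v - v[j_nn]).T)
    elif metric == "dot":
        num = np.abs(np.einsum("ij,ij->i", v, v[j_nn]))
    else:
        raise ValueError("metric must be 'difference' or 'dot'")
    local = num / d_nn * 100.0
    return AberrationReport(
        matched_a_px=a, matched_b_px=b, displacement_px=v,
        local_aberration_pct=local,
        mean_local_aberration_pct=float(local.mean()),
        n_matched=len(pairs),
    )


def _gauss1d(z, a, mu, sigma, b):
    return a * np.exp(-0.5 * ((z - mu) / sigma) ** 2) + b


def _fit_z_center(profile: np.ndarray) -> float:
    z = np.arange(len(profile), dtype=float)
    p0 = [profile.max() - profile.min(), float(np.argmax(profile)),
          max(len(profile) / 6.0, 1.0), profile.min()]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        popt, _ = optimize.curve_fit(_gauss1d, z, profile, p0=p0, maxfev=5000)
    return float(popt[1])


def axial_offset_gauss(stack_a: ImageStack, stack_b: ImageStack,
                       coords_px: np.ndarray, z_step_nm: float,
                       box_nm: float = 320.0,
                       nm_per_px: Optional[float] = None) -> Tuple[float, np.ndarray, int]:
    """Mean axial channel offset (z_B - z_A) in nm from per-bead z-profiles.

    Each bead is boxed (``box_nm`` square), its box projected to a z-intensity
    profile per channel, and both profiles fitted with a 1D Gaussian. Beads
    whose fit fails are excluded and counted. Needs >= 5 z-planes.
    """
    if len(stack_a) < 5 or len(stack_b) < 5:
        raise ValueError("need at least 5 z-planes")
    nmpp = nm_per_px or stack_a.nm_per_px
    half = max(1, int(round(box_nm / 2.0 / nmpp)))
    offsets = []
    n_excluded = 0
    h, w = stack_a.frames.shape[1:]
    for (x, y) in np.asarray(coords_px, dtype=float).reshape(-1, 2):
        r, c = int(round(y)), int(round(x))
        r0, r1 = max(0, r - half), min(h, r + half + 1)
        c0, c1 = max(0, c - half), min(w, c + half + 1)
        prof_a = stack_a.frames[:, r0:r1, c0:c1].sum(axis=(1, 2))
        prof_b = stack_b.frames[:, r0:r1, c0:c1].sum(axis=(1, 2))
        try:
            za = _fit_z_center(prof_a)
            zb = _fit_z_center(prof_b)
        except (RuntimeError, ValueError):
            n_excluded += 1
            continue
        offsets.append((zb - za) * z_step_nm)
    if not offsets:
        raise FitError("axial Gaussian fit failed for every bead")
    arr = np.asarray(offsets)
    return float(arr.mean()), arr, n_excluded


def z_half_auc(profile: LineProfile) -> float:
    """Position (nm) at which the cumulative area reaches half the total.

    Cumulative trapezoid area along the profile; the half-area position is
    found by linear interpolation. Equivalent to the median of the profile
    viewed as a density.
    """
    v = profile.v
    if np.any(v < 0):
        raise ValueError("profile must be nonnegative")
    cum = integrate.cumulative_trapezoid(v, profile.s, initial=0.0)
    total = cum[-1]
    if total <= 0:
        raise PipelineError("zero total area under the profile")
    half = total / 2.0
    i = int(np.searchsorted(cum, half))
    if i == 0:
        return float(profile.s[0])
    frac = (half - cum[i - 1]) / (cum[i] - cum[i - 1])
    return float(profile.s[i - 1] + frac * (profile.s[i] - profile.s[i - 1]))
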