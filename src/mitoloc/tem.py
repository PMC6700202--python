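"""Cristae-junction width profiling on transmission-EM micrographs.

A crista appears in TEM as a pair of dark membrane lines flanking a brighter
lumen. Starting from the junction (CJ) where the crista meets the inner
boundary membrane, intensity profiles are sampled orthogonally to a
user-drawn path every 2 nm (10 nm tangential averaging, up to 130 nm into the
crista). Each profile is halved at its midpoint and the position of the
intensity minimum on either side marks a membrane; the distance between the
two minima is the local crista width. Aggregating stations across many
junctions yields a width-versus-depth curve whose value at station 0 is the
junction width.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .core import Image2D, LineProfile, PipelineError
from .profiles import extract_profile

__all__ = [
    "CJPath",
    "WidthProfile",
    "sample_orthogonal_profiles",
    "width_from_profile",
    "cj_width_curve",
    "STEP_NM",
    "MAX_LEN_NM",
]

STEP_NM = 2.0
MAX_LEN_NM = 130.0


@dataclass
class CJPath:
    """Polyline from the cristae junction into the crista, in pixel coords.

    Vertices are ``(x, y)`` pixel coordinates; the first vertex is the CJ.
    """

    vertices_px: np.ndarray
    nm_per_px: float

    def __post_init__(self) -> None:
        self.vertices_px = np.asarray(self.vertices_px, dtype=float)
        if self.vertices_px.ndim != 2 or self.vertices_px.shape[0] < 2 \
                or self.vertices_px.shape[1] != 2:
            raise ValueError("CJPath needs >= 2 (x, y) vertices")
        if not self.nm_per_px > 0:
            raise ValueError("nm_per_px must be positive")

    @property
    def length_nm(self) -> float:
        seg = np.diff(self.vertices_px, axis=0)
        return float(np.sum(np.hypot(seg[:, 0], seg[:, 1])) * self.nm_per_px)

    def point_and_tangent(self, d_nm: float):
        """Position (px) and unit tangent at arc length ``d_nm`` from the CJ."""
        seg = np.diff(self.vertices_px, axis=0)
        seg_len = np.hypot(seg[:, 0], seg[:, 1]) * self.nm_per_px
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
        if d_nm < 0 or d_nm > cum[-1] + 1e-9:
            raise ValueError("arc length outside path")
        i = int(np.searchsorted(cum, d_nm, side="right") - 1)
        i = min(i, len(seg) - 1)
        frac = (d_nm - cum[i]) / seg_len[i] if seg_len[i] > 0 else 0.0
        pt = self.vertices_px[i] + frac * seg[i]
        tangent = seg[i] / np.hypot(*seg[i])
        return pt, tangent


@dataclass
class WidthProfile:
    """Crista width versus distance from the IBM on a uniform nm grid."""

    d_nm: np.ndarray
    w_nm: np.ndarray
    n_valid: Optional[np.ndarray] = None
    sem_nm: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.d_nm = np.asarray(self.d_nm, dtype=float)
        self.w_nm = np.asarray(self.w_nm, dtype=float)

    @property
    def width_at_cj_nm(self) -> float:
        """Width at station 0 (the junction)."""
        return float(self.w_nm[0])


def station_grid(path_length_nm: float, step_nm: float = STEP_NM,
                 max_len_nm: float = MAX_LEN_NM) -> np.ndarray:
    """Arc-length stations: 0, step, ... up to min(path length, max length)."""
    limit = min(path_length_nm, max_len_nm)
    n = int(np.floor(limit / step_nm)) + 1
    return np.arange(n) * step_nm


def sample_orthogonal_profiles(
    img: Image2D,
    path: CJPath,
    step_nm: float = STEP_NM,
    width_nm: float = 10.0,
    max_len_nm: float = MAX_LEN_NM,
    half_extent_nm: float = 40.0,
) -> List[LineProfile]:
    """Orthogonal profiles at every arc-length station along the path.

    Each profile is perpendicular to the local path tangent, centred on the
    path, extends ``half_extent_nm`` to each side and is averaged over
    ``width_nm`` of tangential width. If a profile would leave the image the
    path is truncated there with a warning.
    """
    if img.nm_per_px != path.nm_per_px:
        raise ValueError("image and path pixel sizes differ")
    nmpp = img.nm_per_px
    width_px = max(1, int(round(width_nm / nmpp)))
    half_px = half_extent_nm / nmpp
    h, w = img.shape
    profiles: List[LineProfile] = []
    for d in station_grid(path.length_nm, step_nm, max_len_nm):
        pt, tan = path.point_and_tangent(d)
        normal = np.array([-tan[1], tan[0]])
        p0 = pt - half_px * normal
        p1 = pt + half_px * normal
        inside = all(
            0 <= p[0] <= w - 1 and 0 <= p[1] <= h - 1 for p in (p0, p1)
        )
        if not inside:
            warnings.warn(
                f"profile at d={d:.0f} nm exits the image; path truncated",
                stacklevel=2,
            )
            break
        profiles.append(extract_profile(img, p0, p1, width_px=width_px))
    return profiles


def width_from_profile(profile: LineProfile) -> float:
    """Crista width from one orthogonal profile, in nm (NaN if invalid).

    The profile is halved at its geometric midpoint (the centre sample of an
    odd-length profile belongs to neither half). In each half the global
    intensity minimum marks a membrane; ties are broken toward the midpoint,
    then toward the lower index. A flat half yields NaN.
    """
    v = profile.v
    n = len(v)
    if n < 4:
        raise ValueError("profile too short (need >= 4 samples)")
    mid = (n - 1) / 2.0
    if n % 2 == 1:
        halves = (np.arange(0, n // 2), np.arange(n // 2 + 1, n))
    else:
        halves = (np.arange(0, n // 2), np.arange(n // 2, n))

    positions = []
    for idx in halves:
        vals = v[idx]
        if vals.max() == vals.min():
            return float("nan")
        cand = idx[vals == vals.min()]
        dist = np.abs(cand - mid)
        cand = cand[dist == dist.min()]
        positions.append(int(cand.min()))
    i_left, i_right = positions
    return float((i_right - i_left) * profile.spacing_nm)


def cj_width_curve(
    widths_per_cj: Sequence[Sequence[float]],
    step_nm: float = STEP_NM,
) -> WidthProfile:
    """Aggregate per-junction width series into a mean +/- SEM curve.

    Junctions of different lengths are pooled per station with unequal n;
    invalid widths (NaN) are excluded. A station with no valid width is
    reported as NaN with ``n_valid`` 0. SEM is 0 where only one value exists.
    """
    if len(widths_per_cj) == 0:
        raise PipelineError("no junctions provided")
    n_st = max(len(w) for w in widths_per_cj)
    mat = np.full((len(widths_per_cj), n_st), np.nan)
    for i, wseries in enumerate(widths_per_cj):
        mat[i, : len(wseries)] = np.asarray(wseries, dtype=float)
    n_valid = np.sum(np.isfinite(mat), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(mat, axis=0)
        sd = np.nanstd(mat, axis=0, ddof=1)
    sem = np.where(n_valid > 1, sd / np.sqrt(np.maximum(n_valid, 1)), 0.0)
    sem = np.where(n_valid == 0, np.nan, sem)
    d = np.arange(n_st) * step_nm
    return WidthProfile(d_nm=d, w_nm=mean, n_valid=n_valid, sem_nm=sem)
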