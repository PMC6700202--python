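"""Synthetic phantoms with known ground truth for every pipeline stage.

Four generators emulate the data the quantification stages consume:

* ``generate_sim_pair`` — dual-colour projections of a tubular mitochondrion
  whose fluorophores sit on concentric cylindrical shells (outer membrane vs.
  inner boundary membrane, radial separation ``shell_sep_nm``), uniformly in
  the inner volume, or enriched on cristae sheets. The 3D density is
  integrated along the optical axis analytically (a shell of radius r projects
  to a density proportional to 1/sqrt(r^2 - u^2)), blurred with a 2D Gaussian
  PSF, and degraded with Poisson shot noise plus Gaussian read noise.
* ``generate_tem_cristae`` — a TEM-like micrograph of a crista whose two dark
  membrane lines flank a lumen of width w(d) = w_inf + (w0 - w_inf) exp(-d/l),
  flaring near the junction.
* ``generate_bead_field`` — two-channel bead images/stacks related by an
  affine (shift + isotropic scale about the field centre) distortion.
* ``generate_trace`` — fluorescence time series (baseline + sigmoidal
  response) x exponential bleach + noise.

All generators take an explicit integer seed; identical (config, seed) pairs
produce bit-identical output, and every output carries a ground-truth record
sufficient to score downstream estimators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .core import Image2D, ImageStack, PipelineError, SizingError, Trace
from .tem import CJPath, WidthProfile, station_grid, STEP_NM, MAX_LEN_NM

__all__ = [
    "SIMPhantomConfig", "SIMGroundTruth", "generate_sim_pair",
    "TEMPhantomConfig", "TEMGroundTruth", "generate_tem_cristae", "TEM_PRESETS",
    "BeadFieldConfig", "BeadGroundTruth", "generate_bead_field",
    "TracePhantomConfig", "TraceGroundTruth", "generate_trace",
]

LABEL_MODES = ("omm_shell", "ibm_shell", "uniform_imm", "cristae_enriched")

# Junction widths (nm) by experimental condition; interior width and decay
# length are shared across conditions (widening is confined to ~60 nm of the
# junction, beyond which cristae look alike).
TEM_PRESETS = {
    "control": 17.1,
    "opa1_kd": 26.9,
    "micu1_kd": 27.9,
}


# --------------------------------------------------------------------------
# SIM tube phantom
# --------------------------------------------------------------------------

@dataclass
class SIMPhantomConfig:
    """Geometry, optics and noise of the dual-colour tube phantom.

    The tube is a straight cylinder of outer-shell radius ``r_outer_nm``;
    the inner shell sits ``shell_sep_nm`` further in. ``photons_per_nm`` is
    the emitted flux per nm of tube length (per channel, before noise).
    """

    tube_length_nm: float = 1000.0
    r_outer_nm: float = 200.0
    shell_sep_nm: float = 21.0
    label_mode_a: str = "omm_shell"
    label_mode_b: str = "ibm_shell"
    cristae_spacing_nm: float = 80.0
    psf_fwhm_nm: float = 110.0
    axial_fwhm_nm: float = 300.0
    nm_per_px: float = 32.0
    photons_per_nm: float = 40.0
    read_noise_sd: float = 3.0
    background: float = 20.0
    orientation_deg: float = 0.0
    shot_noise: bool = True
    max_field_px: int = 4096

    def __post_init__(self) -> None:
        if not (self.r_outer_nm > self.shell_sep_nm >= 0):
            raise ValueError("need r_outer_nm > shell_sep_nm >= 0")
        if self.nm_per_px <= 0 or self.psf_fwhm_nm <= 0:
            raise ValueError("nm_per_px and psf_fwhm_nm must be positive")
        if self.tube_length_nm <= 0:
            raise ValueError("tube_length_nm must be positive")
        for m in (self.label_mode_a, self.label_mode_b):
            if m not in LABEL_MODES:
                raise ValueError(f"unknown label mode {m!r}")


@dataclass
class SIMGroundTruth:
    """What the SIM phantom actually contains, for scoring estimators."""

    true_shell_sep_nm: float
    tube_axis_px: Tuple[Tuple[float, float], Tuple[float, float]]
    true_diameter_a_nm: float
    true_diameter_b_nm: float
    label_mode_a: str
    label_mode_b: str
    total_flux_a: float
    total_flux_b: float
    nm_per_px: float


_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(8)


def _shell_cross_mass(u_lo: np.ndarray, u_hi: np.ndarray, r: float,
                      sigma_z: float) -> np.ndarray:
    """Projected mass of a unit shell between perpendicular offsets u_lo, u_hi.

    A thin cylindrical shell of radius r projects along the optical axis to
    D(u) = 1 / (pi sqrt(r^2 - u^2)) for |u| < r (both walls). With axial
    optical sectioning of Gaussian sigma_z, the wall at height
    z(u) = sqrt(r^2 - u^2) is attenuated by exp(-z^2 / 2 sigma_z^2); the
    substitution u = r sin(phi) removes the edge singularity, leaving
    mass = (1/pi) int exp(-r^2 cos^2(phi) / 2 sigma_z^2) dphi, evaluated by
    Gauss-Legendre quadrature per pixel. sigma_z = inf recovers the pure
    projection, where the integral is (phi_hi - phi_lo) / pi exactly.
    """
    p_lo = np.arcsin(np.clip(u_lo / r, -1.0, 1.0))
    p_hi = np.arcsin(np.clip(u_hi / r, -1.0, 1.0))
    if not math.isfinite(sigma_z):
        return (p_hi - p_lo) / math.pi
    mid = (p_hi + p_lo) / 2.0
    half = (p_hi - p_lo) / 2.0
    phi = mid[..., None] + half[..., None] * _GL_NODES
    integrand = np.exp(-((r * np.cos(phi)) ** 2) / (2.0 * sigma_z ** 2))
    return (half[..., None] * _GL_WEIGHTS * integrand).sum(axis=-1) / math.pi


def _filled_cross_mass(u_lo: np.ndarray, u_hi: np.ndarray, r: float,
                       sigma_z: float) -> np.ndarray:
    """Projected mass of a unit filled cylinder between offsets u_lo, u_hi.

    Density D(u) = 2 sqrt(r^2 - u^2) / (pi r^2); with sectioning the chord
    integral becomes an erf of the chord half-height. Quadrature per pixel.
    """
    lo = np.clip(u_lo, -r, r)
    hi = np.clip(u_hi, -r, r)
    if not math.isfinite(sigma_z):
        def cdf(u):
            return (u * np.sqrt(np.maximum(r * r - u * u, 0.0))
                    + r * r * np.arcsin(u / r)) / (math.pi * r * r)
        return cdf(hi) - cdf(lo)
    from scipy.special import erf
    mid = (hi + lo) / 2.0
    half = (hi - lo) / 2.0
    u = mid[..., None] + half[..., None] * _GL_NODES
    z_half = np.sqrt(np.maximum(r * r - u * u, 0.0))
    density = (sigma_z * math.sqrt(2.0 * math.pi)
               * erf(z_half / (sigma_z * math.sqrt(2.0)))) / (math.pi * r * r)
    return (half[..., None] * _GL_WEIGHTS * density).sum(axis=-1)


def _mode_radius(mode: str, cfg: SIMPhantomConfig) -> float:
    if mode == "omm_shell":
        return cfg.r_outer_nm
    return cfg.r_outer_nm - cfg.shell_sep_nm


def _render_ideal(cfg: SIMPhantomConfig, mode: str):
    """Noise-free photon image of one channel, plus geometry in px."""
    h = cfg.nm_per_px
    theta = math.radians(cfg.orientation_deg)
    c, s = math.cos(theta), math.sin(theta)
    margin = 3.0 * cfg.psf_fwhm_nm
    half_l = cfg.tube_length_nm / 2.0
    r_max = cfg.r_outer_nm
    ex = abs(c) * half_l + abs(s) * r_max + margin
    ey = abs(s) * half_l + abs(c) * r_max + margin
    nx = int(math.ceil(2 * ex / h))
    ny = int(math.ceil(2 * ey / h))
    if max(nx, ny) > cfg.max_field_px:
        raise SizingError(
            f"tube + margin needs {nx}x{ny} px, exceeds max_field_px="
            f"{cfg.max_field_px}"
        )
    x = (np.arange(nx) - (nx - 1) / 2.0) * h
    y = (np.arange(ny) - (ny - 1) / 2.0) * h
    xx, yy = np.meshgrid(x, y)
    t = xx * c + yy * s          # along-axis coordinate (nm)
    u = -xx * s + yy * c         # perpendicular coordinate (nm)

    r = _mode_radius(mode, cfg)
    sigma_z = cfg.axial_fwhm_nm / (2.0 * math.sqrt(2.0 * math.log(2.0))) \
        if math.isfinite(cfg.axial_fwhm_nm) else math.inf
    if mode in ("omm_shell", "ibm_shell"):
        cross = _shell_cross_mass(u - h / 2.0, u + h / 2.0, r, sigma_z)
    else:
        cross = _filled_cross_mass(u - h / 2.0, u + h / 2.0, r, sigma_z)

    if mode == "cristae_enriched":
        # label concentrated on parallel disc sheets along the axis
        sigma_sheet = 4.0  # nm, sheet thickness / 2.355
        n_sheets = max(1, int(cfg.tube_length_nm // cfg.cristae_spacing_nm))
        centers = (np.arange(n_sheets) - (n_sheets - 1) / 2.0) * cfg.cristae_spacing_nm
        from scipy.special import erf
        axial = np.zeros_like(t)
        mass = cfg.tube_length_nm / n_sheets  # same total flux as uniform fill
        for tc in centers:
            axial += 0.5 * mass * (
                erf((t - tc + h / 2.0) / (math.sqrt(2) * sigma_sheet))
                - erf((t - tc - h / 2.0) / (math.sqrt(2) * sigma_sheet))
            )
    else:
        axial = np.clip(
            np.minimum(t + h / 2.0, half_l) - np.maximum(t - h / 2.0, -half_l),
            0.0, h,
        )

    ideal = cfg.photons_per_nm * cross * axial
    axis = (
        (-half_l * c / h + (nx - 1) / 2.0, -half_l * s / h + (ny - 1) / 2.0),
        (half_l * c / h + (nx - 1) / 2.0, half_l * s / h + (ny - 1) / 2.0),
    )
    return ideal, axis


def _apply_noise(ideal: np.ndarray, cfg: SIMPhantomConfig,
                 rng: np.random.Generator) -> np.ndarray:
    img = ideal + cfg.background
    if cfg.shot_noise:
        img = rng.poisson(img).astype(float)
    if cfg.read_noise_sd > 0:
        img = img + rng.normal(0.0, cfg.read_noise_sd, size=img.shape)
    return img


def generate_sim_pair(
    config: SIMPhantomConfig, seed: int
) -> Tuple[Image2D, Image2D, SIMGroundTruth]:
    """Render both channels of the tube phantom with shared geometry."""
    rng = np.random.default_rng(seed)
    sigma_px = config.psf_fwhm_nm / (2.0 * math.sqrt(2.0 * math.log(2.0))) / config.nm_per_px
    ideal_a, axis = _render_ideal(config, config.label_mode_a)
    ideal_b, _ = _render_ideal(config, config.label_mode_b)
    flux_a = float(ideal_a.sum())
    flux_b = float(ideal_b.sum())
    blur_a = ndimage.gaussian_filter(ideal_a, sigma_px, mode="constant")
    blur_b = ndimage.gaussian_filter(ideal_b, sigma_px, mode="constant")
    ch_a = Image2D(_apply_noise(blur_a, config, rng), config.nm_per_px, "chA")
    ch_b = Image2D(_apply_noise(blur_b, config, rng), config.nm_per_px, "chB")
    gt = SIMGroundTruth(
        true_shell_sep_nm=config.shell_sep_nm,
        tube_axis_px=axis,
        true_diameter_a_nm=2.0 * _mode_radius(config.label_mode_a, config),
        true_diameter_b_nm=2.0 * _mode_radius(config.label_mode_b, config),
        label_mode_a=config.label_mode_a,
        label_mode_b=config.label_mode_b,
        total_flux_a=flux_a,
        total_flux_b=flux_b,
        nm_per_px=config.nm_per_px,
    )
    return ch_a, ch_b, gt


# --------------------------------------------------------------------------
# TEM cristae-junction phantom
# --------------------------------------------------------------------------

@dataclass
class TEMPhantomConfig:
    """Funnel-shaped crista rendered as two dark membrane lines.

    ``w_junction_nm`` (w0) is the lumen width at the junction,
    ``w_interior_nm`` (w_inf) the asymptotic interior width and
    ``decay_len_nm`` the funnel decay length. Membranes are Gaussian-profile
    dark lines (sigma = thickness / 2.355) so that the minima-based width
    readout sees smooth minima. ``membrane_contrast`` < 0 makes membranes
    intensity minima relative to the lumen.
    """

    w_junction_nm: float = 17.1
    w_interior_nm: float = 14.0
    decay_len_nm: float = 25.0
    membrane_thickness_nm: float = 5.0
    membrane_contrast: float = -0.6
    nm_per_px: float = 1.0
    noise_sd: float = 0.05
    preset: str = "custom"
    path_length_nm: float = 130.0
    lumen_level: float = 1.0

    def __post_init__(self) -> None:
        if self.w_junction_nm <= 0 or self.w_interior_nm <= 0:
            raise ValueError("widths must be positive")
        if self.membrane_contrast >= 0:
            raise ValueError("membranes must be darker than the lumen "
                             "(membrane_contrast < 0)")
        if self.nm_per_px <= 0 or self.decay_len_nm <= 0:
            raise ValueError("nm_per_px and decay_len_nm must be positive")

    @classmethod
    def from_preset(cls, name: str, **overrides) -> "TEMPhantomConfig":
        if name not in TEM_PRESETS:
            raise ValueError(f"unknown preset {name!r}; "
                             f"available: {sorted(TEM_PRESETS)}")
        return cls(w_junction_nm=TEM_PRESETS[name], preset=name, **overrides)

    def width_at(self, d_nm) -> np.ndarray:
        """Funnel law w(d) = w_inf + (w0 - w_inf) exp(-d / lambda)."""
        d = np.asarray(d_nm, dtype=float)
        return self.w_interior_nm + (
            self.w_junction_nm - self.w_interior_nm
        ) * np.exp(-d / self.decay_len_nm)


@dataclass
class TEMGroundTruth:
    profile: WidthProfile
    unresolvable: bool
    config: TEMPhantomConfig


def generate_tem_cristae(
    config: TEMPhantomConfig,
    seed: int,
    orientation_deg: Optional[float] = None,
) -> Tuple[Image2D, CJPath, TEMGroundTruth]:
    """Render one crista with a straight junction path.

    The path orientation (default: random) and sub-pixel origin are drawn
    from the seed so that repeated phantoms dither the sampling grid. The
    funnel is continued a short way past the junction (d < 0, widths growing)
    so that tangentially averaged profiles at station 0 are unbiased.
    """
    rng = np.random.default_rng(seed)
    if orientation_deg is None:
        orientation_deg = float(rng.uniform(0.0, 360.0))
    h = config.nm_per_px
    L = config.path_length_nm
    flare_nm = 12.0                      # rendered continuation past the CJ
    w_clip = 60.0                        # cap the flare opening
    half_extent = 40.0 + config.membrane_thickness_nm + 10.0

    theta = math.radians(orientation_deg)
    c, s = math.cos(theta), math.sin(theta)
    ex = abs(c) * (L + flare_nm) / 2 + abs(s) * half_extent + 15.0
    ey = abs(s) * (L + flare_nm) / 2 + abs(c) * half_extent + 15.0
    nx = int(math.ceil(2 * ex / h)) + 2
    ny = int(math.ceil(2 * ey / h)) + 2

    # CJ origin near the field centre with sub-pixel jitter
    origin_px = np.array([(nx - 1) / 2.0, (ny - 1) / 2.0]) \
        - np.array([c, s]) * (L / 2.0 / h) + rng.uniform(0.0, 1.0, 2)

    x = np.arange(nx)[None, :] - origin_px[0]
    y = np.arange(ny)[:, None] - origin_px[1]
    d = (x * c + y * s) * h              # along-path distance from CJ (nm)
    u = (-x * s + y * c) * h             # signed orthogonal offset (nm)

    w_half = np.minimum(config.width_at(np.maximum(d, -flare_nm)), w_clip) / 2.0
    sigma_m = config.membrane_thickness_nm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    in_extent = (d >= -flare_nm) & (d <= L + 8.0)
    dip = (
        np.exp(-0.5 * ((u - w_half) / sigma_m) ** 2)
        + np.exp(-0.5 * ((u + w_half) / sigma_m) ** 2)
    ) * in_extent
    img = config.lumen_level * (1.0 + config.membrane_contrast * dip)
    if config.noise_sd > 0:
        img = img + rng.normal(0.0, config.noise_sd * config.lumen_level,
                               size=img.shape)

    end_px = origin_px + np.array([c, s]) * (L / h)
    path = CJPath(np.stack([origin_px, end_px]), nm_per_px=h)

    d_grid = station_grid(L)
    w_true = config.width_at(d_grid)
    gt = TEMGroundTruth(
        profile=WidthProfile(d_nm=d_grid, w_nm=w_true),
        unresolvable=bool(np.any(w_true < 2.0 * h)),
        config=config,
    )
    return Image2D(img, h, "tem"), path, gt


# --------------------------------------------------------------------------
# Bead field phantom
# --------------------------------------------------------------------------

@dataclass
class BeadFieldConfig:
    """Two-channel bead field with affine inter-channel distortion."""

    n_beads: int = 20
    field_px: int = 128
    inter_channel_shift_px: Tuple[float, float] = (0.0, 0.0)
    inter_channel_scale: float = 1.0
    jitter_sd_px: float = 0.0
    spot_sigma_px: float = 1.5
    z_planes: int = 1
    z_offset_nm: float = 0.0
    z_step_nm: float = 60.0
    z_sigma_planes: float = 1.5
    amplitude: float = 1000.0
    noise_sd: float = 2.0
    min_separation_factor: float = 6.0

    def __post_init__(self) -> None:
        if self.n_beads < 2:
            raise ValueError("n_beads must be >= 2")
        if self.spot_sigma_px <= 0:
            raise ValueError("spot_sigma_px must be positive")


@dataclass
class BeadGroundTruth:
    coords_a_px: np.ndarray   # (n, 2) as (x, y)
    coords_b_px: np.ndarray
    z_center_a_planes: float
    z_center_b_planes: float
    config: BeadFieldConfig


def _place_beads(cfg: BeadFieldConfig, rng: np.random.Generator) -> np.ndarray:
    margin = 5.0 * cfg.spot_sigma_px + 2.0
    min_sep = cfg.min_separation_factor * cfg.spot_sigma_px
    coords: List[np.ndarray] = []
    for _ in range(cfg.n_beads):
        for attempt in range(100):
            p = rng.uniform(margin, cfg.field_px - 1 - margin, 2)
            if all(np.hypot(*(p - q)) >= min_sep for q in coords):
                coords.append(p)
                break
        else:
            raise PipelineError(
                "could not place beads without overlap after 100 attempts"
            )
    return np.array(coords)


def _render_spots(coords: np.ndarray, cfg: BeadFieldConfig,
                  z_center: float) -> np.ndarray:
    n = cfg.field_px
    stack = np.zeros((cfg.z_planes, n, n))
    yy, xx = np.mgrid[0:n, 0:n]
    if cfg.z_planes > 1:
        zw = np.exp(-0.5 * ((np.arange(cfg.z_planes) - z_center)
                            / cfg.z_sigma_planes) ** 2)
    else:
        zw = np.ones(1)
    for (x0, y0) in coords:
        spot = cfg.amplitude * np.exp(
            -((xx - x0) ** 2 + (yy - y0) ** 2) / (2.0 * cfg.spot_sigma_px ** 2)
        )
        stack += zw[:, None, None] * spot[None, :, :]
    return stack


def generate_bead_field(
    config: BeadFieldConfig, seed: int
) -> Tuple[ImageStack, ImageStack, BeadGroundTruth]:
    """Render both channels; channel-B coordinates follow the affine map
    ``scale * (r - c0) + c0 + shift + jitter`` about the field centre c0."""
    rng = np.random.default_rng(seed)
    coords_a = _place_beads(config, rng)
    c0 = np.array([(config.field_px - 1) / 2.0] * 2)
    jitter = (
        rng.normal(0.0, config.jitter_sd_px, coords_a.shape)
        if config.jitter_sd_px > 0 else np.zeros_like(coords_a)
    )
    coords_b = (
        config.inter_channel_scale * (coords_a - c0) + c0
        + np.asarray(config.inter_channel_shift_px, dtype=float) + jitter
    )
    z_a = (config.z_planes - 1) / 2.0
    z_b = z_a + config.z_offset_nm / config.z_step_nm
    stack_a = _render_spots(coords_a, config, z_a)
    stack_b = _render_spots(coords_b, config, z_b)
    if config.noise_sd > 0:
        stack_a = stack_a + rng.normal(0.0, config.noise_sd, stack_a.shape)
        stack_b = stack_b + rng.normal(0.0, config.noise_sd, stack_b.shape)
    gt = BeadGroundTruth(coords_a, coords_b, z_a, z_b, config)
    # pixel size is irrelevant for bead metrics in px; use 1 nm/px placeholder
    return (
        ImageStack(stack_a, 1.0, "chA"),
        ImageStack(stack_b, 1.0, "chB"),
        gt,
    )


# --------------------------------------------------------------------------
# Fluorescence trace phantom
# --------------------------------------------------------------------------

@dataclass
class TracePhantomConfig:
    """(baseline + logistic response) x exponential bleach + Gaussian noise."""

    t_step_s: float = 1.0
    n_points: int = 90
    baseline: float = 100.0
    bleach_tau_s: float = 200.0      # math.inf for no bleaching
    response_onset_s: float = 30.0   # logistic midpoint t0
    response_amplitude: float = 60.0
    response_rate: float = 0.35      # logistic rate k (1/s)
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.t_step_s <= 0:
            raise ValueError("t_step_s must be positive")
        if not (self.bleach_tau_s > 0):
            raise ValueError("bleach_tau_s must be positive (math.inf allowed)")


@dataclass
class TraceGroundTruth:
    tau_s: float
    onset_s: float
    max_slope_pct_per_s: float
    t_at_max_slope_s: float
    clean_f: np.ndarray   # bleach-free, noise-free signal


def generate_trace(
    config: TracePhantomConfig, seed: int
) -> Tuple[Trace, TraceGroundTruth]:
    """F(t) = (baseline + A / (1 + exp(-k (t - t0)))) exp(-t/tau) + noise.

    The ground-truth maximal slope of the bleach-free percent-change signal
    follows from the logistic derivative: 100 k A / (4 baseline) %/s at t0.
    The returned trace's baseline window covers samples with t < t0 - 4/k,
    where the response is < 2% of its amplitude.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(config.n_points) * config.t_step_s
    k, t0, amp = config.response_rate, config.response_onset_s, config.response_amplitude
    response = amp / (1.0 + np.exp(-k * (t - t0))) if amp != 0 else np.zeros_like(t)
    clean = config.baseline + response
    decay = (
        np.exp(-t / config.bleach_tau_s)
        if math.isfinite(config.bleach_tau_s) else np.ones_like(t)
    )
    f = clean * decay
    if config.noise_sd > 0:
        f = f + rng.normal(0.0, config.noise_sd, size=f.shape)
    # response-free window: logistic < 0.1% of its amplitude before t0 - 7/k
    pre_end = int(np.searchsorted(t, t0 - 7.0 / k)) if (amp != 0 and k > 0) \
        else config.n_points
    pre_end = max(pre_end, 2)
    trace = Trace(t=t, f=f, baseline_window=(0, pre_end))
    gt = TraceGroundTruth(
        tau_s=config.bleach_tau_s,
        onset_s=t0,
        max_slope_pct_per_s=100.0 * k * amp / (4.0 * config.baseline),
        t_at_max_slope_s=t0,
        clean_f=clean,
    )
    return trace, gt
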