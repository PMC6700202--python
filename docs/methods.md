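# Methods

This note documents the models behind each quantification, the tunable
parameters and their defaults, what the phantom generators do and do not
emulate, and the numerical choices that matter for reproducing results.

## SIM tube phantom

A mitochondrion is modelled as a straight cylinder. Fluorophores sit either
on a thin cylindrical shell (outer membrane at radius `r_outer_nm`, inner
boundary membrane at `r_outer_nm − shell_sep_nm`), uniformly through the
inner volume (a volume stain such as a Mitotracker dye, mode `uniform_imm`),
or concentrated on parallel disc sheets (`cristae_enriched`, spacing
`cristae_spacing_nm`).

**Projection with axial sectioning.** A widefield projection of a shell of
radius r gives the chord density `D(u) ∝ 1/√(r² − u²)`. A reconstructed
3D-SIM slice, however, rejects out-of-focus light: the tube's front and back
walls (at height `z(u) = √(r² − u²)` above the focal plane through the tube
axis) are attenuated. We model this with a Gaussian axial acceptance
`exp(−z²/2σ_z²)` of FWHM `axial_fwhm_nm` (default 300 nm, the standard
3D-SIM axial resolution; `inf` recovers the pure widefield projection). The
sectioning matters: with the pure chord model the inner plateau of the
profile skews each fitted Gaussian arm inward in proportion to the shell
radius, and the half-difference estimator then shrinks the recovered
separation by roughly a third. With realistic sectioning the two channels'
compressions cancel to within ~1 nm at the operating point.

Pixel values are computed by exact per-pixel integration of the projected
density (a `u = r·sinφ` substitution removes the edge singularity; 8-point
Gauss–Legendre quadrature per pixel), multiplied by the axial coverage of the
tube ends, so the rendered flux is analytic. The image is then blurred with
a Gaussian PSF (`psf_fwhm_nm`, default 110 nm — typical reconstructed N-SIM
lateral resolution) and degraded with Poisson shot noise on signal +
background and additive Gaussian read noise (a standard camera model).

Defaults: `r_outer_nm = 200` (a 400 nm tubule), `tube_length_nm = 1000`,
`nm_per_px = 32`, `photons_per_nm = 40`, `background = 20` counts,
`read_noise_sd = 3`. Only the 21 nm default shell separation is a reported
quantity; the rest are conventional imaging values, configurable throughout.

**Not emulated:** curved or branched tubes, SIM reconstruction artifacts
(honeycombing, out-of-focus haze), chromatic misregistration between the two
channels, and labelling stochasticity. Passing phantom tests therefore
demonstrates estimator correctness under ideal geometry, not robustness to
reconstruction pathology.

## Inter-label distance estimation

Cross-section profiles are extracted perpendicular to the (known) tube axis
by bilinear interpolation at 1-px steps, averaged over 3 px of width along
the axis, half-extent 400 nm per side. Each profile is fitted with a
double Gaussian plus constant offset by bounded Levenberg–Marquardt;
initialization takes the two most prominent local maxima of a 3-sample
moving-mean smoothed copy. A unimodal profile yields a flagged,
non-converged fit rather than an exception. Fits with
`rss > 0.2 × total profile variance` are excluded from aggregation (the gate
is configurable).

The estimator is the per-profile half-difference `(D_A − D_B)/2` averaged
over profiles. Reference ensembles (`mitoloc.experiments`) draw a uniformly
random tube orientation per phantom: at axis-aligned orientations the 32 nm
sampling grid aliases the fitted peak positions by ~2 nm, which random
orientations dither away.

Residual bias of the mean is ~1 nm at the operating point (110 nm PSF,
32 nm/px) and grows toward the sampling limit (roughly +4 nm at a 90 nm PSF,
where σ_PSF approaches the pixel pitch); the property tests bound it at
1.5 nm for the operating PSF (n = 400 profiles) and with a 6 nm envelope
across PSF ∈ {90, 110, 130} nm. Per-profile scatter at the default noise is
a few nm SD, so means over ~100 profiles carry sub-nm standard errors —
smaller than the scatter real micrographs show, since phantoms are free of
biological variability.

## IBM association index

Templates: Otsu threshold on a 256-bin histogram of the reference frame
(per-frame in time courses, so templates track bleaching), optional
fill-holes (used when the reference itself is shell-like), then count-based
binary morphology. The morphology contract is the raster binary-options
rule: per iteration a background pixel turns foreground on dilation iff at
least `count` of its 8 neighbours are foreground, erosion symmetrically;
outside the image border counts as background. Defaults
`dilate_iterations = 2`, `erode_iterations = 3`, `count = 1`; the useful
ranges are 1–4 and 2–6 — the values trade shell thickness against
sensitivity per marker and are echoed in every result.

The index is gain-invariant by construction (the ratio cancels a common
scale), which is why background subtraction must precede it: a common
additive offset does *not* cancel. A zero CM mean yields a flagged
NaN result, not an exception, so batch runs survive empty frames.

## TEM cristae-junction phantom and width profiling

The crista is a funnel `w(d) = w∞ + (w₀ − w∞)·exp(−d/λ)` opening at the
junction (d = 0). Membranes are rendered as Gaussian-profile dark lines
(σ = `membrane_thickness_nm`/2.355, default 5 nm thickness, contrast −0.6 of
the lumen level) at lateral offsets ±w(d)/2 in the path frame, so the
orthogonal-profile minima sit exactly on the membrane centerlines. The
funnel is continued ~12 nm past the junction (widths still growing, capped
at 60 nm) so that tangentially averaged station-0 profiles are unbiased.
Condition presets set w₀ to 17.1 / 26.9 / 27.9 nm (control, OPA1-kd,
MICU1-kd); `w∞ = 14 nm` and `λ = 25 nm` are shared across conditions, which
encodes the observation that widening is confined to the ~60 nm nearest the
junction. Pixel size defaults to 1 nm (×27,000-class TEM); additive Gaussian
noise of 5% of the lumen level.

Width readout follows the halved-profile minima rule: the profile (sampled
every 2 nm along the path, 10 nm tangential width, 40 nm orthogonal
half-extent) is split at its geometric midpoint (the centre sample of an
odd-length profile belongs to neither half); each half's global minimum
marks a membrane, ties resolved toward the midpoint then the lower index
(the conservative, narrower reading); a flat half flags the station invalid
(NaN). Minima are pixel-quantized; the phantom's random sub-pixel origin and
orientation dither the quantization so that means over many junctions
converge. Aggregation pools stations across junctions of unequal length with
per-station n and SEM (0 where n = 1).

**Not emulated:** membrane undulations, stain granularity, neighbouring
cristae crossing the profile, and the manual judgement of where to stop the
path — on real micrographs path drawing remains the operator's task; the CLI
consumes path CSVs.

## Chromatic calibration

The lateral metric interprets "relative local aberration" as
`|v_i − v_j| / d_ij × 100%` for each matched bead i and its nearest
neighbour j, with `v = pos_B − pos_A`. This is translation-invariant
(a pure channel shift gives 0) and reports differential distortion: under a
pure magnification difference α about any centre it equals α for every pair
exactly. A literal inner-product reading (`metric="dot"`) is available for
comparison. Beads are paired across channels by mutual nearest neighbour
within a 5 px gate. Localization refines Otsu-floored local maxima with 2D
Gaussian least squares in a ±3σ window.

Axial offset: per bead, a `box_nm` square (default 320 nm) is projected to a
z-intensity profile per channel and fitted with a 1D Gaussian; the offset is
the mean of `(z_B − z_A)` over beads, in nm via the z-step. The half-area
(AUC/2) position uses a cumulative trapezoid and linear interpolation — it
is the median of the profile read as a density.

## Trace kinetics

Bleaching is treated as multiplicative, so traces are *divided* by the
fitted decay `A·exp(−t/τ)` normalized to 1 at the first sample (fitted on a
response-free window; default the trace's pre-stimulus baseline window). A
fitted rate insignificantly below zero (within 3σ of its own uncertainty, or
immaterial over the trace span) is clamped to zero — anti-bleaching is not a
physical correction; a significantly rising fit raises an error naming the
likely cause (response contamination of the window).

The maximal slope is computed on the percent-change signal
`P = 100(f − f₀)/f₀` with a Savitzky–Golay local-polynomial derivative,
window 11 samples, order 3. Order 1 (plain local linear regression) is
available but systematically underestimates a sigmoid's peak slope — the
cubic term of the logistic leaks into symmetric linear windows — by up to
~16% at the default response rate; order 3 cancels that leading bias. The
maximum may be searched within a response epoch (`search_window_s`): after
strong bleach correction the late-trace noise is amplified by `e^{t/τ}` and
would otherwise dominate the global maximum.

A single noisy draw of a derivative estimate carries irreducible scatter
(about 5–7% SD of the true slope at 1%-of-baseline sample noise), so
recovery of the closed-form logistic slope `100·kA/(4·baseline)` %/s is
validated on the ensemble mean over 20 seeded replicates per bleach regime
(τ ∈ {50, 200, ∞} s), which is bounded at 5%. Onset is the first crossing of
`onset_frac` (default 0.05) of the trace's own maximal percent change,
linearly interpolated; the lag time Δt is onset-to-maximal-slope across two
traces and is exactly equivariant under common time shifts on the sampling
grid.

Trace phantom defaults — 90 samples at 1 s, baseline 100, logistic onset
t₀ = 30 s, amplitude 60% of baseline, rate 0.35 s⁻¹, bleach τ = 200 s, noise
1% of baseline — describe a typical agonist-evoked Ca²⁺ transient. The
generated baseline window ends at `t₀ − 7/k`, where the logistic is below
0.1% of its amplitude; ending it at `4/k` (≈2% of amplitude) measurably
biases the fitted bleach τ.

## Morphometrics

Yen's threshold (256-bin histogram, foreground strictly above) feeds
8-connected particle analysis. Axes come from the second-moment ellipse;
`AR = major/minor`. The perimeter is the 4-direction Crofton estimator,
chosen because the form factor is convention-sensitive: Crofton gives
FF ≈ 0.99 for digital disks, honouring FF = 1 for a circle, whereas a raw
boundary walk with √2 diagonals overshoots by ~10%. Particles with a
degenerate minor axis report NaN aspect ratios; minimum-size and
edge-exclusion filters default to off.

## Background subtraction

The rolling-ball background is the grayscale opening of the image with a
ball-shaped (non-flat) structuring element, default radius 50 px, output
clipped at zero. Opening is idempotent, so a second pass changes the result
only through the clip (bounded below 0.5% of the dynamic range for smooth
backgrounds). ROI background subtraction removes the mean of a caller-
asserted signal-free region.

## Determinism and I/O conventions

Every generator takes an explicit integer seed (no global random state);
pipelines at fixed (config, seed) write byte-identical numeric outputs.
Coordinates are 0-based `(x, y)` with x = column; CSV polylines and endpoint
files use `x_px, y_px` column order. Physical pixel size is a first-class
parameter: TIFFs written here embed `nm_per_px`, and readers require an
explicit override when metadata is absent. All user-facing distances are nm.

## Known limitations

- Phantom tubes are straight and isolated; the IBM index on the field of
  view, not per organelle, matches its intended use but phantoms do not test
  crowded fields.
- The double-Gaussian distance estimator assumes the double-line geometry is
  resolved; profiles that fail to show two peaks are excluded, which on real
  data can bias selection toward larger tubes.
- The lateral aberration figure depends on the metric interpretation
  documented above; absolute comparability to instrument-specific reports is
  limited.
- Slope estimates on single noisy traces carry ~5–7% scatter; comparisons
  should use replicate means, as the validation does.
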