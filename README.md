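# mitoloc

Quantification of **sub-mitochondrial protein localization** from dual-colour
super-resolution (SIM) images, transmission electron micrographs and live-cell
fluorescence traces — together with synthetic phantom generators that make
every estimator verifiable against known ground truth without microscope data.

The package is aimed at researchers quantifying where a protein sits *within*
a mitochondrion: on the inner boundary membrane (IBM, the part of the inner
membrane apposed to the outer membrane), in the cristae, or spread through the
inner membrane — and how the cristae-junction geometry and Ca²⁺/membrane-
potential dynamics respond to perturbations.

## What it computes

**IBM association index.** The reference channel (a volume-filling
mitochondrial marker) is Otsu-thresholded; count-based binary dilation and
erosion produce two disjoint templates — a hollow shell (IBM) and the eroded
interior (CM). The index is the ratio of area-normalized mean object-channel
intensities,

```
index = (Σ_IBM I / A_IBM) / (Σ_CM I / A_CM)
```

A peripherally confined label scores > 1, a uniformly distributed one scores
1. Per-frame templates give a time course during, e.g., depolarization.

**Sub-resolution inter-label distance.** A labelled membrane tube appears as
a double line; a cross-section profile `v(s)` is fitted with
`A₁g(s;μ₁,σ₁) + A₂g(s;μ₂,σ₂) + b`, and `D = |μ₂ − μ₁|` reads out the apparent
tube diameter. For two labels on concentric shells, the per-profile
half-difference `δ = (D_A − D_B)/2` estimates their radial spacing: the
PSF-induced compression is common to both channels and largely cancels, so
the mean over ~100 profiles resolves distances an order of magnitude below
the optical resolution. `fwhm()` gives the plain tube width.

**Cristae-junction (CJ) width.** Along a path drawn from the junction into a
crista, intensity profiles are sampled orthogonally every 2 nm (10 nm
tangential averaging, up to 130 nm). Each profile is halved; the intensity
minimum on either side marks a membrane, and the distance between minima is
the local width. Pooling stations across junctions yields width-vs-depth
curves (mean ± SEM) whose station-0 value is the junction width.

**Chromatic calibration.** Sub-pixel bead localization (2D Gaussian fits),
a translation-invariant local lateral aberration metric
(`|v_i − v_j| / d_ij`, in %, with `v` the inter-channel displacement),
axial channel offset from 1D Gaussian fits of per-bead z-profiles, and the
half-area (AUC/2) axial position readout.

**Morphometrics.** Yen binarization, 8-connected particle analysis, aspect
ratio `AR = y/x` (moment-ellipse axes) and form factor `FF = p²/(4πa)` with a
Crofton perimeter (FF ≈ 1 for digital disks), plus the area-weighted FF as a
branching measure.

**Trace kinetics.** Background-ROI subtraction, multiplicative bleach
correction by a fitted exponential decay, ratio traces, maximal slope of the
percent-change signal in %/s (Savitzky–Golay local-polynomial derivative),
response onset/lag times, and stimulus-response deltas.

**Phantoms.** Cylindrical-shell tube projections with 3D-SIM-like axial
sectioning, Gaussian PSF, Poisson + read noise; TEM funnels
`w(d) = w∞ + (w₀−w∞)e^{−d/λ}` with condition presets; affine-distorted bead
fields; `(baseline + logistic) × bleach` traces. Same seed + config →
bit-identical output, and every phantom carries its ground truth.

## Worked example

```python
from mitoloc import experiments

# 105 dual-colour cross-sections of tube phantoms whose outer and inner
# labels sit 21 nm apart, imaged with a 110 nm FWHM PSF at 32 nm/px:
res = experiments.distance_recovery(n_profiles=105, seed=11)
print(f"recovered separation: {res.mean_nm:.1f} +/- {res.sd_nm:.1f} nm "
      f"(n={res.n})")

# 100 TEM junction phantoms at the control-condition width:
curve = experiments.cj_width_recovery("control", n_junctions=100, seed=21)
print(f"junction width (control): {curve.width_at_cj_nm:.2f} "
      f"+/- {curve.sem_nm[0]:.2f} nm (n={int(curve.n_valid[0])})")
```

prints

```
recovered separation: 22.2 +/- 3.0 nm (n=105)
junction width (control): 17.38 +/- 0.06 nm (n=100)
```

The first line shows the double-Gaussian estimator recovering a 21 nm shell
separation — far below the 110 nm optical resolution — to within ~1 nm of
truth; the per-profile scatter (±3 nm here) shrinks as `1/√n` in the mean.
The second line recovers the 17.1 nm ground-truth junction width from
single-pixel-quantized minima positions, dithered across junctions.

The same operations are scriptable from the shell:

```
mitoloc simulate tem --preset control --seed 2 --out out/
mitoloc analyze cj-width --image out/tem.tif --paths out/centerline.csv \
        --nm-per-px 1.0 --out out/widths.csv
```

## Layout

- `mitoloc.synthetic` — phantom generators and ground-truth records
- `mitoloc.preprocess` — rolling-ball/ROI background, bleach correction
- `mitoloc.ibm_index` — binary morphology, shell templates, association index
- `mitoloc.profiles` — profile extraction, double-Gaussian fits, FWHM
- `mitoloc.tem` — orthogonal sampling and CJ width curves
- `mitoloc.chromatic` — bead localization and aberration metrics
- `mitoloc.morphometrics` — Yen threshold, particle descriptors
- `mitoloc.trace_kinetics` — ratios, slopes, lag times, response deltas
- `mitoloc.experiments` — reference phantom ensembles with their analyses
- `mitoloc.io` / `mitoloc.cli` — TIFF/CSV/JSON plumbing, pipeline runner, CLI

See `docs/methods.md` for the models, parameter choices and limitations.
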