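# Methods

This note documents the models, conventions, numerical choices, and
limitations behind `mwibone`. Nothing here states a result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Probe model and calibration

The open-ended coaxial probe is modeled with the Stuchly capacitive
aperture: aperture admittance `Y(ω) = jω(C₀ ε_r + C_f)` and reflection
`Γ = (1 − Y Z₀)/(1 + Y Z₀)`. The model is algebraically invertible, so
permittivity extraction is exact rather than iterative. Its domain excludes
the short (Γ = −1, infinite admittance); inversion raises there.

**Sign convention.** Time dependence `e^{+jωt}`; a lossy passive material
has `ε = ε′ − jε″` with `ε″ ≥ 0`. This is enforced everywhere; a lossless ε
gives `|Γ| = 1` and a lossy one `|Γ| < 1`.

**One-port error model.** Measured and actual reflection are related by the
standard three-term bilinear model `Γ_m = e_d + e_r Γ/(1 − e_s Γ)`. With
`k = e_r − e_d e_s` this is linear in `(e_d, k, e_s)`:
`Γ_m = e_d + k Γ + e_s (Γ Γ_m)`, solved per frequency — exactly for three
standards, by complex least squares for four. The reference liquids are
single-pole Debye models; the defaults (water 22 °C: ε_s = 79.2, ε_∞ = 5.2,
τ = 9.36 ps; propylene glycol 22 °C: ε_s = 19.0, ε_∞ = 3.0, τ = 320 ps) are
literature-informed values used only by the simulator and are configurable.

**Probe parameters.** `C₀` and `C_f` need not be known a priori: since
`Y/(jω) = C₀ε + C_f` is linear in both, they are estimated from de-embedded
sweeps of two or more known liquids by stacking real and imaginary parts
into one linear least-squares problem. A fit returning non-positive
capacitances raises with diagnostics — this is the only "non-convergence"
mode the closed-form solve can have. The simulator default (C₀ = 25 fF,
C_f = 20 fF) is a plausible small-aperture value; no quantitative result
depends on it.

## Sensitivity characterization

Three bench experiments define the probe footprint:

* **Radial kernel.** The response to a centered cylinder of diameter D is
  the kernel mass inside radius D/2, so successive curve increments divided
  by annulus areas recover a piecewise-constant per-area density. Measured
  curves are cleaned with isotonic regression first (noise otherwise
  produces negative annuli, which are floored at zero and the mass
  renormalized to 1). A curve departing from monotone by more than 0.05 is
  rejected as not a cumulative response. The equivalent lateral radius
  `r_eq` is the interpolated radius enclosing 90% of the mass (quantile
  configurable; the cutoff is a convention, not a measurement).
* **Lateral profile.** Sliding a large flat sample across the probe traces
  an edge response, which is fitted with a four-parameter logistic. The
  lateral sensitivity *profile* is the derivative of that logistic,
  peak-normalized — the natural reading of an edge-response experiment.
  Where a composite weight is needed (upscaling), it is the product of the
  radial density and this profile.
* **Depth profile.** Visibility versus slab thickness is fitted with the
  single-exponential saturation `V(t) = 1 − e^{−t/δ}`, the simplest
  saturating family with a closed-form effective depth
  `d_eff(H) = δ(1 − e^{−H/δ})`. The default δ is calibrated so that the
  depth factor ρ = d_eff/H equals 0.16875 at the 8-mm hole depth — the
  constant ratio between the depth-scaled and full-depth reference volumes
  in the study design — giving δ ≈ 1.354 mm. ρ(H) is strictly decreasing
  and lies in (0, 1).

## Acquisition geometry and mapping

A 4×4 array at 16-mm pitch stepped through a 4×4 pattern of 4-mm offsets
interleaves into a 16×16 effective grid at 4-mm spacing (256 effective
antennas); effective cell `(4a + p_i, 4b + p_j)` traces back to antenna
`(a, b)` at step `(p_i, p_j)`. The four 90° rotations are replicates: each
measured grid is de-rotated (`rot90`, exact for 90° multiples) into the
common specimen frame, assuming the specimen stays fixed while the array
rotates.

Upscaling to 0.5-mm maps uses normalized (partition-of-unity) sensitivity
weighting: `ε(x) = Σ W(‖x − p‖) ε_p / Σ W`. Being a convex combination it
cannot overshoot the coarse data, and a constant grid maps to a constant
image. The weight matrix depends only on geometry, kernel, and pixel size
and is cached across calls.

## Volumetry

The CRIM two-phase rule `√ε_mix = φ√ε_fluid + (1 − φ)√ε_background` is
inverted pixel-wise for φ, clipped to [0, 1] with clip events counted. The
region of interest keeps 8-connected components of `Δ√ε > k·σ` (k = 3),
discarding components under 4 pixels; σ is the robust SD (MAD × 1.4826) of
the whole difference map, which the sparse hole signal does not perturb.
The volume is `V = Σ_ROI φ · (pixel area) · d_eff(H)` — areal fractions
promoted to the probe's sensed slab — reported in μL (1 mm³ = 1 μL).
Because upscaled maps already fuse overlapping footprints through
normalized weights, a single pass over pixels realizes the
union-of-sensing-regions integral without double counting.

Repeatability over the four rotations reports the sample SD (n − 1), the
CV, and a Student-t 95% CI (df = 3). The t-based CI reproduces the
reference repeatability intervals exactly; a normal-quantile CI does not.

## CT reference

Holes are located from the known drill layout, not detected from the image.
Each cylindrical VOI (Ø 2 mm × 8 mm) collects voxels by center membership —
the simplest defensible rule; partial-volume effects at 0.94 × 0.94 × 3.0 mm
voxels are a documented limitation of the reference, not corrected. A hole
is positive when ≥ 50% of its voxels reach 250 HU (both thresholds
inclusive); each positive contributes the nominal 25.13 μL. The threshold
bookkeeping (separation gap, midpoint) is stored unrounded and any
threshold inside the empty/filled gap classifies identically. CT and
injected references are depth-rescaled by ρ so all modalities refer to the
same sensed slab.

## Agreement statistics

Conventions matter at n = 7 and are fixed as follows, each verified to
reproduce the reference panel: Lin's CCC uses sample (n − 1) moments with
`C_b = CCC/r`; Bland–Altman percent differences use the *reference* as
denominator; Deming regression uses error-variance ratio λ = 1 (orthogonal
regression; swapping axes inverts the slope); the Wilcoxon signed-rank test
is exact (full sign enumeration — with all seven differences positive,
p = 2/2⁷ = 0.015625); bootstrap CIs are percentile intervals over
specimen-level resamples (B = 10 000, seeded). ICC(2,1) is computed from
two-way ANOVA mean squares and cross-checked against an independent
implementation in the tests.

## Synthetic phantom generator

The generator emulates the study conditions so every stage runs at desk
scale; its defaults *are* those conditions, not tuning knobs:

* seven specimens with hole counts 16/16/25/25/20/20/16 and per-specimen
  baseline permittivity mean/SD matching the reported per-specimen array
  statistics (means 1.13–1.79);
* holes Ø 2 mm × 8 mm on a 4-mm lattice, fill fraction 1.0 by default;
* baseline fields are Gaussian random fields (correlation length 8 mm,
  floored at ε = 1.01) over a 76-mm extent chosen to fit the 60-mm grid
  plus kernel margins;
* per-antenna multiplicative gains drawn at exactly 8.2% CV (the draw is
  standardized, so the realized CV equals the target);
* measurement noise σ_ε = 0.02 per effective cell;
* the gel/contrast fluid permittivity defaults to 62 at 2.5 GHz (a
  water-like gel with contrast loading; configurable — no quantitative
  check depends on it);
* CT holes draw voxel HU from N(25, 73²) truncated below 132 (empty) and
  N(482, 132²) truncated above 388 (filled) over a 150-HU trabecular
  background, preserving the non-overlapping group extremes, so
  classification at 250 HU is perfect by construction and degrades when
  truncation is disabled.

The forward measurement model reads, at each effective cell, the
kernel-weighted average of the *refractive index* field (square root of
permittivity), squared — footprint mixing follows the same CRIM rule the
analysis inverts — times the antenna gain, plus noise. Holes contribute the
depth-weighted visible fraction of their fluid column. All draws descend
from one seeded generator with per-specimen sub-generators, so identical
configurations give identical datasets.

**What the simulator does not emulate:** probe–surface contact variability
and repositioning error between rotations (simulated rotation CVs, ~0.1–1%,
are therefore lower than bench values of 1–5%); frequency-dependent
kernels; 3-D dielectric scattering (the observation model is 2-D plus an
analytic depth weight, matching the pipeline's own assumptions); marrow
texture or diffuse lesion margins. Passing recovery tests therefore show
the *analysis chain* is unbiased and stable under the modeled noise, not
that the hardware achieves this on real bone.

## Problem sizes and numerical choices

The synthetic recovery study uses 20 specimens (cycling the seven reference
specimen designs) — large enough for stable correlation and median-error
estimates while keeping a full run within seconds. Upscaling uses 0.5-mm
pixels; halving the pixel size changes integrated volumes by well under 1%.
The simulator's fine lattice is 0.5 mm. Calibration degeneracy (two
standards with equal actual reflection) and de-embedding denominators below
1e-12 raise errors naming the frequency. Noise-free difference maps get a
tiny ROI noise floor (1e-6 of the peak) so thresholding still separates
signal from exact zeros.

## Known limitations

* The Stuchly model is quasi-static; at 2.5 GHz with high-permittivity
  loads a full-wave aperture model would differ. All quantitative claims
  are therefore made within the capacitive model.
* Specimen-level bench measurements are hardware-specific and not
  re-derivable from first principles here; the published statistics are
  reproduced from the packaged per-specimen volume tables, while the
  physics chain is validated on synthetic data.
* The CV column of the packaged repeatability table is recomputed from
  printed (rounded) mean/SD values, which can shift the last digit by one
  unit for one specimen.
* Per-hole volume attribution is out of scope: volumes are specimen-level
  totals, as in the study design.
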