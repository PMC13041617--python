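# Methods

## Equilibrium binding model

Radioligand kinetics are reduced to a three-compartment model: blood, free
tissue (free concentration `C2`, free fraction `f2`) and specifically bound
(`C3`, capacity `B_max`).  At equilibrium `0 = k_on·f2·C2·(B_max − C3) −
k_off·C3`, so the closed-form bound concentration is

```
C3 = B_max·k_on·f2·C2 / (k_off + k_on·f2·C2)
```

and at tracer (low-occupancy) doses `C3/(f2·C2) → BP = B_max·k_on/k_off =
B_max/K_D` with `K_D = k_off/k_on` (the standard dissociation constant).
`equilibrium_c3` keeps the full saturating form; `binding_potential` is the
linear-regime limit.  Tests verify both against a direct integration of the
kinetic ODE.

## SBR imaging and the summed voxel-based SBR

A voxel's SBR is `(counts − mean_ref)/mean_ref` against the occipital
reference mean; negative values are preserved and removed only by the ROI
threshold.  The brainstem 3D ROI is `SBR ≥ τ` inside an anatomical search
region, where the lower threshold is calibrated once per study as
`τ = floor_2dp(0.05 × mean(max brainstem SBR))` over the first nine control
subjects.  The two-decimal floor is deliberate truncation, not rounding: it
is the rule that maps a calibration mean of 1.71 onto the working threshold
0.08 (0.05 × 1.71 = 0.0855).  A `round(x·100, 9)` guard precedes the floor
so binary float representation noise cannot flip it.  Voxels exactly at τ
are included.

The ROI is split into midbrain (strictly above) and pons (at or below) at a
single transverse plane index along the inferior–superior axis; phantoms
know their true plane (the topmost pons voxel).  The anatomical landmark
construction used on real MRI is not re-derived here — the plane index is
caller-supplied per subject.  Regional burden is the summed voxel-based SBR
(sum over the ROI); summed SBRs are exactly additive over any ROI
partition, unlike means, and the midbrain-to-pons ratio of sums is the
diagnostic metric.  Empty-ROI convention: sums and means are 0 with count 0
and the ratio is undefined (reported missing, never 0).

### Search region

The manual, MRI-guided ROI boundary adjustment is modeled as a
deterministic search mask: the brainstem dilated by a metric margin
(default 16 mm, computed by Euclidean distance transform, enough to capture
PSF spill-out at the widest PSF studied), with contested voxels near the
striatum assigned to whichever structure is closer — the programmatic
analogue of the case-by-case midbrain/striatum boundary judgment that
automated atlases get wrong.  No interactive editing exists.

## Digital phantoms and cohorts

Phantom geometry is parametric and axis-aligned (ellipsoids and slabs) on a
64³ grid of 2 mm isotropic voxels: an occipital reference slab, a
midbrain/pons ellipsoid stack (true boundary plane at voxel index 33), and
a bilateral striatum.  Voxel centers sit at `index × voxel_size`, 0-based,
axis 2 inferior→superior.  Activities follow the binding model: a region
with binding potential BP carries `C_ref·(1 + BP)` over a nonspecific
background at the occipital level `C_ref = 1`, so a blur- and noise-free
phantom's regional mean SBR equals BP exactly (a tested invariant).
Default control-state BPs — midbrain 1.7, pons 1.2, striatum 3.0 — are free
parameters chosen to give brainstem SBR maxima of order 2 and a clearly
hotter striatum; no published per-region values were available to pin them.

Acquisition is emulated by an isotropic Gaussian PSF (default 7 mm FWHM,
the triple-head system class; σ = FWHM/2.3548 per axis, kernel truncated at
4σ, zero-padded edges) followed by scaling to expected counts
(`counts_scale = 800` per unit activity per voxel, putting the reference
region near 800 counts/voxel so Poisson noise is a few percent) and
per-voxel Poisson sampling.  A `poisson=False` hook returns expected counts
for exactness tests.  No projection/reconstruction, scatter or attenuation
is modeled, so the phantoms probe the quantification logic and
partial-volume behaviour, not reconstruction artifacts.

Cohorts default to 20 disease-like and 20 control subjects.  The disease
group multiplies midbrain activity by 0.6 and pons activity by 1.4 —
magnitudes chosen as plausible strong effects in the observed directions
(midbrain down, pons up), not published values.  Between-subject
variability is an independent lognormal factor per region (mean 1, CV 0.15
by default; the background shares the occipital factor so the reference
level stays coherent); ages are per-group normals (62.6 ± 9.4 vs
71.9 ± 10.3 years, truncated at 0) and sex is Bernoulli at 0.53 female.
Controls are generated first so threshold calibration can use the leading
nine.  Everything derives from one `numpy` Generator seeded from the cohort
specification's `seed` field.

## Statistics

Group comparisons use the Mann–Whitney U test (exact distribution when the
combined n ≤ 20 without ties, otherwise normal approximation with tie and
continuity corrections), Fisher's exact test for the sex split, and an
age-adjusted ANCOVA fit by OLS (`outcome ~ intercept + group + age`,
group = 1 for disease, two-sided t tests; rank-deficient designs are
rejected).  ROC analysis is empirical: AUC by midrank (equivalently,
trapezoid over the empirical curve; ties count half, so AUC = U/(n₁n₂), a
tested identity), direction auto-detected so AUC ≥ 0.5 — for the
midbrain-to-pons ratio the positive rule is `ratio ≤ cutoff` — and the
cutoff is the observed metric value maximizing Youden's J, J-ties broken
toward higher specificity.  α = 0.05 two-sided throughout; no
multiple-testing correction, matching the unadjusted reporting convention
the pipeline emulates.

## Histology simulation and IHC density

Synthetic sections emulate the quantification substrate rather than tissue
appearance.  White matter is the top `myelin_fraction` quantile of a
smoothed Gaussian random field (exact pixel count by rank selection);
immunopositive neurites are random 5–20 px line segments confined to gray
matter and adjusted to the exact target pixel count, so ground-truth
density is controlled to one pixel.  Stain concentrations (defaults: DAB
amplitude 0.9, myelin stain 0.7 OD units) are rendered via `I = I0·10^(−C·V)`
with optional Gaussian camera noise and 8-bit quantization.

The density pipeline inverts this: `OD = −log10((I+1)/I0)` (ε = 1 guards
zero intensities; I0 defaults to 255 and should match the acquisition white
level, which makes densities invariant to uniform brightness scaling),
concentrations by `OD·V⁻¹` with negatives clipped after solving, pixel
classes by thresholds in concentration units (per-image Otsu by default,
fixed override available), and density = immunopositive ∩ gray / gray
within a region mask.  Stain vectors default to the published DAB vector
and a blue counterstain vector standing in for Luxol fast blue, with the
residual row a normalized cross product; they are configurable because real
staining batches differ.  Amplitudes were kept below ~0.9 so that 8-bit
quantization plus the ε offset keeps the OD round-trip error under 0.01,
comfortably inside the thresholds' margins.  What passing tests show: the
deconvolution arithmetic and density bookkeeping are exact and robust to
quantization.  What they do not show: performance on real tissue with
stain colocalization, uneven illumination, or stain vectors differing from
the configured ones.

## Numerical conventions

All sums are double precision in numpy's pairwise order; oracle tests
compare against naive accumulation at tolerances ≥ 1e-10 relative.
Partition-additivity is asserted at the same tolerance (double rounding
makes bit-exact equality across different summation orders unattainable in
principle, though differences observed are ~1 ulp).  Thresholding uses ≥;
plane splitting uses strict > for the midbrain side.  Determinism: stage
seeds are `global_seed + crc32(stage_name) mod 2³¹`; identical config and
seed reproduce byte-identical CSV outputs (a tested contract), and the run
manifest records the seed and a SHA-256 config hash even on failure.

## Problem sizes

The shipped drivers and tests run 64³ phantoms with 20+20 subjects, 192²/256²
histology sections with 5+5 subjects, and 100-instance oracle sweeps on 5³
volumes — sizes at which every stage's behaviour (noise level, ROI growth,
group separation) is already in its asymptotic regime while a full run
completes in seconds.

## Known limitations

- Phantom anatomy is parametric; no curved brainstem, no registration
  error, no attenuation/scatter — partial-volume conclusions are about the
  threshold-ROI procedure, not about scanner physics.
- Group effects scale total regional activity (the generator's contract),
  which is a slightly stronger intervention than scaling specific binding
  alone.
- The disease/control effect sizes are free parameters; absolute AUCs from
  simulations characterize the pipeline under the stated conditions, not
  any patient population.
- The midbrain/pons landmark rule and real per-subject SBR tables are not
  reproduced; the boundary is an input.
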