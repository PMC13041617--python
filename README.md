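# sertquant

Semiquantitative quantification of brainstem serotonin-transporter (SERT)
availability from SPECT specific-binding-ratio (SBR) images, with a matching
immunohistochemistry (IHC) density pipeline — built for studying the
parkinsonian type of multiple-system atrophy (MSA-P), where serotonergic
neurons are lost in the midbrain while pontine SERT binding rises.

The package is written for imaging and neuropathology researchers who want
the whole measurement chain — equilibrium binding model, voxel-wise SBR
images, threshold-derived 3D ROIs, summed voxel-based SBR, the
midbrain-to-pons diagnostic ratio, group/ROC statistics, and stained-section
density by color deconvolution — as tested, reusable code.  Because no
patient data ships with it, first-class synthetic generators (digital brain
phantoms and dual-stained histology sections) provide inputs with known
ground truth for every stage.

## The model and the measurements

At equilibrium, a reversibly binding radioligand obeys
`0 = k_on·f2·C2·(B_max − C3) − k_off·C3`, giving the binding potential

```
BP = B_max·k_on/k_off ≈ C3/(f2·C2)
```

which a count image estimates per voxel as the specific binding ratio
against an occipital reference (negligible SERT):

```
SBR = (counts_voxel − mean counts_occipital) / mean counts_occipital
```

Because brainstem SERT uptake is spatially irregular, regional burden is the
**summed voxel-based SBR**: the sum of SBRs over a 3D ROI grown by
thresholding the SBR image inside an anatomical search region.  The lower
threshold is calibrated once as 5% of the mean maximum brainstem SBR of the
first 9 control subjects, truncated at two decimals (a calibration mean of
1.71 yields the working threshold 0.08).  The ROI is split at the
midbrain/pons transverse boundary plane, and the **midbrain-to-pons ratio**
of summed SBRs discriminates disease (lower ratio) from controls via an
empirical ROC with a Youden-index cutoff.

On the pathology side, RGB photomicrographs dual-stained with DAB
(SERT-immunopositive, brown) and a Luxol-fast-blue myelin stain are unmixed
by Beer–Lambert optical-density color deconvolution; SERT density is the
immunopositive fraction of the gray-matter (myelin-negative) area, and the
substantia-nigra-to-raphe density ratio mirrors the imaging ratio.

## Worked example

`analysis/` holds the numbered drivers; each prints what it found and
writes tables under `results/` (volumes go to `scratch/`):

```
python analysis/01_simulate_cohort.py 1   # 20 MSA-P-like + 20 HC phantoms
python analysis/02_quantify_sbr.py        # SBR images, threshold ROIs, summed SBR
python analysis/03_group_stats.py         # Mann-Whitney, ANCOVA, Fisher, ROC
python analysis/04_psf_robustness.py      # partial-volume experiment
python analysis/05_histology_density.py 1 # synthetic IHC cohort
```

With seed 1 the quantification stage prints

```
calibration: mean max SBR 2.11 over 9 HCs -> threshold 0.10
group medians:
       midbrain_summed_sbr  pons_summed_sbr  midbrain_pons_ratio
HC                  694.06           850.43                 0.79
MSA-P               230.98          1539.64                 0.15
```

i.e. the auto-calibrated threshold lands on the two-decimal grid, and the
simulated disease group (midbrain activity ×0.6, pons ×1.4) separates
cleanly.  The statistics stage then reports

```
midbrain_summed_sbr: disease median 230.98 vs control 694.06 (lower), Mann-Whitney p=1.8e-06
pons_summed_sbr:     disease median 1539.64 vs control 850.43 (higher), Mann-Whitney p=0.00062
midbrain_pons_ratio: disease median 0.15 vs control 0.79 (lower), Mann-Whitney p=1.1e-07
ratio ROC: AUC 0.99, cutoff 0.28 (positive rule: ratio <= cutoff), sens 0.95 / spec 1.00
```

— midbrain down, pons up, whole-brainstem total unchanged, and the ratio an
excellent discriminator.  The partial-volume experiment shows why the sum is
preferred over the mean: widening the PSF from 4 to 12 mm FWHM changes the
brainstem summed SBR by 5.6% but the mean SBR by 53.6%.  The histology
driver recovers the simulated section densities to within 10⁻⁴ and finds the
expected directions (substantia nigra lower, raphe higher, SN/raphe ratio
lower in disease, all p = 0.0079 at n = 5/5).

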