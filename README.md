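# popatlas

Population-average brain template construction, maximum-probability-map
(MPM) atlas building, and the deformation / regional-homogeneity statistics
used to validate such templates — implemented as a tested Python library
with a thin command-line interface, and exercised end-to-end on synthetic
brain phantoms with known ground truth.

## Who this is for

Neuroimaging methods researchers who need a self-contained, inspectable
implementation of the classic *iterative align-and-average* templating
recipe: groups whose population is not well served by standard adult
templates, or anyone who wants to study how template sharpness, cohort
size control, and atlas vote fusion behave under controlled conditions.
Every component runs on small synthetic cohorts, so the whole pipeline is
testable on a laptop without any imaging data.

## The method

**Template construction.** Given N skull-stripped, intensity-unified T1w
volumes, the driver alternates between aligning every subject to the
current reference base and voxel-wise averaging the aligned brains into the
next base:

1. *rigid* — a full affine is fitted to the starting reference but only its
   rotation + translation (polar decomposition) is applied → `mean-rigid`;
2. *affine* — full 12-parameter alignment to `mean-rigid` → `mean-affine`,
   followed by an intracranial-volume (ICV) correction: with
   V_coh the cohort-mean ICV and V_aff the mean-brain mask volume, every
   axis is scaled by (V_coh/V_aff)^(1/3) so the template keeps a
   cohort-representative size;
3. *nonlinear ladder* — five stages of increasingly fine nonlinear
   registration (minimum patch sizes 101, 49, 23, 13, 9 mm, with prescribed
   Gaussian/median pre-blurs), each followed by averaging, the same ICV
   rescale, and edge-preserving (Perona–Malik) smoothing.

Each stage records the cohort standard-deviation map and the grey/white
contrast-to-noise ratio CNR = |μ_WM − μ_GM| / sqrt((σ²_GM + σ²_WM)/2); the
stage-5 mean is the final template.  The *typical* template is the cohort
member with the lowest local-Pearson (`lpa`) cost against the final mean.

**Atlases.** Subject parcellations are carried into template space with
nearest-neighbour sampling and fused per voxel: each region's vote fraction
is its probability at that voxel, the plurality label forms the MPM atlas,
and the winner's fraction is stored as a max-probability map.  Typical
atlases are modally smoothed over facewise (7-voxel) neighbourhoods.

**Validation statistics.**

- log relative volume ratio (per region i):
  r_i = ln[ (V_MPM,i / V_MPM,ICV) / (1/N · Σ_j V_j,i / V_j,ICV) ] — 0 means
  the atlas region is volumetrically representative of the cohort;
- mean deformation value mDV = mean over region voxels of |dx|+|dy|+|dz|
  (mm), an intersubject-variability proxy;
- axis-wise median absolute displacement with exact paired Wilcoxon
  signed-rank tests (full 2^n null for n ≤ 25, Bonferroni correction);
- regional homogeneity ReHo = Kendall's coefficient of concordance W over
  a voxel's neighbourhood time series, with paired t-tests across template
  spaces.

**Synthetic cohorts.** `popatlas.synthgen` generates phantom cohorts from a
shared nested-ellipsoid anatomy (CSF shell, ventricles, folded GM ribbon
with ≥ 12 parcels, WM core): per subject a smooth random diffeomorphic warp
(positive Jacobian guaranteed) plus a small rigid offset, a multiplicative
bias field, and additive noise — with every ground-truth transform
returned, so recovery can be measured exactly.

## Worked example

Build a template from a small synthetic cohort with a shortened two-stage
nonlinear ladder:

```python
from popatlas import PhantomSpec, make_base_anatomy, make_cohort, build_template, ncc
from popatlas.templatize import StageEntry, StageSchedule

spec = PhantomSpec(grid_shape=(32, 32, 32), n_subjects=4,
                   warp_amplitude_mm=3.0, seed=7)
truth, labels = make_base_anatomy(spec.grid_shape, spec.voxel_mm, seed=spec.seed)
cohort = [rec for rec, warp, rigid in make_cohort(spec)]

schedule = StageSchedule([
    StageEntry("rigid", "rigid"),
    StageEntry("affine", "affine"),
    StageEntry("NL0", "nonlinear", 41.0, 0.0, 6.0, "gaussian"),
    StageEntry("NL1", "nonlinear", 21.0, 0.0, 2.0, "median"),
])
bundle = build_template(cohort, schedule, reference=truth, seed=7)

mask = truth.data > 0.05 * truth.data.max()
for st in bundle.stages:
    print(f"{st.stage_name:6s}  mean SD {st.mean_sd:6.2f}   CNR {st.cnr:.3f}")
print(f"template vs truth NCC: {ncc(bundle.template, truth, mask=mask):.4f}")
print(f"cohort mean ICV: {bundle.v_coh:.0f} mm^3, typical subject: {bundle.typical_subject_id}")
```

Output:

```
rigid   mean SD  36.73   CNR 3.524
affine  mean SD  29.85   CNR 3.521
NL0     mean SD  29.43   CNR 3.548
NL1     mean SD  24.84   CNR 3.598
template vs truth NCC: 0.9943
cohort mean ICV: 53906 mm^3, typical subject: sub-03
```

The cohort SD map shrinks as alignment refines (36.7 → 24.8), grey/white
CNR rises, the final template correlates at 0.994 with the hidden
ground-truth anatomy, and the brain-mask volume is held at the cohort-mean
ICV.

The same pipeline is available from a shell:

```bash
popatlas simulate --out cohort/ --seed 1234
popatlas build-template --cohort cohort/manifest.tsv \
    --reference cohort/reference.nii.gz --out tmpl/ --seed 1234
popatlas make-atlas --template-dir tmpl/ --cohort cohort/manifest.tsv --out atlas/
popatlas validate --template-dir tmpl/ --atlas-dir atlas/ \
    --cohort cohort/manifest.tsv --out stats/
```

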