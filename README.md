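# puv-fcd

Voxelwise detection of focal cortical dysplasia (FCD) lesions on T1-weighted
MRI by **positive unanimous voting (PUV)** over four Gaussian discriminant
classifiers, with a normative model built from healthy controls and
morphological region refinement. Ships with a synthetic phantom generator so
the entire pipeline can be exercised, evaluated, and reproduced without any
clinical data.

## The method

FCD is a malformation of cortical development and a common cause of
drug-resistant epilepsy. On T1 MRI it shows three radiological signatures:
local cortical **thickening**, **blurring** of the gray/white-matter junction,
and a **signal change** that pulls white matter toward the junction
intensity. The pipeline turns each signature into a voxelwise feature map and
lets an ensemble of simple classifiers vote:

1. **Intensity standardization** — a robust two-point rescale maps the
   1st/99th percentiles of in-brain intensity to 0/255, so histogram peaks
   align across subjects (checked with a histogram-intersection test).
2. **Feature maps** — per subject, four maps on the cortical domain:
   - `F1` GM thickness (mm), from paired Euclidean distance transforms on the
     GM mask;
   - `F2` gradient magnitude, central differences of the standardized volume;
   - `F3` relative intensity, `1 − |Bg − I|/Bg` where `Bg` is the GM/WM
     boundary intensity (midpoint of the GM and WM histogram peaks);
   - `F4` GM/WM boundary width (mm), the thickness of the partial-volume
     transition zone `0.1 < pv_wm < 0.9`.
3. **Normative differencing** — each feature is averaged over a 3×3×3 window
   (27 neighbors) and over K healthy controls to give a normative map
   `F_mu`; the subject's deviation is `Fd = F − F_mu`. The default feature
   group `FG6 = {Fd1, Fd3, Fd4}` feeds the classifiers (groups FG1–FG6 over
   raw and differenced features are selectable).
4. **Four base classifiers**, implemented from their closed forms: naive
   Bayes (diagonal per-class covariance), linear discriminant analysis
   (pooled covariance), quadratic discriminant analysis (per-class
   covariance), and Mahalanobis minimum-distance (pooled covariance, no
   priors). Ties resolve to non-lesional.
5. **Positive unanimous voting** — a voxel is lesional only if *all four*
   classifiers agree. The PUV positive set is the intersection of the
   members' positive sets, so its false-positive count is bounded by the
   best single classifier on every subject — the ensemble trades recall for
   a hard guarantee on specificity.
6. **Region refinement** — binary opening with a 3³ structuring element, then
   26-connected component labeling, then removal of components smaller than
   `Ts = 112.5 mm³` (900 voxels at 0.5 mm isotropic). A subject is called a
   patient iff any positive voxel survives.

Evaluation reports voxel-level and subject-level TPR, FPR, precision and
F-score per classifier and per stage (raw / opened / filtered), through a
leave-one-out cross-validation harness whose normative model is rebuilt from
the training-fold controls only.

## Worked example

Generate a synthetic cohort of 5 controls and 3 patients (64³ grid, 1 mm
spacing) and run leave-one-out cross-validation with the default
configuration:

```bash
puv-fcd phantom --n-controls 5 --n-patients 3 --seed 7 --out cohort
puv-fcd loocv --manifest cohort/manifest.csv --out loocv
```

which prints

```
subject-level TPR=1.000 FPR=0.000 -> loocv
```

and writes `loocv/subject_calls.csv` (all 3 patients called patient, all 5
controls called control) plus `loocv/summary.csv` / `summary.json` with the
voxel-level metrics. For this cohort and seed:

| classifier | stage    | F-score mean | TPR mean | FPR mean |
|------------|----------|-------------:|---------:|---------:|
| NB         | raw      | 0.813        | 0.816    | 0.025    |
| LDA        | raw      | 0.756        | 0.651    | 0.006    |
| QDA        | raw      | 0.889        | 0.863    | 0.008    |
| MDA        | raw      | 0.714        | 0.780    | 0.058    |
| PUV        | raw      | 0.770        | 0.651    | 0.002    |
| PUV        | filtered | 0.693        | 0.550    | 0.002    |

The PUV column shows the intended behavior: its voxel FPR (0.002) is below
every individual classifier's, at the price of recall — unanimity relabels
weakly supported lesional voxels as negative.

The same run through the Python API:

```python
from puv_fcd import PipelineConfig
from puv_fcd.phantom import PhantomConfig, generate_cohort
from puv_fcd.evaluation import loocv_run

cohort = generate_cohort(n_controls=5, n_patients=3, base_cfg=PhantomConfig(),
                         seed=7)
result = loocv_run(cohort, PipelineConfig(seed=7))
print(result.subject_report.tpr, result.subject_report.fpr)   # 1.0 0.0
```

Other commands: `puv-fcd features` (write the four feature maps per subject),
`puv-fcd detect` (train on a full cohort and emit label volumes, regions, and
subject calls), `puv-fcd eval` (score refined PUV labels against ground-truth
masks). All commands accept `--config config.yaml`; defaults are the
published parameter choices (window 3³, FG6, all four classifiers, Lw=3,
Ts=112.5 mm³, 26-connectivity).

## Reproduction

Everything is deterministic given the seeds:

```bash
pytest -q                                             # 208 tests, ~15 s
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script recomputes the package's main quantities — voting
equivalence, the analytic classifier identities, the normative-model oracle
check, threshold conversion, parameter recovery, and a full phantom LOOCV —
and writes them as JSON. With `--seed 1` it reports:

```
voting_equivalence_agreement: 1 (n=4800)
mda_vs_lda_equal_priors_max_score_gap: 1.07e-14 (n=1000)
qda_vs_lda_equal_covariances_max_score_gap: 8.88e-15 (n=1000)
normative_mean_max_abs_error_vs_oracle: 4.44e-16 (n=4096)
ts_voxel_count_at_0p5mm_for_112p5mm3: 900 (n=1)
classifier_min_labeling_accuracy: 0.99825 (n=4000)
mean_recovery_max_error_in_se_units: 1.148 (n=10000)
loocv_subject_tpr: 1 (n=8)
loocv_subject_fpr: 0 (n=8)
loocv_fp_containment_violations: 0 (n=8)
loocv_patient_puv_filtered_f_min: 0.685 (n=3)
loocv_patient_puv_filtered_f_mean: 0.705 (n=3)
loocv_min_surviving_region_volume_mm3: 495 (n=6)
```

See `docs/methods.md` for the model details, parameter defaults, and the
limitations of the phantom.

## Layout

```
src/puv_fcd/
  volume_io.py     NIfTI I/O, standardization, histogram checks, resampling
  phantom.py       synthetic cohorts with FCD-like lesions and exact PV maps
  features.py      F1-F4 maps, normative model, feature groups
  classifiers.py   NB / LDA / QDA / MDA from their closed forms
  voting.py        positive unanimous voting
  postprocess.py   opening, connected regions, size filter, subject call
  evaluation.py    metrics and the LOOCV harness
  pipeline.py      orchestration;  config.py  defaults;  cli.py  commands
```
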