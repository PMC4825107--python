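# Methods note

This note states the model implemented by `puv_fcd`, its parameters and
defaults, the numerical choices, and the limits of what the synthetic
phantoms can demonstrate.

## Problem setting

Input is a cohort of pre-aligned, skull-stripped T1-weighted volumes with
partial-volume (PV) maps for gray matter (GM), white matter (WM) and CSF, a
patient/control flag per subject, and (for evaluation) ground-truth lesion
masks. Orientation, registration, and tissue segmentation are out of scope:
volumes must share one grid, and in-brain voxels are identified by strictly
positive intensity. Output is a binary lesion label volume per subject, a set
of surviving lesion candidate regions, and a patient/control call.

## Intensity standardization

Let `q_lo`, `q_hi` be the 1st and 99th percentiles of in-brain intensity.
The map `x ↦ 255·(x − q_lo)/(q_hi − q_lo)`, clipped to [0, 255], is applied
to in-brain voxels; background stays 0 and clipped in-brain voxels are floored
at a tiny epsilon so the in-brain mask is preserved. The transform is
monotone, invariant to affine input changes `a·x + b` (a > 0), and idempotent
(an already-standardized volume is returned unchanged). Cross-subject
normalization quality is checked by histogram intersection: the fraction
`Σ min(h_q, h_r) / Σ h_r` over the union of the reference's GM and WM peak
windows (peak ± 2 FWHM, peaks found on a 5-bin moving average of the 256-bin
in-brain histogram); a warning is issued below 0.9.

## Feature maps

All features are computed on the classification domain: voxels with any GM
fraction, plus the GM/WM transition zone. Outside the domain, features are 0
and voxels are labeled negative without entering any classifier.

- **F1, GM thickness (mm).** On the GM mask (`pv_gm ≥ 0.5`):
  `d(v, nearest WM voxel) + d(v, nearest non-GM/non-WM voxel) − e`, clipped at
  0, where `d` is the Euclidean distance transform with physical sampling and
  `e` is one voxel edge. This is a deliberate simplification of PDE-based
  cortical thickness; it responds monotonically to thickening, which is what
  the classifier needs.
- **F2, gradient magnitude.** Euclidean norm of per-axis central differences
  of the standardized volume, spacing-aware. Junction blur lowers F2 at the
  GM/WM interface.
- **F3, relative intensity.** `clip(1 − |Bg − I|/Bg, 0, 1)` with `Bg` the
  midpoint of the GM and WM histogram peak intensities. F3 is maximal where
  intensity sits at the junction value, so blurred or signal-shifted lesional
  tissue scores high.
- **F4, GM/WM boundary width (mm).** Inside the transition zone
  `0.1 < pv_wm < 0.9` (with `pv_gm > 0`): twice the distance to the nearest
  non-zone voxel plus one voxel edge; 0 outside. A hard binary junction has an
  empty zone and an all-zero map.

## Normative model and feature groups

For each feature, the normative map `F_mu` is the 3×3×3 boxcar mean (N = 27
neighbors; truncated and renormalized at the grid boundary) of the voxelwise
average over the K training controls. The deviation map is `Fd = F − F_mu`.
Six fixed feature groups are supported:

| group | members |
|-------|---------------------|
| FG1   | F1, F2, F3          |
| FG2   | F1, F2, F3, F4      |
| FG3   | F1, F3, F4          |
| FG4   | Fd1, Fd2, Fd3       |
| FG5   | Fd1, Fd2, Fd3, Fd4  |
| FG6   | Fd1, Fd3, Fd4       |

FG6 is the default (`select_best_group` picks the group with the highest
classifier-averaged F-score when model selection is run explicitly).

## Base classifiers

Two classes: w1 lesional (positive), w2 non-lesional. All four classifiers
are Gaussian discriminants differing only in covariance structure; all are
fitted by sample moments (means, unbiased covariances) with an optional ridge
`ridge · trace(S)/d` on each covariance diagonal (default `1e-6`). Priors
default to training-class frequencies.

- **NB**: diagonal per-class covariances; decision by the log posterior
  ratio.
- **LDA**: pooled covariance `((n1−1)S1 + (n2−1)S2)/(n−2)`; linear
  discriminant `g_i(x) = μ_i'Σ⁻¹x − ½μ_i'Σ⁻¹μ_i + ln p_i`.
- **QDA**: per-class covariances; the default discriminant is the standard
  quadratic one (with the `−½(x−μ)'Σ_i⁻¹(x−μ)` and `−½ln|Σ_i|` terms). A
  linear-only variant that keeps per-class covariances but drops the
  quadratic and log-determinant terms is available as `qda_variant:
  printed`.
- **MDA**: nearest class in squared Mahalanobis distance under the pooled
  covariance; prior-free, identical to LDA at equal priors.

Scores are signed (positive ⇒ lesional); exact ties resolve to negative, the
conservative choice for a detector. Training voxels are drawn from the
classification domain of all training subjects; the negative class is capped
at `neg_per_pos = 10` times the positive count by seeded subsampling, and
features are z-scored with training statistics (label decisions are
affine-covariant, so scaling affects conditioning only).

## Positive unanimous voting

A voxel is lesional iff all four classifiers label it lesional. Formally the
PUV positive set is the intersection of the members' positive sets, so for
every subject `#FP(PUV) ≤ min_j #FP(C_j)` — a structural guarantee, not an
empirical tendency. The closed-form decision (product of the four decision
indicators: NB posterior ratio > 1, LDA and QDA discriminant differences > 0,
Mahalanobis distance ratio D(w2)/D(w1) > 1) agrees bitwise with combining the
four label volumes; ratios of strictly positive quantities are treated as
indicators, and the degenerate `D(w1) = 0` case maps to +inf.

## Region refinement and subject call

Fixed order: binary opening with an Lw³ structuring element (default Lw = 3),
26-connected component labeling, removal of components with physical volume
below `Ts = 112.5 mm³`. The threshold is stored as a volume and converted to
a voxel count via the working spacing (900 voxels at 0.5 mm isotropic; 112.5
voxels at 1 mm). A subject is called a patient iff any positive voxel
survives.

## Evaluation

Voxel metrics are computed within the classification domain: TPR = TP/(TP+FN),
FPR = FP/(FP+TN), precision = TP/(TP+FP), F = harmonic mean of precision and
recall. Conventions: precision 0 when nothing is predicted positive; F 0 when
precision+recall = 0; TPR (hence F) is NaN when the truth has no positives
(controls). Subject-level metrics use the patient call as the positive class.
The LOOCV harness rebuilds the normative model from training-fold controls
only, retrains all classifiers per fold with a per-fold seeded RNG, and
reports per-subject metrics for each classifier at the raw stage and for PUV
at raw/opened/filtered stages.

## Phantom

Each phantom is a perturbed spherical shell on a 64³ grid at 1 mm isotropic
spacing (package defaults): a WM ball (radius 18 mm, mean 160), a GM ribbon
(3 mm, mean 110), a thin CSF layer (2 mm, mean 30), zero background, Gaussian
noise (SD 4) added inside the head. The shell radius is modulated by a
seeded, low-order spherical-harmonic field (bands 2–4, relative amplitude
0.08) so normative maps are spatially non-uniform; all subjects of a cohort
share one field, standing in for registered scans. PV maps come from 3×3×3
subvoxel sampling, so tissue fractions and lesion masks are exact by
construction. Per-subject variation: Gaussian jitter of tissue means (SD 3)
and ribbon thickness (SD 0.15 mm).

Lesions are ball-shaped patches centered on the ribbon carrying the three FCD
signatures: ribbon thickening (factor 2), junction blur (an analytic
erfc-shaped WM/GM membership split with σ = 2 mm, which keeps PV sums exactly
1), and a WM intensity shift of 30 toward the junction value. Patch radii of
8–10 mm put ground-truth masks in the few-thousand-mm³ range typical of
clinically reported FCD lesions. The lesion mask is the set of voxels whose
PV vector changed by more than 0.01 against an unlesioned twin, plus the
intensity-shifted WM voxels.

**What the phantom does *not* show:** clinical performance. It has no real
gyration, no segmentation error (PV maps are exact), no registration error,
no scanner bias fields, and its lesions are geometrically simple. It
demonstrates that the pipeline's machinery is correct — the voting guarantee,
the normative arithmetic, detectability of lesions carrying the three
signatures under noise — not that the method attains any particular clinical
sensitivity.

## Numerical choices

- Distance transforms, opening, labeling: `scipy.ndimage` with physical
  sampling; classifiers and voting are implemented from their closed forms
  (no sklearn at runtime; sklearn serves as an independent oracle in tests).
- Covariance solves use `np.linalg.solve` / `slogdet` (no explicit
  inverses); singular covariances raise.
- Boxcar means use a truncated-window trick (`uniform_filter` on data and on
  ones, then a quotient) to renormalize at grid boundaries.
- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; LOOCV folds use `default_rng([seed, fold_index])`.
- Grid sizes (64³ defaults, 32³ test fixtures) are package choices to keep
  runs fast; all thresholds are physical (mm/mm³) and spacing-aware.

## Limitations

- Unanimity buys specificity with recall: after opening and size filtering,
  voxel-level recall on phantoms is ~0.5 even for clean detections, because
  the rim of a lesion (partial effects) rarely gets all four votes. The
  subject-level calls are robust to this; voxel-level F-scores should be read
  with it in mind.
- The GM thickness feature is a distance-transform surrogate, biased at high
  curvature and for ribbons ≤ 2 voxels.
- The normative model assumes voxelwise correspondence across subjects; it
  absorbs small misalignment through the 3×3×3 window but is not a substitute
  for registration.
- `select_best_group` implements the model-selection rule, but the pipeline
  default is the pre-selected FG6; re-running selection requires a scripted
  sweep over groups.
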