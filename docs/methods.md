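# Methods

## The staging problem

Subjects are staged NC → MCI → AD. Hippocampal atrophy separates
controls from impaired subjects well but blurs between MCI and AD;
CSF chemistry (Aβ42 down, t-tau and p-tau up with disease) carries the
complementary signal but with heavy overlap between adjacent stages.
The cascade therefore decides in two gated steps: NC vs symptomatic
from volume alone, then MCI vs AD from volume plus fuzzified CSF,
evaluated only on subjects the first stage flagged.

## Fuzzy c-means core

`hippostage.fuzzy` implements FCM from scratch (it is the modelling
heart of the package, not a commodity step):

* membership `mu_ij = 1 / sum_k (d_ij/d_ik)^(2/(m-1))`, computed
  stably by normalizing squared distances by their per-item minimum
  before exponentiation, so extreme fuzziness (`m → 1⁺`) cannot
  overflow;
* objective `J = sum_ij mu_ij^m d_ij²` with the simplex constraint
  `sum_i mu_ij = 1`;
* alternating optimization with the stationary center update
  `c_i = sum_j mu_ij^m x_j / sum_j mu_ij^m`. The update pair is a
  coordinate descent on J, so the objective trace is non-increasing;
  this is asserted in tests on every fit.

Numerical choices:

* **Fuzziness `m = 2.0`** — the conventional default; exposed
  everywhere as a parameter.
* **Initialization** — deterministic per-feature quantiles (25th/75th
  percentile for two clusters), so fitting needs no seed; a seeded
  random-restart mode exists.
* **Convergence** — max center displacement < 1e-6, cap 300 iterations.
* **Zero-distance singularity** — an item sitting exactly on a center
  gets crisp membership there; on several coincident centers, a uniform
  split among them.
* **Crisp assignment** — argmax membership, ties broken toward the
  lowest cluster index.
* **Pole labeling** — with two clusters, the cluster whose center mean
  is lower is AD-like when the feature falls with disease (volume,
  Aβ42) and NC-like otherwise; equal center means raise (degenerate
  fit).

Fuzzification is univariate by default — one 2-cluster FCM per CSF
feature (Aβ42, t-tau, p-tau, ratio), each contributing its AD-like
membership as a stage-2 feature. A multivariate mode (one joint FCM on
the standardized 4-feature panel) is provided; univariate is the
default because each biomarker has a known, distinct disease direction
that a single joint membership would conflate.

The CSF ratio is p-tau/Aβ42 by default (the common AD CSF composite;
higher is AD-like), with t-tau/Aβ42 selectable; the choice is recorded
in the serialized model bundle.

## The cascade

* **HLM1**: stage 1 is a supervised binary classifier on
  (left, right, total) volume with target NC vs {MCI ∪ AD}; stage 2 a
  supervised classifier on the 7-feature vector (3 volumes + 4
  memberships). Any of the 13 bank entries can back either stage;
  Extra-Trees is the default and reference model.
* **HLM2**: stage 1 is an *unsupervised* 2-cluster FCM on the volume
  triple (a univariate total-volume mode exists); diagnosis labels are
  never used to fit it. The lower-volume cluster is the symptomatic
  pole. Stage 2 is as in HLM1.
* Stage-2 training uses only MCI/AD records with a complete CSF panel,
  and the fuzzifiers are fitted on exactly those training records —
  never on validation data (the leakage guard is asserted in tests).
* At prediction, symptomatic subjects without CSF are emitted as
  `symptomatic_unspecified` — an abstention, reported as coverage and
  never counted correct.

The 13-model bank is backed by scikit-learn, XGBoost and LightGBM with
library-default hyperparameters and a fixed seed; distance- and
margin-based kinds (SVC, k-NN, MLP, logistic) are wrapped with feature
standardization because volumes are on a mm³ scale. The bank is
deliberately not tuned: the package's claims are about the cascade
structure and fuzzification, not about squeezing any single classifier.

## Volume preprocessing

* **Min–max normalization** maps intensities to [0, 1]; a constant
  volume maps to zeros with a logged warning.
* **Nearest-neighbor resize** uses per-axis factors f = desired/current
  and the standard index map `source = floor(target / f)`, clamped.
  (A literal reading of the resized-to-source index map as sometimes
  printed, `source = target · f`, shrinks indices in the wrong
  direction when downscaling; the standard map is implemented and
  verified against a brute-force triple-loop oracle.) Output spacing is
  divided by the factor, preserving physical extent.
* **Rotation augmentation** defaults to six small angles
  {−15°, −10°, −5°, +5°, +10°, +15°} about the height axis, so 630
  inputs yield 3780 augmented volumes with the originals replaced. The
  angle set is a package choice (six symmetric small angles, 0 excluded
  so outputs are genuinely distinct); rotation is nearest-neighbor with
  out-of-grid voxels set to the input minimum.
* **Volumetry**: with a threshold t, volume = count(p ≥ t) × voxel
  volume; without, the probability sum × voxel volume (the expected
  volume under the map). Default threshold 0.5 when thresholding is
  requested; both paths are supported.

## Synthetic cohort design

The generator emulates the *statistical shape* of an ADNI-like staging
cohort, not its actual measurements:

* group sizes 204 NC / 211 MCI / 215 AD (630 subjects), ~500 of them
  with a complete CSF panel (`csf_missing_rate = 130/630`);
* truncated-at-zero Gaussian markers (positivity of mm³ and pg/mL);
* per-side hippocampal volume means 3700/3600 (NC), 3075/2975 (MCI),
  2700/2600 (AD) mm³, SD 215 — totals 7300/6050/5300. The NC–MCI gap
  is wider than the MCI–AD gap: early atrophy separates controls from
  the symptomatic pool, which is also what lets the unsupervised
  stage 1 of HLM2 find the NC/symptomatic boundary;
* CSF means 1100/850/600 (Aβ42), 240/320/400 (t-tau), 22/30/38 (p-tau)
  pg/mL with SDs 170/55/5.5 — adjacent groups overlap at roughly
  1.3–1.5 SD separation;
* t-tau and p-tau are drawn jointly with correlation 0.7 (independent
  taus would be biologically implausible).

These defaults were fixed once by an upfront design calculation so that
Extra-Trees cascades land in the low-to-mid-90s percent validation
accuracy — challenging but not saturated. Units are pg/mL by
assumption; all numeric means are synthetic configuration values and
documented as such.

What the generator does **not** emulate: scanner effects,
age/sex/demographic covariance, longitudinal follow-up, non-Gaussian
tails, or volume–CSF correlation within a group. Passing tests
therefore demonstrate correctness and robustness of the *pipeline* on
data with the assumed structure, not clinical performance on real
cohorts.

Volume phantoms (two ellipsoidal blobs with NC > MCI > AD sizes, plus
exactly-covering binary masks) exercise the preprocessing/volumetry
path end to end with a known ground-truth volume.

## Evaluation protocol

Single seeded stratified 7:3 train/validation split per run; accuracy
is reported on the validation fold only. Because one split of ~630
subjects is noisy, every harness entry point accepts many seeds and
reports per-seed rows, and the headline numbers are means over 20
seeds. Stage accuracies are tabulated in isolation (stage 1 over the
whole fold; stage 2 over CSF-complete MCI/AD records) alongside the
gated end-to-end 3-class accuracy, where abstentions count against
accuracy and are reported as coverage.

The ablation harness compares volume-only, fuzzified-CSF-only and dual
feature sets with Extra-Trees on both contrasts, restricted to
CSF-complete subjects so the three feature sets see identical samples.

## Known limitations

* The unsupervised stage 1 of HLM2 assumes the NC/symptomatic volume
  gap dominates; on cohorts where MCI volume sits midway between NC
  and AD, a 2-cluster fit can split the symptomatic pool instead.
* Accuracy is the only metric (no ROC/AUC, calibration or
  cost-sensitive thresholds), matching the reporting style the harness
  reproduces.
* Stage-2 probabilities are raw classifier outputs, not calibrated.
* The CSV cohort schema is intentionally rigid (documented header,
  all-or-none CSF panels).
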