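# hippostage

Two-stage ("hybrid learning model") staging of cognitive impairment along
the Alzheimer's continuum — normal control (NC), mild cognitive
impairment (MCI), Alzheimer's disease (AD) — from two complementary
biomarkers:

* **hippocampal volume** (mm³, left + right, from a segmentation
  probability mask), which shrinks as disease progresses, and
* **CSF biomarkers** (amyloid-beta 42, total tau, phosphorylated tau,
  and the p-tau/Aβ42 ratio, pg/mL), which overlap heavily between MCI
  and AD and are therefore *fuzzified* before classification.

It is aimed at researchers prototyping staged screening pipelines on
tabular biomarker data, and ships a seeded synthetic cohort generator so
the full pipeline is runnable and testable without access-restricted
clinical data.

## The model

Both cascade variants decide in two gated stages:

1. **Stage 1 — NC vs symptomatic.** From the volume triple
   (left, right, total). *HLM1* uses a supervised classifier from a
   13-model bank (SVC, decision tree, random forest, XGBoost, LightGBM,
   Extra-Trees, gradient boosting, AdaBoost, k-NN, MLP, Gaussian NB,
   logistic regression, soft voting). *HLM2* instead fits unsupervised
   2-cluster fuzzy c-means (FCM) on the volumes; the low-volume cluster
   is the symptomatic pole.
2. **Stage 2 — MCI vs AD.** Only subjects deemed symptomatic reach
   stage 2, which classifies them (Extra-Trees by default) from the
   volumes plus four fuzzified CSF features.

Fuzzification replaces a raw biomarker value `x` by its membership
toward the AD-like cluster of a 2-cluster FCM fitted on the training
data. FCM membership and objective are

    mu_ij = 1 / sum_k (‖x_j − c_i‖ / ‖x_j − c_k‖)^(2/(m−1)),
    J(U, C) = sum_i sum_j mu_ij^m ‖x_j − c_i‖²,   sum_i mu_ij = 1,

minimised by alternating the membership update with the weighted-mean
center update `c_i = sum_j mu_ij^m x_j / sum_j mu_ij^m` (fuzziness
`m = 2` by default). The AD-like pole is assigned from biology: lower
is AD-like for Aβ42 and volume, higher for the taus and the ratio.

The package also implements the supporting 3D preprocessing math:
min–max intensity normalization, nearest-neighbor resizing via per-axis
scale factors (desired/current), small-angle rotation augmentation, and
mask-based hippocampal volumetry (NIfTI in/out).

## Worked example

```python
from hippostage import CohortSpec, generate_cohort, train_hlm1, train_hlm2
from hippostage.evaluation import SplitSpec, split_cohort, evaluate_cascade

cohort = generate_cohort(CohortSpec(seed=7))          # 630 synthetic subjects
train, val = split_cohort(cohort, SplitSpec(train_fraction=0.7, seed=7))

for name, model in [("HLM1", train_hlm1(train)), ("HLM2", train_hlm2(train))]:
    res = evaluate_cascade(model, val)
    print(f"{name}: stage1 (NC vs symptomatic) = {res['stage1_accuracy']:.3f}, "
          f"stage2 (MCI vs AD) = {res['stage2_accuracy']:.3f}, "
          f"cascade 3-class = {res['cascade_accuracy']:.3f}")
```

prints

```
HLM1: stage1 (NC vs symptomatic) = 0.952, stage2 (MCI vs AD) = 0.952, cascade 3-class = 0.810
HLM2: stage1 (NC vs symptomatic) = 0.937, stage2 (MCI vs AD) = 0.952, cascade 3-class = 0.810
```

Stage-1 accuracy is the NC-vs-symptomatic contrast over the whole
validation fold; stage-2 accuracy is the MCI-vs-AD contrast over the
CSF-complete MCI/AD validation subjects. The end-to-end 3-class cascade
accuracy is lower because stage-1 errors propagate and symptomatic
subjects without a CSF panel are counted as abstentions
(`symptomatic_unspecified`), never as correct.

The same pipeline is available from the shell:

```sh
hippostage synth --out cohort.csv --seed 7
hippostage train --variant hlm2 --cohort cohort.csv --seed 7 --out model/
hippostage predict --model model/ --cohort cohort.csv --out predictions.csv
hippostage evaluate --model model/ --cohort cohort.csv --out results.json
hippostage bank --cohort cohort.csv --variant hlm1 --seeds 3 --out bank.csv
hippostage ablate --cohort cohort.csv --seeds 20 --out ablation.csv
```

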