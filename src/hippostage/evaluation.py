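"""Splits, accuracy scoring, and the experiment harness.

The harness mirrors the reporting style of two-stage staging studies:
per-stage validation accuracy under a single seeded 7:3 train/validation
split, a 13-model comparison table, and a biomarker ablation (volume
only vs CSF only vs dual).  Because a single split is noisy on a
~630-subject cohort, every harness entry point accepts a list of seeds
and reports one row per seed so means and standard errors can be formed.

Per-stage accuracies are computed in isolation, the way staging papers
tabulate them: stage 1 on the NC-vs-symptomatic contrast over the whole
validation fold, stage 2 on the MCI-vs-AD contrast over the CSF-complete
MCI/AD validation records.  The end-to-end cascade accuracy (3-class,
with ``symptomatic_unspecified`` counted as an abstention, never as
correct) is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .staging import (
    CascadeModel,
    ClassifierSpec,
    CLASSIFIER_KINDS,
    VOLUME_COLUMNS,
    build_stage2_features,
    cascade_predict,
    fit_fuzzifiers,
    make_classifier,
    train_hlm1,
    train_hlm2,
)

__all__ = [
    "SplitSpec",
    "split_cohort",
    "score",
    "evaluate_cascade",
    "run_model_bank",
    "run_ablation",
]


@dataclass
class SplitSpec:
    """Train/validation split: fraction in (0,1), optional stratification."""

    train_fraction: float = 0.7
    stratified: bool = True
    seed: int = 0

    def validate(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError(
                f"train_fraction must lie in (0, 1), got {self.train_fraction}"
            )


def split_cohort(
    cohort: pd.DataFrame, spec: SplitSpec | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded train/validation partition (disjoint and exhaustive).

    Train size is floor(fraction * n).  With ``stratified`` the per-label
    fractions are preserved to within one subject per class.
    """
    from sklearn.model_selection import train_test_split

    spec = spec or SplitSpec()
    spec.validate()
    if len(cohort) == 0:
        raise ValueError("cannot split an empty cohort")
    n_train = int(np.floor(spec.train_fraction * len(cohort)))
    if n_train == 0 or n_train == len(cohort):
        raise ValueError(
            f"fraction {spec.train_fraction} leaves an empty fold for n={len(cohort)}"
        )
    stratify = cohort["label"] if spec.stratified else None
    if stratify is not None and stratify.value_counts().min() < 2:
        raise ValueError("stratified split impossible: a class has fewer than 2 members")
    train, val = train_test_split(
        cohort,
        train_size=n_train,
        random_state=spec.seed,
        shuffle=True,
        stratify=stratify,
    )
    return train.reset_index(drop=True), val.reset_index(drop=True)


def score(predicted, truth, ids=None) -> dict:
    """Accuracy and confusion counts for aligned label vectors.

    Abstentions (``symptomatic_unspecified``) are never counted correct;
    ``coverage`` reports the decided fraction.  When ``ids`` pairs are
    given they must match position-wise.
    """
    predicted = np.asarray(predicted, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if predicted.shape != truth.shape:
        raise ValueError(f"length mismatch: {predicted.shape} vs {truth.shape}")
    if ids is not None:
        pid, tid = (np.asarray(i, dtype=object) for i in ids)
        if not np.array_equal(pid, tid):
            raise ValueError("prediction/truth subject ids are not aligned")
    n = len(truth)
    if n == 0:
        raise ValueError("empty label vectors")
    abstained = predicted == "symptomatic_unspecified"
    correct = int(((predicted == truth) & ~abstained).sum())
    labels = sorted(set(truth) | set(predicted))
    confusion = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for t, p in zip(truth, predicted):
        confusion.loc[t, p] += 1
    return {
        "n": n,
        "accuracy": correct / n,
        "n_correct": correct,
        "n_abstained": int(abstained.sum()),
        "coverage": float((~abstained).sum() / n),
        "confusion": confusion,
    }


def _stage1_truth(labels: pd.Series) -> np.ndarray:
    return np.where(labels == "NC", "NC", "symptomatic")


def evaluate_cascade(model: CascadeModel, validation: pd.DataFrame) -> dict:
    """Stage-wise and end-to-end validation accuracy of a fitted cascade.

    * ``stage1_accuracy``: NC vs symptomatic over the full fold.
    * ``stage2_accuracy``: MCI vs AD over CSF-complete MCI/AD records,
      fed directly to the stage-2 classifier (the isolated contrast).
    * ``cascade_accuracy``: 3-class through the full gate, abstentions
      never correct.
    """
    preds = cascade_predict(model, validation)
    s1 = score(preds["stage1_label"], _stage1_truth(validation["label"]))
    cascade = score(
        preds["final_label"],
        validation["label"].to_numpy(object),
        ids=(preds["subject_id"], validation["subject_id"]),
    )
    mask = validation["label"].isin(["MCI", "AD"]) & validation[
        ["abeta_pg_ml", "t_tau_pg_ml", "p_tau_pg_ml"]
    ].notna().all(axis=1)
    stage2_rows = validation.loc[mask]
    if len(stage2_rows):
        X = build_stage2_features(
            stage2_rows, model.fuzzifiers, model.ratio_tag, model.feature_mode
        ).to_numpy()
        pred2 = np.where(model.stage2.predict(X) == 1, "AD", "MCI")
        s2 = score(pred2, stage2_rows["label"].to_numpy(object))
    else:
        s2 = {"n": 0, "accuracy": float("nan"), "confusion": None}
    return {
        "stage1_accuracy": s1["accuracy"],
        "stage2_accuracy": s2["accuracy"],
        "cascade_accuracy": cascade["accuracy"],
        "cascade_coverage": cascade["coverage"],
        "stage1": s1,
        "stage2": s2,
        "cascade": cascade,
    }


def _train_eval(cohort, variant, stage1_spec, stage2_spec, split_seed, train_fraction):
    train, val = split_cohort(
        cohort, SplitSpec(train_fraction=train_fraction, seed=split_seed)
    )
    if variant == "hlm1":
        model = train_hlm1(train, stage1_spec, stage2_spec)
    elif variant == "hlm2":
        model = train_hlm2(train, stage2_spec)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return model, evaluate_cascade(model, val)


def run_model_bank(
    cohort: pd.DataFrame,
    variant: str = "hlm1",
    kinds=CLASSIFIER_KINDS,
    seeds=(0,),
    train_fraction: float = 0.7,
) -> pd.DataFrame:
    """Per-classifier comparison table.

    For HLM1 each bank entry is used at both stages, yielding a stage-1
    and a stage-2 accuracy row per (kind, seed).  For HLM2 stage 1 is
    always fuzzy clustering (one row per seed, kind ``fcm``) and the
    bank varies the stage-2 classifier.
    """
    rows = []
    for kind in kinds:
        if kind not in CLASSIFIER_KINDS:
            raise KeyError(f"unregistered classifier kind {kind!r}")
    for seed in seeds:
        if variant == "hlm2":
            first = True
            for kind in kinds:
                spec = ClassifierSpec(kind, seed=seed)
                _, res = _train_eval(cohort, "hlm2", None, spec, seed, train_fraction)
                if first:
                    rows.append(
                        dict(variant=variant, stage=1, kind="fcm", seed=seed,
                             feature_set="volume", accuracy=res["stage1_accuracy"],
                             n=res["stage1"]["n"])
                    )
                    first = False
                rows.append(
                    dict(variant=variant, stage=2, kind=kind, seed=seed,
                         feature_set="dual", accuracy=res["stage2_accuracy"],
                         n=res["stage2"]["n"])
                )
        else:
            for kind in kinds:
                spec = ClassifierSpec(kind, seed=seed)
                _, res = _train_eval(cohort, "hlm1", spec, spec, seed, train_fraction)
                rows.append(
                    dict(variant=variant, stage=1, kind=kind, seed=seed,
                         feature_set="volume", accuracy=res["stage1_accuracy"],
                         n=res["stage1"]["n"])
                )
                rows.append(
                    dict(variant=variant, stage=2, kind=kind, seed=seed,
                         feature_set="dual", accuracy=res["stage2_accuracy"],
                         n=res["stage2"]["n"])
                )
    table = pd.DataFrame(rows)
    return table.sort_values(["variant", "stage", "kind", "seed"]).reset_index(drop=True)


_ABLATION_SETS = ("volume_only", "csf_only", "dual")
_ABLATION_CONTRASTS = ("nc_vs_symptomatic", "mci_vs_ad")


def _ablation_features(rows, feature_set, fuzzifiers, ratio_tag):
    if feature_set == "volume_only":
        return rows[list(VOLUME_COLUMNS)].to_numpy(dtype=float)
    mode = "memberships_only" if feature_set == "csf_only" else "dual"
    return build_stage2_features(rows, fuzzifiers, ratio_tag, mode).to_numpy()


def run_ablation(
    cohort: pd.DataFrame,
    seeds=(0,),
    train_fraction: float = 0.7,
    ratio_tag: str = "ptau_over_abeta",
    m: float = 2.0,
) -> pd.DataFrame:
    """Biomarker ablation with Extra-Trees throughout.

    Three feature sets (volume only, fuzzified CSF only, dual) by two
    contrasts (NC vs symptomatic; MCI vs AD) by seed.  To keep the three
    feature sets comparable, all contrasts are evaluated on the
    CSF-complete subjects; fuzzifiers are fitted on each contrast's
    training fold only.
    """
    csf_ok = cohort[["abeta_pg_ml", "t_tau_pg_ml", "p_tau_pg_ml"]].notna().all(axis=1)
    base = cohort.loc[csf_ok].reset_index(drop=True)
    if base.empty:
        raise ValueError("ablation requires CSF-complete records")
    rows = []
    for seed in seeds:
        train, val = split_cohort(base, SplitSpec(train_fraction=train_fraction, seed=seed))
        for contrast in _ABLATION_CONTRASTS:
            if contrast == "mci_vs_ad":
                tr = train[train["label"].isin(["MCI", "AD"])]
                va = val[val["label"].isin(["MCI", "AD"])]
                y_tr = (tr["label"] == "AD").astype(int).to_numpy()
                y_va = (va["label"] == "AD").astype(int).to_numpy()
            else:
                tr, va = train, val
                y_tr = (tr["label"] != "NC").astype(int).to_numpy()
                y_va = (va["label"] != "NC").astype(int).to_numpy()
            fuzzifiers = fit_fuzzifiers(tr, m=m, ratio_tag=ratio_tag)
            for feature_set in _ABLATION_SETS:
                X_tr = _ablation_features(tr, feature_set, fuzzifiers, ratio_tag)
                X_va = _ablation_features(va, feature_set, fuzzifiers, ratio_tag)
                clf = make_classifier(ClassifierSpec("extra_tree", seed=seed))
                clf.fit(X_tr, y_tr)
                acc = float((clf.predict(X_va) == y_va).mean())
                rows.append(
                    dict(feature_set=feature_set, contrast=contrast, seed=seed,
                         accuracy=acc, n=len(y_va))
                )
    return pd.DataFrame(rows)
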