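"""The two-stage staging cascade (hybrid learning models HLM1 and HLM2).

Both variants share the same structure:

* **Stage 1 — NC vs symptomatic.**  Decided from the hippocampal volume
  triple (left, right, total, mm^3).  HLM1 uses a supervised classifier
  from a 13-model bank; HLM2 uses unsupervised 2-cluster fuzzy c-means
  with the low-volume cluster mapped to the symptomatic pole.
* **Stage 2 — MCI vs AD.**  Only subjects deemed symptomatic at stage 1
  reach stage 2, which classifies them from the volume triple plus four
  fuzzified CSF features: the AD-like memberships of amyloid-beta 42,
  total tau, phosphorylated tau and the CSF ratio (p-tau / abeta by
  default), each fuzzified by its own 2-cluster fuzzy c-means model
  fitted on the stage-2 training subjects only.

Subjects without a CSF panel cannot be staged beyond "symptomatic" and
are emitted as ``symptomatic_unspecified``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CSF_COLUMNS
from .fuzzy import (
    AD_LIKE,
    HIGHER_IS_AD_LIKE,
    LOWER_IS_AD_LIKE,
    FCMModel,
    assign_crisp,
    fcm_fit,
    fcm_memberships,
    label_clusters,
)

__all__ = [
    "ClassifierSpec",
    "CascadeModel",
    "CLASSIFIER_KINDS",
    "make_classifier",
    "compute_csf_ratio",
    "fit_fuzzifiers",
    "build_stage2_features",
    "train_hlm1",
    "train_hlm2",
    "cascade_predict",
    "save_cascade",
    "load_cascade",
    "VOLUME_COLUMNS",
    "STAGE2_FEATURES",
    "RATIO_TAGS",
]

logger = logging.getLogger(__name__)

VOLUME_COLUMNS = ("vol_left_mm3", "vol_right_mm3", "vol_total_mm3")
MEMBERSHIP_FEATURES = ("mu_abeta", "mu_ttau", "mu_ptau", "mu_ratio")
STAGE2_FEATURES = VOLUME_COLUMNS + MEMBERSHIP_FEATURES

#: CSF ratio definitions, keyed by the tag recorded in the model bundle
RATIO_TAGS = {
    "ptau_over_abeta": ("p_tau_pg_ml", "abeta_pg_ml"),
    "ttau_over_abeta": ("t_tau_pg_ml", "abeta_pg_ml"),
}

#: fuzzifier feature -> (cohort column or "ratio", biological direction)
FUZZIFIER_FEATURES = {
    "abeta": ("abeta_pg_ml", LOWER_IS_AD_LIKE),
    "t_tau": ("t_tau_pg_ml", HIGHER_IS_AD_LIKE),
    "p_tau": ("p_tau_pg_ml", HIGHER_IS_AD_LIKE),
    "ratio": ("ratio", HIGHER_IS_AD_LIKE),
}


# ---------------------------------------------------------------------------
# classifier bank


@dataclass
class ClassifierSpec:
    """A named entry of the 13-model classifier bank."""

    kind: str = "extra_tree"
    seed: int = 0
    params: dict = field(default_factory=dict)


def _make_scaled(est):
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    return make_pipeline(StandardScaler(), est)


def _build(kind: str, seed: int, params: dict):
    from sklearn.ensemble import (
        AdaBoostClassifier,
        ExtraTreesClassifier,
        GradientBoostingClassifier,
        RandomForestClassifier,
        VotingClassifier,
    )
    from sklearn.linear_model import LogisticRegression
    from sklearn.naive_bayes import GaussianNB
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.neural_network import MLPClassifier
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier

    if kind == "svc":
        return _make_scaled(SVC(probability=True, random_state=seed, **params))
    if kind == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **params)
    if kind == "random_forest":
        return RandomForestClassifier(random_state=seed, **params)
    if kind == "xgb":
        from xgboost import XGBClassifier

        return XGBClassifier(
            random_state=seed, eval_metric="logloss", verbosity=0, **params
        )
    if kind == "lgbm":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(random_state=seed, verbose=-1, **params)
    if kind == "extra_tree":
        return ExtraTreesClassifier(random_state=seed, **params)
    if kind == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed, **params)
    if kind == "ada_boost":
        return AdaBoostClassifier(random_state=seed, **params)
    if kind == "k_neighbors":
        return _make_scaled(KNeighborsClassifier(**params))
    if kind == "mlp":
        return _make_scaled(MLPClassifier(random_state=seed, max_iter=1000, **params))
    if kind == "gaussian_nb":
        return GaussianNB(**params)
    if kind == "logistic":
        return _make_scaled(LogisticRegression(max_iter=1000, random_state=seed, **params))
    if kind == "voting_soft":
        return VotingClassifier(
            estimators=[
                ("logistic", _make_scaled(LogisticRegression(max_iter=1000, random_state=seed))),
                ("random_forest", RandomForestClassifier(random_state=seed)),
                ("extra_tree", ExtraTreesClassifier(random_state=seed)),
                ("gaussian_nb", GaussianNB()),
            ],
            voting="soft",
            **params,
        )
    raise KeyError(f"unregistered classifier kind {kind!r}")


CLASSIFIER_KINDS = (
    "svc",
    "decision_tree",
    "random_forest",
    "xgb",
    "lgbm",
    "extra_tree",
    "gradient_boosting",
    "ada_boost",
    "k_neighbors",
    "mlp",
    "gaussian_nb",
    "logistic",
    "voting_soft",
)


def make_classifier(spec: ClassifierSpec):
    """Instantiate a classifier from the bank; distance/margin-based kinds
    are wrapped with feature standardization (volumes are in mm^3)."""
    if spec.kind not in CLASSIFIER_KINDS:
        raise KeyError(
            f"unregistered classifier kind {spec.kind!r}; known: {CLASSIFIER_KINDS}"
        )
    return _build(spec.kind, spec.seed, dict(spec.params))


# ---------------------------------------------------------------------------
# CSF fuzzification


def compute_csf_ratio(panel: pd.DataFrame | pd.Series, tag: str = "ptau_over_abeta"):
    """Composite CSF ratio (default p-tau / abeta; higher is AD-like).

    Accepts a cohort DataFrame (returns a Series, NaN where the panel is
    incomplete) or a single record Series (returns a float).
    """
    if tag not in RATIO_TAGS:
        raise KeyError(f"unknown ratio tag {tag!r}; known: {sorted(RATIO_TAGS)}")
    num_col, den_col = RATIO_TAGS[tag]
    num = panel[num_col]
    den = panel[den_col]
    if np.ndim(num) == 0:
        if pd.isna(num) or pd.isna(den):
            return float("nan")
        if den <= 0:
            raise ValueError(f"ratio denominator {den_col} must be > 0, got {den}")
        return float(num) / float(den)
    den = den.where(den > 0)
    return num / den


def _csf_complete(df: pd.DataFrame) -> pd.Series:
    return df[list(CSF_COLUMNS)].notna().all(axis=1)


def fit_fuzzifiers(
    train: pd.DataFrame,
    m: float = 2.0,
    mode: str = "univariate",
    ratio_tag: str = "ptau_over_abeta",
) -> dict[str, FCMModel]:
    """Fit 2-cluster FCM fuzzifiers on CSF-complete training records.

    Univariate mode (default) fits one 1-D model per feature (abeta,
    t_tau, p_tau, ratio), each labeled with its biological AD-like pole.
    Multivariate mode fits a single joint model on the standardized
    4-feature panel (stored under key ``"joint"``; its pole is taken
    from the abeta axis, which falls with disease).
    """
    if mode not in ("univariate", "multivariate"):
        raise ValueError(f"mode must be univariate or multivariate, got {mode!r}")
    rows = train.loc[_csf_complete(train)].copy()
    if len(rows) < 2:
        raise ValueError("need at least 2 CSF-complete training records")
    rows["ratio"] = compute_csf_ratio(rows, ratio_tag)
    values = {
        name: rows[col if col != "ratio" else "ratio"].to_numpy(dtype=float)
        for name, (col, _) in FUZZIFIER_FEATURES.items()
    }
    for name, x in values.items():
        if np.ptp(x) == 0:
            raise ValueError(f"CSF feature {name!r} is constant in the training data")

    if mode == "univariate":
        fuzzifiers = {}
        for name, (_, direction) in FUZZIFIER_FEATURES.items():
            model = fcm_fit(values[name], c=2, m=m)
            label_clusters(model, direction)
            fuzzifiers[name] = model
        return fuzzifiers

    X = np.column_stack([values[name] for name in FUZZIFIER_FEATURES])
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    model = fcm_fit((X - mu) / sd, c=2, m=m)
    # pole from the standardized abeta axis: the lower-abeta center is AD-like
    abeta_axis = list(FUZZIFIER_FEATURES).index("abeta")
    if model.centers[0, abeta_axis] == model.centers[1, abeta_axis]:
        raise ValueError("degenerate joint fuzzifier: equal abeta centers")
    ad = int(model.centers[:, abeta_axis].argmin())
    model.pole_map = {ad: AD_LIKE, 1 - ad: "NC_like"}
    model.direction = "joint"
    model.scaler_mean_ = mu  # type: ignore[attr-defined]
    model.scaler_sd_ = sd  # type: ignore[attr-defined]
    return {"joint": model}


def _ad_membership(model: FCMModel, x: np.ndarray) -> np.ndarray:
    U = fcm_memberships(x.reshape(-1, model.centers.shape[1]), model.centers, model.m)
    return U[:, model.ad_like_index]


def build_stage2_features(
    records: pd.DataFrame,
    fuzzifiers: dict[str, FCMModel],
    ratio_tag: str = "ptau_over_abeta",
    feature_mode: str = "dual",
) -> pd.DataFrame:
    """Stage-2 feature table: volume triple + AD-like CSF memberships.

    ``feature_mode`` "dual" (default) keeps the raw volumes alongside the
    memberships; "memberships_only" drops the volumes (ablation mode).
    Requires CSF-complete records; raises otherwise.
    """
    if feature_mode not in ("dual", "memberships_only"):
        raise ValueError(f"unknown feature_mode {feature_mode!r}")
    if not _csf_complete(records).all():
        missing = records.loc[~_csf_complete(records), "subject_id"].tolist()
        raise ValueError(f"records missing CSF panels: {missing[:5]} ...")
    rows = records.copy()
    rows["ratio"] = compute_csf_ratio(rows, ratio_tag)
    out = pd.DataFrame(index=rows.index)
    for col in VOLUME_COLUMNS:
        out[col] = rows[col].to_numpy(dtype=float)
    if "joint" in fuzzifiers:
        model = fuzzifiers["joint"]
        X = np.column_stack(
            [
                rows[col if col != "ratio" else "ratio"].to_numpy(dtype=float)
                for _, (col, _) in FUZZIFIER_FEATURES.items()
            ]
        )
        X = (X - model.scaler_mean_) / model.scaler_sd_  # type: ignore[attr-defined]
        mu_joint = _ad_membership(model, X)
        for feat in MEMBERSHIP_FEATURES:
            out[feat] = mu_joint
    else:
        for (name, (col, _)), feat in zip(FUZZIFIER_FEATURES.items(), MEMBERSHIP_FEATURES):
            x = rows[col if col != "ratio" else "ratio"].to_numpy(dtype=float)
            out[feat] = _ad_membership(fuzzifiers[name], x)
    if feature_mode == "memberships_only":
        out = out[list(MEMBERSHIP_FEATURES)]
    return out


# ---------------------------------------------------------------------------
# cascade


@dataclass
class CascadeModel:
    """A fitted two-stage staging model (HLM1 or HLM2)."""

    variant: str  # "hlm1" | "hlm2"
    stage1: object  # fitted classifier (hlm1) or FCMModel on volumes (hlm2)
    stage2: object  # fitted classifier
    fuzzifiers: dict[str, FCMModel]
    ratio_tag: str = "ptau_over_abeta"
    fuzz_mode: str = "univariate"
    feature_mode: str = "dual"
    stage1_spec: ClassifierSpec | None = None
    stage2_spec: ClassifierSpec | None = None
    m: float = 2.0


def _check_two_classes(y: np.ndarray, stage: str):
    if len(np.unique(y)) < 2:
        raise ValueError(f"{stage} training set contains a single class")


def _stage2_training_rows(cohort: pd.DataFrame) -> pd.DataFrame:
    rows = cohort[cohort["label"].isin(["MCI", "AD"])]
    complete = rows.loc[_csf_complete(rows)]
    dropped = len(rows) - len(complete)
    if dropped:
        logger.info("stage 2: excluded %d MCI/AD records without CSF", dropped)
    return complete


def _fit_stage2(cohort, spec, m, fuzz_mode, ratio_tag, feature_mode):
    rows = _stage2_training_rows(cohort)
    y = (rows["label"] == "AD").astype(int).to_numpy()
    _check_two_classes(y, "stage 2")
    fuzzifiers = fit_fuzzifiers(rows, m=m, mode=fuzz_mode, ratio_tag=ratio_tag)
    X = build_stage2_features(rows, fuzzifiers, ratio_tag, feature_mode).to_numpy()
    clf = make_classifier(spec)
    clf.fit(X, y)
    return clf, fuzzifiers


def train_hlm1(
    cohort: pd.DataFrame,
    stage1_spec: ClassifierSpec | None = None,
    stage2_spec: ClassifierSpec | None = None,
    m: float = 2.0,
    fuzz_mode: str = "univariate",
    ratio_tag: str = "ptau_over_abeta",
    feature_mode: str = "dual",
) -> CascadeModel:
    """Train HLM1: supervised stage 1 (volumes), supervised stage 2.

    Stage 1 is trained on the volume triple with target NC vs
    symptomatic (MCI or AD); stage 2 on the fuzzified features of the
    CSF-complete MCI/AD records, with the fuzzifiers fitted on those
    same training records only (no leakage from validation data).
    """
    stage1_spec = stage1_spec or ClassifierSpec("extra_tree")
    stage2_spec = stage2_spec or ClassifierSpec("extra_tree")
    X1 = cohort[list(VOLUME_COLUMNS)].to_numpy(dtype=float)
    y1 = (cohort["label"] != "NC").astype(int).to_numpy()
    _check_two_classes(y1, "stage 1")
    clf1 = make_classifier(stage1_spec)
    clf1.fit(X1, y1)
    clf2, fuzzifiers = _fit_stage2(cohort, stage2_spec, m, fuzz_mode, ratio_tag, feature_mode)
    return CascadeModel(
        variant="hlm1",
        stage1=clf1,
        stage2=clf2,
        fuzzifiers=fuzzifiers,
        ratio_tag=ratio_tag,
        fuzz_mode=fuzz_mode,
        feature_mode=feature_mode,
        stage1_spec=stage1_spec,
        stage2_spec=stage2_spec,
        m=m,
    )


def train_hlm2(
    cohort: pd.DataFrame,
    stage2_spec: ClassifierSpec | None = None,
    m: float = 2.0,
    fuzz_mode: str = "univariate",
    ratio_tag: str = "ptau_over_abeta",
    feature_mode: str = "dual",
    stage1_mode: str = "triple",
) -> CascadeModel:
    """Train HLM2: unsupervised fuzzy-clustering stage 1, supervised stage 2.

    Stage 1 fits 2-cluster FCM on the volume triple (or on total volume
    only with ``stage1_mode="total"``); the lower-volume cluster is the
    symptomatic (AD-like) pole.  Diagnosis labels are never used to fit
    stage 1.  Stage 2 defaults to Extra-Trees on the fuzzified features.
    """
    stage2_spec = stage2_spec or ClassifierSpec("extra_tree")
    if stage1_mode == "triple":
        cols = list(VOLUME_COLUMNS)
    elif stage1_mode == "total":
        cols = ["vol_total_mm3"]
    else:
        raise ValueError(f"stage1_mode must be 'triple' or 'total', got {stage1_mode!r}")
    X1 = cohort[cols].to_numpy(dtype=float)
    fcm = fcm_fit(X1, c=2, m=m)
    label_clusters(fcm, LOWER_IS_AD_LIKE)
    fcm.feature_columns_ = cols  # type: ignore[attr-defined]
    clf2, fuzzifiers = _fit_stage2(cohort, stage2_spec, m, fuzz_mode, ratio_tag, feature_mode)
    return CascadeModel(
        variant="hlm2",
        stage1=fcm,
        stage2=clf2,
        fuzzifiers=fuzzifiers,
        ratio_tag=ratio_tag,
        fuzz_mode=fuzz_mode,
        feature_mode=feature_mode,
        stage2_spec=stage2_spec,
        m=m,
    )


def _stage1_scores(model: CascadeModel, records: pd.DataFrame) -> np.ndarray:
    """P(symptomatic) per record."""
    if model.variant == "hlm2":
        fcm: FCMModel = model.stage1  # type: ignore[assignment]
        cols = getattr(fcm, "feature_columns_", list(VOLUME_COLUMNS))
        X = records[cols].to_numpy(dtype=float)
        return _ad_membership(fcm, X)
    X = records[list(VOLUME_COLUMNS)].to_numpy(dtype=float)
    clf = model.stage1
    proba = clf.predict_proba(X)
    pos = list(clf.classes_).index(1)
    return proba[:, pos]


def cascade_predict(model: CascadeModel, records: pd.DataFrame) -> pd.DataFrame:
    """Run the fitted cascade over a cohort table.

    Returns one row per record with ``stage1_label`` (NC / symptomatic),
    ``final_label`` (NC / MCI / AD / symptomatic_unspecified) and the
    stage scores: ``stage1_score`` = P(symptomatic), ``stage2_score`` =
    P(AD) (NaN for records that never reach stage 2).  Stage 2 is only
    evaluated for records deemed symptomatic at stage 1; symptomatic
    records without a CSF panel are emitted as
    ``symptomatic_unspecified``.
    """
    if model.stage2 is None or model.stage1 is None:
        raise ValueError("cascade model is not fitted")
    records = records.reset_index(drop=True)
    s1 = _stage1_scores(model, records)
    if model.variant == "hlm2":
        fcm: FCMModel = model.stage1  # type: ignore[assignment]
        cols = getattr(fcm, "feature_columns_", list(VOLUME_COLUMNS))
        X1 = records[cols].to_numpy(dtype=float)
        U = fcm_memberships(X1, fcm.centers, fcm.m)
        crisp = np.array([assign_crisp(u) for u in U])
        symptomatic = crisp == fcm.ad_like_index
    else:
        X1 = records[list(VOLUME_COLUMNS)].to_numpy(dtype=float)
        symptomatic = model.stage1.predict(X1).astype(bool)

    final = np.where(symptomatic, "symptomatic_unspecified", "NC").astype(object)
    s2 = np.full(len(records), np.nan)
    has_csf = _csf_complete(records).to_numpy()
    reach = symptomatic & has_csf
    n_unspecified = int((symptomatic & ~has_csf).sum())
    if n_unspecified:
        logger.info(
            "cascade_predict: %d symptomatic records lack CSF -> symptomatic_unspecified",
            n_unspecified,
        )
    if reach.any():
        feats = build_stage2_features(
            records.loc[reach], model.fuzzifiers, model.ratio_tag, model.feature_mode
        ).to_numpy()
        pred = model.stage2.predict(feats)
        proba = model.stage2.predict_proba(feats)
        pos = list(model.stage2.classes_).index(1)
        final[reach] = np.where(pred == 1, "AD", "MCI")
        s2[reach] = proba[:, pos]
    return pd.DataFrame(
        {
            "subject_id": records["subject_id"],
            "stage1_label": np.where(symptomatic, "symptomatic", "NC"),
            "final_label": final,
            "stage1_score": s1,
            "stage2_score": s2,
        }
    )


# ---------------------------------------------------------------------------
# serialization


def save_cascade(model: CascadeModel, path: str | Path) -> None:
    """Serialize a cascade to a directory: JSON manifest + joblib artifacts."""
    import joblib

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format": "hippostage-cascade",
        "variant": model.variant,
        "ratio_tag": model.ratio_tag,
        "fuzz_mode": model.fuzz_mode,
        "feature_mode": model.feature_mode,
        "m": model.m,
        "stage1_spec": None
        if model.stage1_spec is None
        else {"kind": model.stage1_spec.kind, "seed": model.stage1_spec.seed,
              "params": model.stage1_spec.params},
        "stage2_spec": None
        if model.stage2_spec is None
        else {"kind": model.stage2_spec.kind, "seed": model.stage2_spec.seed,
              "params": model.stage2_spec.params},
        "fuzzifiers": {k: v.to_dict() for k, v in model.fuzzifiers.items()},
    }
    if model.variant == "hlm2":
        fcm: FCMModel = model.stage1  # type: ignore[assignment]
        manifest["stage1_fcm"] = fcm.to_dict()
        manifest["stage1_fcm"]["feature_columns"] = getattr(
            fcm, "feature_columns_", list(VOLUME_COLUMNS)
        )
    else:
        joblib.dump(model.stage1, path / "stage1.joblib")
    for name, fz in model.fuzzifiers.items():
        if hasattr(fz, "scaler_mean_"):
            manifest["fuzzifiers"][name]["scaler_mean"] = fz.scaler_mean_.tolist()
            manifest["fuzzifiers"][name]["scaler_sd"] = fz.scaler_sd_.tolist()
    joblib.dump(model.stage2, path / "stage2.joblib")
    (path / "model.json").write_text(json.dumps(manifest, indent=2))


def load_cascade(path: str | Path) -> CascadeModel:
    import joblib

    path = Path(path)
    manifest = json.loads((path / "model.json").read_text())
    if manifest.get("format") != "hippostage-cascade":
        raise ValueError(f"{path} is not a hippostage cascade bundle")
    fuzzifiers = {}
    for name, d in manifest["fuzzifiers"].items():
        fz = FCMModel.from_dict(d)
        if "scaler_mean" in d:
            fz.scaler_mean_ = np.asarray(d["scaler_mean"])  # type: ignore[attr-defined]
            fz.scaler_sd_ = np.asarray(d["scaler_sd"])  # type: ignore[attr-defined]
        fuzzifiers[name] = fz
    if manifest["variant"] == "hlm2":
        fcm = FCMModel.from_dict(manifest["stage1_fcm"])
        fcm.feature_columns_ = manifest["stage1_fcm"]["feature_columns"]  # type: ignore[attr-defined]
        stage1 = fcm
    else:
        stage1 = joblib.load(path / "stage1.joblib")
    stage2 = joblib.load(path / "stage2.joblib")

    def _spec(d):
        return None if d is None else ClassifierSpec(d["kind"], d["seed"], d["params"])

    return CascadeModel(
        variant=manifest["variant"],
        stage1=stage1,
        stage2=stage2,
        fuzzifiers=fuzzifiers,
        ratio_tag=manifest["ratio_tag"],
        fuzz_mode=manifest["fuzz_mode"],
        feature_mode=manifest["feature_mode"],
        stage1_spec=_spec(manifest["stage1_spec"]),
        stage2_spec=_spec(manifest["stage2_spec"]),
        m=manifest["m"],
    )
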