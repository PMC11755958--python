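"""Staging cascade: fuzzification, HLM1/HLM2 training, gated prediction."""

import numpy as np
import pandas as pd
import pytest

from hippostage.cohort import CohortSpec, generate_cohort
from hippostage.fuzzy import fcm_membership
from hippostage.staging import (
    CLASSIFIER_KINDS,
    ClassifierSpec,
    build_stage2_features,
    cascade_predict,
    compute_csf_ratio,
    fit_fuzzifiers,
    load_cascade,
    make_classifier,
    save_cascade,
    train_hlm1,
    train_hlm2,
)


class TestCsfRatio:
    def test_default_definition(self):
        rec = pd.Series({"p_tau_pg_ml": 30.0, "abeta_pg_ml": 600.0, "t_tau_pg_ml": 300.0})
        assert compute_csf_ratio(rec) == pytest.approx(0.05)

    def test_equal_numerator_denominator(self):
        rec = pd.Series({"p_tau_pg_ml": 600.0, "abeta_pg_ml": 600.0, "t_tau_pg_ml": 1.0})
        assert compute_csf_ratio(rec) == pytest.approx(1.0)

    def test_alternative_definition(self):
        rec = pd.Series({"p_tau_pg_ml": 30.0, "abeta_pg_ml": 600.0, "t_tau_pg_ml": 300.0})
        assert compute_csf_ratio(rec, "ttau_over_abeta") == pytest.approx(0.5)

    def test_missing_component_propagates_nan(self):
        rec = pd.Series({"p_tau_pg_ml": np.nan, "abeta_pg_ml": 600.0, "t_tau_pg_ml": 1.0})
        assert np.isnan(compute_csf_ratio(rec))

    def test_unknown_tag_rejected(self):
        with pytest.raises(KeyError, match="unknown ratio tag"):
            compute_csf_ratio(pd.Series(dtype=float), "nonsense")


class TestFuzzifiers:
    @pytest.fixture
    def bimodal_train(self):
        r = np.random.default_rng(0)
        n = 100
        return pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(2 * n)],
                "label": ["MCI"] * n + ["AD"] * n,
                "vol_left_mm3": 3000.0,
                "vol_right_mm3": 2900.0,
                "vol_total_mm3": 5900.0,
                "abeta_pg_ml": np.concatenate(
                    [r.normal(1100, 10, n), r.normal(600, 10, n)]
                ),
                "t_tau_pg_ml": np.concatenate(
                    [r.normal(240, 5, n), r.normal(400, 5, n)]
                ),
                "p_tau_pg_ml": np.concatenate(
                    [r.normal(22, 0.5, n), r.normal(38, 0.5, n)]
                ),
            }
        )

    def test_recovers_separated_centers_and_pole(self, bimodal_train):
        fz = fit_fuzzifiers(bimodal_train)
        centers = np.sort(fz["abeta"].centers.ravel())
        assert abs(centers[0] - 600) < 15 and abs(centers[1] - 1100) < 15
        ad_center = fz["abeta"].centers[fz["abeta"].ad_like_index, 0]
        assert ad_center == centers[0]  # lower abeta is AD-like
        ad_ttau = fz["t_tau"].centers[fz["t_tau"].ad_like_index, 0]
        assert ad_ttau == np.sort(fz["t_tau"].centers.ravel())[1]  # higher tau is AD-like

    def test_membership_limits_at_centers(self, bimodal_train):
        fz = fit_fuzzifiers(bimodal_train)
        model = fz["abeta"]
        ad_center = model.centers[model.ad_like_index, 0]
        rec = bimodal_train.iloc[[0]].copy()
        rec["abeta_pg_ml"] = ad_center
        feats = build_stage2_features(rec, fz)
        assert feats["mu_abeta"].iloc[0] == pytest.approx(1.0)
        rec["abeta_pg_ml"] = model.centers.mean()
        feats = build_stage2_features(rec, fz)
        assert feats["mu_abeta"].iloc[0] == pytest.approx(0.5)

    def test_features_match_direct_membership(self, bimodal_train):
        fz = fit_fuzzifiers(bimodal_train)
        feats = build_stage2_features(bimodal_train, fz)
        for col, feat in [("abeta_pg_ml", "mu_abeta"), ("t_tau_pg_ml", "mu_ttau")]:
            name = {"abeta_pg_ml": "abeta", "t_tau_pg_ml": "t_tau"}[col]
            model = fz[name]
            for i in [0, 50, 150]:
                u = fcm_membership(
                    bimodal_train[col].iloc[i], model.centers, model.m
                )[model.ad_like_index]
                assert feats[feat].iloc[i] == pytest.approx(u)

    def test_constant_feature_rejected(self, bimodal_train):
        bimodal_train["p_tau_pg_ml"] = 30.0
        with pytest.raises(ValueError, match="p_tau"):
            fit_fuzzifiers(bimodal_train)

    def test_multivariate_mode(self, bimodal_train):
        fz = fit_fuzzifiers(bimodal_train, mode="multivariate")
        assert set(fz) == {"joint"}
        feats = build_stage2_features(bimodal_train, fz)
        # joint membership separates the two halves
        assert feats["mu_abeta"][:100].mean() < 0.2
        assert feats["mu_abeta"][100:].mean() > 0.8

    def test_memberships_bounded(self, default_cohort):
        rows = default_cohort.dropna(subset=["abeta_pg_ml"])
        rows = rows[rows["label"].isin(["MCI", "AD"])]
        fz = fit_fuzzifiers(rows)
        feats = build_stage2_features(rows, fz)
        mu = feats[["mu_abeta", "mu_ttau", "mu_ptau", "mu_ratio"]]
        assert (mu.to_numpy() >= 0).all() and (mu.to_numpy() <= 1).all()


class TestClassifierBank:
    def test_all_13_kinds_registered_and_buildable(self):
        assert len(CLASSIFIER_KINDS) == 13
        for kind in CLASSIFIER_KINDS:
            est = make_classifier(ClassifierSpec(kind, seed=0))
            assert hasattr(est, "fit")

    def test_unregistered_kind_rejected(self):
        with pytest.raises(KeyError, match="unregistered"):
            make_classifier(ClassifierSpec("perceptron9000"))


class TestCascade:
    def test_hlm1_beats_majority_on_train(self, default_cohort):
        model = train_hlm1(default_cohort)
        preds = cascade_predict(model, default_cohort)
        truth = np.where(default_cohort["label"] == "NC", "NC", "symptomatic")
        acc = (preds["stage1_label"] == truth).mean()
        majority = max((truth == "NC").mean(), (truth == "symptomatic").mean())
        assert acc >= majority

    def test_stage2_training_excludes_nc(self, default_cohort, monkeypatch):
        seen = {}
        from hippostage import staging

        orig = staging.fit_fuzzifiers

        def spy(train, **kw):
            seen["labels"] = set(train["label"])
            return orig(train, **kw)

        monkeypatch.setattr(staging, "fit_fuzzifiers", spy)
        staging.train_hlm1(default_cohort)
        assert seen["labels"] == {"MCI", "AD"}

    def test_separable_cohort_perfect_validation(self, separable_cohort):
        from hippostage.evaluation import SplitSpec, evaluate_cascade, split_cohort

        train, val = split_cohort(separable_cohort, SplitSpec(seed=0))
        for model in (train_hlm1(train), train_hlm2(train)):
            res = evaluate_cascade(model, val)
            assert res["stage1_accuracy"] == 1.0
            assert res["stage2_accuracy"] == 1.0

    def test_hlm2_stage1_unsupervised_matches_truth_on_separable(self, separable_cohort):
        model = train_hlm2(separable_cohort)
        preds = cascade_predict(model, separable_cohort)
        truth = np.where(separable_cohort["label"] == "NC", "NC", "symptomatic")
        assert (preds["stage1_label"] == truth).mean() >= 0.95
        # the AD-like pole is the lower-volume cluster
        fcm = model.stage1
        ad_center = fcm.centers[fcm.ad_like_index]
        nc_center = fcm.centers[1 - fcm.ad_like_index]
        assert ad_center.mean() < nc_center.mean()

    def test_gating_invariant_random_cohorts(self):
        for seed in range(8):
            cohort = generate_cohort(CohortSpec(n_nc=40, n_mci=40, n_ad=40, seed=seed))
            model = train_hlm1(cohort) if seed % 2 else train_hlm2(cohort)
            preds = cascade_predict(model, cohort)
            stage2_labels = preds["final_label"].isin(
                ["MCI", "AD", "symptomatic_unspecified"]
            )
            assert (preds.loc[stage2_labels, "stage1_label"] == "symptomatic").all()
            assert (preds.loc[preds["final_label"] == "NC", "stage1_label"] == "NC").all()

    def test_missing_csf_becomes_symptomatic_unspecified(self, separable_cohort):
        model = train_hlm1(separable_cohort)
        probe = separable_cohort[separable_cohort["label"] == "AD"].head(5).copy()
        probe[["abeta_pg_ml", "t_tau_pg_ml", "p_tau_pg_ml"]] = np.nan
        preds = cascade_predict(model, probe)
        assert (preds["final_label"] == "symptomatic_unspecified").all()
        assert preds["stage2_score"].isna().all()

    def test_nc_prediction_has_no_stage2_score(self, separable_cohort):
        model = train_hlm1(separable_cohort)
        probe = separable_cohort[separable_cohort["label"] == "NC"].head(5)
        preds = cascade_predict(model, probe)
        assert (preds["final_label"] == "NC").all()
        assert preds["stage2_score"].isna().all()

    def test_determinism(self, default_cohort):
        a = cascade_predict(train_hlm1(default_cohort), default_cohort)
        b = cascade_predict(train_hlm1(default_cohort), default_cohort)
        pd.testing.assert_frame_equal(a, b)

    def test_fuzzifier_leakage_guard(self, default_cohort):
        """Fuzzifiers fitted on the training fold differ from fuzzifiers
        refitted on train+validation: the guard is observable."""
        from hippostage.evaluation import SplitSpec, split_cohort

        train, _ = split_cohort(default_cohort, SplitSpec(seed=1))
        model = train_hlm1(train)
        rows_all = default_cohort[default_cohort["label"].isin(["MCI", "AD"])]
        rows_all = rows_all[
            rows_all[["abeta_pg_ml", "t_tau_pg_ml", "p_tau_pg_ml"]].notna().all(axis=1)
        ]
        refit = fit_fuzzifiers(rows_all)
        assert not np.allclose(
            model.fuzzifiers["abeta"].centers, refit["abeta"].centers
        )

    def test_single_class_cohort_rejected(self, separable_cohort):
        nc_only = separable_cohort[separable_cohort["label"] == "NC"]
        with pytest.raises(ValueError, match="single class"):
            train_hlm1(nc_only)

    def test_serialization_round_trip(self, tmp_path, separable_cohort):
        for trainer in (train_hlm1, train_hlm2):
            model = trainer(separable_cohort)
            out = tmp_path / model.variant
            save_cascade(model, out)
            back = load_cascade(out)
            a = cascade_predict(model, separable_cohort)
            b = cascade_predict(back, separable_cohort)
            pd.testing.assert_frame_equal(a, b)

    def test_hlm2_total_only_mode(self, separable_cohort):
        model = train_hlm2(separable_cohort, stage1_mode="total")
        assert model.stage1.centers.shape == (2, 1)
        preds = cascade_predict(model, separable_cohort)
        truth = np.where(separable_cohort["label"] == "NC", "NC", "symptomatic")
        assert (preds["stage1_label"] == truth).mean() >= 0.95
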