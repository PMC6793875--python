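"""Classifier machinery: PCA retention, RFE-CBR, LOSO leakage, reporting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from affectlab import classify, fusion, pipeline, synthetic
from affectlab.classify import EvaluationReport
from conftest import small_pipeline_config, small_study_config


class TestMakeGrid:
    def test_endpoints_and_count(self):
        g = classify.make_grid()
        assert len(g) == 15
        assert g[0] == pytest.approx(0.1)
        assert g[-1] == pytest.approx(1000.0)

    def test_eighth_value_is_ten(self):
        assert classify.make_grid()[7] == pytest.approx(10.0)


class TestBlockPCA:
    def test_two_identical_features_one_component(self, rng):
        x = rng.standard_normal((100, 1))
        model = classify.fit_block_pca(np.hstack([x, x]), ["a", "b"])
        assert model.n_components == 1
        assert model.explained[0] == pytest.approx(1.0)

    def test_isotropic_block_needs_all_components(self, rng):
        x = rng.standard_normal((500, 5))
        model = classify.fit_block_pca(x, list("abcde"))
        assert model.n_components == 5

    def test_retained_count_matches_eigenvalue_oracle(self, rng):
        for _ in range(10):
            n, p = 80, rng.integers(3, 12)
            scales = rng.uniform(0.1, 5.0, p)
            x = rng.standard_normal((n, p)) * scales
            model = classify.fit_block_pca(x, [f"f{i}" for i in range(p)])
            ev = np.linalg.eigvalsh(np.cov(x, rowvar=False))[::-1]
            oracle = int(np.searchsorted(np.cumsum(ev) / ev.sum(), 0.95) + 1)
            assert model.n_components == oracle

    def test_constant_block_dropped(self):
        assert classify.fit_block_pca(np.ones((50, 3)), list("abc")) is None


class TestSvmRfeCbr:
    def test_informative_component_ranked_first(self):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            y = np.repeat([0, 1], 100)
            r.shuffle(y)
            x = r.standard_normal((200, 10))
            x[:, 3] = (y * 2 - 1) + 0.5 * r.standard_normal(200)
            ranks = classify.svm_rfe_cbr(x, y, c=1.0, gamma=0.1)
            hits += ranks[3] == 1
        assert hits >= 18

    def test_two_components_rank_permutation(self, rng):
        y = np.repeat([0, 1], 30)
        x = rng.standard_normal((60, 2))
        ranks = classify.svm_rfe_cbr(x, y)
        assert sorted(ranks) == [1, 2]

    def test_cbr_keeps_duplicated_informative_features_longer(self):
        """Correlated copies survive longer under CBR than plain RFE."""
        cbr_wins, plain_wins = 0, 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            y = np.repeat([0, 1], 60)
            r.shuffle(y)
            x = r.standard_normal((120, 8))
            signal = (y * 2 - 1) + 0.4 * r.standard_normal(120)
            x[:, 0] = signal
            x[:, 1] = signal + 0.05 * r.standard_normal(120)  # near-duplicate
            ranks_cbr = classify.svm_rfe_cbr(x, y, c=1.0, gamma=0.1,
                                             corr_threshold=0.85)
            ranks_plain = classify.svm_rfe_cbr(x, y, c=1.0, gamma=0.1,
                                               corr_threshold=1.1)  # no groups
            cbr_wins += max(ranks_cbr[0], ranks_cbr[1]) <= 4
            plain_wins += max(ranks_plain[0], ranks_plain[1]) <= 4
        assert cbr_wins >= plain_wins


class TestBalanceAndReport:
    def test_printed_confusion_rows_verdicts(self):
        balanced = {"true_high": 75.58, "false_high": 24.41,
                    "false_low": 34.48, "true_low": 65.5}
        unbalanced = {"true_high": 88.07, "false_high": 11.92,
                      "false_low": 44.18, "true_low": 55.81}
        assert classify.is_balanced(balanced)
        assert not classify.is_balanced(unbalanced)

    def _report(self, case, acc, conf, balanced):
        return EvaluationReport(
            case=case, target="arousal", accuracy=acc, f_score=0.7,
            confusion=conf, balanced=balanced, cost=1.0, gamma=0.1,
            selected_per_block={"HRV": (1, 2), "MPC": (3, 4)},
            predictions=pd.DataFrame())

    def test_delta_accuracy_against_case1(self):
        conf = {"true_high": 70.0, "false_high": 30.0,
                "false_low": 30.0, "true_low": 70.0}
        table = classify.report([
            self._report(1, 68.05, conf, True),
            self._report(2, 71.52, conf, True),
        ])
        assert table.loc[table["case"] == 2, "delta_accuracy"].iloc[0] == "+3.47%"
        assert table.loc[table["case"] == 1, "delta_accuracy"].iloc[0] == ""

    def test_unbalanced_rendered_as_flag(self):
        conf = {"true_high": 88.07, "false_high": 11.92,
                "false_low": 44.18, "true_low": 55.81}
        table = classify.report([self._report(1, 75.0, conf, False)])
        assert table["accuracy"].iloc[0] == "(TN<60)"
        assert table["features_total"].iloc[0] == "4/6"


@pytest.fixture(scope="module")
def arousal_ds(records_small):
    return fusion.build_case(records_small, 1, "arousal", "real")


class TestLosoEvaluate:
    def test_pooled_metrics_recomputable_from_predictions(self, arousal_ds):
        rep = classify.loso_evaluate(arousal_ds, grid=np.array([1.0, 10.0]),
                                     feature_selection=False)
        y = rep.predictions
        acc = 100.0 * (y["y_true"] == y["y_pred"]).mean()
        assert rep.accuracy == pytest.approx(acc, abs=1e-9)
        tp = ((y.y_true == "high") & (y.y_pred == "high")).sum()
        fp = ((y.y_true == "low") & (y.y_pred == "high")).sum()
        fn = ((y.y_true == "high") & (y.y_pred == "low")).sum()
        assert rep.f_score == pytest.approx(2 * tp / (2 * tp + fp + fn),
                                            abs=1e-9)

    def test_confusion_rows_sum_to_100(self, arousal_ds):
        rep = classify.loso_evaluate(arousal_ds, grid=np.array([1.0]),
                                     feature_selection=False)
        c = rep.confusion
        assert c["true_high"] + c["false_high"] == pytest.approx(100.0, abs=0.1)
        assert c["false_low"] + c["true_low"] == pytest.approx(100.0, abs=0.1)

    def test_no_leakage_from_validation_rows(self, records_small):
        """Perturbing a held-out subject's rows must not move its fold's fit."""
        ds = fusion.build_case(records_small, 1, "arousal", "real")
        folds = classify.prepare_folds(ds)
        subject = folds[0].fold_subject
        perturbed = ds.df.copy()
        mask = perturbed["subject_id"] == subject
        feat_cols = fusion.feature_columns()
        perturbed.loc[mask, feat_cols] = (
            perturbed.loc[mask, feat_cols].to_numpy() * 3.0 + 7.0)
        folds2 = classify.prepare_folds(
            fusion.CaseDataset(1, "arousal", perturbed))
        fm1 = next(f for f in folds if f.fold_subject == subject)
        fm2 = next(f for f in folds2 if f.fold_subject == subject)
        pd.testing.assert_series_equal(fm1.medians, fm2.medians)
        pd.testing.assert_series_equal(fm1.mads, fm2.mads)
        np.testing.assert_array_equal(fm1.z_train, fm2.z_train)
        for block in fm1.pcas:
            np.testing.assert_array_equal(fm1.pcas[block].components,
                                          fm2.pcas[block].components)

    def test_perfectly_separable_dataset_is_perfect_and_balanced(self, rng):
        rows = []
        for s in range(6):
            for i in range(8):
                label_high = i % 2 == 0
                feats = {c: np.nan for c in fusion.feature_columns()}
                for c in fusion.BLOCKS["BAND"]:
                    feats[c] = (3.0 if label_high else -3.0) \
                        + 0.01 * rng.standard_normal()
                for c in fusion.BLOCKS["MPC"]:
                    feats[c] = 0.5
                rows.append({"subject_id": f"s{s}", "stage": "museum",
                             "condition": "real", "stimulus_id": f"st{i}",
                             "arousal": 2.0 if label_high else -2.0,
                             "valence": 0.0, **feats})
        records = pd.DataFrame(rows)
        ds = fusion.build_case(records, 1, "arousal", "real")
        rep = classify.loso_evaluate(ds, grid=np.array([0.1, 1.0, 10.0]),
                                     feature_selection=False)
        assert rep.accuracy == 100.0
        assert rep.balanced

    def test_single_class_training_fold_skipped(self, rng):
        rows = []
        for s in range(4):
            for i in range(4):
                feats = {c: rng.standard_normal()
                         for c in fusion.feature_columns()}
                # subject s0 alone carries low labels
                arousal = -2.0 if s == 0 else 2.0
                rows.append({"subject_id": f"s{s}", "stage": "museum",
                             "condition": "real", "stimulus_id": f"st{i}",
                             "arousal": arousal, "valence": 0.0, **feats})
        ds = fusion.build_case(pd.DataFrame(rows), 1, "arousal", "real")
        folds = classify.prepare_folds(ds)
        assert all(f.fold_subject != "s0" for f in folds)
        assert len(folds) == 3


def _arousal_accuracy(n, effects, seed, grid):
    cfg = small_study_config(n)
    study = synthetic.generate_study(n, effects, seed=seed, config=cfg)
    records = pipeline.extract_features(study, small_pipeline_config(n))
    ds = fusion.build_case(records, 1, "arousal", "real")
    return classify.loso_evaluate(ds, grid=grid,
                                  feature_selection=False).accuracy


class TestEndToEndProperties:
    """Dose-response, augmentation and null behaviour of the whole chain.

    Scaled down relative to a full study (few seeds, short museum windows,
    coarse grids) to keep the suite fast; directions and margins were chosen
    from the generator's stated effect sizes, not fitted to runs.
    """

    def test_accuracy_increases_with_effect_size(self):
        grid = classify.make_grid(5)
        scales = (0.0, 0.15, 0.3, 0.6)
        means = []
        for scale in scales:
            accs = [_arousal_accuracy(5, synthetic.EffectModel().scaled(scale),
                                      seed, grid) for seed in (0, 1, 2)]
            means.append(np.mean(accs))
        rho = stats.spearmanr(scales, means).statistic
        assert rho > 0.8

    def test_case2_augmentation_helps_or_matches(self):
        """Congruent calibration-stage effects: median case-2 accuracy >= case 1."""
        grid = classify.make_grid(5)
        scfg = synthetic.StudyConfig(
            n_subjects_per_phase=4, fs=128.0, stages=("iaps", "museum"),
            n_iaps_blocks=6, iaps_block_duration=10.0, museum_duration=24.0)
        pcfg = small_pipeline_config(4, stages=("iaps", "museum"))
        acc1, acc2 = [], []
        for seed in (0, 1, 2):
            study = synthetic.generate_study(
                4, synthetic.EffectModel().scaled(0.12), seed=seed, config=scfg)
            records = pipeline.extract_features(study, pcfg)
            acc1.append(classify.loso_evaluate(
                fusion.build_case(records, 1, "arousal", "real"),
                grid=grid, feature_selection=False).accuracy)
            acc2.append(classify.loso_evaluate(
                fusion.build_case(records, 2, "arousal", "real"),
                grid=grid, feature_selection=False).accuracy)
        assert np.median(acc2) >= np.median(acc1)

    def test_zero_effect_model_is_at_chance(self):
        """Null world: single fixed hyperparameter, binomial 95% band of 0.5."""
        acc = _arousal_accuracy(6, synthetic.EffectModel.zero(), seed=5,
                                grid=np.array([1.0]))
        n = 48  # 6 museum subjects x 8 stimuli
        half_width = 100 * 1.96 * np.sqrt(0.25 / n)
        assert abs(acc - 50.0) <= half_width
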