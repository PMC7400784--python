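import numpy as np
import pandas as pd
import pytest

from pseudomut import (
    EnsembleModel,
    ExpressionMatrix,
    classification_error,
    mean_roc,
    model_from_json,
    train_subclassifier,
)
from pseudomut.ensemble import ErrorCurve, SubClassifier, _LinearRule, select_model


def _em(values, probes=None, samples=None):
    values = np.asarray(values, dtype=float)
    probes = probes or [f"P{i:03d}" for i in range(values.shape[0])]
    samples = samples or [f"S{i:03d}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=probes, columns=samples))


def _constant_voter(vote: int, probes=("P000",)) -> SubClassifier:
    """A stub subclassifier that always votes ``vote`` on any sample."""
    sign = 1.0 if vote == 1 else -1.0
    return SubClassifier(
        iteration=0,
        probes=list(probes),
        ml_method="linsvm",
        estimator=_LinearRule(np.zeros(len(probes)), sign),
        mean=np.zeros(len(probes)),
        std=np.ones(len(probes)),
    )


class TestClassificationError:
    def test_printed_confusion_counts_give_013(self):
        """224 wt with 14 false positives plus 51 mut with 22 false
        negatives: (14+22)/275 = 0.13 at two decimals."""
        truth = np.array([0] * 224 + [1] * 51)
        pred = np.concatenate([
            np.r_[np.ones(14), np.zeros(210)],       # 14 FP among wt
            np.r_[np.zeros(22), np.ones(29)],        # 22 FN among mut
        ]).astype(int)
        err, table = classification_error(pred, truth)
        assert round(err, 2) == 0.13
        assert table == {"TP": 29, "TN": 210, "FP": 14, "FN": 22}

    def test_perfect_and_all_wrong(self):
        truth = np.array([0, 1, 0, 1])
        assert classification_error(truth, truth)[0] == 0.0
        assert classification_error(1 - truth, truth)[0] == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            classification_error([0, 1], [0, 1, 1])


class TestSubClassifier:
    def test_lda_boundary_at_midpoint_of_class_means(self):
        """One probe, two equal-variance, equal-size classes: the LDA
        decision boundary sits at the midpoint of the class means."""
        values = np.array([[-3.0, -2.0, -1.0, 1.0, 2.0, 3.0]])
        labels = np.array([0, 0, 0, 1, 1, 1])
        em = _em(values)
        sub = train_subclassifier(em, labels, ["P000"], "lda")
        # the midpoint (0.0 in raw units) is exactly on the boundary
        mid = pd.DataFrame([[0.0], [0.001], [-0.001]],
                           index=["M0", "M+", "M-"]).T
        mid.index = ["P000"]
        em_mid = ExpressionMatrix(mid)
        scores = sub.decision_score(em_mid, ["M0", "M+", "M-"])
        assert scores[0] == pytest.approx(0.0, abs=1e-9)
        assert scores[1] > 0 and scores[2] < 0

    def test_linear_svm_separable_training_error_zero(self, rng):
        labels = np.array([0] * 10 + [1] * 10)
        values = rng.normal(size=(3, 20))
        values[0] = np.where(labels == 1, 4.0, -4.0)
        em = _em(values)
        sub = train_subclassifier(em, labels, ["P000", "P001"], "linsvm")
        err, _ = classification_error(sub.predict(em, em.sample_ids), labels)
        assert err == 0.0

    def test_permuted_labels_yield_majority_class_prediction(self):
        """With labels shuffled free of the data, the uncompensated learner
        converges to the majority (wt) call, so held-out error approximates
        the minority prevalence."""
        errors = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 200
            labels = (rng.random(n) < 0.18).astype(int)
            values = rng.normal(size=(10, n))
            em = _em(values)
            train = [f"S{i:03d}" for i in range(150)]
            test = [f"S{i:03d}" for i in range(150, 200)]
            sub = train_subclassifier(em.subset_samples(train), labels[:150],
                                      em.probe_ids, "linsvm")
            err, _ = classification_error(sub.predict(em, test), labels[150:])
            errors.append(err)
        assert abs(np.mean(errors) - 0.18) < 0.08

    def test_missing_probe_rejected(self, rng):
        em = _em(rng.normal(size=(2, 8)))
        with pytest.raises(ValueError, match="absent"):
            train_subclassifier(em, np.array([0, 0, 0, 0, 1, 1, 1, 1]),
                                ["P000", "NOPE"], "linsvm")

    @pytest.mark.parametrize("ml", ["lda", "linsvm", "gsvm"])
    def test_serialization_preserves_decisions(self, ml, rng, tmp_path):
        labels = np.array([0] * 12 + [1] * 12)
        values = rng.normal(size=(4, 24))
        values[0] += 2.0 * labels
        em = _em(values)
        sub = train_subclassifier(em, labels, em.probe_ids, ml)
        model = EnsembleModel(combo=("corr", ml), k_star=4, subclassifiers=[sub])
        path = tmp_path / "model.json"
        model.to_json(path)
        restored = model_from_json(path)
        got = restored.subclassifiers[0].decision_score(em, em.sample_ids)
        want = sub.decision_score(em, em.sample_ids)
        np.testing.assert_allclose(got, want, rtol=1e-10, atol=1e-12)


class TestMajorityVote:
    def _votes_em(self):
        return _em(np.zeros((1, 3)), probes=["P000"])

    def test_unanimous_wt(self):
        model = EnsembleModel(("corr", "linsvm"), 1, [_constant_voter(0) for _ in range(100)])
        labels, frac = model.majority_vote_predict(self._votes_em())
        assert labels.tolist() == [0, 0, 0]
        assert frac.tolist() == [0.0, 0.0, 0.0]

    def test_strict_majority_calls_mut(self):
        voters = [_constant_voter(1) for _ in range(51)] + [_constant_voter(0) for _ in range(49)]
        model = EnsembleModel(("corr", "linsvm"), 1, voters)
        labels, frac = model.majority_vote_predict(self._votes_em())
        assert labels.tolist() == [1, 1, 1]
        assert frac[0] == pytest.approx(0.51)

    def test_exact_tie_is_conservative_wt(self):
        voters = [_constant_voter(1) for _ in range(50)] + [_constant_voter(0) for _ in range(50)]
        model = EnsembleModel(("corr", "linsvm"), 1, voters)
        labels, _ = model.majority_vote_predict(self._votes_em())
        assert labels.tolist() == [0, 0, 0]

    def test_voters_missing_probes_abstain(self):
        voters = [
            _constant_voter(1, probes=["P000"]),
            _constant_voter(0, probes=["MISSING"]),
        ]
        model = EnsembleModel(("corr", "linsvm"), 1, voters)
        labels, frac = model.majority_vote_predict(self._votes_em())
        # only the mut voter has full probe coverage -> unanimous mut
        assert labels.tolist() == [1, 1, 1]
        assert frac[0] == pytest.approx(1.0)

    def test_no_voter_with_coverage_is_an_error(self):
        model = EnsembleModel(("corr", "linsvm"), 1, [_constant_voter(1, probes=["MISSING"])])
        with pytest.raises(ValueError, match="no subclassifier"):
            model.majority_vote_predict(self._votes_em())


class TestSelectModel:
    def _curve(self, val_mean, val_sem=None, n_valid=None, n_iter=10):
        ks = list(range(1, len(val_mean) + 1))
        val_sem = val_sem or [0.01] * len(ks)
        n_valid = n_valid or [n_iter] * len(ks)
        return ErrorCurve(
            ks=ks, n_valid=n_valid,
            train_mean=list(val_mean), train_sem=list(val_sem),
            val_mean=list(val_mean), val_sem=list(val_sem),
            c_min=7,
        )

    def test_strict_minimum_with_full_validity(self):
        curve = self._curve([0.5, 0.4, 0.3, 0.2, 0.1, 0.3])
        combo, k_star = select_model({("corr", "linsvm"): curve})
        assert k_star == 5

    def test_one_se_rule_prefers_shorter_lists(self):
        # flat within SEM from k=2 on: smallest such k wins
        curve = self._curve([0.5, 0.105, 0.102, 0.1, 0.104], val_sem=[0.01] * 5)
        _, k_star = select_model({("corr", "linsvm"): curve})
        assert k_star == 2

    def test_dominating_combination_selected(self):
        good = self._curve([0.3, 0.2, 0.1])
        bad = self._curve([0.4, 0.35, 0.3])
        combo, _ = select_model({("corr", "linsvm"): bad, ("corr", "lda"): good})
        assert combo == ("corr", "lda")


class TestMeanROC:
    def test_perfect_separation_has_auc_one(self):
        labels = np.array([0] * 5 + [1] * 5)
        values = np.array([labels.astype(float)])
        em = _em(values)
        sub = SubClassifier(0, ["P000"], "linsvm", _LinearRule([1.0], -0.5),
                            np.zeros(1), np.ones(1))
        model = EnsembleModel(("corr", "linsvm"), 1, [sub])
        _, _, auc = mean_roc(model, em, labels)
        assert auc == pytest.approx(1.0)

    def test_uninformative_scores_near_half(self, rng):
        n, m = 500, 10
        labels = (rng.random(n) < 0.5).astype(int)
        values = rng.normal(size=(m, n))
        em = _em(values)
        subs = [
            SubClassifier(i, [f"P{i:03d}"], "linsvm", _LinearRule([1.0], 0.0),
                          np.zeros(1), np.ones(1))
            for i in range(m)
        ]
        model = EnsembleModel(("corr", "linsvm"), 1, subs)
        _, _, auc = mean_roc(model, em, labels)
        assert abs(auc - 0.5) < 0.05

    def test_single_class_truth_rejected(self, rng):
        em = _em(rng.normal(size=(1, 6)))
        sub = SubClassifier(0, ["P000"], "linsvm", _LinearRule([1.0], 0.0),
                            np.zeros(1), np.ones(1))
        model = EnsembleModel(("corr", "linsvm"), 1, [sub])
        with pytest.raises(ValueError, match="single class"):
            mean_roc(model, em, np.zeros(6, dtype=int))


class TestFittedPipeline:
    """Properties of the full fit on the shared synthetic cohort."""

    def test_training_error_not_above_validation_on_average(self, fitted):
        curve = fitted.error_curve
        assert np.mean(curve.train_mean) <= np.mean(curve.val_mean) + 1e-9

    def test_ensemble_not_worse_than_average_member(self, fitted):
        """Majority-vote test error stays within mean individual
        subclassifier error + 2 SEM (ensemble averaging)."""
        em, labels = fitted.em, fitted.labels
        test_ids = fitted.plan.test_ids
        truth = (labels.loc[test_ids] == "mut").to_numpy(dtype=int)
        errs = [
            classification_error(s.predict(em, test_ids), truth)[0]
            for s in fitted.ensemble.subclassifiers
        ]
        bound = np.mean(errs) + 2 * np.std(errs, ddof=1) / np.sqrt(len(errs))
        assert fitted.test_error <= bound + 1e-9

    def test_no_signal_data_declares_failure(self):
        """With delta=0 the FDR gate leaves too few valid subclassifiers
        and curve building reports failure in nearly every replicate."""
        from pseudomut import PipelineConfig, TP53ClassifierModel
        from pseudomut.simulate import SyntheticConfig, generate_dataset

        failures = 0
        for seed in range(5):
            data = generate_dataset(SyntheticConfig(
                n_wt=100, n_mut=30, n_pm=0, n_normal=0,
                n_probes=300, n_informative=10, delta=0.0,
                n_pathways=0, n_noise_pathways=0, seed=seed,
            ))
            model = TP53ClassifierModel(
                data.em, data.cohort,
                config=PipelineConfig(n_iter=5, c_min=4, k_max=5),
            )
            try:
                model.fit(seed=seed)
            except RuntimeError:
                failures += 1
        assert failures >= 4
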