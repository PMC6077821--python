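"""Aging removal, feature selection, LDS scorer, aggregation and CV pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.linear_model import LogisticRegression

from adsev.biomarker import (BiomarkerConfig, aggregate_train, auc,
                             choose_lambda_l1, fit_aging_model, lds_train,
                             remove_age_effect, run_cv_pipeline,
                             select_features_logreg)
from adsev.cohort_sim import CohortSpec, generate_cohort


class TestAgingModel:
    def test_noiseless_fit_is_exact(self):
        ages = np.linspace(60, 85, 100)
        feats = np.column_stack([5.0 - 0.02 * ages, np.full(100, 2.5)])
        model = fit_aging_model(feats, ages)
        assert model.slopes[0] == pytest.approx(-0.02, abs=1e-9)
        assert model.slopes[1] == pytest.approx(0.0, abs=1e-9)
        assert model.intercepts[1] == pytest.approx(2.5, abs=1e-9)

    def test_noisy_recovery_within_three_standard_errors(self):
        rng = np.random.default_rng(2)
        ages = rng.uniform(60, 85, 500)
        feats = (-0.02 * ages + rng.normal(0, 1, 500)).reshape(-1, 1)
        model = fit_aging_model(feats, ages)
        resid = feats.ravel() - (model.intercepts[0]
                                 + model.slopes[0] * ages)
        se = np.sqrt(resid.var(ddof=2) / ((ages - ages.mean()) ** 2).sum())
        assert abs(model.slopes[0] + 0.02) < 3 * se

    def test_residuals_orthogonal_to_age_on_fitting_controls(self):
        rng = np.random.default_rng(3)
        ages = rng.uniform(60, 85, 200)
        feats = rng.normal(0, 1, (200, 5)) - 0.03 * ages[:, None]
        model = fit_aging_model(feats, ages)
        resid = remove_age_effect(feats, ages, model)
        design = np.column_stack([np.ones_like(ages), ages])
        slopes = np.linalg.lstsq(design, resid, rcond=None)[0][1]
        assert np.abs(slopes).max() < 1e-8

    def test_generalizes_to_held_out_controls(self):
        rng = np.random.default_rng(4)
        def draw(n):
            ages = rng.uniform(60, 85, n)
            return ages, (rng.normal(0, 1, n) - 0.02 * ages).reshape(-1, 1)
        ages_fit, feats_fit = draw(400)
        ages_new, feats_new = draw(400)
        model = fit_aging_model(feats_fit, ages_fit)
        resid = remove_age_effect(feats_new, ages_new, model).ravel()
        r = np.corrcoef(ages_new, resid)[0, 1]
        assert abs(r) < 3 / np.sqrt(400)

    def test_rejects_zero_age_variance(self):
        with pytest.raises(ValueError):
            fit_aging_model(np.zeros((10, 2)), np.full(10, 70.0))

    def test_feature_count_mismatch_rejected(self):
        model = fit_aging_model(np.zeros((5, 2)), np.arange(5.0))
        with pytest.raises(ValueError):
            remove_age_effect(np.zeros((5, 3)), np.arange(5.0), model)


class TestFeatureSelection:
    def _adnc(self, seed=0):
        cohort = generate_cohort(CohortSpec(seed=seed))
        mask = cohort.group_mask("NC", "AD").to_numpy()
        X = cohort.features()[mask]
        y = (cohort.df["group"][mask] == "AD").to_numpy().astype(int)
        return X, y

    def test_huge_penalty_selects_nothing(self):
        X, y = self._adnc()
        assert select_features_logreg(X, y, 1e6).size == 0

    def test_zero_penalty_keeps_everything(self):
        X, y = self._adnc()
        assert select_features_logreg(X, y, 0.0).size == X.shape[1]

    def test_recovers_planted_informative_features(self):
        X, y = self._adnc(seed=1)
        lam = choose_lambda_l1(X, y, seed=0)
        selected = select_features_logreg(X, y, lam)
        recall = len(set(selected) & set(range(10))) / 10
        assert recall >= 0.8

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            select_features_logreg(np.zeros((5, 2)), np.ones(5), 1.0)


class TestLds:
    def test_reduces_to_ridge_logistic_without_unlabeled_term(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(80, 5))
        y = (X[:, 0] + rng.normal(0, 1, 80) > 0).astype(int)
        lam_w = 1.0
        scorer = lds_train(X, y, np.zeros((0, 5)), lambda_w=lam_w,
                           lambda_u=0.0, seed=0)
        ref = LogisticRegression(C=1.0 / (2 * lam_w), solver="lbfgs",
                                 tol=1e-12, max_iter=50000).fit(X, y)
        rel = (np.linalg.norm(scorer.weights - ref.coef_.ravel())
               / np.linalg.norm(ref.coef_))
        assert rel < 1e-4

    def test_scores_are_probabilities(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 3))
        y = (rng.random(40) < 0.5).astype(int)
        y[:2] = [0, 1]
        scorer = lds_train(X, y, rng.normal(size=(30, 3)), seed=0)
        s = scorer.score(rng.normal(size=(100, 3)) * 50)
        assert np.all((s >= 0) & (s <= 1))

    def test_entropy_term_helps_on_low_density_gap(self):
        """Few labels, two well-separated clusters: pushing the boundary out
        of the unlabeled density should not hurt, and usually helps."""
        def replicate(seed):
            rng = np.random.default_rng(seed)
            def draw(n):
                y = rng.integers(0, 2, n)
                X = rng.normal(0, 0.6, (n, 2))
                X[:, 0] += np.where(y == 1, 2.0, -2.0)
                return X, y
            Xl, yl = draw(6)
            while len(np.unique(yl)) < 2:
                Xl, yl = draw(6)
            Xu, _ = draw(200)
            Xt, yt = draw(200)
            accs = []
            for lu in (0.0, 1.0):
                m = lds_train(Xl, yl, Xu, lambda_w=0.01, lambda_u=lu,
                              seed=seed)
                accs.append((((m.score(Xt) > 0.5).astype(int)) == yt).mean())
            return accs
        results = [replicate(100 + i) for i in range(20)]
        wins = sum(1 for a0, a1 in results if a1 >= a0)
        assert wins >= 10

    def test_single_class_labeled_rejected(self):
        with pytest.raises(ValueError):
            lds_train(np.zeros((4, 2)), np.zeros(4), np.zeros((0, 2)))


class TestAggregateAndAuc:
    def test_perfect_separator_reaches_training_auc_one(self):
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1], 30)
        mri = y + rng.normal(0, 0.01, 60)
        rf = aggregate_train(mri, rng.uniform(60, 85, 60),
                             rng.normal(size=(60, 2)), y, seed=0)
        X = np.column_stack([mri, rng.uniform(60, 85, 60),
                             rng.normal(size=(60, 2))])
        assert auc(rf.predict_proba(X)[:, 1], y) == 1.0

    def test_auc_trivial_orderings(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
        assert auc([0.9, 0.8, 0.2, 0.1], [0, 0, 1, 1]) == 0.0
        assert auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_auc_matches_pair_enumeration(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        pairs = [(1.0 if p > q else 0.5 if p == q else 0.0)
                 for p in pos for q in neg]
        assert auc(scores, labels) == pytest.approx(np.mean(pairs), rel=1e-12)

    def test_auc_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(min_value=0, max_value=10 ** 6))
def test_auc_invariant_under_monotone_transform(seed):
    rng = np.random.default_rng(seed)
    scores = rng.normal(size=25)
    labels = rng.integers(0, 2, 25)
    labels[:2] = [0, 1]
    base = auc(scores, labels)
    assert auc(np.exp(scores), labels) == pytest.approx(base, rel=1e-12)
    assert auc(3 * scores - 7, labels) == pytest.approx(base, rel=1e-12)
    assert auc(-scores, labels) == pytest.approx(1 - base, rel=1e-12)


class TestCvPipeline:
    def test_oracle_feature_gives_pooled_auc_one(self):
        """If an MRI feature encodes the conversion label exactly, the
        pipeline must score perfectly."""
        cohort = generate_cohort(CohortSpec(
            n_per_group=(40, 40, 40, 40), seed=2))
        df = cohort.df.copy()
        stage = df["group"].map({"NC": 0.0, "sMCI": 0.0, "pMCI": 10.0,
                                 "AD": 10.0})
        df["f1"] = stage + 0.001 * np.arange(len(df))
        from adsev.cohort_sim import Cohort
        oracle = Cohort(df=df, spec=cohort.spec)
        res = run_cv_pipeline(oracle, n_folds=5, seed=0,
                              config=BiomarkerConfig(n_trees=100))
        assert res.pooled_auc_mri == 1.0

    def test_too_few_subjects_rejected_with_viable_fold_count(self):
        cohort = generate_cohort(CohortSpec(n_per_group=(20, 4, 4, 20),
                                            seed=0))
        with pytest.raises(ValueError, match="folds"):
            run_cv_pipeline(cohort, n_folds=10, seed=0)

    def test_deterministic_given_seed(self):
        cohort = generate_cohort(CohortSpec(n_per_group=(40, 40, 40, 40),
                                            seed=1))
        cfg = BiomarkerConfig(n_trees=50, lambda_l1=0.3)
        a = run_cv_pipeline(cohort, n_folds=5, seed=3, config=cfg)
        b = run_cv_pipeline(cohort, n_folds=5, seed=3, config=cfg)
        assert a.model_digests == b.model_digests
        assert a.pooled_auc_aggregate == b.pooled_auc_aggregate
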