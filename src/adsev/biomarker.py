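"""Four-stage MCI-to-AD conversion biomarker with 10-fold cross-validation.

Stages, all fitted strictly inside each training fold:

1. *Aging-effect removal* — per-feature OLS of feature on age over
   healthy controls only; every subject's features are residualized
   against that model, so normal-aging atrophy cannot masquerade as
   disease signal.
2. *Feature selection* — L1-penalized logistic regression on AD vs NC
   (never on MCI data); selected features are the nonzero coefficients,
   with the penalty chosen by internal stratified 5-fold CV.
3. *MRI scorer* — semi-supervised low-density separation: a logistic
   separator trained on labeled AD/NC plus an entropy penalty on the
   unlabeled MCI subjects that pushes the decision boundary away from
   regions where unlabeled data are dense.  The unlabeled weight is
   annealed from 0 to its target over several convex warm-started steps.
4. *Aggregate biomarker* — a random forest over the MRI score, age and
   baseline cognitive scores of the training-fold MCI subjects.

Evaluation is by the Mann-Whitney AUC over pooled out-of-fold scores of
the MCI subjects, folds stratified by conversion label.
"""

from __future__ import annotations

import hashlib
import pickle
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from adsev.cohort_sim import Cohort

__all__ = [
    "AgingModel", "LdsScorer", "BiomarkerConfig", "CvResult",
    "fit_aging_model", "remove_age_effect", "select_features_logreg",
    "choose_lambda_l1", "lds_train", "aggregate_train", "auc",
    "run_cv_pipeline", "leakage_audit",
]


# ---------------------------------------------------------------------------
# aging-effect removal


@dataclass(frozen=True)
class AgingModel:
    """Per-feature linear age trend fitted on healthy controls."""

    intercepts: np.ndarray  # (d,)
    slopes: np.ndarray  # (d,)

    @property
    def n_features(self) -> int:
        return self.intercepts.shape[0]


def fit_aging_model(features: np.ndarray, ages: np.ndarray) -> AgingModel:
    """OLS of each feature on age over controls: feature = a + b*age + e."""
    X = np.asarray(features, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if X.ndim != 2 or X.shape[0] != ages.shape[0]:
        raise ValueError("features must be (n, d) aligned with ages")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 control subjects")
    if np.var(ages) <= 0:
        raise ValueError("age variance must be positive")
    design = np.column_stack([np.ones_like(ages), ages])
    coefs, *_ = np.linalg.lstsq(design, X, rcond=None)
    return AgingModel(intercepts=coefs[0].copy(), slopes=coefs[1].copy())


def remove_age_effect(features: np.ndarray, ages: np.ndarray,
                      model: AgingModel) -> np.ndarray:
    """Residualize: feature_ij - (intercept_j + slope_j * age_i)."""
    X = np.asarray(features, dtype=float)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"model covers {model.n_features} features, got {X.shape[1]}")
    ages = np.asarray(ages, dtype=float)
    return X - (model.intercepts[None, :] + np.outer(ages, model.slopes))


# ---------------------------------------------------------------------------
# feature selection


def _standardize(X: np.ndarray, mean=None, std=None):
    if mean is None:
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        std = np.where(std > 0, std, 1.0)
    return (X - mean) / std, mean, std


def select_features_logreg(features: np.ndarray, labels: np.ndarray,
                           lambda_l1: float) -> np.ndarray:
    """L1-logistic feature selection on AD/NC; returns sorted nonzero indices.

    Features are standardized internally on the training statistics.
    ``lambda_l1 = 0`` fits the unpenalized model (all coefficients
    nonzero up to a 1e-12 threshold).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if lambda_l1 < 0:
        raise ValueError("lambda_l1 must be >= 0")
    Z, _, _ = _standardize(X)
    if lambda_l1 == 0:
        clf = LogisticRegression(C=np.inf, solver="lbfgs",
                                 max_iter=5000, tol=1e-10)
    else:
        clf = LogisticRegression(l1_ratio=1.0, C=1.0 / lambda_l1,
                                 solver="liblinear", max_iter=5000, tol=1e-10)
    clf.fit(Z, y)
    coefs = clf.coef_.ravel()
    return np.sort(np.nonzero(np.abs(coefs) > 1e-12)[0])


def choose_lambda_l1(features: np.ndarray, labels: np.ndarray,
                     grid: np.ndarray | None = None, n_folds: int = 5,
                     seed: int = 0) -> float:
    """Pick the L1 penalty by stratified CV AUC; ties go to the sparser fit."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if grid is None:
        grid = np.logspace(-2.0, 1.0, 7)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    mean_aucs = []
    for lam in grid:
        fold_aucs = []
        for train_idx, val_idx in skf.split(X, y):
            Z, mu, sd = _standardize(X[train_idx])
            clf = LogisticRegression(l1_ratio=1.0, C=1.0 / lam,
                                     solver="liblinear", max_iter=5000)
            clf.fit(Z, y[train_idx])
            Zval = (X[val_idx] - mu) / sd
            scores = clf.decision_function(Zval)
            if len(np.unique(y[val_idx])) < 2:
                continue
            fold_aucs.append(auc(scores, y[val_idx]))
        mean_aucs.append(np.mean(fold_aucs) if fold_aucs else 0.0)
    mean_aucs = np.asarray(mean_aucs)
    # ties (within 1e-12) resolved toward the largest penalty
    best = np.nonzero(mean_aucs >= mean_aucs.max() - 1e-12)[0][-1]
    return float(grid[best])


# ---------------------------------------------------------------------------
# low-density separation scorer


@dataclass
class LdsScorer:
    """Linear probabilistic scorer p(converter-like | x) = sigmoid(w.x + b)."""

    weights: np.ndarray
    bias: float
    lambda_w: float
    lambda_u: float
    anneal_steps: int
    converged: bool
    final_grad_norm: float
    seed: int

    def score(self, X: np.ndarray) -> np.ndarray:
        return expit(np.asarray(X, float) @ self.weights + self.bias)


def _lds_objective(theta: np.ndarray, Xl: np.ndarray, y: np.ndarray,
                   Xu: np.ndarray, lambda_w: float, lambda_u: float):
    w, b = theta[:-1], theta[-1]
    zl = Xl @ w + b
    # stable log(1 + exp(-s*z)) with s = +-1
    s = 2.0 * y - 1.0
    loss = np.logaddexp(0.0, -s * zl).sum()
    grad_z = expit(zl) - y
    grad_w = Xl.T @ grad_z + 2.0 * lambda_w * w
    grad_b = grad_z.sum()
    obj = loss + lambda_w * float(w @ w)
    if lambda_u > 0 and Xu.shape[0] > 0:
        zu = Xu @ w + b
        p = expit(zu)
        q = 1.0 - p
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = -(np.where(p > 0, p * np.log(p), 0.0)
                    + np.where(q > 0, q * np.log(q), 0.0))
        obj += lambda_u * ent.sum()
        # dH/dz = -z * p * (1 - p)
        gu = -zu * p * q
        grad_w += lambda_u * (Xu.T @ gu)
        grad_b += lambda_u * gu.sum()
    return obj, np.append(grad_w, grad_b)


def lds_train(X_labeled: np.ndarray, y_labeled: np.ndarray,
              X_unlabeled: np.ndarray, lambda_w: float = 1.0,
              lambda_u: float = 1.0, anneal_steps: int = 5, seed: int = 0,
              tol: float = 1e-10, max_iter: int = 2000) -> LdsScorer:
    """Entropy-regularized low-density separation.

    Minimizes sum_labeled logloss + lambda_w ||w||^2
    + lambda_u * sum_unlabeled H(p_w(x)), with the unlabeled weight
    annealed linearly 0 -> lambda_u over ``anneal_steps`` warm-started
    L-BFGS solves (each early step is close to convex, guiding the
    boundary into the low-density gap).  With lambda_u = 0 this is
    exactly ridge-penalized logistic regression.
    """
    Xl = np.asarray(X_labeled, dtype=float)
    y = np.asarray(y_labeled, dtype=float)
    Xu = np.asarray(X_unlabeled, dtype=float)
    if Xu.size == 0:
        Xu = np.zeros((0, Xl.shape[1]))
    if len(np.unique(y)) < 2:
        raise ValueError("labeled set must contain both classes")
    if lambda_w < 0 or lambda_u < 0:
        raise ValueError("penalties must be >= 0")

    rng = np.random.default_rng(seed)
    theta = np.append(rng.normal(0.0, 1e-3, size=Xl.shape[1]), 0.0)
    schedule = ([0.0] if lambda_u == 0 else
                list(lambda_u * np.arange(1, anneal_steps + 1) / anneal_steps))
    result = None
    for lu in schedule:
        result = minimize(
            _lds_objective, theta, args=(Xl, y, Xu, lambda_w, lu),
            method="L-BFGS-B", jac=True,
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-9},
        )
        theta = result.x
    grad_norm = float(np.linalg.norm(result.jac))
    return LdsScorer(
        weights=theta[:-1].copy(), bias=float(theta[-1]),
        lambda_w=lambda_w, lambda_u=lambda_u, anneal_steps=anneal_steps,
        converged=bool(result.success), final_grad_norm=grad_norm, seed=seed,
    )


# ---------------------------------------------------------------------------
# aggregate biomarker and AUC


def aggregate_train(mri_scores: np.ndarray, ages: np.ndarray,
                    cog_scores: np.ndarray, labels: np.ndarray,
                    n_trees: int = 500, max_depth: int | None = None,
                    seed: int = 0) -> RandomForestClassifier:
    """Random forest over [MRI score, age, cognitive scores] vs conversion."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both conversion labels must be present")
    X = np.column_stack([np.asarray(mri_scores, float),
                         np.asarray(ages, float),
                         np.asarray(cog_scores, float)])
    rf = RandomForestClassifier(
        n_estimators=n_trees, max_depth=max_depth, max_features="sqrt",
        random_state=seed, n_jobs=1,
    )
    rf.fit(X, y.astype(int))
    return rf


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# cross-validated pipeline


@dataclass(frozen=True)
class BiomarkerConfig:
    """Hyperparameters of the four-stage pipeline."""

    lambda_l1: float | None = None  # None -> internal 5-fold CV choice
    lambda_grid: tuple[float, ...] | None = None
    lambda_w: float = 1.0
    lambda_u: float = 1.0
    anneal_steps: int = 5
    n_trees: int = 500
    max_depth: int | None = None


@dataclass
class CvResult:
    """Cross-validated scores for the MRI-only and aggregate biomarkers."""

    n_folds: int
    seed: int
    fold_assignment: np.ndarray  # fold id per MCI subject (cohort order)
    mci_index: np.ndarray  # positional indices of MCI subjects in the cohort
    labels: np.ndarray
    mri_scores: np.ndarray  # pooled out-of-fold scores
    aggregate_scores: np.ndarray
    per_fold_auc_mri: list
    per_fold_auc_aggregate: list
    pooled_auc_mri: float
    pooled_auc_aggregate: float
    model_digests: list  # per-fold sha256 of all fitted model bytes
    diagnostics: dict = field(default_factory=dict)


def _digest_models(aging: AgingModel, selected: np.ndarray,
                   lds: LdsScorer, rf: RandomForestClassifier) -> str:
    h = hashlib.sha256()
    h.update(aging.intercepts.tobytes())
    h.update(aging.slopes.tobytes())
    h.update(np.asarray(selected).tobytes())
    h.update(lds.weights.tobytes())
    h.update(np.float64(lds.bias).tobytes())
    h.update(pickle.dumps(rf))
    return h.hexdigest()


@dataclass
class _PipelineData:
    """Cohort arrays plus the stages fitted on NC/AD only.

    The aging model, penalty choice, feature selection and
    standardization statistics involve no MCI subject at all, so they are
    identical in every training fold and are computed once.
    """

    mci_pos: np.ndarray
    labels: np.ndarray
    ages: np.ndarray
    cogs: np.ndarray
    residual: np.ndarray
    aging: AgingModel
    selected: np.ndarray
    Z_adnc: np.ndarray
    y_adnc: np.ndarray
    mu: np.ndarray
    sd: np.ndarray
    lambda_l1: float


def _prepare_pipeline(cohort: Cohort, config: BiomarkerConfig,
                      seed: int) -> _PipelineData:
    df = cohort.df
    mci_pos = np.nonzero(cohort.mci_mask.to_numpy())[0]
    labels = df.iloc[mci_pos]["converter"].to_numpy(dtype=float).astype(int)

    nc_mask = cohort.group_mask("NC").to_numpy()
    ad_mask = cohort.group_mask("AD").to_numpy()
    if nc_mask.sum() < 3 or ad_mask.sum() < 2:
        raise ValueError("cohort needs NC and AD subjects for training")

    all_features = cohort.features()
    all_ages = cohort.ages()
    cogs = df[cohort.cog_columns].to_numpy(float)

    aging = fit_aging_model(all_features[nc_mask], all_ages[nc_mask])
    residual = remove_age_effect(all_features, all_ages, aging)

    X_adnc = np.vstack([residual[nc_mask], residual[ad_mask]])
    y_adnc = np.concatenate([np.zeros(int(nc_mask.sum()), dtype=int),
                             np.ones(int(ad_mask.sum()), dtype=int)])
    lam = config.lambda_l1
    if lam is None:
        grid = (np.asarray(config.lambda_grid)
                if config.lambda_grid is not None else None)
        lam = choose_lambda_l1(X_adnc, y_adnc, grid=grid, seed=seed)
    selected = select_features_logreg(X_adnc, y_adnc, lam)
    if selected.size == 0:
        selected = np.arange(residual.shape[1])  # fall back to all features

    Z_adnc, mu, sd = _standardize(X_adnc[:, selected])
    return _PipelineData(
        mci_pos=mci_pos, labels=labels, ages=all_ages, cogs=cogs,
        residual=residual, aging=aging, selected=selected, Z_adnc=Z_adnc,
        y_adnc=y_adnc, mu=mu, sd=sd, lambda_l1=float(lam),
    )


def _fit_score_fold(data: _PipelineData, train_local: np.ndarray,
                    test_local: np.ndarray, train_labels: np.ndarray,
                    config: BiomarkerConfig, seed: int, fold: int):
    """Fit LDS and the aggregate forest on one training fold, score the test fold.

    ``train_labels`` are the conversion labels of the training-fold MCI
    subjects — held-out labels are not an argument and cannot be used.
    """
    train_pos = data.mci_pos[train_local]
    test_pos = data.mci_pos[test_local]
    Z_train = (data.residual[train_pos][:, data.selected] - data.mu) / data.sd
    Z_test = (data.residual[test_pos][:, data.selected] - data.mu) / data.sd

    lds = lds_train(data.Z_adnc, data.y_adnc, Z_train,
                    lambda_w=config.lambda_w, lambda_u=config.lambda_u,
                    anneal_steps=config.anneal_steps, seed=seed)
    mri_train = lds.score(Z_train)
    mri_test = lds.score(Z_test)

    rf = aggregate_train(mri_train, data.ages[train_pos],
                         data.cogs[train_pos], train_labels,
                         n_trees=config.n_trees, max_depth=config.max_depth,
                         seed=seed + fold)
    X_test_agg = np.column_stack([mri_test, data.ages[test_pos],
                                  data.cogs[test_pos]])
    agg_test = rf.predict_proba(X_test_agg)[:, 1]
    digest = _digest_models(data.aging, data.selected, lds, rf)
    return mri_test, agg_test, digest


def _stratified_assignment(labels: np.ndarray, n_folds: int,
                           seed: int) -> np.ndarray:
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignment = np.empty(labels.shape[0], dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros_like(labels),
                                                labels)):
        assignment[test_idx] = f
    return assignment


def run_cv_pipeline(cohort: Cohort, n_folds: int = 10, seed: int = 0,
                    config: BiomarkerConfig | None = None,
                    fold_assignment: np.ndarray | None = None) -> CvResult:
    """Stratified k-fold evaluation over the MCI subjects.

    NC and AD subjects are auxiliary training data in every fold (they
    are never scored); every fitting step — aging model, feature
    selection, LDS, aggregate forest, standardization — sees only NC, AD
    and training-fold MCI subjects.  Held-out MCI labels are used solely
    to compute the AUC after scoring.
    """
    config = config or BiomarkerConfig()
    data = _prepare_pipeline(cohort, config, seed)
    labels = data.labels
    n_conv, n_stable = int(labels.sum()), int((1 - labels).sum())
    if min(n_conv, n_stable) < n_folds:
        viable = max(min(n_conv, n_stable), 2)
        raise ValueError(
            f"too few MCI subjects per class for {n_folds} folds; "
            f"at most {viable} folds are viable")

    if fold_assignment is None:
        fold_assignment = _stratified_assignment(labels, n_folds, seed)
    else:
        fold_assignment = np.asarray(fold_assignment, dtype=int)
        if fold_assignment.shape[0] != data.mci_pos.shape[0]:
            raise ValueError("fold_assignment must cover every MCI subject")

    mri_oof = np.full(data.mci_pos.shape[0], np.nan)
    agg_oof = np.full(data.mci_pos.shape[0], np.nan)
    per_fold_mri, per_fold_agg, digests = [], [], []

    for f in range(n_folds):
        test_local = fold_assignment == f
        train_local = ~test_local
        mri_test, agg_test, digest = _fit_score_fold(
            data, train_local, test_local, labels[train_local],
            config, seed, f)
        mri_oof[test_local] = mri_test
        agg_oof[test_local] = agg_test
        digests.append(digest)
        test_labels = labels[test_local]
        if len(np.unique(test_labels)) == 2:
            per_fold_mri.append(auc(mri_test, test_labels))
            per_fold_agg.append(auc(agg_test, test_labels))

    return CvResult(
        n_folds=n_folds, seed=seed, fold_assignment=fold_assignment,
        mci_index=data.mci_pos, labels=labels, mri_scores=mri_oof,
        aggregate_scores=agg_oof, per_fold_auc_mri=per_fold_mri,
        per_fold_auc_aggregate=per_fold_agg,
        pooled_auc_mri=auc(mri_oof, labels),
        pooled_auc_aggregate=auc(agg_oof, labels),
        model_digests=digests,
        diagnostics={"selected_features": data.selected.tolist(),
                     "lambda_l1": data.lambda_l1,
                     "n_converters": n_conv, "n_stable": n_stable},
    )


def leakage_audit(cohort: Cohort, n_folds: int = 10, seed: int = 0,
                  config: BiomarkerConfig | None = None,
                  permute_seed: int = 12345) -> dict:
    """Verify that held-out labels cannot influence any fitted model.

    Runs the pipeline once, then for each fold permutes the conversion
    labels *of that held-out fold only* (fold assignment frozen, so
    training labels are untouched) and refits the fold; every per-fold
    model digest must be byte-identical to the baseline.
    """
    config = config or BiomarkerConfig()
    base = run_cv_pipeline(cohort, n_folds=n_folds, seed=seed, config=config)
    data = _prepare_pipeline(cohort, config, seed)
    rng = np.random.default_rng(permute_seed)
    permuted_digests = []
    for f in range(n_folds):
        test_local = base.fold_assignment == f
        train_local = ~test_local
        labels_perm = base.labels.copy()
        labels_perm[test_local] = rng.permutation(labels_perm[test_local])
        _, _, digest = _fit_score_fold(
            data, train_local, test_local, labels_perm[train_local],
            config, seed, f)
        permuted_digests.append(digest)
    identical = base.model_digests == permuted_digests
    return {"identical": identical,
            "base_digests": base.model_digests,
            "permuted_digests": permuted_digests,
            "base_result": base}
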