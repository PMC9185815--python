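"""Repeated cross-validated LASSO logistic-regression ensembles.

The training protocol: the cohort is split in a 10-times-repeated stratified
10-fold cross-validation.  Within each of the 100 training folds the log.clr
normalization is fitted on the training samples only; the enrichment-
constrained variant ("model-2") additionally restricts the feature set to
species whose single-feature AUROC on the training fold is >= 0.5 (disease-
enriched direction) — this is what prevents the classifier from keying on
generic depletion signatures shared across unrelated diseases.  The LASSO
cost is chosen per fold by inner 5-fold AUROC over a fixed log-spaced grid,
the model is fitted with the liblinear L1 solver, and held-out samples are
scored; each sample's cross-validated score is its mean test-fold
probability over the repeats.  A feature's *robustness* is the fraction of
the 100 fold models giving it a nonzero coefficient.

Nothing fitted inside a fold ever sees that fold's test samples — the
normalization parameters and the enrichment filter are functions of the
training partition alone (asserted by a tamper test in the suite).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .normalization import NormalizationParams, apply_frozen, fit_normalization
from .univariate import single_feature_auroc

__all__ = [
    "CVScheme",
    "FoldModel",
    "TrainedEnsemble",
    "RocCurve",
    "make_cv_scheme",
    "enrichment_filter",
    "fit_fold",
    "train_ensemble",
    "predict_ensemble",
    "roc_evaluate",
]

DEFAULT_LAMBDA_GRID = np.logspace(-2, 1, 10)


@dataclass(frozen=True)
class CVScheme:
    """Fold assignment per repeat: ``assignment[r, i]`` is sample i's test fold."""

    n_repeats: int
    n_folds: int
    assignment: np.ndarray  # (n_repeats, n_samples) int fold indices
    stratified: bool
    seed: int
    sample_ids: tuple[str, ...]


def make_cv_scheme(
    labels,
    n_repeats: int = 10,
    n_folds: int = 10,
    stratified: bool = True,
    seed: int = 0,
    sample_ids=None,
) -> CVScheme:
    """Fresh random (stratified) partition per repeat, deterministic given seed."""
    y = np.asarray(labels, dtype=bool)
    n = len(y)
    if sample_ids is None:
        sample_ids = tuple(str(i) for i in range(n))
    if stratified and min(y.sum(), (~y).sum()) < n_folds:
        raise ValueError(
            f"stratified {n_folds}-fold CV needs >= {n_folds} samples per class "
            f"(got {int(y.sum())} cases / {int((~y).sum())} controls)"
        )
    ss = np.random.SeedSequence([int(seed), 916_801])
    assignment = np.empty((n_repeats, n), dtype=np.int64)
    for r, child in enumerate(ss.spawn(n_repeats)):
        rs = int(child.generate_state(1)[0] % (2**31 - 1))
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rs)
        for k, (_, test_idx) in enumerate(splitter.split(np.zeros(n), y)):
            assignment[r, test_idx] = k
    return CVScheme(n_repeats, n_folds, assignment, stratified, int(seed), tuple(sample_ids))


def enrichment_filter(train_matrix: pd.DataFrame, train_labels) -> list[str]:
    """Features whose training single-feature AUROC is >= 0.5 (cases positive).

    Applied inside each training fold of the enrichment-constrained model; an
    empty result is legal and handled upstream as a degenerate fold.
    """
    y = np.asarray(train_labels, dtype=bool)
    mat = train_matrix.to_numpy(dtype=float)
    return [
        str(fid)
        for i, fid in enumerate(train_matrix.index)
        if single_feature_auroc(mat[i], y) >= 0.5
    ]


@dataclass
class FoldModel:
    """One fold's LASSO model plus everything fitted inside its training set."""

    coefficients: dict[str, float]  # nonzero coefficients only
    intercept: float
    cost: float
    norm_params: NormalizationParams
    enrichment_features: list[str] | None  # None for the unconstrained variant
    degenerate: bool = False  # empty enrichment set -> constant 0.5 predictor

    def predict(self, normalized: pd.DataFrame) -> np.ndarray:
        """Probabilities from the stored sparse coefficients on an already
        frozen-normalized matrix (rows = this model's feature universe)."""
        if self.degenerate:
            return np.full(normalized.shape[1], 0.5)
        score = np.full(normalized.shape[1], self.intercept)
        for fid, w in self.coefficients.items():
            score += w * normalized.loc[fid].to_numpy()
        return 1.0 / (1.0 + np.exp(-score))


@dataclass
class TrainedEnsemble:
    variant: str
    fold_models: list[FoldModel]
    norm_params: NormalizationParams  # transfer normalization, fit on full training set
    robustness: pd.Series             # feature -> fraction of fold models using it
    cv_scores: pd.Series              # sample -> mean held-out probability
    scheme_seed: int

    def to_json(self, path: str | Path) -> None:
        d = {
            "variant": self.variant,
            "scheme_seed": self.scheme_seed,
            "norm_params": self.norm_params.to_dict(),
            "robustness": self.robustness.to_dict(),
            "cv_scores": self.cv_scores.to_dict(),
            "fold_models": [
                {
                    "coefficients": m.coefficients,
                    "intercept": m.intercept,
                    "cost": m.cost,
                    "norm_params": m.norm_params.to_dict(),
                    "enrichment_features": m.enrichment_features,
                    "degenerate": m.degenerate,
                }
                for m in self.fold_models
            ],
        }
        Path(path).write_text(json.dumps(d))

    @classmethod
    def from_json(cls, path: str | Path) -> "TrainedEnsemble":
        d = json.loads(Path(path).read_text())
        return cls(
            variant=d["variant"],
            scheme_seed=d["scheme_seed"],
            norm_params=NormalizationParams.from_dict(d["norm_params"]),
            robustness=pd.Series(d["robustness"]),
            cv_scores=pd.Series(d["cv_scores"]),
            fold_models=[
                FoldModel(
                    coefficients={k: float(v) for k, v in m["coefficients"].items()},
                    intercept=float(m["intercept"]),
                    cost=float(m["cost"]),
                    norm_params=NormalizationParams.from_dict(m["norm_params"]),
                    enrichment_features=m["enrichment_features"],
                    degenerate=m["degenerate"],
                )
                for m in d["fold_models"]
            ],
        )


def _fit_lasso(X: np.ndarray, y: np.ndarray, C: float) -> LogisticRegression:
    # l1_ratio=1 selects the pure L1 (LASSO) penalty under the liblinear solver
    # fixed random_state: liblinear shuffles internally and refits must be
    # exactly reproducible
    return LogisticRegression(
        l1_ratio=1.0, C=float(C), solver="liblinear", max_iter=2000, random_state=0
    ).fit(X, y)


def _inner_cv_select(
    X: np.ndarray, y: np.ndarray, lambda_grid: np.ndarray, n_inner: int, seed: int
) -> float:
    """Pick the cost maximizing inner-CV AUROC; smallest C on ties (sparser model)."""
    n_inner = min(n_inner, int(y.sum()), int((~y.astype(bool)).sum()))
    if n_inner < 2:
        return float(lambda_grid[len(lambda_grid) // 2])
    splitter = StratifiedKFold(n_splits=n_inner, shuffle=True, random_state=seed % (2**31 - 1))
    splits = list(splitter.split(X, y))
    aurocs = np.zeros(len(lambda_grid))
    for ci, C in enumerate(lambda_grid):
        preds = np.zeros(len(y))
        for tr, te in splits:
            preds[te] = _fit_lasso(X[tr], y[tr], C).predict_proba(X[te])[:, 1]
        aurocs[ci] = single_feature_auroc(preds, y)
    return float(lambda_grid[int(np.argmax(aurocs))])


def fit_fold(
    table: pd.DataFrame,
    labels: np.ndarray,
    train_idx: np.ndarray,
    variant: str,
    lambda_grid: np.ndarray,
    pseudocount: float,
    inner_seed: int,
    n_inner: int = 5,
) -> FoldModel:
    """Fit one cross-validation fold from the raw (filtered) profile table.

    Everything — normalization, enrichment filter, cost selection, the model —
    is a function of ``table[:, train_idx]`` and ``labels[train_idx]`` only.
    """
    # canonical sample order (sorted IDs): the fitted fold must not depend on
    # the order samples happen to arrive in
    order = train_idx[np.argsort(table.columns[train_idx].astype(str))]
    train_table = table.iloc[:, order]
    y_train = labels[order]
    Z_train, fold_params = fit_normalization(train_table, pseudocount=pseudocount)

    enr: list[str] | None = None
    if variant == "enrichment_constrained":
        enr = enrichment_filter(Z_train, y_train)
        if not enr:
            return FoldModel({}, 0.0, float("nan"), fold_params, [], degenerate=True)
        Z_train = Z_train.loc[enr]

    X = Z_train.to_numpy(dtype=float).T
    C = _inner_cv_select(X, y_train.astype(int), lambda_grid, n_inner, inner_seed)
    model = _fit_lasso(X, y_train.astype(int), C)
    coefs = {
        str(fid): float(w)
        for fid, w in zip(Z_train.index, model.coef_[0])
        if w != 0.0
    }
    return FoldModel(coefs, float(model.intercept_[0]), C, fold_params, enr)


def _fold_predict(fold: FoldModel, table: pd.DataFrame) -> np.ndarray:
    Z = apply_frozen(fold.norm_params, table)
    if fold.enrichment_features is not None and not fold.degenerate:
        Z = Z.loc[fold.enrichment_features]
    return fold.predict(Z)


def train_ensemble(
    table: pd.DataFrame,
    labels,
    scheme: CVScheme | None = None,
    variant: str = "unconstrained",
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
    pseudocount: float = 1e-5,
    seed: int = 0,
) -> TrainedEnsemble:
    """Train the full repeated-CV LASSO ensemble on a model-feature-filtered table.

    ``labels`` is a boolean case indicator aligned with the table's samples.
    Returns the 100 fold models, per-feature robustness, per-sample mean
    cross-validated scores, and a transfer normalization fitted on the full
    training table for frozen application to external cohorts.
    """
    if variant not in ("unconstrained", "enrichment_constrained"):
        raise ValueError(f"unknown variant: {variant}")
    y = np.asarray(labels, dtype=bool)
    if len(np.unique(y)) != 2:
        raise ValueError("labels must contain both classes")
    if scheme is None:
        scheme = make_cv_scheme(y, seed=seed, sample_ids=tuple(map(str, table.columns)))
    cols = tuple(map(str, table.columns))
    if cols != scheme.sample_ids:
        # fold membership follows sample IDs, so cv_scores are invariant to
        # the order samples arrive in
        if set(cols) != set(scheme.sample_ids):
            raise ValueError("scheme sample IDs do not match the table")
        order = [scheme.sample_ids.index(c) for c in cols]
        scheme = CVScheme(scheme.n_repeats, scheme.n_folds,
                          scheme.assignment[:, order], scheme.stratified,
                          scheme.seed, cols)
    n = len(y)
    prob_sum = np.zeros(n)
    prob_cnt = np.zeros(n)
    fold_models: list[FoldModel] = []
    nonzero_counts = pd.Series(0.0, index=table.index.astype(str))
    inner_ss = np.random.SeedSequence([scheme.seed, 271_828])
    inner_seeds = [int(c.generate_state(1)[0]) for c in inner_ss.spawn(scheme.n_repeats * scheme.n_folds)]

    for r in range(scheme.n_repeats):
        for k in range(scheme.n_folds):
            test_mask = scheme.assignment[r] == k
            train_idx = np.flatnonzero(~test_mask)
            fold = fit_fold(
                table, y, train_idx, variant, np.asarray(lambda_grid, dtype=float),
                pseudocount, inner_seeds[r * scheme.n_folds + k],
            )
            fold_models.append(fold)
            p = _fold_predict(fold, table.iloc[:, np.flatnonzero(test_mask)])
            prob_sum[test_mask] += p
            prob_cnt[test_mask] += 1
            for fid in fold.coefficients:
                nonzero_counts[fid] += 1

    cv_scores = pd.Series(prob_sum / prob_cnt, index=pd.Index(table.columns, name="sample_id"))
    robustness = nonzero_counts / len(fold_models)
    _, transfer_params = fit_normalization(table, pseudocount=pseudocount)
    return TrainedEnsemble(variant, fold_models, transfer_params, robustness,
                           cv_scores, scheme.seed)


def predict_ensemble(ensemble: TrainedEnsemble, table: pd.DataFrame) -> pd.Series:
    """Frozen external scoring: mean predicted probability over all fold models.

    Deterministic and invariant to sample order and to extra features in the
    external table; every fold model applies its own frozen normalization.
    """
    overlap = set(map(str, table.index)) & set(ensemble.norm_params.feature_ids)
    if not overlap:
        raise ValueError("external table shares no features with the model")
    probs = np.zeros(table.shape[1])
    for fold in ensemble.fold_models:
        probs += _fold_predict(fold, table)
    return pd.Series(probs / len(ensemble.fold_models),
                     index=pd.Index(table.columns, name="sample_id"))


@dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auroc: float
    ci95: tuple[float, float]


def _delong_variance(scores: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """AUROC and its DeLong variance via midrank placements."""
    pos, neg = scores[y], scores[~y]
    m, k = len(pos), len(neg)
    all_r = stats.rankdata(np.concatenate([pos, neg]))
    r_pos, r_neg = stats.rankdata(pos), stats.rankdata(neg)
    v10 = (all_r[:m] - r_pos) / k          # placement of each positive
    v01 = 1.0 - (all_r[m:] - r_neg) / m    # placement of each negative
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if k > 1 else 0.0
    return auc, s10 / m + s01 / k


def roc_evaluate(scores, labels) -> RocCurve:
    """Empirical ROC curve with trapezoid AUROC and a DeLong 95% CI.

    The trapezoid area over unique thresholds equals the tie-corrected
    Mann-Whitney probability; the CI is clipped to [0, 1].
    """
    from sklearn.metrics import roc_curve

    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    fpr, tpr, thr = roc_curve(y.astype(int), s, drop_intermediate=False)
    auc, var = _delong_variance(s, y)
    half = 1.959963984540054 * np.sqrt(var)
    return RocCurve(thr, fpr, tpr, auc, (max(0.0, auc - half), min(1.0, auc + half)))
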