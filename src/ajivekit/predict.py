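"""Component-based prediction models and their evaluation protocol.

Builds feature tables from a decomposition (joint scores + first few
individual scores per block + clinical covariates) and from the
non-integrative comparator (per-block principal components + covariates),
then evaluates logistic / multinomial models by stratified 10-fold
cross-validated AUC, an L1-penalized (lasso) protocol with unpenalized
covariates, and a 1000-tree random forest with out-of-bag error and
Gini-importance ranking.

AUC conventions: binary AUC is the Mann-Whitney rank statistic; multiclass
AUC is the Hand-Till average of pairwise binary AUCs over all unordered
class pairs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss, roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.preprocessing import StandardScaler

from .ajive import AjiveResult
from .blocks import OmicsBlock

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureTable",
    "PredictionReport",
    "binary_auc",
    "multiclass_auc",
    "build_integrative_features",
    "build_pca_features",
    "build_covariate_features",
    "cv_auc",
    "lasso_protocol",
    "random_forest_eval",
]


@dataclass
class FeatureTable:
    """Samples x predictors design matrix with provenance-tagged columns.

    Provenance tags are one of ``joint``, ``individual:<block>``,
    ``pc:<block>``, ``covariate``.
    """

    X: pd.DataFrame
    provenance: list[str]
    outcome: pd.Series

    def __post_init__(self) -> None:
        if self.X.isna().any().any():
            raise ValueError("feature table contains missing entries")
        if len(self.provenance) != self.X.shape[1]:
            raise ValueError("one provenance tag per column required")
        for tag in self.provenance:
            head = tag.split(":", 1)[0]
            if head not in ("joint", "individual", "pc", "covariate"):
                raise ValueError(f"malformed provenance tag {tag!r}")
        if list(self.outcome.index) != list(self.X.index):
            raise ValueError("outcome index must match feature table rows")

    @property
    def labels(self) -> list[str]:
        return list(self.X.columns)


@dataclass
class PredictionReport:
    """Evaluation record for one model."""

    model_kind: str  # logistic | multinomial | lasso | random_forest
    mean_auc: float
    fold_aucs: list[float] = field(default_factory=list)
    in_sample_auc: float | None = None
    roc_points: pd.DataFrame | None = None  # fpr/tpr of the in-sample fit
    accuracy: float | None = None
    oob_error_pct: float | None = None
    importance_ranking: list[str] | None = None
    importances: pd.Series | None = None
    seed: int | None = None
    fold_assignments: np.ndarray | None = None
    notes: list[str] = field(default_factory=list)


def binary_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC of scores against binary labels."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = labels == np.max(labels)
    n1 = int(pos.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("binary AUC needs both classes present")
    r = rankdata(scores)
    return float((r[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def multiclass_auc(probabilities: pd.DataFrame, labels: Sequence) -> float:
    """Hand-Till multiclass AUC: mean of pairwise binary AUCs.

    ``probabilities`` has one column per class (rows sum to 1); for each
    unordered class pair (i, j) the AUC of column i restricted to samples of
    the two classes is averaged with the AUC of column j, then averaged over
    pairs.
    """
    labels = pd.Series(list(labels))
    probs = probabilities.reset_index(drop=True)
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("probability rows must sum to 1")
    classes = list(probs.columns)
    for c in classes:
        if not (labels == c).any():
            raise ValueError(f"class {c!r} absent from labels")
    pair_aucs = []
    for ci, cj in combinations(classes, 2):
        sel = labels.isin([ci, cj]).to_numpy()
        y = (labels[sel] == ci).to_numpy().astype(int)
        a_ij = binary_auc(probs.loc[sel, ci].to_numpy(), y)
        a_ji = binary_auc(probs.loc[sel, cj].to_numpy(), 1 - y)
        pair_aucs.append(0.5 * (a_ij + a_ji))
    return float(np.mean(pair_aucs))


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def build_integrative_features(
    result: AjiveResult,
    covariates: pd.DataFrame,
    outcome: pd.Series,
    n_individual: int = 5,
) -> FeatureTable:
    """Joint scores + first ``n_individual`` individual scores per block + covariates.

    Joint columns are the common normalized scores (one set, shared across
    blocks). Blocks with fewer than ``n_individual`` individual components
    contribute what they have, with a logged warning.
    """
    n = result.joint.joint_basis.shape[0]
    if len(covariates) != n or len(outcome) != n:
        raise ValueError(
            f"decomposition has {n} samples but covariates/outcome have "
            f"{len(covariates)}/{len(outcome)}"
        )
    cols: dict[str, np.ndarray] = {}
    prov: list[str] = []
    for i in range(result.joint_rank):
        cols[f"Joint_{i + 1}"] = result.joint.joint_basis[:, i]
        prov.append("joint")
    for b in result.blocks:
        take = min(n_individual, b.individual_rank)
        if take < n_individual:
            logger.warning(
                "block %r has only %d individual components (requested %d)",
                b.name,
                b.individual_rank,
                n_individual,
            )
        for i in range(take):
            cols[f"{b.name}Ind_{i + 1}"] = b.individual_scores[:, i]
            prov.append(f"individual:{b.name}")
    for c in covariates.columns:
        cols[str(c)] = covariates[c].to_numpy(dtype=float)
        prov.append("covariate")
    X = pd.DataFrame(cols, index=covariates.index.map(str))
    return FeatureTable(X=X, provenance=prov, outcome=outcome.set_axis(X.index))


def build_pca_features(
    blocks: Sequence[OmicsBlock],
    covariates: pd.DataFrame,
    outcome: pd.Series,
    n_pcs: int = 5,
) -> FeatureTable:
    """Non-integrative comparator: top PCs per block + covariates.

    PC sample scores are the right singular vectors of the centered block
    scaled by their singular values (identical centering to the integrative
    path, no variance scaling).
    """
    cols: dict[str, np.ndarray] = {}
    prov: list[str] = []
    for b in blocks:
        X = b.values
        if np.isnan(X).any():
            raise ValueError(f"block {b.name!r} has missing entries")
        if n_pcs >= min(X.shape):
            raise ValueError(
                f"n_pcs={n_pcs} must be < min(p, n) = {min(X.shape)} for block {b.name!r}"
            )
        Xc = X - X.mean(axis=1, keepdims=True)
        _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        for i in range(n_pcs):
            cols[f"{b.name}PC_{i + 1}"] = Vt[i] * s[i]
            prov.append(f"pc:{b.name}")
    for c in covariates.columns:
        cols[str(c)] = covariates[c].to_numpy(dtype=float)
        prov.append("covariate")
    X = pd.DataFrame(cols, index=covariates.index.map(str))
    return FeatureTable(X=X, provenance=prov, outcome=outcome.set_axis(X.index))


def build_covariate_features(covariates: pd.DataFrame, outcome: pd.Series) -> FeatureTable:
    """Covariates-only baseline table."""
    X = covariates.copy()
    X.index = X.index.map(str)
    return FeatureTable(
        X=X,
        provenance=["covariate"] * X.shape[1],
        outcome=outcome.set_axis(X.index),
    )


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------

def _fit_logistic(X: np.ndarray, y: np.ndarray) -> LogisticRegression:
    """Unregularized maximum-likelihood fit with a tiny-ridge fallback.

    Quasi-separation or non-convergence falls back to an L2 penalty of 1e-8
    (C = 1e8), recorded by the caller.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            model = LogisticRegression(C=np.inf, max_iter=2000)
            model.fit(X, y)
            return model
        except Exception:
            pass
    model = LogisticRegression(C=1e8, max_iter=5000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, y)
    return model


def _auc_from_model(model, X: np.ndarray, y: np.ndarray, multiclass: bool) -> float:
    prob = model.predict_proba(X)
    if multiclass:
        return multiclass_auc(pd.DataFrame(prob, columns=model.classes_), y)
    idx = list(model.classes_).index(model.classes_.max())
    return binary_auc(prob[:, idx], y)


def cv_auc(
    features: FeatureTable,
    model_kind: str = "logistic",
    k: int = 10,
    seed: int = 0,
) -> PredictionReport:
    """Stratified k-fold cross-validated AUC of a (multinomial) logistic model.

    Per-fold AUC is computed on the held-out samples (binary: rank-based;
    multiclass: Hand-Till) and averaged; the model is also refit on the full
    data for an in-sample ROC curve and AUC. Fold assignment is fixed by
    ``seed``. Folds missing a class raise a stratification error; a fold
    whose fit fails is skipped with a recorded note.
    """
    if model_kind not in ("logistic", "multinomial"):
        raise ValueError(f"model_kind must be logistic or multinomial, got {model_kind!r}")
    X = features.X.to_numpy(dtype=float)
    y = features.outcome.to_numpy()
    classes = np.unique(y)
    multiclass = model_kind == "multinomial"
    if multiclass and classes.size != 4:
        raise ValueError(f"multinomial protocol expects 4 classes, got {classes.size}")
    if not multiclass and classes.size != 2:
        raise ValueError(f"logistic protocol expects 2 classes, got {classes.size}")
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = pd.Series(y).value_counts()
    if (counts < k).any():
        raise ValueError(
            f"stratification error: class {counts.idxmin()!r} has {counts.min()} "
            f"samples, fewer than k={k} folds"
        )

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignments = np.empty(len(y), dtype=int)
    fold_aucs: list[float] = []
    fold_accs: list[float] = []
    notes: list[str] = []
    for f, (tr, te) in enumerate(skf.split(X, y)):
        assignments[te] = f
        try:
            model = _fit_logistic(X[tr], y[tr])
            fold_aucs.append(_auc_from_model(model, X[te], y[te], multiclass))
            fold_accs.append(float((model.predict(X[te]) == y[te]).mean()))
        except Exception as exc:  # pragma: no cover - defensive
            notes.append(f"fold {f} skipped: {exc}")
            logger.warning("cv_auc: fold %d skipped (%s)", f, exc)

    full = _fit_logistic(X, y)
    in_auc = _auc_from_model(full, X, y, multiclass)
    roc = None
    if not multiclass:
        prob = full.predict_proba(X)[:, list(full.classes_).index(full.classes_.max())]
        fpr, tpr, _ = roc_curve(y, prob, pos_label=full.classes_.max())
        roc = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    return PredictionReport(
        model_kind=model_kind,
        mean_auc=float(np.mean(fold_aucs)),
        fold_aucs=fold_aucs,
        in_sample_auc=float(in_auc),
        roc_points=roc,
        accuracy=float(np.mean(fold_accs)),
        seed=seed,
        fold_assignments=assignments,
        notes=notes,
    )


def lasso_protocol(
    blocks: Sequence[OmicsBlock],
    covariates: pd.DataFrame,
    outcome: pd.Series,
    repeats: int = 50,
    train_frac: float = 2.0 / 3.0,
    k_inner: int = 10,
    seed: int = 0,
    n_lambdas: int = 20,
    lambda_rule: str = "min",
) -> PredictionReport:
    """L1-penalized logistic regression with unpenalized clinical covariates.

    Per repeat: a stratified split keeps ``train_frac`` of samples for
    training; the penalty is chosen on the training portion by ``k_inner``-
    fold cross-validation (minimum mean deviance by default, ``"1se"``
    selectable), and AUC is measured on the held-out portion. Omics features
    are standardized inside the path; covariates carry zero penalty,
    implemented by inflating their columns so the L1 cost of a unit effect
    is negligible. Reports the mean held-out AUC across repeats and how
    often each predictor was selected.
    """
    if not (0 < train_frac < 1):
        raise ValueError("train_frac must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    omics = np.vstack([b.values for b in blocks]).T  # samples x total features
    feat_labels = [f for b in blocks for f in b.feature_ids]
    cov = covariates.to_numpy(dtype=float)
    cov_labels = [str(c) for c in covariates.columns]
    y = pd.Series(outcome).to_numpy()
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("lasso protocol expects a binary outcome")
    ybin = (y == classes.max()).astype(int)

    COV_INFLATION = 1e4  # effective penalty factor ~1e-4 for covariates
    Cs = np.logspace(-3, 2, n_lambdas)
    held_aucs: list[float] = []
    selected = np.zeros(len(feat_labels) + len(cov_labels))
    for rep in range(repeats):
        for attempt in range(10):
            rs = int(rng.integers(2**31 - 1))
            tr, te = train_test_split(
                np.arange(len(ybin)),
                train_size=train_frac,
                stratify=ybin,
                random_state=rs,
            )
            if len(np.unique(ybin[tr])) == 2 and len(np.unique(ybin[te])) == 2:
                break
            logger.warning("lasso_protocol: degenerate split redrawn (repeat %d)", rep)
        scaler = StandardScaler().fit(omics[tr])
        sd = np.where(scaler.scale_ > 0, scaler.scale_, 1.0)
        Xtr_om = (omics[tr] - scaler.mean_) / sd
        Xte_om = (omics[te] - scaler.mean_) / sd
        csc = StandardScaler().fit(cov[tr])
        csd = np.where(csc.scale_ > 0, csc.scale_, 1.0)
        Xtr = np.hstack([Xtr_om, (cov[tr] - csc.mean_) / csd * COV_INFLATION])
        Xte = np.hstack([Xte_om, (cov[te] - csc.mean_) / csd * COV_INFLATION])

        # inner CV over the penalty grid: minimize mean held-out deviance
        kf = StratifiedKFold(n_splits=k_inner, shuffle=True, random_state=rs)
        dev = np.zeros(len(Cs))
        for itr, ite in kf.split(Xtr, ybin[tr]):
            for ci, C in enumerate(Cs):
                m = LogisticRegression(
                    l1_ratio=1, C=C, solver="liblinear", max_iter=500
                ).fit(Xtr[itr], ybin[tr][itr])
                p = m.predict_proba(Xtr[ite])[:, 1]
                dev[ci] += log_loss(ybin[tr][ite], p, labels=[0, 1])
        dev /= k_inner
        if lambda_rule == "min":
            best = int(np.argmin(dev))
        elif lambda_rule == "1se":
            se = dev.std() / np.sqrt(k_inner)
            ok = np.where(dev <= dev.min() + se)[0]
            best = int(ok[0])  # smallest C (strongest penalty) within one SE
        else:
            raise ValueError(f"unknown lambda_rule {lambda_rule!r}")
        final = LogisticRegression(
            l1_ratio=1, C=Cs[best], solver="liblinear", max_iter=1000
        ).fit(Xtr, ybin[tr])
        held_aucs.append(binary_auc(final.predict_proba(Xte)[:, 1], ybin[te]))
        selected += (np.abs(final.coef_[0]) > 1e-10).astype(float)

    sel = pd.Series(selected / repeats, index=feat_labels + cov_labels)
    return PredictionReport(
        model_kind="lasso",
        mean_auc=float(np.mean(held_aucs)),
        fold_aucs=held_aucs,
        importances=sel,
        seed=seed,
        notes=[f"selection frequency over {repeats} repeats stored in importances"],
    )


def random_forest_eval(
    features: FeatureTable, n_trees: int = 1000, seed: int = 0
) -> PredictionReport:
    """Random forest with out-of-bag diagnostics and Gini importance ranking.

    Reports OOB classification error (%), OOB accuracy, AUC computed from
    the OOB class probabilities (binary rank-based or Hand-Till), and all
    predictors ranked by mean decrease in Gini impurity.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    X = features.X.to_numpy(dtype=float)
    y = features.outcome.to_numpy()
    rf = RandomForestClassifier(
        n_estimators=n_trees, oob_score=True, random_state=seed, n_jobs=1
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small-n forests may miss OOB coverage
        rf.fit(X, y)
    oob_prob = rf.oob_decision_function_
    # rows without OOB coverage hold NaN; fall back to uniform for them
    bad = np.isnan(oob_prob).any(axis=1)
    if bad.any():
        oob_prob = oob_prob.copy()
        oob_prob[bad] = 1.0 / oob_prob.shape[1]
    pred = rf.classes_[np.argmax(oob_prob, axis=1)]
    oob_acc = float((pred == y).mean())
    if rf.classes_.size == 2:
        auc = binary_auc(oob_prob[:, list(rf.classes_).index(rf.classes_.max())], y)
    else:
        auc = multiclass_auc(pd.DataFrame(oob_prob, columns=rf.classes_), y)
    importances = pd.Series(rf.feature_importances_, index=features.labels)
    ranking = list(importances.sort_values(ascending=False).index)
    return PredictionReport(
        model_kind="random_forest",
        mean_auc=float(auc),
        accuracy=oob_acc,
        oob_error_pct=100.0 * (1.0 - oob_acc),
        importance_ranking=ranking,
        importances=importances,
        seed=seed,
    )
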