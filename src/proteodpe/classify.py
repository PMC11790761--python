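"""Discriminative-feature analysis: gradient-boosted classification of one
disease versus controls on differentially expressed proteins.

The differentially expressed protein list is partitioned 70/30 into train
and test *feature* sets (a protein split, with a ``split_axis`` switch for
the conventional sample split), a gradient-boosted tree classifier is
tuned by exhaustive grid search with stratified 5-fold cross-validation
optimizing F1, per-protein importances are the mean absolute TreeSHAP
additive attributions, and principal components of the non-zero-importance
feature submatrix are tested against diagnosis and severity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy import stats
from sklearn.model_selection import GridSearchCV, StratifiedKFold

from .containers import ProteinMatrix, SampleTable

log = logging.getLogger("proteodpe")

__all__ = [
    "split_features",
    "tune_and_train",
    "shap_importance",
    "pc_association",
    "PcAssociation",
    "DEFAULT_GRID",
]

#: grid over the boosted-tree hyperparameters tuned by CV F1
DEFAULT_GRID = {
    "learning_rate": [0.1, 0.3],
    "max_depth": [2, 4],
    "gamma": [0.0, 1.0],
    "colsample_bytree": [0.8, 1.0],
    "subsample": [0.8, 1.0],
}


def split_features(
    features: list[str], train_fraction: float = 0.7, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Seeded random partition of the feature (protein) list.

    The train set takes ``floor(train_fraction * n)`` features; train and
    test are disjoint with complete union, deterministic given the seed.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    if len(features) < 2:
        raise ValueError("need at least 2 features to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(features))
    n_train = int(np.floor(train_fraction * len(features)))
    train = [features[i] for i in sorted(perm[:n_train])]
    test = [features[i] for i in sorted(perm[n_train:])]
    return train, test


def _feature_frame(
    matrix: ProteinMatrix,
    samples: SampleTable,
    features: list[str],
    positive_group: str,
    reference_group: str,
) -> tuple[pd.DataFrame, np.ndarray]:
    samples = samples.aligned_to(matrix)
    diag = samples.data["diagnosis"].astype(str)
    keep = diag.isin([positive_group, reference_group])
    ids = samples.data.index[keep]
    X = matrix.values.loc[features, ids].T
    y = (diag.loc[ids] == positive_group).to_numpy(dtype=int)
    return X, y


def tune_and_train(
    matrix: ProteinMatrix,
    samples: SampleTable,
    features: list[str],
    grid: dict | None = None,
    k_folds: int = 5,
    seed: int = 0,
    positive_group: str = "disease_1",
    reference_group: str = "control",
    n_estimators: int = 50,
) -> GridSearchCV:
    """Exhaustive grid search of a gradient-boosted classifier by CV F1.

    Folds are stratified and seeded; the winning setting is refit on all
    samples. Binary contrast only (one disease versus the reference
    group).
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    X, y = _feature_frame(matrix, samples, features, positive_group,
                          reference_group)
    counts = np.bincount(y, minlength=2)
    if counts.min() < k_folds:
        raise ValueError(
            f"stratified {k_folds}-fold CV impossible: class counts {counts}"
        )
    base = xgb.XGBClassifier(
        n_estimators=n_estimators,
        objective="binary:logistic",
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        eval_metric="logloss",
    )
    cv = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(
        base,
        param_grid=grid if grid is not None else DEFAULT_GRID,
        scoring="f1",
        cv=cv,
        n_jobs=1,
        refit=True,
    )
    search.fit(X, y)
    log.info("best CV F1 %.3f with %s", search.best_score_, search.best_params_)
    return search


def shap_importance(
    model,
    matrix: ProteinMatrix,
    samples: SampleTable,
    features: list[str],
    dpe: pd.DataFrame | None = None,
    positive_group: str = "disease_1",
    reference_group: str = "control",
) -> pd.DataFrame:
    """Mean-|TreeSHAP| per-feature importance of a fitted tree ensemble.

    Per-sample additive attributions come from the booster itself
    (``pred_contribs``); they sum, per sample, to the margin prediction.
    Importance is the mean absolute attribution across samples; features
    with exactly zero importance (never used by any tree) are flagged.
    Direction of regulation and logFC are annotated from the DPE table
    when given.
    """
    estimator = model.best_estimator_ if isinstance(model, GridSearchCV) else model
    booster = estimator.get_booster()
    X, _ = _feature_frame(matrix, samples, features, positive_group,
                          reference_group)
    dm = xgb.DMatrix(X, feature_names=list(X.columns))
    contribs = booster.predict(dm, pred_contribs=True)  # (n, f+1), last = bias
    imp = np.abs(contribs[:, :-1]).mean(axis=0)
    table = pd.DataFrame({"accession": features, "importance": imp})
    if dpe is not None:
        ann = dpe.set_index("accession")
        table["logFC"] = ann["logFC"].reindex(features).to_numpy()
        table["gene_symbol"] = ann["gene_symbol"].reindex(features).to_numpy()
        table["direction"] = np.where(table["logFC"] >= 0, "up", "down")
    table["nonzero"] = table["importance"] > 0
    return table.sort_values(
        ["importance", "accession"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


@dataclass
class PcAssociation:
    """Variance explained and covariate associations of leading PCs."""

    table: pd.DataFrame  # per PC: var_explained, diagnosis p, severity tau/p
    scores: pd.DataFrame  # samples x PCs

    def __post_init__(self) -> None:
        v = self.table["var_explained"].to_numpy()
        if ((v < 0) | (v > 1 + 1e-12)).any() or (np.diff(v) > 1e-12).any():
            raise ValueError("variance fractions must be in [0,1], non-increasing")


def pc_association(
    matrix: ProteinMatrix,
    samples: SampleTable,
    features: list[str],
    n_pcs: int = 2,
    positive_group: str = "disease_1",
    reference_group: str = "control",
) -> PcAssociation:
    """PCA of the selected-feature submatrix, tested against covariates.

    PC1..n are tested against diagnosis by two-sided rank-sum and against
    the ordinal severity stage by Kendall tau-b (severity-defined samples
    only). Constant features are dropped with a warning.
    """
    if len(features) < 3:
        raise ValueError("need at least 3 features")
    X, y = _feature_frame(matrix, samples, features, positive_group,
                          reference_group)
    if X.shape[0] < 4:
        raise ValueError("need at least 4 samples")
    sd = X.to_numpy().std(axis=0)
    if (sd == 0).any():
        log.warning("%d constant features dropped", int((sd == 0).sum()))
        X = X.loc[:, sd > 0]
    A = X.to_numpy() - X.to_numpy().mean(axis=0, keepdims=True)
    U, S, _ = np.linalg.svd(A, full_matrices=False)
    n_pcs = min(n_pcs, S.size)
    var_frac = (S**2) / (S**2).sum()
    scores = U[:, :n_pcs] * S[:n_pcs]
    sev = samples.data["severity"].reindex(X.index)
    rows = []
    for j in range(n_pcs):
        pc = scores[:, j]
        p_diag = float(
            stats.mannwhitneyu(pc[y == 1], pc[y == 0],
                               alternative="two-sided").pvalue
        )
        keep = sev.notna().to_numpy()
        if keep.sum() >= 8 and np.unique(sev[keep]).size >= 2:
            tau, p_sev = stats.kendalltau(pc[keep],
                                          sev[keep].astype(float).to_numpy())
        else:
            tau, p_sev = np.nan, np.nan
        rows.append(
            {
                "pc": f"PC{j + 1}",
                "var_explained": float(var_frac[j]),
                "p_diagnosis": p_diag,
                "severity_tau": float(tau) if tau == tau else np.nan,
                "p_severity": float(p_sev) if p_sev == p_sev else np.nan,
            }
        )
    return PcAssociation(
        table=pd.DataFrame(rows),
        scores=pd.DataFrame(scores, index=X.index,
                            columns=[f"PC{j + 1}" for j in range(n_pcs)]),
    )
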