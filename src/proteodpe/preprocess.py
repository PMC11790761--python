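"""Normalization, filtering, imputation and batch QC for TMT proteomics.

The stage mirrors the standard downstream processing of isobaric-label
data: channel totals are equalized and intensities expressed relative to a
common reference channel scaled to 100; low-confidence identifications and
proteins missing in more than a set fraction of samples are removed;
remaining missing values are imputed by local least squares (regression on
the most correlated fully-observed proteins); and residual batch structure
is screened by testing pool separation along leading principal components.
Batch exclusion is an explicit opt-in — flagging never silently drops
samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import Confidence, ProteinMatrix, SampleTable

log = logging.getLogger("proteodpe")

__all__ = [
    "PreprocessReport",
    "normalize_reference",
    "filter_proteins",
    "LocalLeastSquaresImputer",
    "impute_lls",
    "batch_qc",
    "exclude_batches",
]


@dataclass
class PreprocessReport:
    """Bookkeeping for the preprocessing stage."""

    n_removed_confidence: int = 0
    n_removed_missing: int = 0
    n_imputed_cells: int = 0
    batch_pc_assoc: dict = field(default_factory=dict)
    flagged_batches: list = field(default_factory=list)
    excluded_batches: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for n in (self.n_removed_confidence, self.n_removed_missing,
                  self.n_imputed_cells):
            if n < 0:
                raise ValueError("report counts must be non-negative")


def normalize_reference(
    matrix: ProteinMatrix, reference_column: str
) -> tuple[ProteinMatrix, list[str]]:
    """Two-step reference-channel normalization of raw linear intensities.

    (1) every channel is scaled so its total abundance matches the
    highest-total channel; (2) each protein row is scaled so its value in
    the reference channel equals 100, expressing all channels as
    ratios-to-reference x 100. Proteins whose reference value is zero (or
    missing) cannot be row-scaled; they are left unscaled and returned as a
    flagged list.

    Returns the normalized matrix and the list of flagged accessions.
    """
    if reference_column not in matrix.sample_ids:
        raise ValueError(f"reference column {reference_column!r} not present")
    values = matrix.values.to_numpy(dtype=float, copy=True)
    mask = matrix.missing_mask.to_numpy()
    work = np.where(mask, 0.0, values)
    totals = work.sum(axis=0)
    top = totals.max()
    factors = np.divide(top, totals, out=np.ones_like(totals), where=totals > 0)
    values = values * factors[None, :]

    ref_idx = matrix.sample_ids.get_loc(reference_column)
    ref = values[:, ref_idx]
    bad = mask[:, ref_idx] | ~(ref > 0)
    flagged = matrix.protein_ids[bad].tolist()
    if flagged:
        log.warning(
            "%d proteins lack a usable reference value; left unscaled", len(flagged)
        )
    row_factor = np.ones(matrix.n_proteins)
    row_factor[~bad] = 100.0 / ref[~bad]
    values = values * row_factor[:, None]
    values[mask] = np.nan
    out = pd.DataFrame(values, index=matrix.protein_ids, columns=matrix.sample_ids)
    return (
        ProteinMatrix(out, matrix.missing_mask.copy(), matrix.gene_symbols,
                      matrix.confidence),
        flagged,
    )


def filter_proteins(
    matrix: ProteinMatrix,
    max_missing_fraction: float = 0.25,
    min_confidence: Confidence = Confidence.HIGH,
) -> tuple[ProteinMatrix, PreprocessReport]:
    """Drop low-confidence proteins, then proteins too often missing.

    Confidence below ``min_confidence`` is removed first; then any protein
    whose missing fraction *strictly exceeds* ``max_missing_fraction``
    (missing in more than that share of samples) is removed. A protein
    missing in exactly the boundary fraction is retained.
    """
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must lie in [0, 1]")
    conf_rank = matrix.confidence.map(lambda c: Confidence(c).rank)
    keep_conf = conf_rank >= Confidence(min_confidence).rank
    n_removed_conf = int((~keep_conf).sum())
    step1 = matrix.subset_proteins(matrix.protein_ids[keep_conf])

    frac = step1.missing_mask.mean(axis=1)
    keep_miss = frac <= max_missing_fraction
    n_removed_miss = int((~keep_miss).sum())
    out = step1.subset_proteins(step1.protein_ids[keep_miss])
    if out.n_proteins == 0:
        raise ValueError(
            "no proteins survive filtering; relax max_missing_fraction or "
            "min_confidence"
        )
    report = PreprocessReport(
        n_removed_confidence=n_removed_conf, n_removed_missing=n_removed_miss
    )
    return out, report


class LocalLeastSquaresImputer(TransformerMixin, BaseEstimator):
    """Impute missing intensities by local least squares regression.

    For each protein with missing cells, the ``k_neighbors`` fully-observed
    proteins most correlated with it (absolute Pearson over the protein's
    observed samples) serve as regressors: an OLS model fitted on the
    observed samples predicts the missing ones. Observed cells are never
    altered. If the neighbor system is rank-deficient the imputer falls
    back to the neighbor mean with a warning.

    Parameters
    ----------
    k_neighbors : int, default 10
        Number of correlated neighbor proteins used per target.
    """

    def __init__(self, k_neighbors: int = 10):
        self.k_neighbors = k_neighbors

    def fit(self, matrix: ProteinMatrix, y=None) -> "LocalLeastSquaresImputer":
        complete = ~matrix.missing_mask.to_numpy().any(axis=1)
        if complete.sum() < self.k_neighbors:
            raise ValueError(
                f"need >= {self.k_neighbors} fully observed proteins, "
                f"have {int(complete.sum())}"
            )
        self.complete_rows_ = np.flatnonzero(complete)
        self.n_features_in_ = matrix.n_proteins
        return self

    def transform(self, matrix: ProteinMatrix) -> ProteinMatrix:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "complete_rows_")
        values = matrix.values.to_numpy(dtype=float, copy=True)
        mask = matrix.missing_mask.to_numpy()
        if not mask.any():
            return matrix.copy()
        pool = values[self.complete_rows_]  # complete proteins x samples
        n_imputed = 0
        for gi in np.flatnonzero(mask.any(axis=1)):
            obs = ~mask[gi]
            mis = mask[gi]
            y = values[gi, obs]
            if obs.sum() < 3:
                fill = np.nanmean(values[gi])
                values[gi, mis] = fill
                n_imputed += int(mis.sum())
                continue
            sub = pool[:, obs]
            ys = y - y.mean()
            xs = sub - sub.mean(axis=1, keepdims=True)
            denom = np.sqrt((xs**2).sum(axis=1) * (ys**2).sum())
            with np.errstate(invalid="ignore", divide="ignore"):
                corr = np.abs(xs @ ys) / denom
            corr = np.nan_to_num(corr, nan=0.0)
            corr[self.complete_rows_ == gi] = -1.0  # never self
            nbr = np.argsort(-corr, kind="stable")[: self.k_neighbors]
            X_obs = np.column_stack([np.ones(obs.sum()), pool[nbr][:, obs].T])
            X_mis = np.column_stack([np.ones(mis.sum()), pool[nbr][:, mis].T])
            beta, _, rank, _ = np.linalg.lstsq(X_obs, y, rcond=None)
            if rank < X_obs.shape[1]:
                log.warning(
                    "singular neighbor system for %s; neighbor-mean fallback",
                    matrix.protein_ids[gi],
                )
                values[gi, mis] = pool[nbr][:, mis].mean(axis=0)
            else:
                values[gi, mis] = X_mis @ beta
            n_imputed += int(mis.sum())
        self.n_imputed_cells_ = n_imputed
        out = pd.DataFrame(values, index=matrix.protein_ids,
                           columns=matrix.sample_ids)
        fresh_mask = pd.DataFrame(
            np.zeros_like(mask), index=matrix.protein_ids,
            columns=matrix.sample_ids, dtype=bool
        )
        result = ProteinMatrix(out, fresh_mask, matrix.gene_symbols,
                               matrix.confidence)
        result.imputed_mask = matrix.missing_mask.copy()  # provenance
        return result


def impute_lls(matrix: ProteinMatrix, k_neighbors: int = 10) -> ProteinMatrix:
    """Functional wrapper over :class:`LocalLeastSquaresImputer`."""
    imputer = LocalLeastSquaresImputer(k_neighbors=k_neighbors)
    return imputer.fit(matrix).transform(matrix)


def batch_qc(
    matrix: ProteinMatrix,
    samples: SampleTable,
    n_pcs: int = 5,
    p_threshold: float = 1e-3,
) -> PreprocessReport:
    """Screen for batch separation along leading principal components.

    PCA is run on the centered log2 matrix with samples as observations;
    each batch is tested against all other samples on each of the first
    ``n_pcs`` component scores by a two-sided rank-sum test. Batches with
    p below ``p_threshold`` on any component are flagged. Flagging never
    removes samples — see :func:`exclude_batches`.
    """
    if matrix.n_samples < 3:
        raise ValueError("batch QC needs at least 3 samples")
    samples = samples.aligned_to(matrix)
    batches = samples.data["batch"].astype(str)
    if batches.nunique() < 2:
        return PreprocessReport(batch_pc_assoc={}, flagged_batches=[])
    X = matrix.values.to_numpy(dtype=float).T  # samples x proteins
    if np.isnan(X).any():
        raise ValueError("batch QC requires a fully imputed matrix")
    X = X - X.mean(axis=0, keepdims=True)
    n_pcs = min(n_pcs, min(X.shape) - 1)
    # scores = U * S from the thin SVD
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :n_pcs] * S[:n_pcs]
    assoc: dict[str, float] = {}
    flagged: list[str] = []
    for batch in sorted(batches.unique()):
        in_b = (batches == batch).to_numpy()
        if in_b.sum() < 2 or (~in_b).sum() < 2:
            continue
        pvals = [
            stats.mannwhitneyu(
                scores[in_b, j], scores[~in_b, j], alternative="two-sided"
            ).pvalue
            for j in range(n_pcs)
        ]
        assoc[batch] = float(min(pvals))
        if assoc[batch] < p_threshold:
            flagged.append(batch)
    return PreprocessReport(batch_pc_assoc=assoc, flagged_batches=flagged)


def exclude_batches(
    matrix: ProteinMatrix, samples: SampleTable, batches: list[str]
) -> tuple[ProteinMatrix, SampleTable]:
    """Drop all samples belonging to the named batches (explicit opt-in)."""
    samples = samples.aligned_to(matrix)
    keep = ~samples.data["batch"].astype(str).isin(batches)
    kept_ids = samples.data.index[keep]
    return matrix.subset_samples(kept_ids), SampleTable(samples.data.loc[kept_ids])
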