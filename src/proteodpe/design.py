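"""Design-matrix construction and surrogate-variable-guided covariate
selection.

Surrogate variables (SVs) are latent factors of the expression residuals
after removing the modelled covariates; here they are used purely as a
diagnostic: the covariate-selection loop keeps adding the candidate most
correlated with the first SV until no candidate reaches the correlation
threshold (default |r| < 0.2), at which point the design is considered to
capture the systematic structure of the data.

SVs are computed as right singular vectors of the residual matrix, with the
number retained chosen by permutation parallel analysis: a singular value
counts as signal while it exceeds the 95th percentile of its null
distribution under independent row-wise permutation of the residuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import ProteinMatrix, SampleTable

log = logging.getLogger("proteodpe")

__all__ = [
    "DesignSpec",
    "SvReport",
    "build_design_matrix",
    "surrogate_variables",
    "iterative_design",
    "SurrogateVariableAnalysis",
]

#: covariates expanded to indicator columns (reference level dropped)
CATEGORICAL = ("sex", "batch", "diagnosis")


@dataclass(frozen=True)
class DesignSpec:
    """Ordered adjustment covariates plus the diagnosis contrast."""

    covariates: tuple[str, ...] = ("age", "sex", "batch")
    contrast: str = "diagnosis"
    reference_group: str = "control"

    def __post_init__(self) -> None:
        if self.contrast in self.covariates:
            raise ValueError("contrast must not appear among covariates")

    def with_covariate(self, name: str) -> "DesignSpec":
        return replace(self, covariates=self.covariates + (name,))


@dataclass
class SvReport:
    """Surrogate variables plus the covariate-screen trace."""

    sv_scores: pd.DataFrame  # samples x retained SVs
    n_sv: int
    singular_values: np.ndarray
    null_thresholds: np.ndarray
    corr_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    iterations: list = field(default_factory=list)


def _resolve(
    name: str, samples: SampleTable, cells=None
) -> pd.Series | pd.DataFrame:
    if name in samples.data.columns:
        return samples.data[name]
    if cells is not None and name in cells.scores.columns:
        return cells.scores[name].reindex(samples.sample_ids)
    raise KeyError(f"covariate {name!r} not found in sample table or cell estimates")


def _expand(name: str, col: pd.Series, reference: str | None = None) -> pd.DataFrame:
    """Indicator-expand a categorical covariate, dropping one reference level."""
    col = col.astype(str)
    levels = sorted(col.unique())
    if reference is not None and reference in levels:
        levels.remove(reference)
        levels = [reference] + levels
    kept = levels[1:]
    out = {}
    for lv in kept:
        ind = (col == lv).astype(float)
        if ind.sum() == 0:
            log.warning("level %s=%s has zero samples; dropped", name, lv)
            continue
        out[f"{name}[{lv}]"] = ind
    return pd.DataFrame(out, index=col.index)


def build_design_matrix(
    design: DesignSpec,
    samples: SampleTable,
    cells=None,
    include_contrast: bool = True,
) -> pd.DataFrame:
    """Expand a DesignSpec to a numeric model matrix with intercept.

    Categorical covariates become indicator columns with one reference
    level dropped; the diagnosis contrast becomes one indicator per disease
    versus the reference group. Numeric covariates (age, cell estimates)
    pass through unchanged.
    """
    parts: list[pd.DataFrame] = [
        pd.DataFrame({"intercept": 1.0}, index=samples.sample_ids)
    ]
    for name in design.covariates:
        col = _resolve(name, samples, cells)
        if name in CATEGORICAL or col.dtype == object:
            parts.append(_expand(name, col))
        else:
            parts.append(pd.DataFrame({name: col.astype(float)}))
    if include_contrast:
        diag = samples.data[design.contrast].astype(str)
        expanded = _expand(design.contrast, diag, reference=design.reference_group)
        if expanded.to_numpy().sum() == 0:
            log.warning("all samples in the reference group; contrast columns zero")
        parts.append(expanded)
    X = pd.concat(parts, axis=1)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the collinear columns for the error message
        _, R = np.linalg.qr(X.to_numpy())
        bad = [X.columns[i] for i in range(X.shape[1]) if abs(R[i, i]) < 1e-8]
        raise ValueError(f"design matrix rank-deficient; collinear columns: {bad}")
    return X


def surrogate_variables(
    matrix: ProteinMatrix,
    design_matrix: pd.DataFrame,
    n_perm: int = 50,
    seed: int = 0,
    z_crit: float = 3.0,
) -> SvReport:
    """Estimate surrogate variables from expression residuals.

    Each protein is regressed on the design by least squares; candidate SVs
    are right singular vectors of the residual matrix. The number retained
    comes from permutation parallel analysis: each singular value's null
    distribution is built from ``n_perm`` independent row-wise permutations
    of the residuals (re-projected onto the design's orthogonal complement
    so the null matches the observed geometry), and a component is kept
    while its observed singular value exceeds the null mean by more than
    ``z_crit`` null standard deviations. The studentized rule corrects the
    anti-conservativeness of a raw null quantile, whose permutation spread
    is narrower than the sampling spread of the top singular value.
    """
    Y = matrix.values.to_numpy(dtype=float)
    if np.isnan(Y).any():
        raise ValueError("surrogate variable analysis requires a complete matrix")
    X = design_matrix.to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank-deficient")
    H = X @ np.linalg.pinv(X)
    E = Y - Y @ H.T  # residuals, proteins x samples

    def singvals(mat: np.ndarray) -> np.ndarray:
        g = mat.T @ mat
        w = np.linalg.eigvalsh(g)[::-1]
        return np.sqrt(np.clip(w, 0.0, None))

    obs = singvals(E)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, obs.size))
    P = np.eye(H.shape[0]) - H  # re-project permutations for a matched null
    for b in range(n_perm):
        null[b] = singvals(rng.permuted(E, axis=1) @ P.T)
    thresholds = null.mean(axis=0) + z_crit * null.std(axis=0, ddof=1)
    n_sv = 0
    while n_sv < obs.size and obs[n_sv] > thresholds[n_sv]:
        n_sv += 1
    _, _, Vt = np.linalg.svd(E, full_matrices=False)
    scores = pd.DataFrame(
        Vt[:n_sv].T,
        index=matrix.sample_ids,
        columns=[f"SV{i + 1}" for i in range(n_sv)],
    )
    return SvReport(
        sv_scores=scores, n_sv=n_sv, singular_values=obs,
        null_thresholds=thresholds,
    )


class SurrogateVariableAnalysis:
    """Thin object wrapper holding SV-analysis settings (sklearn-style)."""

    def __init__(self, n_perm: int = 50, seed: int = 0, z_crit: float = 3.0):
        self.n_perm = n_perm
        self.seed = seed
        self.z_crit = z_crit

    def fit(self, matrix: ProteinMatrix, design_matrix: pd.DataFrame):
        self.report_ = surrogate_variables(
            matrix, design_matrix, n_perm=self.n_perm, seed=self.seed,
            z_crit=self.z_crit,
        )
        return self

    def transform(self, matrix: ProteinMatrix) -> pd.DataFrame:
        return self.report_.sv_scores


def _candidate_vector(name: str, samples: SampleTable, cells) -> pd.DataFrame:
    """Numeric representation of a candidate covariate for the |r| screen.

    Categorical candidates contribute one indicator column per non-reference
    level; the screen uses the maximum |r| over those columns.
    """
    col = _resolve(name, samples, cells)
    if name in CATEGORICAL or col.dtype == object:
        return _expand(name, col)
    return pd.DataFrame({name: col.astype(float)})


def iterative_design(
    matrix: ProteinMatrix,
    base: DesignSpec,
    candidates: list[str],
    samples: SampleTable,
    cells=None,
    r_threshold: float = 0.2,
    n_perm: int = 50,
    seed: int = 0,
) -> tuple[DesignSpec, SvReport]:
    """Grow the design until SV1 no longer correlates with any candidate.

    Each round computes SVs under the current design and the |Pearson r|
    between SV1 and every remaining candidate; the candidate with maximal
    |r| is added while that maximum is at or above ``r_threshold`` (ties go
    to the earlier-listed candidate). The loop records a full trace and
    stops when the screen falls below the threshold, no SV survives
    parallel analysis, or candidates are exhausted.
    """
    if set(candidates) & set(base.covariates):
        raise ValueError("candidates must be disjoint from the base design")
    design = base
    remaining = list(candidates)
    iterations: list[tuple[str | None, float]] = []
    report = None
    while True:
        X = build_design_matrix(design, samples, cells)
        report = surrogate_variables(matrix, X, n_perm=n_perm, seed=seed)
        if report.n_sv == 0 or not remaining:
            iterations.append((None, 0.0))
            break
        sv1 = report.sv_scores.iloc[:, 0].to_numpy()
        corrs: dict[str, float] = {}
        for name in remaining:
            cols = _candidate_vector(name, samples, cells)
            rs = [
                abs(np.corrcoef(sv1, cols[c].to_numpy())[0, 1])
                for c in cols.columns
                if np.std(cols[c].to_numpy()) > 0
            ]
            corrs[name] = float(max(rs)) if rs else 0.0
        best = max(remaining, key=lambda n: corrs[n])  # earlier-listed wins ties
        tied = [n for n in remaining if corrs[n] == corrs[best]]
        if len(tied) > 1:
            log.info("correlation tie among %s; adding %s", tied, best)
        if corrs[best] >= r_threshold:
            iterations.append((best, corrs[best]))
            design = design.with_covariate(best)
            remaining.remove(best)
        else:
            iterations.append((None, corrs[best]))
            break
    report.iterations = iterations
    # final correlation table for the report
    sv_cols = report.sv_scores.columns
    rows = []
    for name in candidates:
        cols = _candidate_vector(name, samples, cells)
        for sv in sv_cols:
            sv_vec = report.sv_scores[sv].to_numpy()
            rs = [
                abs(np.corrcoef(sv_vec, cols[c].to_numpy())[0, 1])
                for c in cols.columns
                if np.std(cols[c].to_numpy()) > 0
            ]
            rows.append({"sv": sv, "covariate": name,
                         "abs_r": float(max(rs)) if rs else 0.0})
    report.corr_table = pd.DataFrame(rows)
    return design, report
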