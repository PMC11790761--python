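"""Per-protein moderated linear models and cross-disease overlap analysis.

Each protein's log2 intensity is regressed on a shared design; residual
variances are shrunk toward a pooled prior by empirical Bayes, yielding
moderated t-statistics with ``d0 + d_g`` degrees of freedom. The prior
hyperparameters (d0, s0^2) are estimated by method of moments on the log
residual variances using digamma/trigamma matching, the classic moderation
construction: if s_g^2 ~ s0^2 * chi^2_{d_g}/d_g scaled by a
scaled-inverse-chi-square prior with d0 df, then

    E[log s_g^2] = log s0^2 + psi(d_g/2) - log(d_g/2)  (shifted)
    Var[log s_g^2] = psi'(d_g/2) + psi'(d0/2)

so d0 solves psi'(d0/2) = Var(e_g) - psi'(d_g/2) for the moment-corrected
log variances e_g. d0 = 0 turns moderation off (ordinary per-protein t);
d0 = inf pools all proteins to the common prior variance.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from sklearn.base import BaseEstimator

from .containers import ProteinMatrix, SampleTable

log = logging.getLogger("proteodpe")

__all__ = [
    "ModerationParams",
    "ModeratedLinearModel",
    "OverlapReport",
    "fit_moderated",
    "adjust_bh",
    "severity_model",
    "subset_bonferroni",
    "overlap_analysis",
]

_VAR_FLOOR = 1e-12


@dataclass
class ModerationParams:
    """Empirical-Bayes variance-moderation hyperparameters."""

    d0: float  # prior degrees of freedom, may be inf
    s0_sq: float  # prior variance
    sigma_sq: np.ndarray  # per-protein residual variance
    df_residual: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError("prior df must be >= 0")
        if self.s0_sq <= 0 and self.d0 > 0:
            raise ValueError("prior variance must be positive")


def trigamma_inverse(y: float) -> float:
    """Solve psi'(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if abs(dif / x) < 1e-10:
            break
    return float(x)


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) to residual variances."""
    s2 = np.clip(s2, _VAR_FLOOR, None)
    e = np.log(s2) - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2.0))
    if e_var > 0:
        d0 = 2.0 * trigamma_inverse(e_var)
        s0_sq = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))
    return d0, s0_sq


class ModeratedLinearModel(BaseEstimator):
    """Empirical-Bayes moderated linear model across proteins.

    Parameters
    ----------
    prior_df : "empirical", float or numpy.inf
        d0. "empirical" estimates it from the data; 0 disables shrinkage
        (ordinary per-protein t); inf pools to the common prior variance.

    Attributes (after :meth:`fit`)
    ------------------------------
    coef_ : (p, d) array of regression coefficients.
    sigma2_ : per-protein residual variance.
    posterior_var_ : shrunken variances s~^2.
    params_ : :class:`ModerationParams`.
    """

    def __init__(self, prior_df: float | str = "empirical"):
        self.prior_df = prior_df

    def fit(self, X: pd.DataFrame, Y: np.ndarray) -> "ModeratedLinearModel":
        Xv = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        n, d = Xv.shape
        if Y.shape[1] != n:
            raise ValueError("Y must be proteins x samples matching X rows")
        if n < d + 2:
            raise ValueError(f"need >= {d + 2} samples for {d} design columns")
        if np.isnan(Y).any():
            raise ValueError("moderated fit requires a fully imputed matrix")
        rank = np.linalg.matrix_rank(Xv)
        if rank < d:
            raise ValueError("design matrix is rank-deficient")
        pinv = np.linalg.pinv(Xv)
        beta = Y @ pinv.T  # p x d
        resid = Y - beta @ Xv.T
        df = float(n - d)
        if df <= 0:
            raise ValueError("zero residual degrees of freedom")
        s2 = (resid**2).sum(axis=1) / df
        n_floored = int((s2 < _VAR_FLOOR).sum())
        if n_floored:
            log.warning("%d proteins with ~zero residual variance floored",
                        n_floored)
        s2 = np.clip(s2, _VAR_FLOOR, None)

        if self.prior_df == "empirical":
            d0, s0_sq = _fit_variance_prior(s2, df)
        else:
            d0 = float(self.prior_df)
            s0_sq = float(np.exp(np.mean(np.log(s2)))) if d0 > 0 else 1.0
        if np.isinf(d0):
            post = np.full_like(s2, s0_sq)
        elif d0 == 0:
            post = s2
        else:
            post = (d0 * s0_sq + df * s2) / (d0 + df)

        self.columns_ = list(X.columns) if hasattr(X, "columns") else list(range(d))
        self.coef_ = beta
        self.sigma2_ = s2
        self.posterior_var_ = post
        self.unscaled_cov_ = np.linalg.inv(Xv.T @ Xv)
        self.params_ = ModerationParams(d0=d0, s0_sq=s0_sq, sigma_sq=s2,
                                        df_residual=df)
        return self

    def t_table(self, columns: list[str]) -> pd.DataFrame:
        """Moderated t, raw p and coefficient for the named design columns."""
        d0, df = self.params_.d0, self.params_.df_residual
        total_df = df if np.isinf(d0) else df + d0
        rows = {}
        for col in columns:
            j = self.columns_.index(col)
            se = np.sqrt(self.posterior_var_ * self.unscaled_cov_[j, j])
            t = self.coef_[:, j] / se
            if np.isinf(total_df):
                p = 2.0 * stats.norm.sf(np.abs(t))
            else:
                p = 2.0 * stats.t.sf(np.abs(t), total_df)
            rows[col] = (self.coef_[:, j], t, p)
        return rows


def adjust_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-values cannot be adjusted")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def fit_moderated(
    matrix: ProteinMatrix,
    design_matrix: pd.DataFrame,
    contrasts: list[str],
    prior_df: float | str = "empirical",
) -> tuple[pd.DataFrame, ModerationParams]:
    """Fit the moderated model and tabulate the named contrast columns.

    Returns a long table with one row per (protein, contrast): log2
    fold-change (the contrast coefficient), moderated t, raw p, BH-adjusted
    p within contrast, and the rank by |logFC| within contrast (1 =
    largest).
    """
    model = ModeratedLinearModel(prior_df=prior_df).fit(
        design_matrix, matrix.values.to_numpy(dtype=float)
    )
    tables = model.t_table(contrasts)
    frames = []
    for contrast in contrasts:
        coef, t, p = tables[contrast]
        adj = adjust_bh(p)
        frame = pd.DataFrame(
            {
                "accession": matrix.protein_ids,
                "gene_symbol": matrix.gene_symbols.to_numpy(),
                "contrast": contrast,
                "logFC": coef,
                "t": t,
                "p_value": p,
                "adj_p_value": adj,
            }
        )
        frame["rank_abs_logfc"] = (
            (-frame["logFC"].abs()).rank(method="first").astype(int)
        )
        frames.append(frame)
    return pd.concat(frames, ignore_index=True), model.params_


def severity_model(
    matrix: ProteinMatrix,
    samples: SampleTable,
    cells=None,
    cell_covariates: tuple[str, ...] = (),
    severity_column: str = "severity",
    n_pcs: int = 5,
    batch_p_threshold: float = 0.01,
    prior_df: float | str = "empirical",
) -> tuple[pd.DataFrame, dict]:
    """Severity-association model with a PC substituted for batch.

    Restricted to samples with a defined severity stage. A PCA of their
    expression is screened for batch association (one-way rank test per
    leading component); the most batch-associated component replaces the
    block of batch indicators, reducing model complexity at small n. If no
    component associates with batch at the threshold, the model falls back
    to indicator encoding with a warning. The severity stage enters as a
    numeric covariate; its slope (log2 per stage) is reported as the
    effect.
    """
    samples = samples.aligned_to(matrix)
    sev = samples.data[severity_column]
    keep = sev.notna()
    if keep.sum() < 8:
        raise ValueError("need >= 8 samples with defined severity")
    sub = matrix.subset_samples(samples.data.index[keep])
    meta = samples.data.loc[keep]

    X_expr = sub.values.to_numpy(dtype=float).T
    X_expr = X_expr - X_expr.mean(axis=0, keepdims=True)
    n_pcs = min(n_pcs, min(X_expr.shape) - 1)
    U, S, _ = np.linalg.svd(X_expr, full_matrices=False)
    scores = U[:, :n_pcs] * S[:n_pcs]
    batches = meta["batch"].astype(str)
    pvals = []
    for j in range(n_pcs):
        groups = [scores[(batches == b).to_numpy(), j]
                  for b in sorted(batches.unique())]
        groups = [g for g in groups if len(g) >= 2]
        if len(groups) < 2:
            pvals.append(1.0)
            continue
        pvals.append(float(stats.kruskal(*groups).pvalue))
    pvals = np.asarray(pvals)
    info: dict = {"pc_batch_p": pvals.tolist()}
    parts = [pd.DataFrame({"intercept": 1.0}, index=meta.index)]
    if pvals.min() < batch_p_threshold:
        pc_idx = int(np.argmin(pvals))
        info["batch_pc"] = pc_idx + 1
        parts.append(pd.DataFrame({f"PC{pc_idx + 1}": scores[:, pc_idx]},
                                  index=meta.index))
    else:
        log.warning("no expression PC associated with batch at p<%g; "
                    "falling back to indicator encoding", batch_p_threshold)
        info["batch_pc"] = None
        from .design import _expand

        parts.append(_expand("batch", batches))
    if cells is not None:
        for name in cell_covariates:
            parts.append(pd.DataFrame(
                {name: cells.scores[name].reindex(meta.index).to_numpy()},
                index=meta.index,
            ))
    parts.append(pd.DataFrame({"age": meta["age"].astype(float)}))
    from .design import _expand as _exp

    parts.append(_exp("sex", meta["sex"]))
    parts.append(pd.DataFrame({"severity": sev[keep].astype(float)}))
    X = pd.concat(parts, axis=1)
    table, params = fit_moderated(sub, X, ["severity"], prior_df=prior_df)
    info["params"] = params
    return table, info


def subset_bonferroni(dpe: pd.DataFrame, symbols: list[str]) -> pd.DataFrame:
    """Bonferroni re-adjustment within a nominated protein family.

    Filters the table to the named gene symbols with nominal p < 0.05 and
    multiplies each raw p by the count of selected proteins (capped at 1) —
    the sub-analysis used for focused families such as the mitochondrial
    ribosomal proteins.
    """
    if not symbols:
        raise ValueError("symbols must be non-empty")
    sel = dpe[dpe["gene_symbol"].isin(symbols) & (dpe["p_value"] < 0.05)].copy()
    if sel.empty:
        log.warning("no nominated proteins reach nominal p < 0.05")
        sel["bonferroni_p"] = pd.Series(dtype=float)
        return sel
    sel["bonferroni_p"] = np.minimum(sel["p_value"] * len(sel), 1.0)
    return sel


@dataclass
class OverlapReport:
    """Cross-disease intersections and fold-change concordance."""

    fdr_intersections: dict  # combination tuple -> set of accessions
    nominal_intersections: dict
    logfc_common: pd.DataFrame  # common (nominal) proteins x diseases
    logfc_correlation: pd.DataFrame  # pairwise Pearson r of logFC
    discordant: dict = field(default_factory=dict)  # pair -> accession list

    def __post_init__(self) -> None:
        for combo, fdr_set in self.fdr_intersections.items():
            if combo in self.nominal_intersections:
                if not fdr_set <= self.nominal_intersections[combo]:
                    raise ValueError(
                        "FDR-level intersection must be nested in nominal"
                    )


def overlap_analysis(
    dpe_by_disease: dict[str, pd.DataFrame], alpha: float = 0.05
) -> OverlapReport:
    """Intersections of significant proteins across disease contrasts.

    Computes, for every combination of >= 2 diseases, the intersection of
    FDR-significant (adjusted p < alpha) and nominally significant
    (raw p < alpha) proteins; for the all-disease nominal common set,
    pairwise Pearson correlations of log fold-changes and the proteins with
    discordant fold-change signs per disease pair.
    """
    if len(dpe_by_disease) < 2:
        raise ValueError("need at least 2 disease tables")
    universes = {d: set(t["accession"]) for d, t in dpe_by_disease.items()}
    shared = set.intersection(*universes.values())
    if not shared:
        raise ValueError("disease tables have disjoint protein universes")
    fdr_sets = {
        d: set(t.loc[t["adj_p_value"] < alpha, "accession"])
        for d, t in dpe_by_disease.items()
    }
    nom_sets = {
        d: set(t.loc[t["p_value"] < alpha, "accession"])
        for d, t in dpe_by_disease.items()
    }
    diseases = sorted(dpe_by_disease)
    fdr_inter, nom_inter = {}, {}
    for r in range(2, len(diseases) + 1):
        for combo in itertools.combinations(diseases, r):
            fdr_inter[combo] = set.intersection(*(fdr_sets[d] for d in combo))
            nom_inter[combo] = set.intersection(*(nom_sets[d] for d in combo))
    common = sorted(nom_inter[tuple(diseases)])
    logfc = pd.DataFrame(
        {
            d: dpe_by_disease[d].set_index("accession")["logFC"].loc[common]
            for d in diseases
        }
    )
    corr = logfc.corr(method="pearson") if len(common) >= 2 else pd.DataFrame()
    discordant = {}
    for a, b in itertools.combinations(diseases, 2):
        disc = logfc.index[np.sign(logfc[a]) != np.sign(logfc[b])].tolist()
        discordant[(a, b)] = disc
    return OverlapReport(
        fdr_intersections=fdr_inter,
        nominal_intersections=nom_inter,
        logfc_common=logfc,
        logfc_correlation=corr,
        discordant=discordant,
    )
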