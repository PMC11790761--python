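"""Marker-gene-profile (MGP) estimation of relative cell-type abundance.

A cell type's MGP is the first principal component of its marker panel's
expression across samples: each marker row is z-scored, the marker x sample
submatrix is decomposed, and the PC1 sample scores are reported as a
unitless *relative* abundance estimate (no simplex projection — MGPs rank
samples by cell content, they are not counts). The component sign is
aligned so that the estimate correlates positively with the majority of
markers; markers whose loading opposes the majority after alignment are
reported for QC.

Validation statistics mirror the standard use of MGPs in case-control
brain proteomics: rank-sum group comparisons against a reference group,
Kendall tau-b against an ordinal severity stage, and pairwise Pearson
correlation structure between cell types.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MarkerPanel, ProteinMatrix, SampleTable

log = logging.getLogger("proteodpe")

__all__ = [
    "CellEstimates",
    "CellStatReport",
    "MarkerGeneProfileEstimator",
    "estimate_mgp",
    "estimate_all_panels",
    "compare_groups",
    "severity_correlation",
    "crosstype_correlation",
]


@dataclass
class CellEstimates:
    """Samples x cell types MGP scores plus marker-panel QC metadata."""

    scores: pd.DataFrame
    markers_used: dict = field(default_factory=dict)
    pc1_var_explained: dict = field(default_factory=dict)
    sign_flipped: dict = field(default_factory=dict)
    discordant_markers: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy()).all():
            raise ValueError("cell estimates must be finite")
        for ct, v in self.pc1_var_explained.items():
            if not 0.0 <= v <= 1.0 + 1e-12:
                raise ValueError(f"pc1_var_explained out of range for {ct}")


@dataclass
class CellStatReport:
    """Group tests, severity correlations and cross-type correlations."""

    group_tests: pd.DataFrame = field(default_factory=pd.DataFrame)
    severity_corr: pd.DataFrame = field(default_factory=pd.DataFrame)
    pairwise_corr: dict = field(default_factory=dict)


class MarkerGeneProfileEstimator:
    """Estimate one cell type's MGP (sklearn-style fit/transform).

    Parameters
    ----------
    panel : MarkerPanel
        Cell type name and marker gene symbols.
    min_markers : int, default 3
        Minimum usable markers after the symbol join and variance filter.
    drop_uncorrelated : bool, default False
        Optional removal of markers whose inter-marker correlation is low
        (mean |r| to the other markers below ``min_intermarker_r``) before
        the decomposition; off by default.
    """

    def __init__(
        self,
        panel: MarkerPanel,
        min_markers: int = 3,
        drop_uncorrelated: bool = False,
        min_intermarker_r: float = 0.1,
    ):
        self.panel = panel
        self.min_markers = min_markers
        self.drop_uncorrelated = drop_uncorrelated
        self.min_intermarker_r = min_intermarker_r

    def fit(self, matrix: ProteinMatrix, y=None) -> "MarkerGeneProfileEstimator":
        wanted = set(self.panel.markers)
        rows = matrix.protein_ids[matrix.gene_symbols.isin(wanted)]
        found_symbols = set(matrix.gene_symbols.loc[rows])
        missing = sorted(wanted - found_symbols)
        if len(rows) < self.min_markers:
            raise ValueError(
                f"panel {self.panel.cell_type!r}: only {len(rows)} markers in "
                f"the matrix (need >= {self.min_markers}); missing symbols: "
                f"{missing}"
            )
        sub = matrix.values.loc[rows].to_numpy(dtype=float)
        if np.isnan(sub).any():
            raise ValueError("MGP estimation requires a complete (imputed) matrix")
        sd = sub.std(axis=1, ddof=0)
        zero_var = sd == 0
        if zero_var.any():
            log.warning(
                "panel %s: %d zero-variance markers dropped",
                self.panel.cell_type, int(zero_var.sum()),
            )
            rows = rows[~zero_var]
            sub = sub[~zero_var]
            sd = sd[~zero_var]
        if len(rows) < self.min_markers and len(rows) != 1:
            raise ValueError(
                f"panel {self.panel.cell_type!r}: fewer than "
                f"{self.min_markers} usable markers after variance filter"
            )
        Z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
        if self.drop_uncorrelated and Z.shape[0] > 2:
            C = np.corrcoef(Z)
            mean_abs = (np.abs(C).sum(axis=1) - 1.0) / (Z.shape[0] - 1)
            keep = mean_abs >= self.min_intermarker_r
            if keep.sum() >= max(self.min_markers, 1) and not keep.all():
                log.info(
                    "panel %s: dropped %d low-correlation markers",
                    self.panel.cell_type, int((~keep).sum()),
                )
                rows, Z = rows[keep], Z[keep]

        U, S, Vt = np.linalg.svd(Z, full_matrices=False)
        scores = S[0] * Vt[0]  # PC1 sample scores
        loadings = U[:, 0]
        # sign alignment: estimates should rise with the majority of markers
        marker_corr = np.array([np.corrcoef(scores, z)[0, 1] for z in Z])
        n_pos = int((marker_corr > 0).sum())
        n_neg = int((marker_corr < 0).sum())
        flip = n_neg > n_pos or (n_neg == n_pos and loadings.mean() < 0)
        if flip:
            scores, loadings, marker_corr = -scores, -loadings, -marker_corr
        discordant = matrix.gene_symbols.loc[rows[marker_corr < 0]].tolist()
        if discordant:
            log.info(
                "panel %s: %d markers load against the majority: %s",
                self.panel.cell_type, len(discordant), discordant,
            )
        self.scores_ = pd.Series(scores, index=matrix.sample_ids,
                                 name=self.panel.cell_type)
        self.markers_used_ = matrix.gene_symbols.loc[rows].tolist()
        self.pc1_var_explained_ = float(S[0] ** 2 / (S**2).sum())
        self.sign_flipped_ = bool(flip)
        self.discordant_markers_ = discordant
        return self

    def transform(self, matrix: ProteinMatrix) -> pd.Series:
        return self.scores_


def estimate_mgp(matrix: ProteinMatrix, panel: MarkerPanel, **kwargs) -> CellEstimates:
    """Estimate the MGP for a single marker panel."""
    est = MarkerGeneProfileEstimator(panel, **kwargs).fit(matrix)
    ct = panel.cell_type
    return CellEstimates(
        scores=est.scores_.to_frame(),
        markers_used={ct: est.markers_used_},
        pc1_var_explained={ct: est.pc1_var_explained_},
        sign_flipped={ct: est.sign_flipped_},
        discordant_markers={ct: est.discordant_markers_},
    )


def estimate_all_panels(
    matrix: ProteinMatrix, panels: list[MarkerPanel], **kwargs
) -> CellEstimates:
    """Run :func:`estimate_mgp` over every panel and column-bind the scores.

    Neuronal-subtype panels run through the identical code path — there is
    no special-casing by panel name.
    """
    cols, used, var, flip, disc = {}, {}, {}, {}, {}
    for panel in panels:
        one = estimate_mgp(matrix, panel, **kwargs)
        ct = panel.cell_type
        cols[ct] = one.scores[ct]
        used[ct] = one.markers_used[ct]
        var[ct] = one.pc1_var_explained[ct]
        flip[ct] = one.sign_flipped[ct]
        disc[ct] = one.discordant_markers[ct]
    return CellEstimates(
        scores=pd.DataFrame(cols),
        markers_used=used,
        pc1_var_explained=var,
        sign_flipped=flip,
        discordant_markers=disc,
    )


def _rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided rank-sum p: exact when both n <= 10 and tie-free."""
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) <= 10 and len(b) <= 10 and not ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    )


def compare_groups(
    est: CellEstimates,
    samples: SampleTable,
    reference_group: str = "control",
    adjust_across_cell_types: bool = False,
) -> CellStatReport:
    """Rank-sum tests of each disease group against the reference group.

    p-values are reported unadjusted per (cell type, comparison) by
    default; ``adjust_across_cell_types`` applies BH within each disease
    comparison across cell types.
    """
    diag = samples.data["diagnosis"].reindex(est.scores.index)
    if (diag == reference_group).sum() < 3:
        raise ValueError(f"reference group {reference_group!r} needs >= 3 samples")
    rows = []
    for group in sorted(diag.unique()):
        if group == reference_group:
            continue
        in_g = (diag == group).to_numpy()
        if in_g.sum() < 3:
            log.warning("group %s has < 3 samples; comparison skipped", group)
            continue
        for ct in est.scores.columns:
            a = est.scores.loc[in_g, ct].to_numpy()
            b = est.scores.loc[(diag == reference_group).to_numpy(), ct].to_numpy()
            rows.append({"cell_type": ct, "group": group,
                         "p_value": _rank_sum_p(a, b)})
    table = pd.DataFrame(rows, columns=["cell_type", "group", "p_value"])
    if adjust_across_cell_types and not table.empty:
        from .dpe import adjust_bh

        table["adj_p_value"] = (
            table.groupby("group")["p_value"].transform(
                lambda s: adjust_bh(s.to_numpy())
            )
        )
    return CellStatReport(group_tests=table)


def severity_correlation(
    est: CellEstimates, samples: SampleTable, min_samples: int = 8
) -> CellStatReport:
    """Kendall tau-b of each cell type's estimate against ordinal severity."""
    sev = samples.data["severity"].reindex(est.scores.index)
    keep = sev.notna()
    if keep.sum() < min_samples:
        raise ValueError(
            f"need >= {min_samples} samples with defined severity"
        )
    sev_v = sev[keep].astype(float).to_numpy()
    rows = []
    for ct in est.scores.columns:
        x = est.scores.loc[keep.to_numpy(), ct].to_numpy()
        if np.unique(sev_v).size < 2:
            rows.append({"cell_type": ct, "tau": np.nan, "p_value": np.nan})
            continue
        tau, p = stats.kendalltau(x, sev_v)
        rows.append({"cell_type": ct, "tau": float(tau), "p_value": float(p)})
    return CellStatReport(severity_corr=pd.DataFrame(rows))


def crosstype_correlation(
    est: CellEstimates, samples: SampleTable, by_group: bool = True
) -> CellStatReport:
    """Pearson correlation matrices between cell-type estimates, per group."""
    out: dict[str, pd.DataFrame] = {}
    if by_group:
        diag = samples.data["diagnosis"].reindex(est.scores.index)
        for group in sorted(diag.unique()):
            in_g = (diag == group).to_numpy()
            if in_g.sum() < 3:
                log.warning("group %s has < 3 samples; correlations skipped",
                            group)
                continue
            out[group] = est.scores.loc[in_g].corr(method="pearson")
    else:
        out["all"] = est.scores.corr(method="pearson")
    return CellStatReport(pairwise_corr=out)
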