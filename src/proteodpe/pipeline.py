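"""End-to-end orchestration of the analysis stages on a simulated cohort.

``run_all`` executes simulate -> preprocess -> deconvolve -> design -> dpe
-> enrich -> classify and writes every result table with deterministic row
order, so two runs with the same configuration are byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as cls
from . import deconvolution as dec
from . import dpe as dpe_mod
from . import enrichment as enr
from . import preprocess as pre
from .containers import RunConfig
from .design import DesignSpec, iterative_design
from .io import (
    write_gmt,
    write_marker_panels,
    write_protein_matrix,
    write_sample_table,
    write_table,
)
from .simulate import SimConfig, simulate_cohort, truth_report

log = logging.getLogger("proteodpe")


def run_all(
    outdir: str | Path,
    run_config: RunConfig | None = None,
    sim_config: SimConfig | None = None,
) -> dict:
    """Run every stage on a freshly simulated cohort; returns a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = run_config or RunConfig()
    sim = sim_config or SimConfig(seed=cfg.seed)

    # -- simulate ---------------------------------------------------------
    matrix, samples, panels, gene_sets, truth = simulate_cohort(sim)
    write_protein_matrix(matrix, outdir / "matrix_raw.tsv")
    write_sample_table(samples, outdir / "samples.tsv")
    write_marker_panels(panels, outdir / "markers.tsv")
    write_gmt(gene_sets, outdir / "gene_sets.gmt")
    write_table(truth_report(truth), outdir / "truth.tsv",
                sort_by=["parameter", "accession"], config=cfg)

    # -- preprocess -------------------------------------------------------
    filtered, report = pre.filter_proteins(
        matrix, max_missing_fraction=cfg.missing_fraction
    )
    imputed = pre.impute_lls(filtered)
    qc = pre.batch_qc(imputed, samples)
    report.batch_pc_assoc = qc.batch_pc_assoc
    report.flagged_batches = qc.flagged_batches
    extreme = sorted(
        b for b, p in report.batch_pc_assoc.items() if p < cfg.batch_exclude_p
    )
    if cfg.exclude_flagged_batches and extreme:
        report.excluded_batches = extreme
        imputed, samples = pre.exclude_batches(imputed, samples, extreme)
        log.info("excluded flagged batches %s (%d samples remain)",
                 extreme, imputed.n_samples)
    (outdir / "preprocess_report.json").write_text(
        json.dumps(
            {
                "n_removed_confidence": report.n_removed_confidence,
                "n_removed_missing": report.n_removed_missing,
                "batch_pc_assoc": report.batch_pc_assoc,
                "flagged_batches": report.flagged_batches,
                "excluded_batches": report.excluded_batches,
            },
            indent=2,
            sort_keys=True,
        )
    )
    write_protein_matrix(imputed, outdir / "matrix_imputed.tsv")

    # -- deconvolve -------------------------------------------------------
    cells = dec.estimate_all_panels(imputed, panels)
    scores = cells.scores.copy()
    scores.insert(0, "sample_id", scores.index)
    write_table(scores, outdir / "cell_estimates.tsv", sort_by=["sample_id"],
                config=cfg)
    group_stats = dec.compare_groups(cells, samples)
    write_table(group_stats.group_tests, outdir / "cell_group_tests.tsv",
                sort_by=["cell_type", "group"], config=cfg)
    if samples.severity.notna().sum() >= 8:
        sev_stats = dec.severity_correlation(cells, samples)
        write_table(sev_stats.severity_corr, outdir / "cell_severity_corr.tsv",
                    sort_by=["cell_type"], config=cfg)

    # -- design -----------------------------------------------------------
    base = DesignSpec(covariates=tuple(cfg.covariates))
    candidates = [c for c in cells.scores.columns]
    final_design, sv_report = iterative_design(
        imputed, base, candidates, samples, cells,
        r_threshold=cfg.sv_corr_max, seed=cfg.seed,
    )
    (outdir / "design.json").write_text(
        json.dumps(
            {
                "covariates": list(final_design.covariates),
                "n_sv": sv_report.n_sv,
                "iterations": [
                    {"added": a, "max_abs_r": r} for a, r in sv_report.iterations
                ],
            },
            indent=2,
            sort_keys=True,
        )
    )

    # -- dpe --------------------------------------------------------------
    from .design import build_design_matrix

    X = build_design_matrix(final_design, samples, cells)
    contrast_cols = [c for c in X.columns if c.startswith("diagnosis[")]
    dpe_table, params = dpe_mod.fit_moderated(imputed, X, contrast_cols)
    write_table(dpe_table, outdir / "dpe.tsv",
                sort_by=["contrast", "adj_p_value", "accession"], config=cfg)
    by_disease = {
        c.split("[")[1].rstrip("]"): dpe_table[dpe_table["contrast"] == c]
        for c in contrast_cols
    }
    overlap = dpe_mod.overlap_analysis(by_disease, alpha=cfg.fdr_alpha)
    overlap_rows = [
        {
            "combination": "+".join(combo),
            "level": level,
            "n_common": len(members),
            "members": ";".join(sorted(members)),
        }
        for level, inter in (
            ("fdr", overlap.fdr_intersections),
            ("nominal", overlap.nominal_intersections),
        )
        for combo, members in sorted(inter.items())
    ]
    write_table(pd.DataFrame(overlap_rows), outdir / "overlap.tsv",
                sort_by=["level", "combination"], config=cfg)

    if samples.severity.notna().sum() >= 8:
        sev_table, _ = dpe_mod.severity_model(
            imputed, samples, cells,
            cell_covariates=tuple(c for c in ("neurons", "endothelial")
                                  if c in cells.scores.columns),
        )
        write_table(sev_table, outdir / "dpe_severity.tsv",
                    sort_by=["adj_p_value", "accession"], config=cfg)

    # -- enrich -----------------------------------------------------------
    first = contrast_cols[0]
    ranked = enr.rank_statistic(dpe_table[dpe_table["contrast"] == first])
    min_size = min(10, max(3, len(gene_sets[next(iter(sorted(gene_sets)))]) // 5))
    enr_table = enr.gsea_preranked(
        ranked, gene_sets, n_perm=1000, seed=cfg.seed, min_size=min_size
    )
    write_table(enr_table, outdir / "enrichment.tsv",
                sort_by=["adj_p_value", "set_name"], config=cfg)
    lef = enr.leading_edge_frequency(enr_table, alpha=cfg.fdr_alpha)
    write_table(
        lef.rename_axis("gene_symbol").reset_index(),
        outdir / "leading_edge_frequency.tsv",
        sort_by=["n_leading_edges", "gene_symbol"],
        config=cfg,
    )
    kappa = enr.kappa_simplify(
        gene_sets, sorted(set(imputed.gene_symbols)), kappa_max=cfg.kappa_max
    )
    (outdir / "kappa_clusters.json").write_text(
        json.dumps(
            {
                "clusters": kappa.clusters,
                "representatives": kappa.representatives,
                "max_residual_kappa": kappa.max_residual_kappa,
            },
            indent=2,
            sort_keys=True,
        )
    )

    # -- classify ---------------------------------------------------------
    disease = sorted(by_disease)[0]
    table_d = by_disease[disease]
    dep = table_d.loc[table_d["adj_p_value"] < cfg.fdr_alpha, "accession"]
    if len(dep) < 10:  # fall back to the strongest nominal hits
        dep = table_d.nsmallest(30, "p_value")["accession"]
    features = sorted(dep)
    train, test = cls.split_features(features, seed=cfg.seed)
    # small grid keeps the stage quick; the full grid is configurable
    grid = {"learning_rate": [0.3], "max_depth": [2, 4], "gamma": [0.0],
            "colsample_bytree": [1.0], "subsample": [1.0]}
    model = cls.tune_and_train(
        matrix=_named_subset(imputed, train), samples=samples,
        features=train, grid=grid, seed=cfg.seed,
        positive_group=disease,
    )
    importance = cls.shap_importance(
        model, imputed, samples, train, dpe=table_d, positive_group=disease
    )
    write_table(importance, outdir / "importance.tsv",
                sort_by=["importance", "accession"], config=cfg)
    nonzero = importance.loc[importance["nonzero"], "accession"].tolist()
    if len(nonzero) >= 3:
        assoc = cls.pc_association(imputed, samples, sorted(nonzero),
                                   positive_group=disease)
        write_table(assoc.table, outdir / "pc_association.tsv",
                    sort_by=["pc"], config=cfg)

    manifest = {
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        "n_proteins_raw": matrix.n_proteins,
        "n_proteins_final": imputed.n_proteins,
        "n_samples": matrix.n_samples,
        "final_covariates": list(final_design.covariates),
        "outputs": sorted(p.name for p in outdir.iterdir()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True))
    return manifest


def _named_subset(matrix, accessions):
    return matrix.subset_proteins(sorted(accessions))
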