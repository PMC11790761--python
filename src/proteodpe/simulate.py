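"""Synthetic bulk-proteome cohorts with known ground truth.

Bulk tissue signal is additive in molecule counts, so samples are formed as
convex mixtures of cell-type signature profiles on the *linear* intensity
scale and logged afterwards:

    observed = log2( sum_c  p_c * 2^(signature_c) )
               + disease effect + severity slope * stage + batch offset
               + age/sex terms + Gaussian(0, noise_sd)

(additive log-scale terms shared across cell types factor out of the
mixture exactly). Missingness is left-censored — per sample, the lowest
``censor_quantile`` fraction of intensities is masked — which is the
dominant missingness mode of isobaric-label (TMT) proteomics and stresses
an imputer the way real data would.

Defaults describe a cohort of 120 samples in four diagnostic groups
(48 control / 48 disease_1 / 12 disease_2 / 12 disease_3 — the 73/73/18/17
imbalance of a typical parkinsonism brain-bank series scaled to 120),
4000 proteins, five brain cell types with 40 markers each, six TMT pools
with one designated outlier pool carrying inflated offsets to exercise
batch QC.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import (
    Confidence,
    GeneSetCollection,
    MarkerPanel,
    ProteinMatrix,
    SampleTable,
)

__all__ = ["SimConfig", "SimTruth", "simulate_cohort", "truth_report"]

DEFAULT_CELL_TYPES = (
    "neurons",
    "astrocytes",
    "oligodendrocytes",
    "microglia",
    "endothelial",
)
DEFAULT_BASE_PROPORTIONS = (0.40, 0.20, 0.25, 0.10, 0.05)


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; all randomness flows from ``seed``."""

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {
            "control": 48,
            "disease_1": 48,
            "disease_2": 12,
            "disease_3": 12,
        }
    )
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    base_proportions: tuple[float, ...] = DEFAULT_BASE_PROPORTIONS
    #: per-group additive shifts to base proportions (renormalized)
    proportion_shifts: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "disease_1": {"neurons": -0.10, "astrocytes": 0.04, "endothelial": -0.015},
            "disease_2": {"neurons": -0.05, "oligodendrocytes": 0.03},
            "disease_3": {"oligodendrocytes": 0.04},
        }
    )
    proportion_concentration: float = 100.0
    n_proteins: int = 4000
    markers_per_type: int = 40
    marker_margin: float = 3.0  # log2 elevation of a marker in its own type
    signature_mean: float = 10.0
    signature_sd: float = 1.5
    cross_type_sd: float = 0.4  # non-marker signature spread across cell types
    #: disease -> number of truly differential proteins, drawn inside
    #: designated "affected" gene sets
    n_de_per_disease: int = 120
    de_effect_log2: float = 0.5
    n_gene_sets: int = 40
    gene_set_size: int = 50
    n_affected_sets: int = 3  # per disease, sets that concentrate the effects
    severity_max: int = 6
    n_severity_proteins: int = 30
    severity_slope_log2: float = 0.1
    n_batches: int = 6
    batch_sd: float = 0.05
    outlier_batch_sd: float = 0.6
    outlier_batch: bool = True
    age_mean: float = 75.0
    age_sd: float = 8.0
    n_age_proteins: int = 100
    age_slope_log2: float = 0.01  # per year
    n_sex_proteins: int = 50
    sex_effect_log2: float = 0.2
    frac_medium_confidence: float = 0.04
    frac_low_confidence: float = 0.02
    noise_sd: float = 0.3
    censor_quantile: float = 0.05
    seed: int = 0

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)

    @property
    def diseases(self) -> tuple[str, ...]:
        return tuple(g for g in self.n_per_group if g != "control")


@dataclass
class SimTruth:
    """Ground-truth parameters of a simulated cohort."""

    proportions: pd.DataFrame  # samples x cell types, rows on the simplex
    de_effects: pd.DataFrame  # proteins x diseases, signed log2
    severity_effects: pd.Series  # protein -> log2 slope per severity unit
    batch_offsets: pd.DataFrame  # proteins x batches, log2 shifts
    signatures: pd.DataFrame  # proteins x cell types, mean log2 intensity
    noise_sd: float
    censor_quantile: float
    affected_sets: dict  # disease -> list of gene-set names carrying effects
    outlier_batch: str | None

    def __post_init__(self) -> None:
        sums = self.proportions.sum(axis=1).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("proportion rows must sum to 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be positive")


def _shifted_simplex(
    base: np.ndarray, cell_types: Sequence[str], shifts: Mapping[str, float]
) -> np.ndarray:
    out = base.copy()
    for ct, delta in shifts.items():
        out[list(cell_types).index(ct)] += delta
    out = np.clip(out, 1e-4, None)
    return out / out.sum()


def simulate_cohort(
    config: SimConfig,
) -> tuple[ProteinMatrix, SampleTable, list[MarkerPanel], GeneSetCollection, SimTruth]:
    """Generate a cohort: matrix, metadata, marker panels, gene sets, truth."""
    k = len(config.cell_types)
    p = config.n_proteins
    if any(n < 3 for n in config.n_per_group.values()):
        raise ValueError("need at least 3 samples per group")
    if config.markers_per_type < 5:
        raise ValueError("need at least 5 markers per cell type")
    if p < k * config.markers_per_type:
        raise ValueError(
            f"{p} proteins cannot host {k} x {config.markers_per_type} markers"
        )
    rng = np.random.default_rng(config.seed)

    accessions = pd.Index([f"P{i:05d}" for i in range(p)], name="accession")
    symbols = pd.Series([f"G{i:05d}" for i in range(p)], index=accessions,
                        name="gene_symbol")

    # -- signatures and marker panels ------------------------------------
    base_sig = rng.normal(config.signature_mean, config.signature_sd, size=p)
    signatures = base_sig[:, None] + rng.normal(0.0, config.cross_type_sd, size=(p, k))
    marker_rows = rng.choice(p, size=k * config.markers_per_type, replace=False)
    panels: list[MarkerPanel] = []
    for ci, ct in enumerate(config.cell_types):
        rows = marker_rows[ci * config.markers_per_type:(ci + 1) * config.markers_per_type]
        signatures[rows, :] = base_sig[rows, None]  # flat across other types
        signatures[rows, ci] = base_sig[rows] + config.marker_margin
        panels.append(MarkerPanel(ct, tuple(symbols.iloc[rows])))

    # -- samples, groups, covariates -------------------------------------
    sample_ids, diagnosis = [], []
    for group, n in config.n_per_group.items():
        for j in range(n):
            sample_ids.append(f"S_{group}_{j:03d}")
            diagnosis.append(group)
    n_samples = len(sample_ids)
    diagnosis = np.array(diagnosis)
    age = rng.normal(config.age_mean, config.age_sd, size=n_samples)
    sex = rng.choice(["F", "M"], size=n_samples)
    order = rng.permutation(n_samples)  # spread groups across pools
    batch = np.empty(n_samples, dtype=object)
    for pos, si in enumerate(order):
        batch[si] = f"pool{pos % config.n_batches + 1}"
    batch_names = [f"pool{b + 1}" for b in range(config.n_batches)]

    # -- proportions ------------------------------------------------------
    base = np.asarray(config.base_proportions, dtype=float)
    base = base / base.sum()
    proportions = np.empty((n_samples, k))
    for gi, group in enumerate(config.n_per_group):
        mask = diagnosis == group
        centre = _shifted_simplex(
            base, config.cell_types, config.proportion_shifts.get(group, {})
        )
        proportions[mask] = rng.dirichlet(
            centre * config.proportion_concentration, size=int(mask.sum())
        )

    # -- gene sets and disease effects ------------------------------------
    diseases = config.diseases
    set_names = [f"SET{j:03d}" for j in range(config.n_gene_sets)]
    sets: dict[str, list[str]] = {}
    for name in set_names:
        members = rng.choice(p, size=config.gene_set_size, replace=False)
        sets[name] = sorted(symbols.iloc[members])
    de_effects = np.zeros((p, len(diseases)))
    affected_sets: dict[str, list[str]] = {}
    sym_to_row = pd.Series(np.arange(p), index=symbols.to_numpy())
    for di, disease in enumerate(diseases):
        chosen = [
            set_names[j]
            for j in rng.choice(
                config.n_gene_sets, size=config.n_affected_sets, replace=False
            )
        ]
        affected_sets[disease] = chosen
        pool = sorted({g for name in chosen for g in sets[name]})
        n_de = min(config.n_de_per_disease, len(pool))
        hit = rng.choice(len(pool), size=n_de, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_de)
        mags = np.abs(rng.normal(config.de_effect_log2, config.de_effect_log2 / 4,
                                 size=n_de))
        rows = sym_to_row[np.asarray(pool, dtype=object)[hit]].to_numpy()
        de_effects[rows, di] = signs * mags

    # -- severity (disease_1 only), correlated with neuron loss -----------
    severity = np.full(n_samples, np.nan)
    d1 = diagnosis == (diseases[0] if diseases else "")
    if d1.any():
        neuron_col = list(config.cell_types).index(config.cell_types[0])
        z = -(proportions[d1, neuron_col] - proportions[d1, neuron_col].mean())
        z = z / (z.std() + 1e-12) + rng.normal(0, 0.8, size=int(d1.sum()))
        stages = np.clip(
            np.round((z - z.min()) / (np.ptp(z) + 1e-12) * config.severity_max),
            0,
            config.severity_max,
        )
        severity[d1] = stages
    severity_effects = np.zeros(p)
    sev_rows = rng.choice(p, size=config.n_severity_proteins, replace=False)
    severity_effects[sev_rows] = config.severity_slope_log2

    # -- batch, age, sex effects ------------------------------------------
    batch_offsets = rng.normal(0.0, config.batch_sd, size=(p, config.n_batches))
    outlier_name = None
    if config.outlier_batch and config.n_batches >= 2:
        outlier_name = batch_names[-1]
        batch_offsets[:, -1] = rng.normal(0.0, config.outlier_batch_sd, size=p)
    age_slopes = np.zeros(p)
    age_rows = rng.choice(p, size=config.n_age_proteins, replace=False)
    age_slopes[age_rows] = config.age_slope_log2 * rng.choice([-1, 1], size=config.n_age_proteins)
    sex_effects = np.zeros(p)
    sex_rows = rng.choice(p, size=config.n_sex_proteins, replace=False)
    sex_effects[sex_rows] = config.sex_effect_log2 * rng.choice([-1, 1], size=config.n_sex_proteins)

    # -- assemble observations --------------------------------------------
    linear = np.power(2.0, signatures)  # p x k
    mixture = linear @ proportions.T  # p x n
    values = np.log2(mixture)
    for di, disease in enumerate(diseases):
        values[:, diagnosis == disease] += de_effects[:, [di]]
    sev_filled = np.nan_to_num(severity, nan=0.0)
    values += severity_effects[:, None] * sev_filled[None, :]
    batch_idx = np.array([batch_names.index(b) for b in batch])
    values += batch_offsets[:, batch_idx]
    values += age_slopes[:, None] * (age - config.age_mean)[None, :]
    values += sex_effects[:, None] * (sex == "M")[None, :].astype(float)
    if config.noise_sd > 0:
        values += rng.normal(0.0, config.noise_sd, size=values.shape)

    # -- left-censoring ----------------------------------------------------
    mask = np.zeros_like(values, dtype=bool)
    if config.censor_quantile > 0:
        cuts = np.quantile(values, config.censor_quantile, axis=0)
        mask = values < cuts[None, :]
    censored = values.copy()
    censored[mask] = np.nan

    # -- confidence labels -------------------------------------------------
    conf = np.array([Confidence.HIGH] * p, dtype=object)
    n_med = int(round(config.frac_medium_confidence * p))
    n_low = int(round(config.frac_low_confidence * p))
    flagged = rng.choice(p, size=n_med + n_low, replace=False)
    conf[flagged[:n_med]] = Confidence.MEDIUM
    conf[flagged[n_med:]] = Confidence.LOW

    matrix = ProteinMatrix(
        pd.DataFrame(censored, index=accessions, columns=sample_ids),
        pd.DataFrame(mask, index=accessions, columns=sample_ids),
        symbols,
        pd.Series(conf, index=accessions, name="confidence"),
    )
    samples = SampleTable(
        pd.DataFrame(
            {
                "diagnosis": diagnosis,
                "age": age,
                "sex": sex,
                "batch": batch,
                "severity": severity,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    truth = SimTruth(
        proportions=pd.DataFrame(
            proportions, index=sample_ids, columns=list(config.cell_types)
        ),
        de_effects=pd.DataFrame(de_effects, index=accessions, columns=list(diseases)),
        severity_effects=pd.Series(severity_effects, index=accessions),
        batch_offsets=pd.DataFrame(batch_offsets, index=accessions,
                                   columns=batch_names),
        signatures=pd.DataFrame(signatures, index=accessions,
                                columns=list(config.cell_types)),
        noise_sd=config.noise_sd,
        censor_quantile=config.censor_quantile,
        affected_sets=affected_sets,
        outlier_batch=outlier_name,
    )
    collection = GeneSetCollection(sets, source="synthetic")
    return matrix, samples, panels, collection, truth


def truth_report(truth: SimTruth) -> pd.DataFrame:
    """Flatten ground-truth effect parameters to one row per (protein, term).

    Emits one row per protein per disease effect plus one severity row, i.e.
    ``p * (n_diseases + 1)`` rows, for parameter-recovery bookkeeping.
    """
    rows = []
    for disease in truth.de_effects.columns:
        col = truth.de_effects[disease]
        rows.append(
            pd.DataFrame(
                {
                    "accession": col.index,
                    "parameter": f"de_{disease}",
                    "value": col.to_numpy(),
                }
            )
        )
    rows.append(
        pd.DataFrame(
            {
                "accession": truth.severity_effects.index,
                "parameter": "severity_slope",
                "value": truth.severity_effects.to_numpy(),
            }
        )
    )
    return pd.concat(rows, ignore_index=True)
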