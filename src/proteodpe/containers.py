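"""Core domain containers shared by every pipeline stage.

The central object is :class:`ProteinMatrix`, a proteins x samples table of
log2 (or raw linear) intensities together with a missingness mask and
per-protein metadata (accession, gene symbol, identification confidence).
Accessions are the row key; gene symbols are the join key to marker panels
and gene-set collections and may repeat across rows (protein isoforms map to
one symbol).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Confidence",
    "ProteinMatrix",
    "SampleTable",
    "MarkerPanel",
    "GeneSetCollection",
    "RunConfig",
]


class Confidence(str, Enum):
    """Protein identification FDR confidence tier."""

    HIGH = "high"
    MEDIUM = "medium"
    LOW = "low"

    __str__ = str.__str__

    @property
    def rank(self) -> int:
        return {"low": 0, "medium": 1, "high": 2}[self.value]


@dataclass
class ProteinMatrix:
    """Protein intensity matrix (proteins x samples) with missingness mask.

    Parameters
    ----------
    values : pandas.DataFrame
        Intensities, indexed by protein accession, columns are sample ids.
        Cells under ``missing_mask`` hold NaN.
    missing_mask : pandas.DataFrame
        Boolean, same shape/labels as ``values``; True marks a missing cell.
    gene_symbols : pandas.Series
        One gene symbol per protein row (may repeat across rows).
    confidence : pandas.Series
        Identification confidence per protein row (``Confidence`` values).
    """

    values: pd.DataFrame
    missing_mask: pd.DataFrame
    gene_symbols: pd.Series
    confidence: pd.Series

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate protein accessions: {dups}")
        if self.values.shape != self.missing_mask.shape:
            raise ValueError(
                f"values {self.values.shape} and missing_mask "
                f"{self.missing_mask.shape} shapes disagree"
            )
        if not self.values.index.equals(self.missing_mask.index) or not (
            self.values.columns.equals(self.missing_mask.columns)
        ):
            raise ValueError("values and missing_mask labels disagree")
        self.gene_symbols = self.gene_symbols.reindex(self.values.index)
        self.confidence = self.confidence.reindex(self.values.index)
        observed = self.values.to_numpy()[~self.missing_mask.to_numpy()]
        if np.isnan(observed).any():
            raise ValueError("NaN present outside the missing mask")

    # -- convenience -----------------------------------------------------
    @property
    def protein_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "ProteinMatrix":
        return ProteinMatrix(
            self.values.copy(),
            self.missing_mask.copy(),
            self.gene_symbols.copy(),
            self.confidence.copy(),
        )

    def subset_proteins(self, accessions: Sequence[str]) -> "ProteinMatrix":
        idx = pd.Index(accessions)
        return ProteinMatrix(
            self.values.loc[idx],
            self.missing_mask.loc[idx],
            self.gene_symbols.loc[idx],
            self.confidence.loc[idx],
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "ProteinMatrix":
        cols = pd.Index(sample_ids)
        return ProteinMatrix(
            self.values[cols],
            self.missing_mask[cols],
            self.gene_symbols,
            self.confidence,
        )

    def complete(self) -> bool:
        """True if no cell is missing."""
        return not bool(self.missing_mask.to_numpy().any())


@dataclass
class SampleTable:
    """Per-sample covariates: diagnosis, age, sex, batch, ordinal severity.

    ``severity`` is a Braak-style ordinal stage and may be undefined (NaN)
    for samples where staging was not assessed.
    """

    data: pd.DataFrame

    REQUIRED = ("diagnosis", "age", "sex", "batch")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"sample table lacks required columns: {missing}")
        if not self.data.index.is_unique:
            raise ValueError("duplicate sample ids")
        if "severity" not in self.data.columns:
            self.data = self.data.assign(severity=np.nan)

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def diagnosis(self) -> pd.Series:
        return self.data["diagnosis"]

    @property
    def severity(self) -> pd.Series:
        return self.data["severity"]

    def groups(self) -> list[str]:
        return sorted(self.data["diagnosis"].unique().tolist())

    def aligned_to(self, matrix: ProteinMatrix) -> "SampleTable":
        """Reorder rows to the matrix columns; error on mismatch."""
        missing = matrix.sample_ids.difference(self.data.index)
        if len(missing):
            raise ValueError(f"samples absent from table: {missing.tolist()}")
        return SampleTable(self.data.loc[matrix.sample_ids])


@dataclass(frozen=True)
class MarkerPanel:
    """A named cell type and its marker gene symbols."""

    cell_type: str
    markers: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.markers) == 0:
            raise ValueError(f"panel {self.cell_type!r} has no markers")
        if len(set(self.markers)) != len(self.markers):
            raise ValueError(f"panel {self.cell_type!r} has duplicate markers")


class GeneSetCollection(Mapping[str, frozenset]):
    """Named gene sets (e.g. GO or KEGG pathways) keyed by set name."""

    def __init__(self, sets: Mapping[str, Sequence[str]], source: str = "custom"):
        self._sets: dict[str, frozenset] = {}
        for name, members in sets.items():
            if name in self._sets:
                raise ValueError(f"duplicate set name {name!r}")
            self._sets[name] = frozenset(members)
        self.source = source

    def __getitem__(self, name: str) -> frozenset:
        return self._sets[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def subset(self, names: Sequence[str]) -> "GeneSetCollection":
        return GeneSetCollection({n: self._sets[n] for n in names}, self.source)

    def restrict_to(self, universe: Sequence[str]) -> "GeneSetCollection":
        uni = frozenset(universe)
        return GeneSetCollection(
            {n: s & uni for n, s in self._sets.items()}, self.source
        )


@dataclass
class RunConfig:
    """Pipeline-wide thresholds, seed and paths.

    Defaults follow the analysis conventions for this pipeline: significance
    at FDR < 0.05, proteins missing in more than 25% of samples removed,
    covariate-selection loop stops at |r| < 0.2 against the first surrogate
    variable, gene sets merged until no Cohen's kappa exceeds 0.4.
    """

    fdr_alpha: float = 0.05
    missing_fraction: float = 0.25
    sv_corr_max: float = 0.2
    kappa_max: float = 0.4
    seed: int = 0
    #: batch QC only flags; removal happens in orchestration when enabled.
    #: Mild pool effects stay (they are model-adjusted); only extreme
    #: separations (p below batch_exclude_p) are dropped.
    exclude_flagged_batches: bool = True
    batch_exclude_p: float = 1e-8
    covariates: tuple[str, ...] = ("age", "sex", "batch")
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_alpha < 1.0:
            raise ValueError("fdr_alpha must lie in (0, 1)")
        if not 0.0 <= self.missing_fraction <= 1.0:
            raise ValueError("missing_fraction must lie in [0, 1]")

    def hash(self) -> str:
        """Stable digest of the configuration, stamped on result tables."""
        payload = {
            "fdr_alpha": self.fdr_alpha,
            "missing_fraction": self.missing_fraction,
            "sv_corr_max": self.sv_corr_max,
            "kappa_max": self.kappa_max,
            "seed": self.seed,
            "covariates": list(self.covariates),
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
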