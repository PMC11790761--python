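"""Readers and writers for the pipeline's tabular formats.

Matrices travel as wide TSV (first column accession, header row sample ids),
sample metadata as CSV/TSV, gene sets as GMT, configuration as YAML. All
writers emit deterministic, byte-stable output so that two runs with the
same configuration produce identical files.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .containers import (
    Confidence,
    GeneSetCollection,
    MarkerPanel,
    ProteinMatrix,
    RunConfig,
    SampleTable,
)

log = logging.getLogger("proteodpe")

#: Tokens treated as a missing cell in wide TSV matrices (case-insensitive).
NA_TOKENS = frozenset({"", "na", "nan"})


def _is_na(token: str) -> bool:
    return token.strip().lower() in NA_TOKENS


def read_protein_matrix(
    path: str | Path,
    dialect: str = "wide_tsv",
    gene_symbols: pd.Series | None = None,
    confidence: pd.Series | None = None,
) -> ProteinMatrix:
    """Parse a wide TSV protein intensity matrix.

    The first column holds protein accessions, the header row sample ids.
    Empty cells and the tokens NA/NaN (any case) are recorded in the missing
    mask; values are returned untransformed. Duplicate accessions and
    non-numeric cells are hard errors.
    """
    if dialect != "wide_tsv":
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        sample_ids = header[1:]
        accessions: list[str] = []
        rows: list[list[float]] = []
        masks: list[list[bool]] = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            acc = fields[0]
            vals, mask = [], []
            for col, tok in zip(sample_ids, fields[1:]):
                if _is_na(tok):
                    vals.append(np.nan)
                    mask.append(True)
                else:
                    try:
                        vals.append(float(tok))
                    except ValueError:
                        raise ValueError(
                            f"non-numeric cell at row {acc!r} (line {lineno}), "
                            f"column {col!r}: {tok!r}"
                        ) from None
                    mask.append(False)
            accessions.append(acc)
            rows.append(vals)
            masks.append(mask)
    index = pd.Index(accessions, name="accession")
    if not index.is_unique:
        dups = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate protein accessions: {dups}")
    values = pd.DataFrame(rows, index=index, columns=sample_ids, dtype=float)
    missing = pd.DataFrame(masks, index=index, columns=sample_ids, dtype=bool)
    if gene_symbols is None:
        gene_symbols = pd.Series(index.to_numpy(), index=index, name="gene_symbol")
    if confidence is None:
        confidence = pd.Series(Confidence.HIGH, index=index, name="confidence")
    return ProteinMatrix(values, missing, gene_symbols, confidence)


def write_protein_matrix(matrix: ProteinMatrix, path: str | Path) -> None:
    """Write a matrix as wide TSV; masked cells become ``NA``."""
    path = Path(path)
    out = matrix.values.copy()
    with path.open("w", encoding="utf-8") as fh:
        fh.write("accession\t" + "\t".join(map(str, out.columns)) + "\n")
        arr = out.to_numpy()
        mask = matrix.missing_mask.to_numpy()
        for i, acc in enumerate(out.index):
            cells = [
                "NA" if mask[i, j] else repr(float(arr[i, j]))
                for j in range(arr.shape[1])
            ]
            fh.write(str(acc) + "\t" + "\t".join(cells) + "\n")


def read_sample_table(path: str | Path) -> SampleTable:
    """Read sample metadata (TSV or CSV by extension), sample_id as index."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    return SampleTable(df)


def write_sample_table(samples: SampleTable, path: str | Path) -> None:
    samples.data.to_csv(path, sep="\t", index_label="sample_id")


def read_marker_panels(path: str | Path) -> list[MarkerPanel]:
    """Read marker panels from a two-column TSV: cell_type, gene symbol."""
    df = pd.read_csv(path, sep="\t")
    panels = []
    for cell_type, grp in df.groupby(df.columns[0], sort=True):
        markers = tuple(dict.fromkeys(grp[df.columns[1]].astype(str)))
        panels.append(MarkerPanel(str(cell_type), markers))
    return panels


def write_marker_panels(panels: Sequence[MarkerPanel], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("cell_type\tgene_symbol\n")
        for panel in panels:
            for m in panel.markers:
                fh.write(f"{panel.cell_type}\t{m}\n")


def read_gmt(path: str | Path, source: str = "custom") -> GeneSetCollection:
    """Parse a GMT file: per line ``name<TAB>description<TAB>member...``.

    The description field is discarded (logged for provenance). Duplicate
    members within a line are deduplicated with a warning; a line with fewer
    than three fields is an error naming the line number.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    n_lines = 0
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path.name}:{lineno}: GMT line needs >= 3 fields, "
                    f"got {len(fields)}"
                )
            name, desc, members = fields[0], fields[1], fields[2:]
            members = [m for m in members if m]
            deduped = list(dict.fromkeys(members))
            if len(deduped) != len(members):
                log.warning(
                    "GMT set %s: %d duplicate members removed",
                    name,
                    len(members) - len(deduped),
                )
            log.debug("GMT set %s description: %s", name, desc)
            sets[name] = deduped
            n_lines += 1
    if n_lines == 0:
        log.warning("GMT file %s is empty", path)
    return GeneSetCollection(sets, source=source)


def write_gmt(sets: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for name in sorted(sets):
            members = sorted(sets[name])
            fh.write(name + "\t" + sets.source + "\t" + "\t".join(members) + "\n")


def write_table(
    table: pd.DataFrame,
    path: str | Path,
    sort_by: Sequence[str] | None = None,
    config: RunConfig | None = None,
) -> None:
    """Write a result table as tab-separated UTF-8 with deterministic order.

    Rows are sorted by ``sort_by`` (ties broken by the full remaining column
    order, then index) so repeated runs are byte-identical. Floats use
    ``repr`` round-trip precision. A config hash comment is prepended when a
    RunConfig is supplied.
    """
    path = Path(path)
    out = table.copy()
    if sort_by:
        out = out.sort_values(list(sort_by), kind="mergesort")
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        if config is not None:
            fh.write(f"# config_hash={config.hash()}\n")
        # %.17g guarantees float round-trip at full double precision
        out.to_csv(fh, sep="\t", index=False, lineterminator="\n",
                   float_format="%.17g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#",
                       float_precision="round_trip")


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from YAML; unknown keys go to ``paths``."""
    with Path(path).open("r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    known = {"fdr_alpha", "missing_fraction", "sv_corr_max", "kappa_max", "seed"}
    kwargs = {k: raw[k] for k in known if k in raw}
    if "covariates" in raw:
        kwargs["covariates"] = tuple(raw["covariates"])
    kwargs["paths"] = {k: v for k, v in raw.items() if k not in known | {"covariates"}}
    return RunConfig(**kwargs)
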