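import numpy as np
import pandas as pd
import pytest

from proteodpe import preprocess as pre
from proteodpe.containers import ProteinMatrix, SampleTable
from proteodpe.deconvolution import estimate_all_panels
from proteodpe.simulate import SimConfig, simulate_cohort


def make_matrix(values, sample_ids=None, accessions=None, symbols=None,
                confidence="high", mask=None):
    """Build a ProteinMatrix from a plain 2-D array for unit tests."""
    values = np.asarray(values, dtype=float)
    p, n = values.shape
    accessions = pd.Index(
        accessions if accessions is not None else [f"P{i:04d}" for i in range(p)],
        name="accession",
    )
    sample_ids = sample_ids if sample_ids is not None else [f"S{j}" for j in range(n)]
    if mask is None:
        mask = np.isnan(values)
    vals = values.copy()
    vals[np.asarray(mask, dtype=bool)] = np.nan
    symbols = pd.Series(
        symbols if symbols is not None else accessions.to_numpy(),
        index=accessions, name="gene_symbol",
    )
    conf = pd.Series(
        confidence if not np.isscalar(confidence) else [confidence] * p,
        index=accessions, name="confidence",
    )
    return ProteinMatrix(
        pd.DataFrame(vals, index=accessions, columns=sample_ids),
        pd.DataFrame(np.asarray(mask, dtype=bool), index=accessions,
                     columns=sample_ids),
        symbols,
        conf,
    )


def make_samples(n, groups=None, batches=2, seed=0, severity=None):
    rng = np.random.default_rng(seed)
    groups = groups if groups is not None else ["control"] * (n // 2) + [
        "disease_1"
    ] * (n - n // 2)
    data = pd.DataFrame(
        {
            "diagnosis": groups,
            "age": rng.normal(75, 8, n),
            "sex": rng.choice(["F", "M"], n),
            "batch": [f"pool{i % batches + 1}" for i in range(n)],
            "severity": severity if severity is not None else np.nan,
        },
        index=pd.Index([f"S{j}" for j in range(n)], name="sample_id"),
    )
    return SampleTable(data)


SMALL_SIM = SimConfig(
    n_per_group={"control": 20, "disease_1": 20, "disease_2": 8, "disease_3": 8},
    n_proteins=1500,
    markers_per_type=20,
    outlier_batch=False,
    n_batches=3,
    seed=7,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort shared by unit tests (no outlier batch)."""
    return simulate_cohort(SMALL_SIM)


@pytest.fixture(scope="session")
def small_imputed(small_cohort):
    matrix, samples, panels, sets, truth = small_cohort
    filtered, _ = pre.filter_proteins(matrix)
    imputed = pre.impute_lls(filtered)
    return imputed, samples, panels, sets, truth


@pytest.fixture(scope="session")
def small_cells(small_imputed):
    imputed, samples, panels, _, truth = small_imputed
    return estimate_all_panels(imputed, panels)
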