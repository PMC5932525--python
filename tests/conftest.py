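import numpy as np
import pandas as pd
import pytest

from itraqpipe import (
    BatchDesign,
    GeneratorParams,
    ReporterTable,
    assemble_matrix,
    generate_cohort,
    generate_design,
    normalize_batch,
)


@pytest.fixture(scope="session")
def design36() -> BatchDesign:
    """The study's template: 6 batches x 6 channels, 2 per group per batch."""
    return generate_design(6, 6, ("G1", "G2", "Ctrl"), seed=1)


@pytest.fixture(scope="session")
def design6() -> BatchDesign:
    """Single-batch 6-channel design."""
    return generate_design(1, 6, ("G1", "G2", "Ctrl"), seed=0)


@pytest.fixture(scope="session")
def small_cohort(design36):
    """300-protein cohort at the default study conditions, plus truth."""
    params = GeneratorParams(n_proteins=300, seed=11)
    tables, truth = generate_cohort(design36, params)
    return tables, truth


@pytest.fixture(scope="session")
def small_matrix(design36, small_cohort):
    tables, _ = small_cohort
    return assemble_matrix([normalize_batch(t) for t in tables], design36)


def make_table(batch: str, rows: dict, channels) -> ReporterTable:
    """Build a ReporterTable from {protein: [intensities]}."""
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(channels))
    df.index.name = "protein_id"
    return ReporterTable(batch, df.astype(float))


def matrix_from(arr, proteins, samples) -> pd.DataFrame:
    m = pd.DataFrame(np.asarray(arr, dtype=float), index=proteins, columns=samples)
    m.index.name = "protein_id"
    m.columns.name = "sample_id"
    return m
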