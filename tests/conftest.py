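import numpy as np
import pandas as pd
import pytest

from asciteome.containers import ExpressionMatrix, Layer, SampleAnnotation
from asciteome.synthetic import CohortConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_matrix(values, genes=None, samples=None, layer=Layer.LFQ):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), layer)


def make_annotation(samples, cell_types, assay="proteome", patients=None):
    patients = patients or [f"P{i}" for i in range(len(samples))]
    return SampleAnnotation(pd.DataFrame({
        "sample_id": samples,
        "patient_id": patients,
        "cell_type": cell_types,
        "assay": assay if isinstance(assay, list) else [assay] * len(samples),
    }))


@pytest.fixture(scope="session")
def small_cohort():
    """Small but complete cohort exercising every planted structure."""
    cfg = CohortConfig(n_patients=10, n_genes=1500, seed=42,
                       n_membrane_receptor=120, n_secreted=200,
                       n_growth_factor=100, n_orphan_ligand=10,
                       n_selective_per_type=25,
                       surrogate_block_sizes=(10, 9),
                       n_planted_tu_positive=12, n_planted_tu_negative=4)
    return generate_cohort(cfg)
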