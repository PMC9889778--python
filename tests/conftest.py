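import numpy as np
import pandas as pd
import pytest

from fibroscape.containers import CellMatrix
from fibroscape.synthetic import CellTypeSpec, CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def two_type_cohort() -> CellMatrix:
    """Small fibroblast/mural cohort with planted 20-gene signatures."""
    cfg = CohortConfig(
        n_patients=6,
        cells_per_patient=150,
        n_genes=800,
        cell_type_spec=[
            CellTypeSpec("fibroblast", 0.6, 20, 1.5),
            CellTypeSpec("mural", 0.4, 20, 1.5),
        ],
        batch_sd=0.0,
        seed=101,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def three_type_cohort() -> CellMatrix:
    """12-sample cohort with three planted subpopulations (log2FC 2)."""
    cfg = CohortConfig(
        n_patients=12,
        cells_per_patient=200,
        n_genes=1200,
        batch_sd=0.0,
        cell_type_spec=[
            CellTypeSpec("adventitial", 0.4, 25, 2.0),
            CellTypeSpec("alveolar", 0.35, 25, 2.0),
            CellTypeSpec("myofibroblast", 0.25, 25, 2.0),
        ],
        seed=202,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def tiny_matrix() -> CellMatrix:
    """Deterministic 10-gene x 5-cell matrix for arithmetic oracles."""
    rng = np.random.default_rng(7)
    counts = rng.poisson(20.0, size=(10, 5))
    return CellMatrix(
        counts=counts,
        genes=[f"g{i}" for i in range(10)],
        cell_meta=pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(5)],
                "patient_id": ["p0"] * 5,
                "sample_id": ["p0"] * 5,
            }
        ),
    )
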