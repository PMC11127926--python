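import numpy as np
import pytest

from prscohort.io import CohortTable, GenotypeMatrix, PRSModel, PRSModelVariant
from prscohort.simulate import SimulationConfig, simulate_study


@pytest.fixture
def small_matrix():
    """4 samples x 3 variants with one missing genotype."""
    dosage = np.array(
        [
            [0.0, 1.0, 2.0],
            [1.0, 0.0, 0.0],
            [2.0, np.nan, 1.0],
            [0.0, 2.0, 0.0],
        ]
    )
    return GenotypeMatrix(
        sample_ids=["s1", "s2", "s3", "s4"],
        variant_keys=[("1", 100, "A", "G"), ("1", 200, "C", "T"), ("2", 50, "G", "A")],
        dosage=dosage,
    )


@pytest.fixture
def two_variant_model():
    return PRSModel(
        "toy",
        [
            PRSModelVariant("1", 100, "G", "A", 0.5),
            PRSModelVariant("1", 200, "C", "T", -0.2),
        ],
    )


@pytest.fixture
def pheno_frame():
    import pandas as pd

    def make(n_case=4, n_control=6, site="breast"):
        rows = []
        for i in range(n_case):
            rows.append((f"case_{i}", "case", site, "female", 60.0, "alive", 3.0))
        for i in range(n_control):
            rows.append((f"ctrl_{i}", "control", site, "male", 62.0, "deceased", 1.5))
        return CohortTable(
            pd.DataFrame(
                rows,
                columns=[
                    "sample_id",
                    "cohort",
                    "organ_site",
                    "sex",
                    "age",
                    "vital_status",
                    "survival_years",
                ],
            )
        )

    return make


@pytest.fixture(scope="session")
def small_study():
    """A complete seeded synthetic study, sized for fast tests."""
    cfg = SimulationConfig(
        seed=11, n_case=40, n_control=160, n_variants=30, pool_size=1600
    )
    return simulate_study(cfg)
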