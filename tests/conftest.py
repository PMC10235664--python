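import numpy as np
import pandas as pd
import pytest

from protnet import ProteinMatrix, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cohort():
    """Compact cohort with two recoverable modules and phenotypes."""
    cfg = simulate.SimulationConfig(
        n_subjects=400,
        n_analytes=40,
        module_spec=[simulate.ModuleSpec(12), simulate.ModuleSpec(10)],
        planted_effects=[],
        status_factor_effect=0.0,
        missing_rate_range=(0.0, 0.05),
        lod_censor_rate=0.02,
        seed=7,
    )
    proteins, pheno, truth = simulate.generate_cohort(cfg)
    proteins = simulate.inject_missingness(proteins, cfg)
    return cfg, proteins, pheno, truth


def make_matrix(values: np.ndarray, stage: str = "raw", prefix: str = "A") -> ProteinMatrix:
    """Wrap a plain array as a ProteinMatrix with generated IDs."""
    n, p = values.shape
    return ProteinMatrix(
        values=pd.DataFrame(
            values,
            index=pd.Index([f"S{i:04d}" for i in range(n)], name="subject_id"),
            columns=pd.Index([f"{prefix}{j:03d}" for j in range(p)], name="analyte"),
        ),
        stage=stage,
    )
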