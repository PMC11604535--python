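import numpy as np
import pandas as pd
import pytest

from risi.io import ExpressionMatrix
from risi.preprocess import preprocess_pipeline
from risi.scoring import score_cohort
from risi.simulate import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """600-gene, 40/40/40 synthetic cohort with ground truth and weights."""
    cfg = GeneratorConfig(
        n_genes=600,
        n_per_condition={"healthy": 40, "moderate_infection": 40, "sepsis": 40},
        seed=11,
    )
    bundle, truth, w_rt, w_si = generate_cohort(cfg)
    return bundle, truth, w_rt, w_si


@pytest.fixture(scope="session")
def small_scored(small_cohort):
    """Preprocessed matrix and per-sample levels for the small cohort."""
    bundle, truth, w_rt, w_si = small_cohort
    Z, _ = preprocess_pipeline(bundle.expression, bundle.samples.control_ids)
    levels = score_cohort(Z, w_rt, w_si, control_ids=bundle.samples.control_ids)
    return Z, levels


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_matrix(values, genes=None, samples=None, scale="standardized"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), scale)
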