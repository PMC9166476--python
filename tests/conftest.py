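import numpy as np
import pandas as pd
import pytest

from statepert.gem_io import ExpressionMatrix
from statepert import synthetic


@pytest.fixture
def tiny_gem() -> ExpressionMatrix:
    """3 genes × 2 samples, no missing values."""
    return ExpressionMatrix(pd.DataFrame(
        [[1.0, 2.0], [3.0, 4.0], [8.0, 16.0]],
        index=["gA", "gB", "gC"], columns=["s1", "s2"]))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


STUDY_SEEDS = (1, 2, 3, 4, 5)


@pytest.fixture(scope="session")
def study_runs(tmp_path_factory):
    """Five full pipeline runs at study scale (6 classes, 2000 genes,
    40 train + 10 held-out per class), one per seed.

    Shared by every test that checks a property of the trained
    perturbation system; generating these dominates suite runtime.
    """
    from statepert.pipeline import RunConfig, run_pipeline

    runs = []
    for seed in STUDY_SEEDS:
        out = tmp_path_factory.mktemp(f"study_seed{seed}")
        cfg = RunConfig(seed=seed, output_dir=str(out),
                        cohort=synthetic.CohortConfig(seed=seed),
                        make_plots=False)
        runs.append(run_pipeline(cfg))
    return runs


@pytest.fixture(scope="session")
def small_cohort():
    """Fast cohort for unit tests: 400 genes, 15+5 samples per class."""
    cfg = synthetic.CohortConfig(n_genes=400, n_train_per_class=15,
                                 n_heldout_per_class=5,
                                 n_shared_effect_genes=10,
                                 n_stage_specific_genes=10,
                                 n_batch_genes=30, seed=7)
    gem, labels, truth = synthetic.generate_cohort(cfg)
    return cfg, gem, labels, truth
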