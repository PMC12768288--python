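import numpy as np
import pytest

from seedstack import synthetic
from seedstack.pipeline import RunConfig


@pytest.fixture(scope="session")
def small_spec():
    """3 varieties × 30 seeds; full grid; default separation."""
    return synthetic.default_spec(seed=11, n_classes=3, n_per_class=30)


@pytest.fixture(scope="session")
def small_tables(small_spec):
    return synthetic.generate_multimodal(small_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def tiny_run_config(tmp_path):
    """A structurally complete but cheap pipeline configuration."""
    return RunConfig(
        synthetic_params=dict(n_classes=3, n_per_class=30),
        cars_runs=8,
        cars_components=5,
        cars_cv_folds=3,
        koa_population=4,
        koa_iterations=3,
        families=("DT", "KNN", "SVM"),
        stacking_folds=3,
        seed=5,
        out_dir=str(tmp_path / "run"),
    )
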