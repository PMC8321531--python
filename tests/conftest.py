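import pytest

from redpred import RedundancyModel, syndata


def small_model(trios, gene_table, **kwargs):
    """Reduced-size model configuration used across the suite: 8 balanced
    replicates, 5-fold out-of-fold scoring, fixed SVM C=1 (no grid search).
    The selection size stays at the protocol default of 200 and is clamped to
    the candidate pool of the compact synthetic feature schema."""
    defaults = dict(
        definition="RD9",
        algorithm="svm",
        n_replicates=8,
        cv_folds=5,
        grid={"C": [1.0]},
    )
    defaults.update(kwargs)
    return RedundancyModel(trios, gene_table, **defaults)


@pytest.fixture(scope="session")
def benchmark():
    """Default synthetic benchmark: 300 trios, 190:110 balance, strong
    planted effects, zero emission noise."""
    return syndata.generate_benchmark(seed=7)


@pytest.fixture(scope="session")
def fitted(benchmark):
    """A fitted reduced-size inclusive-redundancy model on the benchmark."""
    trios, gene_table, _ = benchmark
    return small_model(trios, gene_table).fit(seed=7)
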