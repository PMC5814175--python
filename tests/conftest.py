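import numpy as np
import pytest

from cyclederg import (
    ExpressionDataset,
    GeneSet,
    PanCancerSimConfig,
    simulate_pancancer,
)


@pytest.fixture
def tiny_dataset() -> ExpressionDataset:
    """3 genes x 4 samples across two cohorts, one NA."""
    values = np.array(
        [
            [1.0, 3.0, 2.0, 4.0],
            [1.0, 2.0, 10.0, 10.0],
            [5.0, 5.0, np.nan, 6.0],
        ]
    )
    return ExpressionDataset(
        gene_ids=["CDK1", "CDK4", "ACTB"],
        sample_ids=["s1", "s2", "s3", "s4"],
        values=values,
        cohort_of={"s1": "A", "s2": "A", "s3": "B", "s4": "B"},
    )


@pytest.fixture
def small_sim():
    """One simulated cohort with a known 1.0 log2 shift on a 20-gene set."""
    cfg = PanCancerSimConfig(
        n_cohorts=1,
        genes_per_matrix=400,
        samples_per_cohort=40,
        set_size=40,
        delta=1.0,
        seed=11,
    )
    return simulate_pancancer(cfg)


@pytest.fixture
def cc_set() -> GeneSet:
    return GeneSet("CC", "toy cell-cycle set", frozenset({"CDK1", "CDK4"}))
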