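import pandas as pd
import pytest

from agenet import CohortConfig, ExpressionMatrix, RunConfig, SampleMetadata


@pytest.fixture
def run_config():
    return RunConfig()


@pytest.fixture
def tiny_tpm():
    """3 genes x 4 samples, all well above the expression filter."""
    data = pd.DataFrame(
        [[10.0, 20.0, 30.0, 40.0],
         [11.0, 22.0, 33.0, 44.0],
         [40.0, 30.0, 20.0, 10.0]],
        index=["gA", "gB", "gC"], columns=["s1", "s2", "s3", "s4"])
    return ExpressionMatrix(data, "tpm")


@pytest.fixture
def tiny_meta():
    return SampleMetadata(pd.DataFrame({
        "sample_id": ["s1", "s2", "s3", "s4"],
        "group": ["young", "young", "aging", "aging"],
        "tissue": ["t0"] * 4,
        "batch": ["b1", "b2", "b1", "b2"],
    }))


@pytest.fixture
def module_cohort():
    """One tissue with a 20-gene module whose connectivity collapses with
    age, on a 40-gene background; no mean shifts."""
    cfg = CohortConfig(n_genes=60, n_tissues=1, n_young=40, n_aging=40,
                       n_de_genes=0, de_log2fc=0.0,
                       module_sizes=(20,), loading_young=(0.9,),
                       loading_aging=(0.0,), seed=7)
    from agenet import generate_tissue
    return cfg, generate_tissue(cfg, 0)


def null_cohort_config(n_genes=200, per_group=30, seed=0):
    return CohortConfig(n_genes=n_genes, n_tissues=1, n_young=per_group,
                        n_aging=per_group, n_de_genes=0, de_log2fc=0.0,
                        module_sizes=(), loading_young=(), loading_aging=(),
                        seed=seed)
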