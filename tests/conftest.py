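import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ccons.io import OtuTable
from ccons.pipeline import run_conservatism
from ccons.simulate import SyntheticConfig, make_dataset

settings.register_profile("default", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("default")


def make_table(counts, projects=None, envs=None, level="99", child_to_parent=None):
    """Build an OtuTable from a dict sample_id -> {otu: count}."""
    sample_ids = list(counts)
    otu_ids = sorted({o for row in counts.values() for o in row})
    mat = np.zeros((len(sample_ids), len(otu_ids)), dtype=np.int64)
    for i, s in enumerate(sample_ids):
        for o, c in counts[s].items():
            mat[i, otu_ids.index(o)] = c
    meta = pd.DataFrame(
        {
            "project_id": [
                (projects or {}).get(s, f"proj_{s}") for s in sample_ids
            ],
            "env_keywords": [[] for _ in sample_ids],
            "environments": [
                frozenset((envs or {}).get(s, ())) for s in sample_ids
            ],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return OtuTable(mat, sample_ids, otu_ids, level=level, meta=meta,
                    child_to_parent=child_to_parent)


@pytest.fixture(scope="session")
def small_dataset():
    """A modest planted-conservatism dataset shared across read-only tests."""
    config = SyntheticConfig(seed=0, n_otus=120, n_samples=500, n_projects=15)
    return make_dataset(config)


@pytest.fixture(scope="session")
def small_result(small_dataset):
    """Pipeline output on the small dataset (windows may be None at this size)."""
    return run_conservatism(small_dataset, n_pairs=600, max_comparisons=150, seed=0)
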