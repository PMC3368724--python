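import numpy as np
import pytest

from synthmap.segdata import DatasetMeta, GameteMatrix


def make_matrix(loci, calls, dataset_id="ds1", group="LG01", groups=None, N=None):
    calls = np.asarray(calls, dtype=np.int8)
    n = calls.shape[1]
    meta = DatasetMeta(dataset_id=dataset_id, N=N or n)
    return GameteMatrix(
        dataset=meta,
        loci=list(loci),
        groups=list(groups) if groups is not None else [group] * len(loci),
        calls=calls,
        individuals=[f"{dataset_id}_i{j}" for j in range(n)],
    )


@pytest.fixture
def tiny_matrix():
    """3 loci x 4 gametes, one linkage group, no missing calls."""
    return make_matrix(
        ["A", "B", "C"],
        [[0, 0, 1, 1], [0, 0, 1, 1], [0, 1, 1, 0]],
    )


@pytest.fixture
def true_map_small():
    from synthmap.simfix import simulate_true_map
    return simulate_true_map(n_groups=2, markers_per_group=10, length_cM=100.0, seed=7)
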