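import numpy as np
import pytest

from msapkit import MsapDataset, SampleMeta


def make_dataset(states_by_sample: dict[str, list[int]], meta: dict[str, tuple] | None = None):
    """Build a small MsapDataset from per-sample state-rank lists.

    ``meta`` maps sample_id -> (genotype, condition, timepoint_das); defaults
    to a single-genotype control series.
    """
    lanes_by_rank = np.array([[1, 1], [1, 0], [0, 1], [0, 0]], dtype=np.uint8)
    sample_ids = list(states_by_sample)
    n_loci = len(next(iter(states_by_sample.values())))
    samples = []
    for i, sid in enumerate(sample_ids):
        if meta and sid in meta:
            genotype, condition, das = meta[sid]
        else:
            genotype, condition, das = "G1", "control", 4 + i
        samples.append(
            SampleMeta(sample_id=sid, genotype=genotype, condition=condition, timepoint_das=das)
        )
    presence = np.stack(
        [lanes_by_rank[np.asarray(states_by_sample[sid])] for sid in sample_ids], axis=1
    )
    return MsapDataset(
        locus_ids=[f"L{i}" for i in range(n_loci)], samples=samples, presence=presence
    )


@pytest.fixture
def random_dataset():
    """300-locus two-sample dataset with uniformly random states (seeded)."""
    rng = np.random.default_rng(1234)
    states = {
        "s_before": rng.integers(0, 4, size=300).tolist(),
        "s_after": rng.integers(0, 4, size=300).tolist(),
    }
    return make_dataset(states)
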