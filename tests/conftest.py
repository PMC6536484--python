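import numpy as np
import pandas as pd
import pytest

import polyband as pb


def boolean_cover(intervals, length: int) -> np.ndarray:
    """Base-resolution membership oracle for interval operations."""
    mask = np.zeros(length, dtype=bool)
    for s, e in intervals:
        mask[s:e] = True
    return mask


def random_intervals(rng, n, length, max_len=500):
    starts = rng.integers(0, length - 1, n)
    ends = np.minimum(length, starts + rng.integers(1, max_len, n))
    return list(zip(starts.tolist(), ends.tolist()))


def frame(chrom, pairs, **extra):
    df = pd.DataFrame({"chrom": chrom, "start": [s for s, _ in pairs],
                       "end": [e for _, e in pairs]})
    for k, v in extra.items():
        df[k] = v
    return df


@pytest.fixture(scope="session")
def sim_default():
    """Default synthetic genome + features, seed 1 (session-cached)."""
    cfg = pb.SimConfig(seed=1)
    genome = pb.simulate_genome(cfg)
    features = pb.simulate_features(cfg, genome)
    return cfg, genome, features


@pytest.fixture(scope="session")
def segmented_default(sim_default):
    cfg, genome, features = sim_default
    domains = genome.domains()
    target = domains[domains["chrom"] == cfg.target_chrom].reset_index(drop=True)
    structures = pb.segment(target)
    return domains, structures
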