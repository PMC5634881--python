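import numpy as np
import pandas as pd
import pytest

from riberflow.containers import CountMatrix
from riberflow.simulate import SimConfig, simulate_rip_counts


@pytest.fixture(scope="session")
def default_cfg() -> SimConfig:
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def rip_dataset(default_cfg):
    """One simulated RIP experiment shared across read-only tests."""
    return simulate_rip_counts(default_cfg)


@pytest.fixture()
def tiny_matrix() -> CountMatrix:
    """Six-sample IP/input matrix with hand-sized counts."""
    counts = pd.DataFrame(
        {
            "ip_r1": [800, 40, 12, 0],
            "ip_r2": [820, 38, 9, 0],
            "ip_r3": [790, 41, 11, 0],
            "in_r1": [100, 40, 10, 0],
            "in_r2": [105, 42, 12, 0],
            "in_r3": [95, 39, 8, 0],
        },
        index=pd.Index(["g_big", "g_flat", "g_low", "g_zero"], name="feature_id"),
    )
    design = pd.DataFrame(
        {
            "cell_line": ["case"] * 6,
            "fraction": ["IP"] * 3 + ["input"] * 3,
            "condition": ["steady"] * 6,
            "replicate": [1, 2, 3, 1, 2, 3],
        },
        index=counts.columns,
    )
    return CountMatrix(counts, design)


def random_intervals(rng: np.random.Generator, n: int, chroms: dict, prefix: str,
                     max_len: int = 300) -> pd.DataFrame:
    names = list(chroms)
    rows = []
    for i in range(n):
        c = names[rng.integers(0, len(names))]
        length = int(rng.integers(10, max_len))
        start = int(rng.integers(0, chroms[c] - length))
        rows.append((c, start, start + length, f"{prefix}_{i}", 0, "."))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
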