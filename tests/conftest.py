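import numpy as np
import pandas as pd
import pytest

from nucscore import PipelineConfig, SimulationDesign, simulate_experiment


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_experiment(config):
    """One modest simulated assay shared by read-only tests."""
    return simulate_experiment(
        config, SimulationDesign(n_mrna=30, n_trna=10), n_chrom=2,
        chrom_length=60_000, depth=40, gc_beta=0.5, seed=7,
    )


def make_window_frame(counts: dict[str, list[int]], start_step: int = 25) -> pd.DataFrame:
    """Hand-built window table from per-sample count lists."""
    n = len(next(iter(counts.values())))
    df = pd.DataFrame(
        {
            "chrom": "chrI",
            "start": np.arange(n) * start_step,
            "end": np.arange(n) * start_step + 167,
            "gc": 0.5,
            "tract_bp": 0,
        }
    )
    for col, vals in counts.items():
        df[col] = vals
    return df
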