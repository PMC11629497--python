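import pandas as pd
import pytest
from hypothesis import settings

from solcurate import synthetic_data as sd

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from solcurate.standardize import standardize_table


@pytest.fixture(scope="session")
def universe():
    """Fifty distinct organic molecules, fixed seed."""
    return sd.generate_universe(50, seed=7)


@pytest.fixture(scope="session")
def truth(universe):
    return sd.build_ground_truth(universe)


@pytest.fixture(scope="session")
def duplicated_compilation(universe, truth):
    """Two sources sharing molecules, 30% representation-variant duplicates.

    Returns (standardized tables dict, generation log)."""
    specs = [
        sd.SourceSpec("src1", 300, noise_sd=0.4, dup_fraction=0.30, frac_inorganic=0.02),
        sd.SourceSpec("src2", 200, noise_sd=0.6, bias=0.2, dup_fraction=0.10),
    ]
    tables, log = sd.generate_sources(universe, truth, specs, seed=11)
    std = {name: standardize_table(df) for name, df in tables.items()}
    return std, log


def prediction_table(errors, weights=None):
    """Build a minimal prediction table with the given signed errors."""
    n = len(errors)
    return pd.DataFrame(
        {
            "record_id": [f"r{i}" for i in range(n)],
            "y_pred": [float(e) for e in errors],
            "y_obs": [0.0] * n,
            "weight": list(weights) if weights is not None else [1.0] * n,
            "fold": [0] * n,
        }
    )
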