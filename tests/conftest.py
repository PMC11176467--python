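import numpy as np
import pandas as pd
import pytest

from mrmediate import HarmonizedDataset
from mrmediate.gwas_io import STANDARD_ROLES


@pytest.fixture
def toy3() -> HarmonizedDataset:
    """Three strong instruments with mild heterogeneity."""
    return HarmonizedDataset.from_arrays(
        beta_exposure=[0.1, 0.2, 0.15],
        se_exposure=[0.005, 0.005, 0.01],
        beta_outcome=[0.05, 0.08, 0.09],
        se_outcome=[0.01, 0.01, 0.02],
    )


@pytest.fixture
def toy4() -> HarmonizedDataset:
    """Four instruments, enough for Egger and PRESSO minimums."""
    return HarmonizedDataset.from_arrays(
        beta_exposure=[0.1, 0.2, 0.15, 0.12],
        se_exposure=[0.005, 0.005, 0.01, 0.008],
        beta_outcome=[0.05, 0.08, 0.09, 0.06],
        se_outcome=[0.01, 0.01, 0.02, 0.015],
    )


def make_summary_frame(rows: list[dict]) -> pd.DataFrame:
    """Build a standard summary-statistics frame from partial row dicts."""
    defaults = {
        "chr": "1",
        "pos": 1_000_000,
        "ea": "A",
        "oa": "G",
        "eaf": 0.3,
        "beta": 0.1,
        "se": 0.01,
        "pval": 1e-10,
        "n": 100_000,
    }
    filled = []
    for i, row in enumerate(rows):
        merged = {"snp": f"rs{i + 1}", **defaults, **row}
        filled.append(merged)
    if not filled:
        return pd.DataFrame(columns=list(STANDARD_ROLES))
    return pd.DataFrame(filled)[list(STANDARD_ROLES)]


@pytest.fixture
def summary_frame_factory():
    return make_summary_frame


def noiseless_dataset(theta: float, j: int = 5) -> HarmonizedDataset:
    """Instruments with exactly proportional effects (tiny SEs, no noise)."""
    gamma = np.linspace(0.05, 0.2, j)
    return HarmonizedDataset.from_arrays(
        beta_exposure=gamma,
        se_exposure=np.full(j, 1e-6),
        beta_outcome=theta * gamma,
        se_outcome=np.full(j, 1e-6),
    )


@pytest.fixture
def noiseless_factory():
    return noiseless_dataset
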