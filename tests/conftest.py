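import logging

import numpy as np
import pandas as pd
import pytest

from ridephysio.segmentation import RideLayout

logging.getLogger("ridephysio").setLevel(logging.ERROR)


@pytest.fixture
def layout180() -> RideLayout:
    return RideLayout(total_duration=180.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_cell_table(
    rng: np.random.Generator,
    n: int = 6,
    a_levels=("human", "selfdriving"),
    b_levels=("smooth", "deer", "kid"),
    subject_sd: float = 1.0,
    noise_sd: float = 1.0,
    cond_effect: float = 0.0,
) -> pd.DataFrame:
    """Random long-format cell table for ANOVA tests."""
    rows = []
    for s in range(n):
        icpt = rng.normal(0, subject_sd)
        for i, a in enumerate(a_levels):
            shift = cond_effect * (0.5 if i == 0 else -0.5)
            for b in b_levels:
                rows.append(
                    {
                        "subject": f"S{s}",
                        "condition": a,
                        "event": b,
                        "value": icpt + shift + rng.normal(0, noise_sd),
                    }
                )
    return pd.DataFrame(rows)
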