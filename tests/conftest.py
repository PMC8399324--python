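import numpy as np
import pandas as pd
import pytest

from embryocm import synthetic as syn
from embryocm.config import RunConfig


@pytest.fixture(scope="session")
def run_config() -> RunConfig:
    return RunConfig(seed=7)


@pytest.fixture(scope="session")
def small_bundle() -> syn.SyntheticBundle:
    """A compact cohort with two shift and two qualitative planted effects."""
    planted = (
        syn.PlantedEffect("F0001", {"cryo": "frozen", "culture": "BSA"},
                          mode="shift", log2_effect=2.5, direction=-1),
        syn.PlantedEffect("F0002", {"cryo": "frozen", "culture": "FCS"},
                          mode="qualitative", direction=-1),
        syn.PlantedEffect("F0003", {"cryo": "fresh"},
                          mode="shift", log2_effect=2.5, direction=1),
        syn.PlantedEffect("F0004", {}, mode="qualitative", direction=1),
    )
    cfg = syn.GeneratorConfig(seed=7, n_features=30, planted=planted)
    return syn.generate_cohort(cfg)


@pytest.fixture(scope="session")
def toy_samples() -> pd.DataFrame:
    """A hand-sized annotation sheet for block-enumeration oracles."""
    rng = np.random.default_rng(11)
    rows = []
    for i in range(24):
        rows.append(
            {
                "sample_id": f"S{i:02d}",
                "cryo": "fresh" if i < 10 else "frozen",
                "breed": "AV" if i % 2 else "H",
                "culture": "BSA" if i % 3 else "FCS",
                "bull": f"bull{i % 3 + 1}",
                "stage0h": ["M", "EB", "B"][i % 3],
                "stage24h": ["ExB", "FEB"][i % 2],
                "age": 7,
                "D40": int(rng.random() < 0.5),
            }
        )
    df = pd.DataFrame(rows)
    df["D62"] = df["D40"]
    df["Birth"] = (df["D62"] & (np.arange(len(df)) % 2 == 0)).astype(int)
    return df
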