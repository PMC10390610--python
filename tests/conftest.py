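import numpy as np
import pandas as pd
import pytest

from varmeta.meta_regression import MetaDataset
from varmeta.synthetic_data import ArmLevelSimConfig, simulate_meta_dataset


def make_dataset(rows: list[dict]) -> MetaDataset:
    """Build a MetaDataset from explicit per-arm dicts, filling derived
    columns (weight, log_mean, lnsd_bc) from n / mean_pct / sd_pct."""
    df = pd.DataFrame(rows)
    if "weight" not in df:
        df["weight"] = 2.0 * df["n"] - 1.0
    if "log_mean" not in df:
        df["log_mean"] = np.log(df["mean_pct"].astype(float))
    if "lnsd_bc" not in df:
        df["lnsd_bc"] = np.log(df["sd_pct"].astype(float)) + 1.0 / df["weight"]
    if "drug_class" not in df:
        df["drug_class"] = np.where(df["treatment"] == "placebo", "placebo", "other")
    if "arm_id" not in df:
        df["arm_id"] = [f"a{i}" for i in range(len(df))]
    return MetaDataset(frame=df)


@pytest.fixture(scope="session")
def small_dataset() -> MetaDataset:
    """A fixed 3-trial, 7-arm dataset with hand-written values, small
    enough for dense-matrix oracle fits."""
    rows = [
        dict(trial_id="A", treatment="placebo", n=40, mean_pct=8.1, sd_pct=1.20),
        dict(trial_id="A", treatment="verum", n=45, mean_pct=7.2, sd_pct=1.05),
        dict(trial_id="A", treatment="verum", n=50, mean_pct=7.0, sd_pct=1.30),
        dict(trial_id="B", treatment="placebo", n=80, mean_pct=8.4, sd_pct=0.90),
        dict(trial_id="B", treatment="verum", n=85, mean_pct=7.6, sd_pct=1.10),
        dict(trial_id="C", treatment="placebo", n=25, mean_pct=7.9, sd_pct=1.40),
        dict(trial_id="C", treatment="verum", n=30, mean_pct=7.1, sd_pct=1.55),
    ]
    return make_dataset(rows)


@pytest.fixture(scope="session")
def medium_dataset() -> MetaDataset:
    """A reproducible 10-trial simulated dataset for oracle comparisons."""
    return simulate_meta_dataset(ArmLevelSimConfig(n_trials=10, seed=42))


@pytest.fixture(scope="session")
def paper_scale_dataset() -> MetaDataset:
    """One dataset at the default study-design scale (174 trials)."""
    return simulate_meta_dataset(ArmLevelSimConfig(seed=20251001 % 2**31))
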