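import numpy as np
import pandas as pd
import pytest

from metacog.observer_sim import CohortSpec, ObserverParams


@pytest.fixture(scope="session")
def tiny_cohort_spec() -> CohortSpec:
    """A fast 2-groups-of-4 cohort for pipeline wiring tests."""
    return CohortSpec(
        n_per_group=4,
        group_params={
            "placebo": ObserverParams(p_miss=0.0, p_fast=0.0),
            "propranolol": ObserverParams(sigma_meta=0.25, p_miss=0.0, p_fast=0.0),
        },
        n_trials=48,
        n_blocks=4,
        seed=11,
    )


def make_trials(
    n: int,
    subject_id: str = "s1",
    group: str = "placebo",
    block: int = 2,
    rt: float = 500.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Hand-constructable trial table with the canonical columns."""
    rng = rng or np.random.default_rng(0)
    stim = rng.choice(["left", "right"], size=n)
    resp = np.where(rng.uniform(size=n) < 0.75, stim, np.where(stim == "left", "right", "left"))
    conf = rng.uniform(size=n)
    return pd.DataFrame(
        {
            "subject_id": subject_id,
            "group": group,
            "block": block,
            "trial": np.arange(1, n + 1),
            "variance_condition": 20.0,
            "mean_orientation_deg": 7.0,
            "stimulus_direction": stim,
            "response": resp,
            "correct": (resp == stim).astype(float),
            "rt_ms": rt,
            "confidence": conf,
            "confidence_start": 0.5,
            "confidence_bin": pd.array([pd.NA] * n, dtype="Int64"),
        }
    )
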