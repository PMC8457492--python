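import numpy as np
import pandas as pd
import pytest

from speedcontours.design import DesignConfig, build_design


@pytest.fixture(scope="session")
def default_config() -> DesignConfig:
    return DesignConfig()


@pytest.fixture(scope="session")
def default_design(default_config) -> pd.DataFrame:
    return build_design(default_config)


def make_trials(angle_deg: float, magnitudes, reps: int = 1, condition: str | None = None) -> pd.DataFrame:
    """Minimal trial table: one orientation, given level magnitudes."""
    from speedcontours.design import cue_offsets, label_condition

    condition = condition or label_condition(angle_deg)
    rows = []
    for m in magnitudes:
        w_t, w_d = cue_offsets(angle_deg, m)
        for _ in range(reps):
            rows.append(("S1", angle_deg, condition, m, w_t, w_d))
    return pd.DataFrame(
        rows,
        columns=["subject_id", "orientation_deg", "condition", "magnitude",
                 "w_duration", "w_distance"],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)
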