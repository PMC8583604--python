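import numpy as np
import pandas as pd
import pytest

from twovisit.cohort import PowerDesignConfig, generate_power_dataset


@pytest.fixture
def balanced_two_period():
    """Tiny complete balanced dataset with a hand-computable interaction.

    Reference arm changes +2 per subject, the other arm +5, so the
    difference of group mean changes is exactly 3.
    """
    rows = []
    values = {
        ("A", 1): (10, 12),
        ("A", 2): (14, 16),
        ("B", 3): (20, 25),
        ("B", 4): (22, 27),
    }
    for (grp, sid), (y0, y1) in values.items():
        rows.append({"subject_id": sid, "group": "PDTA" if grp == "A" else "PDTA_CAD", "visit": "baseline", "time": 0, "y": y0})
        rows.append({"subject_id": sid, "group": "PDTA" if grp == "A" else "PDTA_CAD", "visit": "followup", "time": 1, "y": y1})
    return pd.DataFrame(rows)


@pytest.fixture
def power_dataset():
    return generate_power_dataset(PowerDesignConfig(seed=123))


def design_from(df):
    """Full-model design matrix (time, group, interaction) from a power table."""
    t = df["time"].to_numpy(dtype=float)
    g = df["cad"].to_numpy(dtype=float)
    return np.column_stack([t, g, t * g])
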