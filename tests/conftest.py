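import math

import numpy as np
import pandas as pd
import pytest

from leachflux import BudgetConstants


@pytest.fixture
def constants() -> BudgetConstants:
    return BudgetConstants()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20250919)


def make_treatment_table(groups: dict[float, np.ndarray]) -> pd.DataFrame:
    """Assemble a long-format treatment table from {dilution: responses}."""
    rows = []
    for dose, values in groups.items():
        for i, v in enumerate(values, start=1):
            rows.append(
                {
                    "treatment": "control" if dose == 0 else "leachate",
                    "dilution_pct": dose,
                    "replicate": i,
                    "response": float(v),
                }
            )
    return pd.DataFrame(rows)


def biomass_ug_ml(cells_per_ml: float, esd_um: float) -> float:
    """Independent biomass oracle: sphere volume, 0.123 pg/µm³, pg -> µg."""
    volume = math.pi / 6.0 * esd_um**3
    return cells_per_ml * 0.123 * volume * 1e-6
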