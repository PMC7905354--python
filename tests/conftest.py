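import numpy as np
import pandas as pd
import pytest

from ccdiet.core_data import PhenotypeTable
from ccdiet.synthetic_data import cc22_config, simulate_study, tiny_config


@pytest.fixture(scope="session")
def tiny_table():
    table, _ = simulate_study(tiny_config(11))
    return table


@pytest.fixture(scope="session")
def cc22_table():
    table, truth = simulate_study(cc22_config(11))
    return table, truth


@pytest.fixture(scope="session")
def null_calibration_500():
    """Shared null-simulation run for type-I rate and p-uniformity checks."""
    from ccdiet.pipeline import mixed_model_null_calibration

    return mixed_model_null_calibration(n_reps=500, seed=20)


def make_table(rows) -> PhenotypeTable:
    """Build a PhenotypeTable from minimal row dicts, defaulting design columns."""
    defaults = {
        "batch": 1, "cage_baseline": "B1", "cage_randomized": "R1",
        "timepoint": "baseline", "diet": "AIN76A", "trait": "y", "units": "au",
    }
    full = []
    for i, row in enumerate(rows):
        r = dict(defaults)
        r.setdefault("mouse_id", f"m{i}")
        r.update(row)
        full.append(r)
    df = pd.DataFrame(full)
    cols = ["mouse_id", "strain", "diet", "batch", "cage_baseline",
            "cage_randomized", "timepoint", "trait", "value", "units"]
    return PhenotypeTable(df[cols])


def one_way_table(groups: dict[str, list[float]], timepoint="baseline") -> PhenotypeTable:
    """One-way strain layout: {strain: values} with all nuisance factors constant."""
    rows = []
    i = 0
    for strain, values in groups.items():
        for v in values:
            rows.append({"mouse_id": f"m{i}", "strain": strain, "value": float(v),
                         "timepoint": timepoint,
                         "diet": "AIN76A" if timepoint == "baseline" else "HP"})
            i += 1
    return make_table(rows)


def balanced_layout(rng: np.random.Generator, a: int, n: int,
                    var_strain: float = 1.0, var_resid: float = 1.0):
    """Balanced one-way normal layout; returns (table, values-by-strain)."""
    groups = {}
    for s in range(a):
        mu = rng.normal(0, np.sqrt(var_strain))
        groups[f"S{s:02d}"] = (mu + rng.normal(0, np.sqrt(var_resid), n)).tolist()
    return one_way_table(groups), groups
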