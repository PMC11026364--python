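import numpy as np
import pandas as pd
import pytest

from tracequant import SimConfig, profile_cohort, simulate_tracing_cohort
from tracequant.io import apply_inclusion_rules


@pytest.fixture(scope="session")
def default_cohort():
    """One default 40-mouse synthetic tracing cohort, filtered and profiled."""
    cfg = SimConfig()
    records, metas = simulate_tracing_cohort(cfg, seed=7)
    records, metas, _ = apply_inclusion_rules(records, metas)
    profiles = profile_cohort(records, metas)
    return {"config": cfg, "records": records, "metas": metas, "profiles": profiles}


@pytest.fixture()
def section_csv(tmp_path):
    """A tiny well-formed section table on disk."""
    path = tmp_path / "sections.csv"
    pd.DataFrame({
        "mouse_id": ["m1", "m1", "m1", "m2", "m2"],
        "ap_mm": [-2.8, -3.4, -3.5, -2.8, -3.4],
        "region": ["CA1_py", "SUB", "Vis cortex", "CA1_py", "SUB"],
        "n_input": [120, 20, 10, 50, 5],
        "n_starter": [0, 4, 0, 0, 2],
    }).to_csv(path, index=False)
    return path


@pytest.fixture()
def mouse_csv(tmp_path):
    path = tmp_path / "mice.csv"
    pd.DataFrame({
        "mouse_id": ["m1", "m2"],
        "genotype": ["WT", "5xFAD"],
        "age_group": ["young", "middle"],
        "sex": ["F", "M"],
    }).to_csv(path, index=False)
    return path
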