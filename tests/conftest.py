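import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from dux4kit import CtTable, GuideStrand, guide_from_target_site
from dux4kit.reference import HUMAN_TARGET_SITE

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def human_guide() -> GuideStrand:
    """Guide fully complementary to the printed human DUX4 target site."""
    return guide_from_target_site(HUMAN_TARGET_SITE, "siDUX4.6")


def make_ct_table(
    treated_targets, mock_targets, treated_hk, mock_hk, n_reps=1
) -> CtTable:
    """Build a small Ct table with 4 target and 2 housekeeping genes."""
    genes = ["T1", "T2", "T3", "T4", "H1", "H2"]
    rows, samples, cond = [], [], []
    for r in range(n_reps):
        rows.append(list(mock_targets) + list(mock_hk))
        samples.append(f"mock_{r}")
        cond.append("mock")
        rows.append(list(treated_targets) + list(treated_hk))
        samples.append(f"treated_{r}")
        cond.append("treated")
    ct = pd.DataFrame(rows, index=samples, columns=genes, dtype=float)
    condition = pd.Series(cond, index=samples)
    return CtTable(ct=ct, condition=condition, group=condition.rename("group"))
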