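import numpy as np
import pandas as pd
import pytest

from urbanbear import BearSpec, SimConfig, SeasonCalendar


@pytest.fixture(scope="session")
def calendar():
    return SeasonCalendar()


@pytest.fixture(scope="session")
def small_config():
    """One-bear-scale simulation config used across modules (coarse fixes)."""
    return SimConfig(seed=11, fix_interval_min=120, extent_km=10.0)


@pytest.fixture(scope="session")
def two_year_bear():
    """A bear monitored through one good and one poor food year."""
    return BearSpec(bear_id="B00", gender="F", age=5,
                    years_monitored=[(2008, "good"), (2009, "poor")])


def simulate_lmm_table(rng, n_bears=60, gender_eff=1.26, sd_re=0.5, sd_eps=0.8):
    """Random-intercept data with a bear-level gender effect on the response.

    Effect size and noise follow the ln(home-range-area) scale: gender
    contrast 1.26 with residual SD < 1.
    """
    rows = []
    for i in range(n_bears):
        g = "M" if i % 2 else "F"
        u = rng.normal(0.0, sd_re)
        for season in ("pre_hyperphagia", "hyperphagia"):
            fy = "good" if rng.random() < 0.6 else "poor"
            rows.append(dict(
                bear_id=f"b{i}", gender=g, age=int(rng.integers(1, 12)),
                season=season, foodyr=fy,
                y=1.47 + gender_eff * (g == "M") + u + rng.normal(0.0, sd_eps)))
    return pd.DataFrame(rows)
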