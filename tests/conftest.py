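import numpy as np
import pytest

from movecomp.simulate import GeneratorConfig


#: Published central compositions (min per 600-min day) used as fixed inputs.
WINDOW_MINUTES = {
    "week": (559.72, 6.57, 33.71),
    "weekend": (586.80, 4.60, 8.60),
    "four_day": (570.99, 5.78, 23.23),
}


@pytest.fixture
def rng():
    return np.random.default_rng(20160602)


@pytest.fixture
def small_config():
    """Default study conditions at a small cohort size for fast tests."""
    return GeneratorConfig(n_participants=40, seed=7)


@pytest.fixture
def default_config():
    return GeneratorConfig(seed=7)


def build_planted_profiles():
    """10 synthetic participants with 3 planted inclusion-rule violations.

    P03 keeps only 2 valid days, P06 has valid weekdays but no valid
    weekend day, P09 never reaches 6 h of wear; the other 7 qualify.
    """
    import pandas as pd
    from datetime import date

    def row(pid, day, wear_h):
        wear = wear_h * 60.0
        return {
            "participant_id": pid,
            "date": day,
            "day_type": "weekend" if day.weekday() >= 5 else "weekday",
            "wear_min": wear,
            "sb_min": wear * 0.9,
            "lpa_min": wear * 0.02,
            "mvpa_min": wear * 0.08,
        }

    days = [date(2016, 6, d) for d in (2, 3, 4, 5)]  # Thu, Fri, Sat, Sun
    rows = []
    for i in range(1, 11):
        pid = f"P{i:02d}"
        for j, day in enumerate(days):
            wear_h = 10.0
            if pid == "P03" and j >= 2:
                wear_h = 4.0
            if pid == "P06" and day.weekday() >= 5:
                wear_h = 3.0
            if pid == "P09":
                wear_h = 5.5
            rows.append(row(pid, day, wear_h))
    rows.append(row("P06", date(2016, 6, 6), 10.0))
    rows.append(row("P06", date(2016, 6, 7), 10.0))
    return pd.DataFrame(rows)


def null_composition_config(n: int, seed: int) -> GeneratorConfig:
    """Default conditions but with no composition effect on any outcome."""
    cfg = GeneratorConfig(n_participants=n, seed=seed)
    for name, beta in cfg.true_beta.items():
        beta = np.asarray(beta, float).copy()
        beta[1:3] = 0.0
        cfg.true_beta[name] = beta
    return cfg
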