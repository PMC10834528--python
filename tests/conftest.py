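import numpy as np
import pandas as pd
import pytest

from uplift_rct import CohortSchema, CohortTable


def make_cohort(arms, successes, features=None, schema=None, event_times=None):
    """Build a minimal cohort from aligned arm/success vectors (+ optional features)."""
    n = len(arms)
    successes = np.asarray(successes, dtype=int)
    rng = np.random.default_rng(0)
    if event_times is None:
        event_times = np.where(successes == 1, 12.0, 6.0 + 0.01 * np.arange(n))
    df = pd.DataFrame(
        {
            "subject_id": [f"P{i}" for i in range(n)],
            "registration_order": np.arange(1, n + 1),
            "arm": list(arms),
            "success": successes,
            "event_time": event_times,
            "event_indicator": 1 - successes,
        }
    )
    if features:
        for name, vals in features.items():
            df[name] = vals
    if schema is None:
        cont = tuple(k for k, v in (features or {}).items()
                     if np.issubdtype(np.asarray(v).dtype, np.number))
        cat = tuple(k for k in (features or {}) if k not in cont)
        schema = CohortSchema(continuous=cont, categorical=cat)
    return CohortTable(df, schema)


@pytest.fixture
def small_trial():
    """A 40-subject separable fixture: one feature drives success in both arms."""
    rng = np.random.default_rng(42)
    n = 40
    arms = (["treatment", "control"] * (n // 2))
    x = rng.normal(size=n)
    # treated subjects with x>0 succeed; controls with x>0 fail -> z perfectly separated by x
    succ = [(1 if xi > 0 else 0) if a == "treatment" else (0 if xi > 0 else 1)
            for xi, a in zip(x, arms)]
    return make_cohort(arms, succ, features={"x": x})
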