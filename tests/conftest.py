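import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_participant_table(
    n: int,
    n_events: int,
    seed: int = 0,
    n_treated: int | None = None,
    horizon: float = 7.0,
) -> pd.DataFrame:
    """Small hand-rolled participant table: ``n_events`` events at random
    times before the horizon, the rest administratively censored."""
    rng = np.random.default_rng(seed)
    event = np.zeros(n, dtype=int)
    event[rng.permutation(n)[:n_events]] = 1
    time = np.where(event == 1, rng.uniform(0.5, horizon - 0.5, n), horizon)
    arm = np.full(n, "control", dtype=object)
    if n_treated is None:
        n_treated = n // 2
    arm[rng.permutation(n)[:n_treated]] = "treated"
    return pd.DataFrame(
        {
            "id": [f"P{i:05d}" for i in range(n)],
            "arm": arm,
            "event": event,
            "time": time,
            "age": rng.normal(74, 5, n),
            "frail": rng.binomial(1, 0.05, n),
            "sex": rng.choice(["F", "M"], size=n, p=[0.66, 0.34]),
        }
    )


@pytest.fixture(scope="session")
def graded_trial():
    """One moderate risk-graded simulated trial with latent truth."""
    from riskhte import ScenarioConfig, generate_trial

    return generate_trial(ScenarioConfig(n_participants=2000, effect_mode="risk_graded", seed=20))
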