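import numpy as np
import pytest

from tremorkit import SessionConfig, extract_windows, simulate_session


@pytest.fixture(scope="session")
def fs() -> float:
    return 50.0


@pytest.fixture(scope="session")
def small_session():
    """One short labelled session with all three severities represented.

    Boosted severity probabilities and a short bout length keep the session
    small while guaranteeing class coverage; the signal model itself is the
    default one.
    """
    cfg = SessionConfig(
        duration_s=1800.0,
        severity_stationary=(0.5, 0.3, 0.2),
        mean_bout_s=120.0,
        nodata_prob=0.0,
        seed=7,
    )
    rec, events, schedule = simulate_session(cfg, return_schedule=True)
    return cfg, rec, events, schedule


@pytest.fixture(scope="session")
def small_windows(small_session):
    _, rec, events, _ = small_session
    windows = extract_windows(rec, events)
    labels = np.array([w.label for w in windows])
    assert len(np.unique(labels)) == 3, "fixture must cover all severities"
    return windows
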