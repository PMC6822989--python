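import numpy as np
import pytest

from striaseq.config import AnalysisConfig
from striaseq.core_data import Session, Trial, Unit
from striaseq.synthetic_data import (
    early_cohort_spec,
    extended_cohort_spec,
    generate_session,
)
from striaseq import psth, units


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_trial(t0=100.0, presses=(1.0, 1.5, 2.0, 2.5, 3.0), pe_latency=1.0):
    """Rewarded ratio-5 trial with press times given relative to insertion."""
    press_times = [t0 + p for p in presses]
    retraction = press_times[-1] + 0.05
    return Trial(
        lever_insertion=t0,
        press_times=press_times,
        lever_retraction=retraction,
        reward_port_entry=retraction + pe_latency,
    )


@pytest.fixture
def trial():
    return make_trial()


@pytest.fixture(scope="session")
def small_session():
    """One small DT5 session with ground-truth archetypes (all types)."""
    spec = extended_cohort_spec(seed=7, n_units={"DLS": 14, "DMS": 14})
    return generate_session(spec, 0)


@pytest.fixture(scope="session")
def small_pems(small_session, config):
    units.screen_session(small_session, config)
    pems = [
        p
        for p in (
            psth.peri_event_matrix(u, small_session, config)
            for u in units.msns(small_session.units)
        )
        if p is not None
    ]
    assert pems
    return pems


@pytest.fixture(scope="session")
def taxonomy_cohort(config):
    """Mid-sized extended cohort for clustering tests (session-scoped: the
    generation plus peri-event normalization dominates test runtime)."""
    spec = extended_cohort_spec(seed=11, n_units={"DLS": 80, "DMS": 95})
    s = generate_session(spec, 99)
    units.screen_session(s, config)
    pems = [
        p
        for p in (psth.peri_event_matrix(u, s, config) for u in units.msns(s.units))
        if p is not None
    ]
    return s, pems
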