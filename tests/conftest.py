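"""Shared fixtures: synthetic sessions generated at test time.

The full-scale ``table3`` fixtures reproduce the committed study profile
(~2 h 20 min at 100 Hz); they are session-scoped because several evaluation
tests share them.  ``short_session`` is a cheap 10-minute session with the
same per-class signal model for unit-level checks.
"""

import pytest
from hypothesis import settings

import henactivity as ha

# property-based tests must be reproducible run to run
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def short_session():
    cfg = ha.table3_profile(seed=11, duration_s=600.0)
    return ha.simulate_session(cfg)


@pytest.fixture(scope="session")
def short_features(short_session):
    trace, track = short_session
    windows = ha.make_windows(trace, track, ha.WindowSpec(1.0, 0.5))
    return ha.build_feature_matrix(windows)


@pytest.fixture(scope="session")
def table3_session():
    return ha.simulate_session(ha.table3_profile(seed=7))


@pytest.fixture(scope="session")
def table3_features(table3_session):
    trace, track = table3_session
    return {
        w: ha.build_feature_matrix(
            ha.make_windows(trace, track, ha.WindowSpec(w, 0.5))
        )
        for w in (1.0, 4.0)
    }
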