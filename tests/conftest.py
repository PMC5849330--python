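import pytest

from franciscana_availability import FilterConfig, filter_cycles, make_fixture
from franciscana_availability.records import DiveCycle, GroupSession


@pytest.fixture(scope="session")
def fixture_sessions():
    """The packaged 337-cycle / 120-group dataset."""
    return make_fixture()


@pytest.fixture(scope="session")
def filtered(fixture_sessions):
    """(kept sessions, exclusion report) after the default filter."""
    return filter_cycles(fixture_sessions, FilterConfig())


def make_session(
    group_id="G1",
    durations=((10.0, 30.0), (20.0, 40.0)),
    group_size=2,
    **kwargs,
):
    """Small hand-built session for unit tests."""
    defaults = dict(
        calves=False, depth_m=7.0, transparency_cm=110.0, tide_m=0.7
    )
    defaults.update(kwargs)
    cycles = tuple(
        DiveCycle(group_id=group_id, cycle_index=i + 1, surface_s=s, dive_s=d)
        for i, (s, d) in enumerate(durations)
    )
    return GroupSession(
        group_id=group_id, group_size=group_size, cycles=cycles, **defaults
    )
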