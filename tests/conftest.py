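import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fermflux as ff

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_bundle():
    """Matched kinetic trajectory + toy network + compound map."""
    return ff.generate_fermentation_fixture()


@pytest.fixture(scope="session")
def fixture_traj(fixture_bundle):
    return fixture_bundle[0]


@pytest.fixture(scope="session")
def toy_net():
    return ff.toy_network()


@pytest.fixture(scope="session")
def fixture_phases(fixture_traj):
    return ff.detect_phases(fixture_traj)


@pytest.fixture(scope="session")
def fixture_fluxes(fixture_bundle):
    traj, net, cmap = fixture_bundle
    return ff.run_dfba(traj, net, cmap, times=traj.times)


@pytest.fixture(scope="session")
def fixture_scores(fixture_fluxes, fixture_phases):
    return ff.compute_flux_scores(fixture_fluxes, fixture_phases)


@pytest.fixture()
def quiescent_state():
    """No sugars, no nitrogen: every state frozen except the regulator."""
    return ff.make_initial_state(XC=0.29, XP=0.59, XmRNA=0.12, Eth=5.0,
                                 Mal=2.0, GNS=0.0)


def make_flux_trajectory(times, series: dict, dw):
    """Hand-assembled FluxTrajectory for score tests."""
    times = np.asarray(times, dtype=float)
    rids = tuple(series)
    fluxes = np.column_stack([np.asarray(series[r], dtype=float) for r in rids])
    return ff.FluxTrajectory(
        times=times,
        fluxes=fluxes,
        objective_values=np.zeros(times.size),
        statuses=("optimal",) * times.size,
        dw=np.asarray(dw, dtype=float),
        reaction_ids=rids,
    )
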