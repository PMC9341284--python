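import pytest

from empathnet.ae_snn import EMOTIONS, TrainingSchedule, build_network, train


@pytest.fixture(scope="session")
def default_schedule():
    return TrainingSchedule()


@pytest.fixture(scope="session")
def trained():
    """Network trained for the full default schedule (100 epochs per emotion),
    together with its per-epoch weight trajectory.  Training is deterministic,
    so one instance serves every test that needs a converged network."""
    net = build_network()
    net, trajectory = train(net, EMOTIONS, TrainingSchedule())
    return net, trajectory


@pytest.fixture(scope="session")
def trained_net(trained):
    return trained[0]
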