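import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy2():
    """Hand-set 2-state / 2-observation / 1-action chain for oracle tests."""
    from coeruleus.mdp import DirichletParams, TaskModel

    A = np.array([[0.8, 0.3], [0.2, 0.7]])
    B = np.array([[0.9, 0.4], [0.1, 0.6]])[:, :, None]
    C = np.zeros(2)
    D = np.array([0.6, 0.4])
    model = TaskModel(A=A, B=B, C=C, D=D, policies=np.zeros((1, 2), int), horizon=3)
    counts = DirichletParams(
        a=np.ones((2, 2)), b=np.ones((2, 2, 1)), d=np.ones(2)
    )
    return model, counts


@pytest.fixture
def gonogo():
    from coeruleus.tasks import build_gonogo

    return build_gonogo(rng=np.random.default_rng(7))


@pytest.fixture
def bandit():
    from coeruleus.tasks import build_explore_exploit

    return build_explore_exploit(rng=np.random.default_rng(7))
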