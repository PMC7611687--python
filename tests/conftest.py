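import numpy as np
import pytest

from normgame import CommunityParams, LinearAttitudeModel


@pytest.fixture
def scenario1():
    """Homogeneous n=10 community with weak persuasion (severe dilemma)."""
    return CommunityParams.homogeneous(10), LinearAttitudeModel.homogeneous(10)


@pytest.fixture
def scenario2():
    """n=20 community with strong norm payoffs and cheap violence."""
    return (
        CommunityParams.homogeneous(20, s=1.5, c=0.4, norm=5.0),
        LinearAttitudeModel.homogeneous(20),
    )


def random_linear_instance(rng, n=None):
    """Random community + linear attitude model with log-uniform parameters
    in [0.2, 5] and tolerances uniform in [0, 0.9]."""
    if n is None:
        n = int(rng.integers(2, 7))

    def lu(size):
        return np.exp(rng.uniform(np.log(0.2), np.log(5.0), size=size))

    params = CommunityParams(
        n=n,
        s=lu(n),
        t=rng.uniform(0.0, 0.9, size=n),
        c=lu(n),
        N=lu((n, n)),
        D=lu((n, n)),
    )
    model = LinearAttitudeModel(intercepts=rng.uniform(0.5, 3.0, size=n), slopes=lu((n, n)) * 0.1)
    return params, model
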