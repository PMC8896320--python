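import numpy as np
import pytest

from pwmclust import PWM, PWMCollection

BASES = "ACGT"


def one_hot_pwm(name: str, consensus: str) -> PWM:
    """Exact one-hot PWM for an ACGT consensus string."""
    m = np.zeros((len(consensus), 4))
    for i, ch in enumerate(consensus):
        m[i, BASES.index(ch)] = 1.0
    return PWM(name, m)


def random_pwm(name: str, length: int, rng: np.random.Generator) -> PWM:
    """Random stochastic PWM with moderately sharp columns."""
    return PWM(name, np.vstack([rng.dirichlet([1, 1, 1, 1])
                                for _ in range(length)]))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def uniform_pwm():
    return PWM("uniform4", np.full((4, 4), 0.25))
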