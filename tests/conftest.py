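import numpy as np
import pytest

from markovcea import ModelConfig, PseudoIPD


@pytest.fixture
def case_config() -> ModelConfig:
    """The bundled case-study configuration (increased price)."""
    return ModelConfig()


@pytest.fixture
def exp_ipd() -> PseudoIPD:
    """Seeded exponential pseudo-IPD (rate 0.08/month) with admin censoring."""
    rng = np.random.default_rng(42)
    times = rng.exponential(1 / 0.08, 200)
    events = (times <= 30.0).astype(int)
    times = np.minimum(times, 30.0)
    return PseudoIPD(records=list(zip(times.tolist(), events.tolist())))


def rel_err(value: float, reference: float) -> float:
    return abs(value - reference) / abs(reference)
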