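import numpy as np
import pytest

from streamseg import ModelConfig
from streamseg.competition import PerceptTrace


@pytest.fixture(scope="session")
def model() -> ModelConfig:
    """Package-default model configuration."""
    return ModelConfig()


@pytest.fixture(scope="session")
def fast_model() -> ModelConfig:
    """Cheaper configuration for unit tests: coarser integration step.

    dt = 2 ms still satisfies dt < tau_u / 5 and resolves the tone
    envelope; it halves most simulation costs relative to the default.
    """
    base = ModelConfig()
    return base.with_(competition=base.competition.with_(dt=0.002))


def make_trace(segregated, dt=0.01) -> PerceptTrace:
    seg = np.asarray(segregated, dtype=np.uint8)
    return PerceptTrace(t=np.arange(len(seg)) * dt, segregated=seg)
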