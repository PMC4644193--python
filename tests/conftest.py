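import math

import numpy as np
import pytest

from fdfluor import FrequencyResponse, MultiExpModel, SampledSignal


@pytest.fixture
def fig5_mixture() -> MultiExpModel:
    """Two-component emitter: rates 1 and 1000, DC amplitude fractions 0.9/0.1."""
    return MultiExpModel([(0.9, 1.0), (0.1, 1e-3)])


def make_phase_curve(model: MultiExpModel, omega: np.ndarray, phase_sd=None) -> FrequencyResponse:
    """Noiseless phase/mod curve of a model, optionally tagged with sds."""
    f = model.fractions / model.fractions.sum()
    h = (f / (1.0 + 1j * np.multiply.outer(omega, model.lifetimes))).sum(axis=-1)
    return FrequencyResponse(
        frequencies=omega,
        phase_deg=-np.degrees(np.angle(h)),
        mod=np.abs(h),
        phase_sd=phase_sd,
    )


def sampled_square(omega: float, n_cycles: int, spc: int, low=0.0, high=2.0) -> SampledSignal:
    """Square wave with edges exactly on sample boundaries (high first)."""
    period = 2.0 * math.pi / omega
    idx = np.arange(n_cycles * spc)
    v = np.where(idx % spc < spc // 2, high, low)
    return SampledSignal(0.0, period / spc, v)
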