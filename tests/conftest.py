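import numpy as np
import pytest

from adaptbias import DesignSpec, Regime


RATIO_REGIMES = [Regime.FLEXIBLE, Regime.EQUAL, Regime.TRT_GE_CTRL]


def random_design(rng, regime=None) -> DesignSpec:
    """A random bounded/unbounded design for property tests."""
    if regime is None:
        options = RATIO_REGIMES + [Regime.FIXED_CONTROL]
        regime = options[int(rng.integers(len(options)))]
    r_min = float(rng.uniform(0.0, 2.0))
    r_max = float(np.inf if rng.random() < 0.3 else r_min + rng.uniform(0.0, 4.0))
    if regime == Regime.FIXED_CONTROL:
        r0 = float(rng.uniform(0.0, 2.0))
        return DesignSpec(regime=regime, r_min=0.0, r_max=max(r_max, r0), r0_fixed=r0)
    return DesignSpec(regime=regime, r_min=r_min, r_max=r_max)


@pytest.fixture
def rng():
    return np.random.default_rng(20151012)
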