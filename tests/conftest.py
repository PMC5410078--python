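import numpy as np
import pytest

from ivimdwi import BValueScheme, IVIMParams, MonoexpParams, biexp_signal


@pytest.fixture(scope="session")
def scheme() -> BValueScheme:
    return BValueScheme.study_scheme()


@pytest.fixture(scope="session")
def cancer_params() -> IVIMParams:
    """Generating means of the tumor population."""
    return IVIMParams(s0=100.0, f=0.42, adc_slow=0.84e-3, adc_fast=6.39e-3)


@pytest.fixture(scope="session")
def healthy_params() -> IVIMParams:
    """Generating means of the healthy-pancreas population (fast perfusion
    regime: the pseudo-diffusion exponential is nearly extinct by b=400)."""
    return IVIMParams(s0=100.0, f=0.39, adc_slow=0.92e-3, adc_fast=14.05e-3)


@pytest.fixture(scope="session")
def cancer_signal(scheme, cancer_params) -> np.ndarray:
    return biexp_signal(cancer_params, scheme.array)


@pytest.fixture(scope="session")
def healthy_signal(scheme, healthy_params) -> np.ndarray:
    return biexp_signal(healthy_params, scheme.array)


@pytest.fixture(scope="session")
def mono_params() -> MonoexpParams:
    return MonoexpParams(s0=100.0, adc_total=1.38e-3)
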