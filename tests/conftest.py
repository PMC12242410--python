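import pytest

from glycotube import bare_params, default_params, with_param


@pytest.fixture
def baseline():
    """Baseline conditions of the density/length landscape analyses:
    kappa=10 kBT, sigma=0.012 kBT/nm^2, lam=c0=f=0, N=20, a=10, v=a^3,
    R0=100 nm."""
    return bare_params()


@pytest.fixture
def table_defaults():
    """Full default parameter set (lam=0.5 kBT/nm, c0=0.02 nm^-1, f=1 kBT/nm)."""
    return default_params()


@pytest.fixture
def at_density(baseline):
    """Factory: baseline parameters at a given grafting density (nm^-2)."""

    def make(rho, **extra):
        p = with_param(baseline, "rho", rho)
        for k, v in extra.items():
            p = with_param(p, k, v)
        return p

    return make
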