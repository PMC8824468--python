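import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_trace(amplitudes, lifetimes, *, baseline=0.0, t_start=0.2, t_end=10.0,
               step=0.02, channel="cy3", noise_sigma=None, rng=None):
    """Synthesize a decay trace directly from the exponential model.

    Independent of the package's own generator: plain sum of
    exponentials, optionally with heteroscedastic Gaussian noise
    sigma_i = max(1e-4, noise_sigma * sqrt(I_i)).
    """
    from lretfit.decay import DecayTrace

    t = np.arange(t_start, t_end + step / 2, step)
    y = np.full_like(t, float(baseline))
    for a, tau in zip(amplitudes, lifetimes):
        y = y + a * np.exp(-t / tau)
    if noise_sigma:
        sigma = np.maximum(1e-4, noise_sigma * np.sqrt(np.abs(y)))
        y = y + (rng or np.random.default_rng(0)).normal(0.0, sigma)
    return DecayTrace(times=t, intensities=y, channel=channel, delay=t_start)


@pytest.fixture(scope="session")
def atp_truth():
    """Noiseless ground truth for the nucleotide-binding-domain construct,
    ATP condition (the worked-example study conditions)."""
    from lretfit.synthetic import reference_ground_truth

    return reference_ground_truth("NBD", ("ATP",))


@pytest.fixture(scope="session")
def toy_state_targets():
    """Inter-protomer probe targets for three toy conformers, taken from
    the bundled ATP-condition distances (closed / partially open / open)."""
    return {
        "closed": {(51, 51): 37.7, (13, 13): 35.4, (13, 51): 36.7},
        "partially_open": {(51, 51): 46.2, (13, 13): 51.0, (13, 51): 51.5},
        "open": {(51, 51): 78.0, (13, 13): 77.8, (13, 51): 79.7},
    }


@pytest.fixture(scope="session")
def toy_conformers(toy_state_targets):
    from lretfit.synthetic import build_toy_conformers

    return build_toy_conformers(toy_state_targets)
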