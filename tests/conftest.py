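import numpy as np
import pytest

from octatten import synthetic_data as sd


def flat_layers(**mu_overrides):
    """Layer stack with zero lateral variability and no foveal pit."""
    layers = {}
    for name, spec in sd._default_layers().items():
        mu = mu_overrides.get(name, spec.mu_per_um)
        layers[name] = sd.LayerSpec(spec.thickness_um, 0.0, mu, pit_depth_um=0.0)
    return layers


@pytest.fixture
def flat_noiseless_spec():
    """Deterministic phantom: flat layers, no speckle, reduced grid."""
    return sd.PhantomSpec.desk(layers=flat_layers(), noise_l=None, n_x=24, n_y=16)


@pytest.fixture
def pit_noiseless_spec():
    """Noiseless phantom with the default foveal pit and smooth thickness fields."""
    return sd.PhantomSpec.desk(noise_l=None)


@pytest.fixture
def small_cohort_metrics():
    return sd.simulate_cohort(sd.CohortSpec(), mode="metrics", seed=123)


def constant_mu_ascan(mu=0.001, n=2000, dz=2.62, alpha=0.1, i0=1e8):
    profile = np.full(n, mu)
    return sd.simulate_ascan(profile, alpha, i0, dz, noise_l=None), profile
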