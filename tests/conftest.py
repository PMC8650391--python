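import numpy as np
import pytest

from augresp.latent_model import LatentParameters
from augresp.synthetic_data import generate, muse_like_preset
from augresp.trial_data import EndpointSpec


@pytest.fixture(scope="session")
def preset():
    """(LatentParameters, EndpointSpec, baseline_law) of the built-in preset."""
    return muse_like_preset()


@pytest.fixture(scope="session")
def preset_data(preset):
    """One medium-sized dataset simulated from the preset."""
    params, spec, baseline_law = preset
    return generate(params, 250, baseline_law, seed=7)


@pytest.fixture(scope="session")
def preset_fit(preset, preset_data):
    from augresp.latent_model import fit_latent_model

    _, spec, _ = preset
    return fit_latent_model(preset_data, spec)


@pytest.fixture
def simple_spec():
    """One continuous + one binary component."""
    return EndpointSpec(n_cont=1, has_binary=True, thresholds=(0.0,))


@pytest.fixture
def simple_params():
    R = np.array([[1.0, -0.45], [-0.45, 1.0]])
    return LatentParameters(
        alpha=np.array([0.5]),
        beta=np.array([-0.8]),
        gamma=np.array([0.4]),
        sigma=np.array([1.3]),
        alpha_b=-0.2,
        beta_b=0.5,
        R=R,
    )


def random_correlation(rng, d=3, jitter=0.3):
    """Random positive-definite correlation matrix via a factor draw."""
    A = rng.standard_normal((d, d))
    C = A @ A.T + jitter * np.eye(d)
    s = np.sqrt(np.diag(C))
    R = C / np.outer(s, s)
    np.fill_diagonal(R, 1.0)
    return R
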