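import numpy as np
import pytest

import flexsome as fx
from flexsome.scattering import compute_pool_curves
from flexsome.synthetic import make_domain_templates, sphere_bead_cloud


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def dumbbell_pool():
    """Small pool of two-lobe protomers with flexible linkers."""
    r = np.random.default_rng(7)
    domains, blueprint = make_domain_templates("dumbbell", rng=r)
    models = [fx.build_protomer(blueprint, domains, r) for _ in range(60)]
    return fx.Pool.from_models(models, seed=7)


@pytest.fixture(scope="session")
def sphere_pool():
    """Pool of size-graded globules: every member has a distinct curve."""
    r = np.random.default_rng(3)
    models = [fx.ConformerModel(beads=sphere_bead_cloud(rad, 150, r))
              for rad in np.linspace(12, 60, 100)]
    return compute_pool_curves(fx.Pool.from_models(models, seed=3))


def random_cloud(radius, n, rng):
    """Uniform random (non-lattice) bead cloud in a sphere; smooth p(r)."""
    u = rng.random(n)
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v * (radius * u ** (1 / 3))[:, None]
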