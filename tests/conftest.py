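import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20140894)


def random_cloud_domain(n, rng, box=20.0, sequence=None):
    """Domain with uniformly random Cβ positions in a cube — for oracles."""
    from contactprop.structures_io import STANDARD_AA, Domain, Residue

    coords = rng.uniform(-box, box, size=(n, 3))
    if sequence is None:
        sequence = "".join(
            STANDARD_AA[k] for k in rng.integers(0, 20, n)
        )
    residues = [
        Residue(seq_index=i + 1, aa_type=sequence[i], cbeta=coords[i])
        for i in range(n)
    ]
    return Domain(domain_id=f"cloud{n}", residues=residues)


@pytest.fixture
def cloud_factory(rng):
    return lambda n, **kw: random_cloud_domain(n, rng, **kw)
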