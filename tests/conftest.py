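import numpy as np
import pytest

from petmr_hypoxia.geometry import GridGeometry
from petmr_hypoxia.phantom import PhantomSpec, generate_study


def small_phantom_spec(**overrides) -> PhantomSpec:
    """A compact phantom (40x40x30 @ 2x2x3 mm) that keeps tests fast while
    preserving every structural feature of the default study: shrinking
    tumour and nodal spheres, resolving hypoxic cores, NT reference sphere
    and an air background."""
    kwargs = dict(
        grid=GridGeometry.isotropic((40, 40, 30), (2.0, 2.0, 3.0)),
        body_center=(40.0, 40.0, 45.0), body_radius=34.0,
        tumour_center=(26.0, 28.0, 45.0), tumour_radii=(12.0, 10.0, 8.0),
        ln_center=(26.0, 56.0, 45.0), ln_radii=(9.0, 8.0, 6.0),
        hypoxic_radii=(6.0, 4.0, 0.0), ln_hypoxic_radii=(5.0, 3.0, 0.0),
        nt_center=(58.0, 26.0, 45.0), nt_radius=7.0,
        seed=7,
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    return small_phantom_spec()


@pytest.fixture(scope="session")
def small_study(small_spec):
    return generate_study(small_spec, patient_id="test-01")


@pytest.fixture(scope="session")
def noise_free_study():
    spec = small_phantom_spec(mri_noise_sigma=0.0, pet_noise_sigma=0.0)
    return generate_study(spec, patient_id="nf-01"), spec


@pytest.fixture()
def grid10() -> GridGeometry:
    return GridGeometry.isotropic((10, 10, 10))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
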