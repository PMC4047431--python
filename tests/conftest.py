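import numpy as np
import pytest

from irisid import (BoundaryConditions, GeometryConfig, OgdenParameters,
                    build_reference_geometry)
from irisid.datasets import reference_mean_parameters

#: fitted slope of the reference ACD-pressure series (mm/mmHg)
ACD_SLOPE = 0.004848459564646648


@pytest.fixture(scope="session")
def mean_params() -> OgdenParameters:
    return reference_mean_parameters()


@pytest.fixture(scope="session")
def coarse_geometry() -> GeometryConfig:
    """Very coarse geometry for unit tests that only need a working model."""
    return GeometryConfig(n_radial=8, n_thickness=2)


@pytest.fixture(scope="session")
def coarse_mesh(coarse_geometry):
    return build_reference_geometry(coarse_geometry)


@pytest.fixture(scope="session")
def default_mesh():
    return build_reference_geometry(GeometryConfig())


@pytest.fixture()
def lens_bc() -> BoundaryConditions:
    return BoundaryConditions(lens_translation=ACD_SLOPE)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250922)
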