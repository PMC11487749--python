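import warnings

import numpy as np
import pytest

from neogyri.gyrification import GIConfig, local_gi, outer_smoothed_surface
from neogyri.synthetic import CohortSpec, SurfaceSpec, generate_bumpy_sphere, generate_cohort

warnings.filterwarnings("ignore", message=".*optimal value found.*")


# Small-scale geometry used by the unit tests: 20 mm spheres with parameters
# scaled to match (closing 5 mm, ROI 8 mm at 1 mm voxels).
UNIT_GICFG = GIConfig(
    closing_radius=5.0, voxel_size=1.0, roi_radius=8.0, outer_vertex_stride=2
)


@pytest.fixture(scope="session")
def sphere20():
    return generate_bumpy_sphere(SurfaceSpec(base_radius=20.0, bump_amplitude=0.0,
                                             mesh_subdivisions=4))


@pytest.fixture(scope="session")
def bumpy20():
    return generate_bumpy_sphere(
        SurfaceSpec(base_radius=20.0, bump_amplitude=0.1, bump_frequency=6,
                    mesh_subdivisions=4)
    )


@pytest.fixture(scope="session")
def bumpy20_envelope(bumpy20):
    return outer_smoothed_surface(bumpy20, UNIT_GICFG)


@pytest.fixture(scope="session")
def bumpy20_lgi(bumpy20, bumpy20_envelope):
    return local_gi(bumpy20, bumpy20_envelope, UNIT_GICFG)


@pytest.fixture(scope="session")
def null_cohort():
    """400 reference subjects, no clinical group, no deficit."""
    return generate_cohort(CohortSpec(n_reference=400, n_clinical=0, seed=7))


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(CohortSpec(seed=0))
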