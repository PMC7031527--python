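import numpy as np
import pytest

from pemfdose import coil as cm
from pemfdose import phantom as ph
from pemfdose.tissues import TissueProperties


@pytest.fixture(scope="session")
def flat_coil():
    """Applicator-sized coil in the z=0 plane, centered at the origin."""
    frame = cm.CoilFrame(np.zeros(3), [1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0])
    return cm.CoilGeometry(frame)


@pytest.fixture(scope="session")
def small_head():
    """Coarse layered head used by several suites (cheap to build)."""
    return ph.build_layered_head(radius_mm=60.0,
                                 layers=(("skin", 4), ("skull", 7),
                                         ("csf", 3), ("grey", 10)),
                                 voxel_size_mm=2.5)


@pytest.fixture(scope="session")
def uniform_sphere_phantom():
    """Homogeneous conducting sphere (sigma = 0.1 S/m, radius 50 mm)."""
    props = TissueProperties("conductor", np.array([50.0, 7500.0]),
                             np.array([0.1, 0.1]), np.array([0.0, 0.0]))
    return ph.build_layered_head(radius_mm=50.0, layers=(), core="conductor",
                                 voxel_size_mm=2.0, tissue_table={7: props},
                                 name="uniform-sphere")


def uniform_bz_vector_potential(B_tesla, center_mm=(0.0, 0.0, 0.0)):
    """A-field callable for a uniform B along z: A = B x r / 2."""
    center = np.asarray(center_mm, dtype=float)

    def a_field(points_mm):
        r = (np.atleast_2d(points_mm) - center) * 1e-3
        Bv = np.array([0.0, 0.0, B_tesla])
        return 0.5 * np.cross(Bv, r)

    return a_field
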