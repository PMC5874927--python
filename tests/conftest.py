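import pytest

from dtspos.geometry import make_full_fan_geometry, select_arc
from dtspos.phantoms import PhantomSpec, make_cube_phantom, make_pelvis_phantom


@pytest.fixture(scope="session")
def tiny_geom():
    """Small odd-sized detector so the central pixel is exact."""
    return make_full_fan_geometry(
        20.0, 200.0, 75, detector=(65, 49, 4.0), sad_mm=1000.0, sdd_mm=1500.0
    )


@pytest.fixture(scope="session")
def small_cube():
    """50 mm water cube on a 64^3 / 2 mm grid."""
    return make_cube_phantom(
        PhantomSpec(kind="cube", shape=(64, 64, 64), voxel_mm=(2.0, 2.0, 2.0),
                    edge_mm=50.0)
    )


@pytest.fixture(scope="session")
def small_pelvis():
    return make_pelvis_phantom(
        PhantomSpec(kind="pelvis", shape=(64, 64, 64), voxel_mm=(2.0, 2.0, 2.0),
                    body_semiaxes_mm=(40.0, 45.0, 32.0))
    )


@pytest.fixture(scope="session")
def tiny_arc(tiny_geom):
    """Nine projections spanning ~43 deg around 0 deg."""
    arc = select_arc(tiny_geom, 0.0, 45.0)
    return arc.with_angles(arc.angles_deg[::2])
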