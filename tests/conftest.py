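import numpy as np
import pytest

from mrcvasc.partition import partition_nested, partition_subregions
from mrcvasc.roots import synthesize_roots
from mrcvasc.sdf import DistanceField, build_distance_field
from mrcvasc.surface import make_sphere_surface, make_synthetic_surface


@pytest.fixture(scope="session")
def sphere10():
    """Radius-10 mm icosphere fixture."""
    return make_sphere_surface(10.0, subdivisions=4)


@pytest.fixture(scope="session")
def sphere10_field(sphere10):
    return build_distance_field(sphere10, h=0.5, margin=3.0)


@pytest.fixture(scope="session")
def sphere20():
    return make_sphere_surface(20.0, subdivisions=4)


@pytest.fixture(scope="session")
def sphere20_field(sphere20):
    return build_distance_field(sphere20, h=0.5, margin=3.0)


@pytest.fixture(scope="session")
def flat_field():
    """A planar 'surface': ψ(x) = z on a coarse grid (Γ is the z = 0 plane).

    Handy for bifurcation-geometry tests where relocation must be a no-op.
    """
    n = 41
    h = 1.0
    origin = np.array([-20.0, -20.0, -20.0])
    z = origin[2] + h * np.arange(n)
    psi = np.broadcast_to(z, (n, n, n)).copy()
    return DistanceField(origin=origin, h=h, psi=psi)


@pytest.fixture(scope="session")
def small_run():
    """A small but complete two-level growth shared across tests.

    Smooth synthetic hemisphere pair at reduced resolution, 3000 terminals,
    100 LV1 subregions, 6+6 labelled roots.
    """
    from mrcvasc.growth import GrowthConfig, run_mrc

    surface = make_synthetic_surface(subdivisions=4)
    field = build_distance_field(surface, h=1.0, margin=3.0)
    lv1 = partition_subregions(surface, 100, 11)
    lv2 = partition_nested(surface, lv1, 10, 12)
    counts = {("artery", lab): 1 for lab in ("LACA", "LMCA", "LPCA", "RACA", "RMCA", "RPCA")}
    counts |= {("vein", f"V{i}"): 1 for i in range(6)}
    roots = synthesize_roots(surface, field, counts, 13, min_separation=12.0)
    config = GrowthConfig(
        n_terminals_total=3000, alpha=2.0, n_lv1_subregions=100, seed=5
    )
    forest = run_mrc(surface, field, lv1, lv2, roots, config)
    return {
        "surface": surface,
        "field": field,
        "lv1": lv1,
        "lv2": lv2,
        "roots": roots,
        "config": config,
        "forest": forest,
    }
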