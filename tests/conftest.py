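import numpy as np
import pytest

from heartnc.geometry_core import BinaryMask, SurfaceMesh, voxelize_on_grid
from heartnc.phantom import (
    HeartPhantomParams,
    ThoraxPhantomParams,
    generate_heart,
    generate_thorax_ct,
    thorax_grid,
    thorax_layout,
)
from heartnc.projection import render_drr

COARSE_CT_SPACING = (0.2, 0.2, 0.3)


def make_cube_mesh(side=1.0, origin=(0.0, 0.0, 0.0)):
    """Analytic closed unit-cube surface (12 triangles, outward-oriented)."""
    o = np.asarray(origin, dtype=float)
    v = o + side * np.array(
        [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
         [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]],
        dtype=float,
    )
    f = np.array(
        [[0, 2, 1], [0, 3, 2], [4, 5, 6], [4, 6, 7], [0, 1, 5], [0, 5, 4],
         [1, 2, 6], [1, 6, 5], [2, 3, 7], [2, 7, 6], [3, 0, 4], [3, 4, 7]]
    )
    return SurfaceMesh(v, f, name="cube")


@pytest.fixture
def cube_mesh():
    return make_cube_mesh()


@pytest.fixture
def cube_mask():
    g = np.zeros((14, 14, 14), dtype=bool)
    g[2:12, 2:12, 2:12] = True
    return BinaryMask(g, (0.1, 0.1, 0.1))


@pytest.fixture
def sphere_mesh():
    return generate_heart(HeartPhantomParams(semi_axes=(1.0, 1.0, 1.0)))


@pytest.fixture(scope="session")
def default_thorax():
    return ThoraxPhantomParams(W1=15.0, W2=24.8, L=14.3, spacing=COARSE_CT_SPACING)


@pytest.fixture(scope="session")
def phantom_scene(default_thorax):
    """Thorax CT + radiograph with an embedded heart, shared across tests."""
    layout = thorax_layout(default_thorax)
    center = (0.5, layout.upper_row_y + default_thorax.L / 2.0 + 1.0, -1.5)
    heart = generate_heart(
        HeartPhantomParams(
            semi_axes=(4.2, 5.2, 3.6),
            lobe_amplitudes=(0.3, 0.4, 0.25, 0.35),
            center=center,
        )
    )
    shape, spacing, origin = thorax_grid(default_thorax)
    mask = voxelize_on_grid(heart, shape, spacing, origin)
    ct = generate_thorax_ct(default_thorax, heart, heart_mask=mask)
    drr = render_drr(ct, heart_mask=mask, landmarks=layout.landmarks)
    return {
        "thorax": default_thorax,
        "layout": layout,
        "heart": heart,
        "heart_mask": mask,
        "ct": ct,
        "drr": drr,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(42)
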