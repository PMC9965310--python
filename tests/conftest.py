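import numpy as np
import pytest

from rwnseg.cochlear_frame import fit_ccs
from rwnseg.phantom import PhantomSpec, generate_phantom


def exact_pit_spec(**overrides) -> PhantomSpec:
    """Axis-aligned 10x10x5-voxel pit at 0.1 mm: analytic counts are exact."""
    defaults = dict(
        spacing=0.1,
        niche_shape="box_pit",
        niche_dims=(1.0, 1.0, 0.5),
        middle_ear="none",
        wall_taper=0.0,
        air_cells=False,
        noise_sigma=0.0,
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def pit_gt():
    """Noise-free exact pit phantom (500 niche voxels)."""
    return generate_phantom(exact_pit_spec())


@pytest.fixture(scope="session")
def pit_frame(pit_gt):
    return fit_ccs(pit_gt.fiducials)


@pytest.fixture(scope="session")
def default_gt():
    """Default realistic box-pit phantom at the 0.1 mm working resolution."""
    from rwnseg.phantom import default_spec

    return generate_phantom(default_spec("box_pit", spacing=0.1))


def random_rotation(rng) -> np.ndarray:
    """Uniform random proper rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
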