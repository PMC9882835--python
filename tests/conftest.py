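import numpy as np
import pytest

from hyphoshell import synthetic_data as sd
from hyphoshell import tipmodel as tm
from hyphoshell import wallmap as wm


@pytest.fixture(scope="session")
def wt_params():
    """Canonical calibrated wild-type parameter set."""
    return tm.CALIBRATED_WT


@pytest.fixture(scope="session")
def slow_example_params():
    """A slow, closed-form-friendly parameter set (h* = 60 nm exactly)."""
    return tm.ModelParams(gamma=1.0, alpha=0.05, phi=3.0, beta_incorp=0.5,
                          mu=1.0, epsilon=0.2, P=1.1, R=1.2, Y=64.0)


@pytest.fixture(scope="session")
def default_spec():
    return sd.ImagingSpec(seed=3)


@pytest.fixture(scope="session")
def flat_phantom():
    """Capsule phantom with a uniform 80 nm wall."""
    return sd.make_phantom(radius_um=1.2, length_um=5.0, h_nm=80.0)


@pytest.fixture(scope="session")
def rendered_flat(flat_phantom, default_spec):
    return sd.render_image(flat_phantom, default_spec)


@pytest.fixture(scope="session")
def flat_map(rendered_flat):
    return wm.map_thickness(rendered_flat)


def brute_force_curve_distance(inner: np.ndarray, outer: np.ndarray,
                               refine: int = 4) -> np.ndarray:
    """Independent oracle: nearest distance (um) from each inner point to the
    densified outer polyline."""
    from scipy.spatial import cKDTree

    closed = np.vstack([outer, outer[:1]])
    t = np.linspace(0.0, 1.0, refine, endpoint=False)
    dense = (closed[:-1][:, None, :]
             + (closed[1:] - closed[:-1])[:, None, :] * t[None, :, None])
    tree = cKDTree(dense.reshape(-1, 2))
    d, _ = tree.query(inner)
    return d
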