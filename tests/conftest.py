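import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from archasym.landmarks import Configuration, ConfigurationSet, plain_scheme


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def triangle_set():
    """Three distinct planar triangles (centered)."""
    scheme = plain_scheme(3, dims=2)
    tris = [
        np.array([[0.0, 0.0], [1.0, 0.0], [0.4, 0.9]]),
        np.array([[0.0, 0.1], [1.2, 0.0], [0.6, 0.7]]),
        np.array([[-0.1, 0.0], [0.9, 0.2], [0.3, 1.1]]),
    ]
    configs = [Configuration(t - t.mean(axis=0), individual=f"t{i}") for i, t in enumerate(tris)]
    return ConfigurationSet(scheme, configs)


def make_bilateral_set(
    n_ind=6,
    n_points=8,
    dims=3,
    n_reps=2,
    sigma=0.02,
    seed=0,
    sites=None,
):
    """Small bilateral configuration set with iid noise around one base
    shape (right sides mirrored), for design-level tests."""
    rng = np.random.default_rng(seed)
    scheme = plain_scheme(n_points, dims)
    base = rng.normal(size=(n_points, dims))
    base -= base.mean(axis=0)
    base /= np.sqrt(np.sum(base**2))
    configs = []
    for i in range(n_ind):
        site = sites[i % len(sites)] if sites else None
        for side in ("L", "R"):
            shape = base.copy()
            if side == "R":
                shape[:, 0] = -shape[:, 0]
            for rep in range(1, n_reps + 1):
                configs.append(
                    Configuration(
                        shape + sigma * rng.normal(size=(n_points, dims)),
                        individual=f"i{i}",
                        side=side,
                        replicate=rep,
                        site=site,
                    )
                )
    return ConfigurationSet(scheme, configs)
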