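import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString

from segmap.synthetic import StreetNetwork


def make_network(coord_lists, covariates: pd.DataFrame | None = None, signs=None):
    """Hand-built network from explicit polyline coordinate lists."""
    geoms = [LineString(c) for c in coord_lists]
    ids = list(range(len(geoms)))
    segments = pd.DataFrame(
        {"segment_id": ids, "geometry": geoms, "length_m": [g.length for g in geoms]}
    )
    if covariates is None:
        covariates = pd.DataFrame(index=pd.Index(ids, name="segment_id"))
    else:
        covariates = covariates.set_axis(pd.Index(ids, name="segment_id"))
    return StreetNetwork(segments, covariates, dict(signs or {}))


@pytest.fixture
def two_parallel_segments():
    """Segment 0 along y=0, segment 1 along y=10, both x in [0, 50]."""
    return make_network([[(0, 0), (50, 0)], [(0, 10), (50, 10)]])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def simulate_pass_means(
    rng,
    n_segments,
    mean_extra_passes,
    beta,
    sigma2_b,
    sigma2_e,
    cov_sd=1.0,
):
    """Drive-pass means straight from the random-intercept model.

    Covariates are iid normal, constant within segment; returns
    (pass_means frame, covariates frame, true betas including intercept).
    """
    p = len(beta) - 1
    names = [f"z{j}" for j in range(p)]
    X = rng.normal(0.0, cov_sd, (n_segments, p))
    cov = pd.DataFrame(X, columns=names)
    cov.index.name = "segment_id"
    b = rng.normal(0.0, np.sqrt(sigma2_b), n_segments)
    n_i = 1 + rng.poisson(mean_extra_passes, n_segments)
    mu = beta[0] + X @ np.asarray(beta[1:])
    seg = np.repeat(np.arange(n_segments), n_i)
    eps = rng.normal(0.0, np.sqrt(sigma2_e), len(seg))
    pm = pd.DataFrame(
        {"segment_id": seg, "mean_concentration": (mu + b)[seg] + eps}
    )
    return pm, cov, names
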