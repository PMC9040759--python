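import numpy as np
import pandas as pd
import pytest

from ncycomm.synth import SyntheticConfig, make_community
from ncycomm.tables import AbundanceTable, SampleMetadata


def make_table(values, feature_kind="taxon", sample_ids=None, feature_ids=None):
    arr = np.asarray(values, dtype=float)
    sample_ids = sample_ids or [f"s{i}" for i in range(arr.shape[0])]
    feature_ids = feature_ids or [f"f{j}" for j in range(arr.shape[1])]
    return AbundanceTable(
        pd.DataFrame(arr, index=sample_ids, columns=feature_ids),
        feature_kind=feature_kind,
    )


def make_meta(lat, lon=None, depth=None, layer=None, **env):
    lat = np.asarray(lat, dtype=float)
    n = lat.size
    frame = pd.DataFrame(
        {
            "latitude": lat,
            "longitude": np.zeros(n) if lon is None else np.asarray(lon, float),
            "depth": np.zeros(n) if depth is None else np.asarray(depth, float),
            "layer": ["SRF"] * n if layer is None else list(layer),
            **{k: np.asarray(v, float) for k, v in env.items()},
        },
        index=[f"s{i}" for i in range(n)],
    )
    return SampleMetadata(frame)


def planted_response_table(rng, cand, planted=("v1", "v3"), m=8, eps=0.03):
    """Community table whose Hellinger response is built from the planted
    variables: unit-norm rows perturbed linearly along two orthonormal
    feature directions, one per planted variable."""
    n = len(cand)
    hbar = np.full(m, 1 / np.sqrt(m))
    dirs = []
    for _ in planted:
        u = rng.normal(size=m)
        for prev in [hbar, *dirs]:
            u -= (u @ prev) * prev
        dirs.append(u / np.linalg.norm(u))
    h = np.tile(hbar, (n, 1))
    for var, u in zip(planted, dirs):
        v = np.clip(cand[var].to_numpy(), -2.5, 2.5)
        h = h + eps * np.outer(v, u)
    assert (h > 0).all()
    return make_table(1000.0 * h**2)


@pytest.fixture(scope="session")
def community():
    """One seeded mid-stochasticity community reused across tests."""
    cfg = SyntheticConfig(
        n_stations=10, n_taxa=120, n_traits=24, stochastic_weight=0.5, seed=1
    )
    metadata, taxon, trait, truth = make_community(cfg)
    return cfg, metadata, taxon, trait, truth
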