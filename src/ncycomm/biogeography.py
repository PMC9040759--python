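"""Geographic distances, latitudinal diversity gradient, distance decay.

The latitudinal diversity gradient (LDG) is the decline of within-sample
richness with absolute latitude; the distance-decay relationship (DDR) is
the decline of log community similarity with log geographic distance, whose
slope S indexes spatial turnover. Both are fit by ordinary least squares;
for the DDR, which regresses non-independent pairwise quantities, a
Mantel-style permutation p-value (sample-label shuffling) is reported
alongside the parametric one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix

from .tables import LAYERS, SampleMetadata

__all__ = ["EARTH_RADIUS_KM", "RegressionFit", "geo_distance", "ldg", "ddr"]

#: IUGG mean Earth radius.
EARTH_RADIUS_KM = 6371.009


@dataclass
class RegressionFit:
    """An OLS fit: slope S, intercept, r-squared, p-values and sample size."""

    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int
    stderr: float = np.nan
    p_permutation: float = np.nan
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("regression needs at least 3 observations")


def geo_distance(metadata: SampleMetadata) -> DistanceMatrix:
    """Great-circle (haversine) distances between samples, in kilometers.

    Samples at the same station (identical coordinates, e.g. different
    depths of one cast) are at distance zero.
    """
    lat = np.radians(metadata.frame["latitude"].to_numpy(dtype=float))
    lon = np.radians(metadata.frame["longitude"].to_numpy(dtype=float))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    a = np.clip(a, 0.0, 1.0)
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2  # exact symmetry against float noise
    return DistanceMatrix(d, ids=[str(s) for s in metadata.sample_ids])


def _subset_ids(metadata: SampleMetadata, subset: str) -> list:
    if subset == "all":
        return metadata.sample_ids
    if subset not in LAYERS:
        raise ValueError(f"subset must be 'all' or one of {LAYERS}, got {subset!r}")
    mask = metadata.frame["layer"] == subset
    return list(metadata.frame.index[mask])


def ldg(
    richness_per_sample: pd.Series,
    metadata: SampleMetadata,
    subset: str = "all",
) -> RegressionFit:
    """Latitudinal diversity gradient: OLS of richness on absolute latitude."""
    ids = [s for s in _subset_ids(metadata, subset) if s in richness_per_sample.index]
    if len(ids) < 3:
        raise ValueError(f"fewer than 3 samples in subset {subset!r}")
    y = richness_per_sample.loc[ids].to_numpy(dtype=float)
    x = np.abs(metadata.frame.loc[ids, "latitude"].to_numpy(dtype=float))
    if np.ptp(x) == 0:
        raise ValueError("latitude is constant over the subset; LDG undefined")
    fit = stats.linregress(x, y)
    return RegressionFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=len(ids),
        stderr=float(fit.stderr),
    )


def _ddr_pairs(
    sim: np.ndarray, geo: np.ndarray
) -> tuple[np.ndarray, np.ndarray, int]:
    """Retained (log10 distance, log10 similarity) pairs for a DDR fit.

    Same-station pairs (zero distance) and non-positive similarities are
    excluded: both are outside the log-log model's support.
    """
    iu = np.triu_indices(sim.shape[0], k=1)
    c, d = sim[iu], geo[iu]
    keep = (d > 0) & (c > 0)
    return np.log10(d[keep]), np.log10(c[keep]), int((~keep).sum())


def ddr(
    similarity: pd.DataFrame | np.ndarray,
    geo: DistanceMatrix,
    subset_ids: list | None = None,
    n_perm: int = 999,
    rng: np.random.Generator | int | None = None,
) -> RegressionFit:
    """Distance-decay relationship: OLS of log10 similarity on log10 distance.

    ``similarity`` is a square community-similarity matrix (C = 1 - Bray-
    Curtis) aligned with the geographic distance matrix ``geo``. The slope S
    is the DDR slope. Significance is reported two ways: the parametric OLS
    p-value, and a permutation p obtained by shuffling sample labels of the
    similarity matrix (999 permutations by default), which respects the
    non-independence of pairs.
    """
    if isinstance(similarity, pd.DataFrame):
        ids = list(similarity.index)
        sim = similarity.to_numpy(dtype=float)
    else:
        ids = list(geo.ids)
        sim = np.asarray(similarity, dtype=float)
    geo_df = pd.DataFrame(geo.data, index=geo.ids, columns=geo.ids)
    if subset_ids is not None:
        ids = [str(s) for s in subset_ids]
        sim = pd.DataFrame(sim, index=similarity.index, columns=similarity.columns).loc[ids, ids].to_numpy()
    g = geo_df.loc[ids, ids].to_numpy(dtype=float)

    logd, logc, n_excluded = _ddr_pairs(sim, g)
    if logd.size < 3:
        raise ValueError("fewer than 3 retained pairs for the DDR fit")
    if np.ptp(logd) == 0:
        raise ValueError("geographic distances constant over retained pairs")
    fit = stats.linregress(logd, logc)
    slope = float(fit.slope)

    p_perm = np.nan
    if n_perm and n_perm > 0:
        rng = np.random.default_rng(rng)
        n = sim.shape[0]
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            ld, lc, _ = _ddr_pairs(sim[np.ix_(perm, perm)], g)
            if ld.size < 3 or np.ptp(ld) == 0:
                continue
            s = stats.linregress(ld, lc).slope
            if abs(s) >= abs(slope) - 1e-15:
                count += 1
        p_perm = (count + 1) / (n_perm + 1)

    return RegressionFit(
        slope=slope,
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=int(logd.size),
        stderr=float(fit.stderr),
        p_permutation=float(p_perm),
        n_excluded=n_excluded,
    )
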