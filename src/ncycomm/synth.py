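"""Synthetic ocean-community generator with tunable niche vs neutral assembly.

Generates paired taxon and functional-trait abundance tables plus
geo-environmental metadata that reproduce the statistical structure the
analysis pipeline assumes: stations spread along a latitudinal span and
sampled at three depths (SRF / DCM / MES), environmental variables with
realistic cross-correlations (temperature anti-correlated with nitrate and
phosphate, oxygen declining with depth), compositional count tables with a
controllable mix of environmental filtering and regional-pool stochasticity,
and a many-taxa-to-one-trait redundancy mapping.

The assembly model: each trait occupies a tolerance band on a composite
depth-temperature environmental axis; each member taxon draws an
independent Gaussian niche optimum within its trait's band. Expected
taxon abundance in a sample mixes the niche response (weight 1 - w) with a
fixed lognormal regional-pool relative abundance (weight w); counts are
multinomial at a fixed sequencing depth, so row totals are exact. Because
member optima tile the trait band, trait-level composition tracks the
environment more tightly than taxon-level composition — the functional-
redundancy mechanism by which taxonomy can drift stochastically while
function stays deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import AbundanceTable, SampleMetadata

__all__ = [
    "SyntheticConfig",
    "CommunityTruth",
    "make_metadata",
    "make_taxon_table",
    "derive_trait_table",
    "make_community",
]

_LAYER_DEPTHS = {"SRF": 5.0, "DCM": 70.0, "MES": 600.0}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic community and its environment.

    ``stochastic_weight`` w is the neutral (regional-pool) mixing weight:
    w = 0 gives purely niche-determined composition, w = 1 a pure regional-
    pool draw identical in expectation across samples. ``redundancy`` (mean
    taxa per trait) is ``n_taxa / n_traits``.
    """

    n_stations: int = 10
    n_taxa: int = 150
    n_traits: int = 30
    stochastic_weight: float = 0.5
    niche_breadth: float = 0.5       # sigma of the Gaussian niche, axis in SD units
    trait_band_halfwidth: float = 0.8  # tolerance band for member-taxon optima
    sequencing_depth: int = 20_000
    latitude_span: tuple[float, float] = (-62.0, 62.0)
    env_noise: float = 1.0           # SD multiplier on environmental noise terms
    seed: int = 0
    n_samples: int | None = None     # defaults to n_stations x 3 layers

    def __post_init__(self) -> None:
        if not (0.0 <= self.stochastic_weight <= 1.0):
            raise ValueError("stochastic_weight w must lie in [0, 1]")
        if self.niche_breadth <= 0:
            raise ValueError("niche_breadth must be positive")
        if self.n_taxa < self.n_traits:
            raise ValueError("need n_taxa >= n_traits (redundancy >= 1)")
        if min(self.n_stations, self.n_taxa, self.n_traits, self.sequencing_depth) <= 0:
            raise ValueError("counts must be positive")
        if self.n_samples is None:
            self.n_samples = self.n_stations * 3
        if self.n_samples % (self.n_stations * 3) != 0:
            raise ValueError(
                f"n_samples ({self.n_samples}) must be divisible by "
                f"stations x layers ({self.n_stations * 3})"
            )

    @property
    def redundancy(self) -> float:
        """Mean taxa per trait, R."""
        return self.n_taxa / self.n_traits


@dataclass
class CommunityTruth:
    """Ground truth of a simulated community, for parameter-recovery tests."""

    trait_assignment: dict[str, str]   # taxon -> trait
    niche_optima: pd.Series            # per taxon, on the composite axis
    trait_centers: pd.Series           # per trait
    env_axis: pd.Series                # per sample composite axis value
    regional_pool: pd.Series           # per taxon relative abundance
    stochastic_weight: float = 0.5
    redundancy: float = 1.0

    def as_dict(self) -> dict:
        return {
            "stochastic_weight": self.stochastic_weight,
            "redundancy": self.redundancy,
            "trait_assignment": dict(self.trait_assignment),
            "trait_centers": self.trait_centers.to_dict(),
        }


def make_metadata(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> SampleMetadata:
    """Simulate station coordinates, depths, layers and environment.

    Stations are spread over the latitude span; each is sampled at the
    three layer depths. Environmental variables are depth/latitude
    responses plus Gaussian noise, with the canonical oceanographic sign
    structure: temperature falls with absolute latitude and depth; oxygen
    falls with depth; nitrate, phosphate, NO2NO3 and silicate rise with
    depth and against temperature (Redfield-like coupling between N and P).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    reps = config.n_samples // (config.n_stations * 3)
    lo, hi = config.latitude_span
    lats = np.linspace(lo, hi, config.n_stations) + rng.normal(0, 1.0, config.n_stations)
    lats = np.clip(lats, -89.0, 89.0)
    # stations along a cruise-track transect: longitude co-varies with
    # latitude so that geographic distance couples to the latitudinal
    # environmental gradient (the prerequisite for distance decay)
    lons = np.linspace(-160.0, 160.0, config.n_stations) + rng.normal(0, 3.0, config.n_stations)
    lons = np.clip(lons, -180.0, 180.0)

    rows = []
    s = config.env_noise
    for st in range(config.n_stations):
        for layer, depth in _LAYER_DEPTHS.items():
            for rep in range(reps):
                temp = 28.0 - 0.30 * abs(lats[st]) - 0.025 * depth + rng.normal(0, 1.0 * s)
                oxygen = max(240.0 - 0.25 * depth + rng.normal(0, 10.0 * s), 1.0)
                nitrate = max(32.0 - 0.95 * temp + 0.008 * depth + rng.normal(0, 2.0 * s), 0.0)
                phosphate = max(nitrate / 16.0 + rng.normal(0, 0.08 * s), 0.0)
                no2no3 = max(nitrate + rng.normal(0, 0.5 * s), 0.0)
                silicate = max(2.0 + 0.045 * depth + 0.15 * abs(lats[st]) + rng.normal(0, 1.5 * s), 0.0)
                salinity = 35.0 + rng.normal(0, 0.3 * s)
                suffix = f"_{rep + 1}" if reps > 1 else ""
                rows.append(
                    {
                        "sample_id": f"S{st + 1:03d}_{layer}{suffix}",
                        "latitude": lats[st],
                        "longitude": lons[st],
                        "depth": depth,
                        "layer": layer,
                        "temperature": temp,
                        "oxygen": oxygen,
                        "nitrate": nitrate,
                        "phosphate": phosphate,
                        "NO2NO3": no2no3,
                        "silicate": silicate,
                        "salinity": salinity,
                    }
                )
    frame = pd.DataFrame(rows).set_index("sample_id")
    return SampleMetadata(frame)


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / (sd if sd > 0 else 1.0)


def _environmental_axis(metadata: SampleMetadata) -> pd.Series:
    """Composite depth-temperature niche axis, z-scored over samples."""
    depth = metadata.frame["depth"].to_numpy(dtype=float)
    temp = metadata.frame["temperature"].to_numpy(dtype=float)
    axis = _zscore(0.6 * _zscore(np.log1p(depth)) - 0.4 * _zscore(temp))
    return pd.Series(axis, index=metadata.frame.index, name="env_axis")


def make_taxon_table(
    config: SyntheticConfig,
    metadata: SampleMetadata,
    rng: np.random.Generator | None = None,
) -> tuple[AbundanceTable, CommunityTruth]:
    """Simulate the taxon count table and return it with its ground truth.

    Expected abundance of taxon t in sample s is
    ``(1 - w) * niche(t, env_s) + w * pi_t`` (both components normalized to
    compositions), with ``niche`` Gaussian on the composite environmental
    axis and ``pi`` a lognormal rank-abundance regional pool; counts are a
    multinomial draw at the configured sequencing depth.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    w = config.stochastic_weight
    taxa = [f"taxon{i + 1:04d}" for i in range(config.n_taxa)]
    traits = [f"trait{i + 1:03d}" for i in range(config.n_traits)]

    # every trait gets at least one member; remaining taxa assigned uniformly
    owner = list(range(config.n_traits))
    owner += rng.integers(0, config.n_traits, config.n_taxa - config.n_traits).tolist()
    owner = np.array(owner)
    rng.shuffle(owner)
    assignment = {taxa[i]: traits[owner[i]] for i in range(config.n_taxa)}

    centers = rng.uniform(-1.8, 1.8, config.n_traits)
    optima = centers[owner] + rng.uniform(
        -config.trait_band_halfwidth, config.trait_band_halfwidth, config.n_taxa
    )
    pool = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_taxa)
    pool = pool / pool.sum()

    env = _environmental_axis(metadata)
    e = env.to_numpy()
    niche = np.exp(
        -((e[:, None] - optima[None, :]) ** 2) / (2.0 * config.niche_breadth**2)
    )
    niche_sum = niche.sum(axis=1, keepdims=True)
    niche_sum[niche_sum == 0] = 1.0
    expected = (1.0 - w) * (niche / niche_sum) + w * pool[None, :]
    expected = expected / expected.sum(axis=1, keepdims=True)

    counts = np.stack(
        [rng.multinomial(config.sequencing_depth, expected[i]) for i in range(len(e))]
    ).astype(float)
    table = AbundanceTable(
        pd.DataFrame(counts, index=metadata.frame.index, columns=taxa),
        feature_kind="taxon",
    )
    truth = CommunityTruth(
        trait_assignment=assignment,
        niche_optima=pd.Series(optima, index=taxa),
        trait_centers=pd.Series(centers, index=traits),
        env_axis=env,
        regional_pool=pd.Series(pool, index=taxa),
        stochastic_weight=w,
        redundancy=config.redundancy,
    )
    return table, truth


def derive_trait_table(
    taxon_table: AbundanceTable, trait_assignment: dict[str, str]
) -> AbundanceTable:
    """Sum member-taxon abundances into trait abundances (totals conserved)."""
    missing = [t for t in taxon_table.feature_ids if t not in trait_assignment]
    if missing:
        raise ValueError(f"taxa without a trait assignment: {missing[:5]}")
    labels = [trait_assignment[t] for t in taxon_table.feature_ids]
    grouped = taxon_table.data.T.groupby(labels).sum().T
    return AbundanceTable(grouped, feature_kind="trait", normalized=taxon_table.normalized)


def make_community(
    config: SyntheticConfig,
) -> tuple[SampleMetadata, AbundanceTable, AbundanceTable, CommunityTruth]:
    """One-call simulation: metadata, taxon table, trait table, ground truth."""
    rng = np.random.default_rng(config.seed)
    metadata = make_metadata(config, rng)
    taxon_table, truth = make_taxon_table(config, metadata, rng)
    trait_table = derive_trait_table(taxon_table, truth.trait_assignment)
    return metadata, taxon_table, trait_table, truth
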