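"""Richness-constrained null models and the stochastic-ratio statistic.

The stochastic ratio (ST) quantifies how much of the observed between-
sample community similarity structure is attributable to stochastic
(neutral, dispersal/drift-driven) rather than deterministic (selection-
driven) assembly. Null communities are generated under constraints on
within-sample (local) richness and across-sample (regional) richness:
each sample draws exactly its observed number of features from the
regional pool, with selection probability proportional to each feature's
occupancy, and its observed total abundance is then allocated over the
drawn features. The mean similarity over the null ensemble gives the
null expectation E_ij for every pair; comparing it with the observed
similarity C_ij yields per-pair contributions

    ST_ij^A = E_ij / C_ij              if C_ij >= E_ij   (more similar than null)
    ST_ij^B = (1 - E_ij) / (1 - C_ij)  if C_ij <  E_ij   (less similar than null)

and the pooled ratio ST = (sum ST^A + sum ST^B) / (n_A + n_B), which is 1
for a fully stochastic community and tends to 0 under strong determinism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .tables import AbundanceTable, SampleMetadata

__all__ = [
    "NullEnsemble",
    "StochasticityResult",
    "randomize_community",
    "null_ensemble",
    "stochastic_ratio",
    "run_stochasticity",
]


@dataclass
class NullEnsemble:
    """Per-pair expected similarity under the richness-constrained null.

    ``expected_similarity`` is a symmetric samples x samples DataFrame of
    E_ij (mean over ``n_null`` randomized communities of 1 - Bray-Curtis);
    the null dissimilarity expectation is G_ij = 1 - E_ij.
    """

    expected_similarity: pd.DataFrame
    n_null: int
    allocation: str = "regional_mean"
    selection: str = "occupancy"

    def __post_init__(self) -> None:
        e = self.expected_similarity.to_numpy(dtype=float)
        if (e < -1e-9).any() or (e > 1 + 1e-9).any():
            raise ValueError("expected similarities must lie in [0, 1]")
        if not np.allclose(e, e.T):
            raise ValueError("expected similarity matrix must be symmetric")

    @property
    def expected_dissimilarity(self) -> pd.DataFrame:
        return 1.0 - self.expected_similarity


@dataclass
class StochasticityResult:
    """The pooled stochastic ratio and its per-pair contributions.

    ``pairs`` holds one row per unordered sample pair with the observed
    similarity C, null expectation E, branch (``A`` when C >= E, else
    ``B``) and the contribution value; every contribution lies in [0, 1].
    """

    st: float
    n_a: int
    n_b: int
    pairs: pd.DataFrame
    group: str = "all"
    table_kind: str = "taxon"

    def __post_init__(self) -> None:
        if not (0.0 <= self.st <= 1.0 + 1e-12):
            raise ValueError(f"ST must lie in [0, 1], got {self.st}")
        if self.n_a + self.n_b != len(self.pairs):
            raise ValueError("n_A + n_B must equal the number of retained pairs")


def _occupancy(x: np.ndarray) -> np.ndarray:
    return (x > 0).sum(axis=0).astype(float)


def _bray_curtis_condensed(x: np.ndarray) -> np.ndarray:
    return pdist(x, metric="braycurtis")


def _curveball_presence(
    presence: np.ndarray, rng: np.random.Generator, n_iter: int | None = None
) -> np.ndarray:
    """Curveball trades on a presence/absence matrix.

    Preserves both row sums (per-sample richness) and column sums (feature
    occupancy) exactly; used by the strict fixed-occupancy null variant.
    """
    pres = presence.copy()
    n = pres.shape[0]
    if n_iter is None:
        n_iter = 5 * n
    feature_lists = [set(np.flatnonzero(row)) for row in pres]
    for _ in range(n_iter):
        i, j = rng.choice(n, size=2, replace=False)
        a, b = feature_lists[i], feature_lists[j]
        only_a = list(a - b)
        only_b = list(b - a)
        k = min(len(only_a), len(only_b))
        if k == 0:
            continue
        # swap a random subset of the tradable features between the two rows
        take_a = rng.choice(len(only_a), size=k, replace=False)
        take_b = rng.choice(len(only_b), size=k, replace=False)
        n_swap = int(rng.integers(0, k + 1))
        for s in range(n_swap):
            fa, fb = only_a[take_a[s]], only_b[take_b[s]]
            a.discard(fa); a.add(fb)
            b.discard(fb); b.add(fa)
    out = np.zeros_like(pres)
    for r, feats in enumerate(feature_lists):
        out[r, list(feats)] = 1
    return out


def randomize_community(
    table: AbundanceTable,
    rng: np.random.Generator | int | None = None,
    allocation: str = "regional_mean",
    selection: str = "occupancy",
) -> AbundanceTable:
    """One null community under the richness-constrained randomization.

    For each sample independently: draw exactly its observed richness of
    features from the regional pool without replacement, with probability
    proportional to feature occupancy across the table (``selection=
    "occupancy"``; the Raup-Crick convention, preserving regional richness
    in expectation), or via curveball trades that fix occupancy exactly
    (``selection="fixed_occupancy"``). The sample's total abundance is then
    assigned to the drawn features either by multinomial allocation with
    probabilities proportional to each feature's regional mean relative
    abundance renormalized over the drawn set (``allocation=
    "regional_mean"``, the default) or by shuffling the sample's own
    abundance values onto the drawn features (``allocation="shuffle"``).
    Per-sample richness and per-sample totals are preserved exactly.
    """
    if allocation not in ("regional_mean", "shuffle"):
        raise ValueError(f"unknown allocation {allocation!r}")
    if selection not in ("occupancy", "fixed_occupancy"):
        raise ValueError(f"unknown selection {selection!r}")
    rng = np.random.default_rng(rng)
    x = table.values()
    n, m = x.shape
    if n < 2:
        raise ValueError("null model needs at least 2 samples")
    occ = _occupancy(x)
    pool = np.flatnonzero(occ > 0)
    richness = (x > 0).sum(axis=1)
    if (richness == 0).any():
        bad = [table.sample_ids[i] for i in np.flatnonzero(richness == 0)]
        raise ValueError(f"all-zero samples cannot be randomized: {bad}")
    if (richness > pool.size).any():
        raise ValueError("sample richness exceeds the regional pool size")
    totals = x.sum(axis=1)
    rel = x / totals[:, None]
    regional_mean = rel.mean(axis=0)

    out = np.zeros_like(x, dtype=float)
    if selection == "fixed_occupancy":
        pres = _curveball_presence((x > 0).astype(np.int8), rng)
        drawn_sets = [np.flatnonzero(pres[i]) for i in range(n)]
    else:
        p_occ = occ[pool] / occ[pool].sum()
        drawn_sets = [
            pool[rng.choice(pool.size, size=int(richness[i]), replace=False, p=p_occ)]
            for i in range(n)
        ]

    integral = bool(np.allclose(totals, np.round(totals)) and np.allclose(x, np.round(x)))
    for i in range(n):
        drawn = drawn_sets[i]
        if allocation == "shuffle":
            vals = x[i, x[i] > 0]
            out[i, drawn] = rng.permutation(vals)
            continue
        probs = regional_mean[drawn]
        if probs.sum() <= 0:
            probs = np.ones(drawn.size)
        probs = probs / probs.sum()
        if integral:
            counts = rng.multinomial(int(round(totals[i])), probs).astype(float)
            # multinomial may zero a drawn feature; shift one unit in to keep
            # the richness constraint hard
            zero = np.flatnonzero(counts == 0)
            for z in zero:
                donor = int(np.argmax(counts))
                counts[donor] -= 1
                counts[z] += 1
            out[i, drawn] = counts
        else:
            out[i, drawn] = totals[i] * probs
    return AbundanceTable(
        pd.DataFrame(out, index=table.data.index, columns=table.data.columns),
        table.feature_kind,
        table.normalized,
    )


def null_ensemble(
    table: AbundanceTable,
    n_null: int = 1000,
    rng: np.random.Generator | int | None = None,
    allocation: str = "regional_mean",
    selection: str = "occupancy",
) -> NullEnsemble:
    """Expected pairwise similarity E_ij over ``n_null`` randomized draws.

    Each draw randomizes the community under the richness constraints and
    computes 1 - Bray-Curtis for every pair; E_ij is the ensemble mean.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    rng = np.random.default_rng(rng)
    n = table.shape[0]
    acc = np.zeros(n * (n - 1) // 2)
    for _ in range(n_null):
        null_tab = randomize_community(table, rng, allocation=allocation, selection=selection)
        acc += 1.0 - _bray_curtis_condensed(null_tab.values())
    e = squareform(acc / n_null)
    ids = table.sample_ids
    return NullEnsemble(
        pd.DataFrame(e, index=ids, columns=ids),
        n_null=n_null,
        allocation=allocation,
        selection=selection,
    )


def stochastic_ratio(
    observed_similarity: pd.DataFrame,
    ensemble: NullEnsemble,
    pair_subset: list | None = None,
    group: str = "all",
    table_kind: str = "taxon",
) -> StochasticityResult:
    """Pool per-pair contributions into the stochastic ratio ST.

    ``observed_similarity`` is the square matrix of C_ij = 1 - Bray-Curtis;
    ``pair_subset``, when given, restricts the pooled pairs to those sample
    ids (e.g. one layer). Degenerate pairs C = E = 0 and C = E = 1
    contribute 1 (the fixed point of both branch formulas).
    """
    e_df = ensemble.expected_similarity
    ids = list(observed_similarity.index) if pair_subset is None else list(pair_subset)
    if len(ids) < 2:
        raise ValueError("need at least 2 samples (1 pair)")
    c = observed_similarity.loc[ids, ids].to_numpy(dtype=float)
    e = e_df.loc[ids, ids].to_numpy(dtype=float)
    iu = np.triu_indices(len(ids), k=1)
    c_pairs, e_pairs = c[iu], e[iu]
    if c_pairs.size == 0:
        raise ValueError("empty pair set")

    branch_a = c_pairs >= e_pairs
    values = np.empty_like(c_pairs)
    with np.errstate(divide="ignore", invalid="ignore"):
        values[branch_a] = np.where(
            c_pairs[branch_a] > 0, e_pairs[branch_a] / c_pairs[branch_a], 1.0
        )
        values[~branch_a] = (1.0 - e_pairs[~branch_a]) / (1.0 - c_pairs[~branch_a])
    values = np.clip(values, 0.0, 1.0)

    pairs = pd.DataFrame(
        {
            "sample_i": [ids[i] for i in iu[0]],
            "sample_j": [ids[j] for j in iu[1]],
            "C": c_pairs,
            "E": e_pairs,
            "branch": np.where(branch_a, "A", "B"),
            "contribution": values,
        }
    )
    n_a = int(branch_a.sum())
    n_b = int(c_pairs.size - n_a)
    st = float(values.sum() / (n_a + n_b))
    return StochasticityResult(st=st, n_a=n_a, n_b=n_b, pairs=pairs, group=group, table_kind=table_kind)


def run_stochasticity(
    table: AbundanceTable,
    metadata: SampleMetadata | None = None,
    n_null: int = 1000,
    rng: np.random.Generator | int | None = None,
    allocation: str = "regional_mean",
    selection: str = "occupancy",
    groups: tuple[str, ...] = ("all", "SRF", "DCM", "MES"),
) -> dict[str, StochasticityResult]:
    """Stochastic ratios for the global sample set and each layer.

    Layer subsets re-generate their null ensembles from the subset alone:
    the regional pool, occupancies and regional mean abundances of, say,
    the mesopelagic layer differ from the global ones. Layers with fewer
    than 2 samples are skipped.
    """
    rng = np.random.default_rng(rng)
    results: dict[str, StochasticityResult] = {}
    for grp in groups:
        if grp == "all":
            sub = table
        else:
            if metadata is None:
                continue
            meta = metadata.align_to(table.sample_ids)
            ids = [s for s in table.sample_ids if meta.frame.loc[s, "layer"] == grp]
            if len(ids) < 2:
                continue
            sub = table.subset_samples(ids)
        x = sub.values()
        obs_sim = pd.DataFrame(
            squareform(1.0 - _bray_curtis_condensed(x)) + np.eye(x.shape[0]),
            index=sub.sample_ids,
            columns=sub.sample_ids,
        )
        ens = null_ensemble(
            sub, n_null=n_null, rng=rng, allocation=allocation, selection=selection
        )
        results[grp] = stochastic_ratio(
            obs_sim, ens, group=grp, table_kind=table.feature_kind
        )
    return results
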