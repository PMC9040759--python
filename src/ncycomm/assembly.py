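"""Permutation-based multivariate tests and environmental-driver attribution.

Implements the group-difference tests used to contrast epipelagic and
mesopelagic communities (PERMANOVA, ANOSIM, MRPP on Bray-Curtis matrices),
Mantel and partial Mantel tests relating community dissimilarity to
geographic and environmental distances, per-pathway two-group comparisons
with Benjamini-Hochberg correction, and random-forest factor-importance
ranking of geo-environmental variables.

All permutation p-values use the add-one convention
``p = (#{permuted >= observed} + 1) / (n_perm + 1)`` and therefore never
equal zero. Permutation loops are batched with einsum over a matrix of
permuted group labels, which keeps large calibration studies (hundreds of
simulated datasets x 999 permutations) inside a few seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

from .tables import AbundanceTable, SampleMetadata

__all__ = [
    "PermTestResult",
    "bh_adjust",
    "permanova",
    "anosim",
    "mrpp",
    "mantel",
    "partial_mantel",
    "environment_distance",
    "compare_groups",
    "factor_importance",
]

_EPS = 1e-12


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]


@dataclass
class PermTestResult:
    """Result of a permutation test: statistic, p and null-statistic summary."""

    method: str
    statistic: float
    p_value: float
    n_permutations: int
    perm_mean: float
    perm_sd: float
    extra: dict | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"permutation p must lie in (0, 1], got {self.p_value}")


def _codes_and_sizes(grouping) -> tuple[np.ndarray, np.ndarray]:
    codes, _ = pd.factorize(np.asarray(grouping))
    sizes = np.bincount(codes)
    if len(sizes) < 2:
        raise ValueError("need at least 2 groups")
    if (sizes < 2).any():
        raise ValueError(f"singleton group(s): sizes {sizes.tolist()}")
    return codes, sizes


def _perm_label_matrix(
    codes: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_perm, n) matrix of freely permuted group labels."""
    n = codes.size
    out = np.empty((n_perm, n), dtype=codes.dtype)
    for p in range(n_perm):
        out[p] = codes[rng.permutation(n)]
    return out


def _within_group_sums(mat: np.ndarray, labels: np.ndarray, n_groups: int) -> np.ndarray:
    """For each label row: per-group sums of mat over ordered within pairs.

    Returns (n_perm, n_groups); entry [p, g] = sum_{i,j in g, i != j} mat[i, j]
    (diagonal of ``mat`` must be zero).
    """
    sums = np.empty((labels.shape[0], n_groups))
    for g in range(n_groups):
        m = (labels == g).astype(float)
        sums[:, g] = np.einsum("pi,ij,pj->p", m, mat, m)
    return sums


def permanova(
    dist: DistanceMatrix,
    grouping,
    n_perm: int = 999,
    rng: np.random.Generator | int | None = None,
) -> PermTestResult:
    """Permutational multivariate ANOVA on a distance matrix.

    Pseudo-F = (SS_A / (a-1)) / (SS_W / (n-a)) with SS_T = sum of squared
    distances over pairs / n, SS_W accumulated per group, SS_A = SS_T - SS_W;
    p by free permutation of group labels.
    """
    rng = np.random.default_rng(rng)
    codes, sizes = _codes_and_sizes(grouping)
    n, a = codes.size, sizes.size
    d2 = np.asarray(dist.data, dtype=float) ** 2
    ss_t = d2[np.triu_indices(n, k=1)].sum() / n

    def pseudo_f(label_rows: np.ndarray) -> np.ndarray:
        within = _within_group_sums(d2, label_rows, a) / 2.0  # ordered -> unordered
        group_sizes = np.stack(
            [(label_rows == g).sum(axis=1) for g in range(a)], axis=1
        )
        ss_w = (within / group_sizes).sum(axis=1)
        ss_a = ss_t - ss_w
        return (ss_a / (a - 1)) / (ss_w / (n - a))

    f_obs = float(pseudo_f(codes[None, :])[0])
    perm = pseudo_f(_perm_label_matrix(codes, n_perm, rng))
    p = (np.sum(perm >= f_obs - _EPS) + 1) / (n_perm + 1)
    return PermTestResult("permanova", f_obs, float(p), n_perm, float(perm.mean()), float(perm.std()))


def _rank_matrix(d: np.ndarray) -> np.ndarray:
    """Symmetric matrix of tie-averaged ranks of the unordered pair distances."""
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    ranks = stats.rankdata(d[iu])
    r = np.zeros_like(d)
    r[iu] = ranks
    return r + r.T


def anosim(
    dist: DistanceMatrix,
    grouping,
    n_perm: int = 999,
    rng: np.random.Generator | int | None = None,
) -> PermTestResult:
    """Analysis of similarities: R = (rb - rw) / (n(n-1)/4) on pair ranks."""
    rng = np.random.default_rng(rng)
    codes, sizes = _codes_and_sizes(grouping)
    n, a = codes.size, sizes.size
    r = _rank_matrix(np.asarray(dist.data, dtype=float))
    n_pairs = n * (n - 1) // 2
    total = r[np.triu_indices(n, k=1)].sum()
    n_within = int((sizes * (sizes - 1) // 2).sum())
    n_between = n_pairs - n_within
    denom = n * (n - 1) / 4.0

    def r_stat(label_rows: np.ndarray) -> np.ndarray:
        s_within = _within_group_sums(r, label_rows, a).sum(axis=1) / 2.0
        mean_w = s_within / n_within
        mean_b = (total - s_within) / n_between
        return (mean_b - mean_w) / denom

    r_obs = float(r_stat(codes[None, :])[0])
    perm = r_stat(_perm_label_matrix(codes, n_perm, rng))
    p = (np.sum(perm >= r_obs - _EPS) + 1) / (n_perm + 1)
    return PermTestResult("anosim", r_obs, float(p), n_perm, float(perm.mean()), float(perm.std()))


def mrpp(
    dist: DistanceMatrix,
    grouping,
    n_perm: int = 999,
    rng: np.random.Generator | int | None = None,
) -> PermTestResult:
    """Multi-response permutation procedure.

    delta = sum_g (n_g / n) * mean within-group distance; chance-corrected
    effect size A = 1 - delta / E[delta_perm]; p = P(delta_perm <= delta_obs)
    since tighter groups give smaller delta.
    """
    rng = np.random.default_rng(rng)
    codes, sizes = _codes_and_sizes(grouping)
    n, a = codes.size, sizes.size
    d = np.asarray(dist.data, dtype=float)

    def delta(label_rows: np.ndarray) -> np.ndarray:
        within = _within_group_sums(d, label_rows, a) / 2.0
        group_sizes = np.stack(
            [(label_rows == g).sum(axis=1) for g in range(a)], axis=1
        )
        mean_within = within / (group_sizes * (group_sizes - 1) / 2.0)
        return (mean_within * group_sizes / n).sum(axis=1)

    d_obs = float(delta(codes[None, :])[0])
    perm = delta(_perm_label_matrix(codes, n_perm, rng))
    p = (np.sum(perm <= d_obs + _EPS) + 1) / (n_perm + 1)
    a_stat = 1.0 - d_obs / perm.mean()
    return PermTestResult(
        "mrpp", a_stat, float(p), n_perm, float(perm.mean()), float(perm.std()),
        extra={"delta": d_obs},
    )


def _tri(x: np.ndarray) -> np.ndarray:
    return x[np.triu_indices(x.shape[0], k=1)]


def _matrix_for_method(d: np.ndarray, method: str) -> np.ndarray:
    """Optionally rank-transform pair entries (for Spearman correlations).

    The multiset of pair values is permutation-invariant, so ranking once
    and correlating ranks under permutation equals Spearman per permutation.
    """
    if method == "pearson":
        return d
    if method == "spearman":
        return _rank_matrix(d)
    raise ValueError(f"method must be pearson or spearman, got {method!r}")


def mantel(
    d1: DistanceMatrix | np.ndarray,
    d2: DistanceMatrix | np.ndarray,
    n_perm: int = 999,
    method: str = "pearson",
    rng: np.random.Generator | int | None = None,
) -> PermTestResult:
    """Mantel test: correlation of unordered pair entries of two matrices.

    p-value is one-sided (observed-or-larger r), by simultaneous row/column
    permutation of the first matrix.
    """
    rng = np.random.default_rng(rng)
    a = np.asarray(d1.data if isinstance(d1, DistanceMatrix) else d1, dtype=float)
    b = np.asarray(d2.data if isinstance(d2, DistanceMatrix) else d2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("matrices must match in shape")
    am = _matrix_for_method(a, method)
    bm = _matrix_for_method(b, method)
    y = _tri(bm)
    r_obs = float(np.corrcoef(_tri(am), y)[0, 1])
    n = a.shape[0]
    perm = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.permutation(n)
        perm[i] = np.corrcoef(_tri(am[np.ix_(idx, idx)]), y)[0, 1]
    p = (np.sum(perm >= r_obs - _EPS) + 1) / (n_perm + 1)
    return PermTestResult(f"mantel_{method}", r_obs, float(p), n_perm, float(perm.mean()), float(perm.std()))


def partial_mantel(
    dA: DistanceMatrix | np.ndarray,
    dB: DistanceMatrix | np.ndarray,
    dC: DistanceMatrix | np.ndarray,
    n_perm: int = 999,
    method: str = "pearson",
    rng: np.random.Generator | int | None = None,
) -> PermTestResult:
    """Partial Mantel test of A vs B controlling for C.

    r_AB.C = (r_AB - r_AC r_BC) / sqrt((1 - r_AC^2)(1 - r_BC^2)); p by
    permuting the first matrix (one-sided). Typical use: community
    dissimilarity vs environmental distance, controlling geographic distance.
    """
    rng = np.random.default_rng(rng)
    mats = [
        np.asarray(m.data if isinstance(m, DistanceMatrix) else m, dtype=float)
        for m in (dA, dB, dC)
    ]
    if len({m.shape for m in mats}) != 1:
        raise ValueError("matrices must match in shape")
    am, bm, cm = (_matrix_for_method(m, method) for m in mats)
    vb, vc = _tri(bm), _tri(cm)
    r_bc = float(np.corrcoef(vb, vc)[0, 1])

    def partial_r(a_mat: np.ndarray) -> float:
        va = _tri(a_mat)
        r_ab = float(np.corrcoef(va, vb)[0, 1])
        r_ac = float(np.corrcoef(va, vc)[0, 1])
        numer = r_ab - r_ac * r_bc
        if min(1 - r_ac**2, 1 - r_bc**2) <= _EPS:
            # B identical to the control: nothing left to correlate
            if abs(numer) <= 1e-9:
                return 0.0
            raise ValueError("degenerate control: |r_AC| or |r_BC| equals 1")
        return numer / np.sqrt((1 - r_ac**2) * (1 - r_bc**2))

    r_obs = partial_r(am)
    n = am.shape[0]
    perm = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.permutation(n)
        perm[i] = partial_r(am[np.ix_(idx, idx)])
    p = (np.sum(perm >= r_obs - _EPS) + 1) / (n_perm + 1)
    return PermTestResult(
        f"partial_mantel_{method}", float(r_obs), float(p), n_perm,
        float(perm.mean()), float(perm.std()),
    )


def environment_distance(
    metadata: SampleMetadata, variables: list[str] | None = None, standardize: bool = True
) -> DistanceMatrix:
    """Euclidean distance over (z-scored) environmental variables.

    Standardization keeps variables on incommensurate units (degrees C,
    umol/kg, meters) from dominating the distance.
    """
    env = metadata.env if variables is None else metadata.frame[variables]
    x = env.to_numpy(dtype=float)
    if standardize:
        sd = x.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd
    from scipy.spatial.distance import pdist, squareform

    return DistanceMatrix(squareform(pdist(x)), ids=[str(s) for s in metadata.sample_ids])


def compare_groups(
    table: AbundanceTable,
    metadata: SampleMetadata,
    grouping: str = "epi_vs_meso",
    test: str = "wilcoxon",
) -> pd.DataFrame:
    """Per-feature two-group comparison with Benjamini-Hochberg correction.

    Defaults to the two-sided Wilcoxon rank-sum (Mann-Whitney U) between
    epipelagic and mesopelagic samples, exact where sample sizes permit.
    Returns per feature: statistic, raw p, BH-adjusted p and the group in
    which the feature has the higher median ("direction").
    """
    if test != "wilcoxon":
        raise ValueError(f"unsupported test {test!r}")
    meta = metadata.align_to(table.sample_ids)
    labels = meta.zone() if grouping == "epi_vs_meso" else meta.layers
    groups = labels.unique()
    if len(groups) != 2:
        raise ValueError(f"two-group comparison needs exactly 2 groups, got {list(groups)}")
    g1, g2 = sorted(groups)
    x1 = table.data.loc[labels == g1]
    x2 = table.data.loc[labels == g2]
    rows = []
    for feat in table.feature_ids:
        a, b = x1[feat].to_numpy(float), x2[feat].to_numpy(float)
        if np.ptp(np.concatenate([a, b])) == 0:
            stat, p = np.nan, 1.0
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
            stat, p = float(res.statistic), float(res.pvalue)
        direction = g1 if np.median(a) > np.median(b) else g2
        rows.append((feat, stat, p, direction))
    out = pd.DataFrame(rows, columns=["feature", "statistic", "p_value", "higher_in"])
    out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out.set_index("feature")[["statistic", "p_value", "p_adjusted", "higher_in"]]


def factor_importance(
    response,
    env_matrix: pd.DataFrame,
    n_trees: int = 500,
    n_perm_repeats: int = 10,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Random-forest importance ranking of geo-environmental factors.

    Fits an ensemble of regression trees of ``response`` (a feature's
    abundance vector or a diversity index) on the factor matrix, scores each
    factor by permutation importance (mean decrease in R^2 over
    ``n_perm_repeats`` shuffles), and reports alongside it the univariate
    OLS r^2 of each single factor — the "best single factor" column mirrors
    the largest-circle/bar readout of driver plots.

    Returns a DataFrame indexed by factor, sorted by decreasing importance.
    """
    from sklearn.ensemble import RandomForestRegressor
    from sklearn.inspection import permutation_importance

    rng = np.random.default_rng(rng)
    y = np.asarray(response, dtype=float).ravel()
    if np.ptp(y) == 0:
        raise ValueError("constant response; importance undefined")
    if len(y) != len(env_matrix):
        raise ValueError("response and factor matrix lengths differ")
    x = env_matrix.to_numpy(dtype=float)
    seed = int(rng.integers(2**31 - 1))
    forest = RandomForestRegressor(
        n_estimators=n_trees, oob_score=True, random_state=seed, n_jobs=1
    )
    forest.fit(x, y)
    imp = permutation_importance(
        forest, x, y, n_repeats=n_perm_repeats, random_state=seed, n_jobs=1
    )
    uni_r2 = []
    for j in range(x.shape[1]):
        if np.ptp(x[:, j]) == 0:
            uni_r2.append(0.0)
        else:
            uni_r2.append(float(stats.linregress(x[:, j], y).rvalue ** 2))
    out = pd.DataFrame(
        {
            "importance": imp.importances_mean,
            "importance_sd": imp.importances_std,
            "univariate_r2": uni_r2,
        },
        index=list(env_matrix.columns),
    ).sort_values("importance", ascending=False)
    out.attrs["oob_r2"] = float(forest.oob_score_)
    out.attrs["best_factor"] = out.index[0]
    return out
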