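"""Spatial eigenvectors (PCNM), forward selection and variation partitioning.

PCNM (principal coordinates of neighbour matrices) turns a geographic
distance matrix into orthogonal spatial eigenvectors describing structure
at all detectable scales; forward selection picks the environmental
variables and spatial axes with significant conditional explanatory power
under a constrained-ordination model; variation partitioning (VPA) splits
the community variance into pure-environmental (a), shared (b),
pure-spatial (c) and unexplained (d) fractions from adjusted R-squared
values of the partial models.

Two constrained-ordination models are available: redundancy analysis (RDA)
on Hellinger-transformed relative abundances — the pipeline default, since
its adjusted R-squared yields unbiased additive fractions — and canonical
correspondence analysis (CCA), which works on the chi-square-standardized
contingency residuals with row (sample-total) weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from skbio import DistanceMatrix

from .tables import AbundanceTable

__all__ = [
    "PcnmBasis",
    "VpaResult",
    "pcnm",
    "hellinger",
    "forward_select",
    "variation_partition",
]

_RANK_TOL = 1e-9


@dataclass
class PcnmBasis:
    """PCNM spatial eigenvectors: truncation threshold, eigenvalues, scores."""

    threshold_km: float
    eigenvalues: np.ndarray            # positive, descending
    scores: pd.DataFrame               # samples x axes, orthonormal columns

    @property
    def n_axes(self) -> int:
        return self.scores.shape[1]


def pcnm(geo: DistanceMatrix, eig_rel_tol: float = 1e-8) -> PcnmBasis:
    """Principal coordinates of neighbour matrices from geographic distances.

    The truncation threshold t is the longest edge of the minimum spanning
    tree of the distance matrix (the smallest t keeping all samples
    connected); distances beyond t are replaced by 4t; the modified matrix
    is double-centered and eigendecomposed, and axes with eigenvalue
    > ``eig_rel_tol`` x the largest are retained as orthonormal eigenvector
    scores.
    """
    d = np.asarray(geo.data, dtype=float)
    n = d.shape[0]
    if n < 4:
        raise ValueError("PCNM needs at least 4 samples")
    if np.all(d == 0):
        raise ValueError("all points identical; PCNM undefined")
    mst = minimum_spanning_tree(d).toarray()
    t = float(mst.max())
    trunc = d.copy()
    trunc[d > t] = 4.0 * t
    np.fill_diagonal(trunc, 0.0)
    # Gower double-centering of -0.5 * D^2
    a = -0.5 * trunc**2
    a -= a.mean(axis=0)
    a -= a.mean(axis=1)[:, None]
    a += a.mean()  # restores grand mean removed twice
    a = (a + a.T) / 2
    eigval, eigvec = np.linalg.eigh(a)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    keep = eigval > eig_rel_tol * eigval[0]
    eigval, eigvec = eigval[keep], eigvec[:, keep]
    scores = pd.DataFrame(
        eigvec,
        index=list(geo.ids),
        columns=[f"PCNM{i + 1}" for i in range(eigvec.shape[1])],
    )
    return PcnmBasis(threshold_km=t, eigenvalues=eigval, scores=scores)


def hellinger(table: AbundanceTable) -> np.ndarray:
    """Hellinger transform: square root of within-sample relative abundances."""
    x = table.values()
    totals = x.sum(axis=1, keepdims=True)
    if (totals <= 0).any():
        raise ValueError("all-zero samples cannot be Hellinger-transformed")
    return np.sqrt(x / totals)


class _ConstrainedModel:
    """Shared linear-algebra core for RDA and CCA explained fractions.

    Both models reduce to projecting a response matrix Y onto the column
    space of a design matrix: for RDA, Y is the column-centered Hellinger
    matrix and designs are centered predictor columns; for CCA, Y is the
    chi-square contingency residual matrix Q = (P - rc') / sqrt(rc') and
    predictor columns are weighted-centered and scaled by sqrt(row weight).
    R-squared is the explained fraction of total variance (RDA) or inertia
    (CCA).
    """

    def __init__(self, table: AbundanceTable, model: str = "rda"):
        if model not in ("rda", "cca"):
            raise ValueError(f"model must be 'rda' or 'cca', got {model!r}")
        self.model = model
        self.n = table.shape[0]
        if model == "rda":
            y = hellinger(table)
            self.y = y - y.mean(axis=0)
            self.row_scale = np.ones(self.n)
            self.weights = np.full(self.n, 1.0 / self.n)
        else:
            x = table.values()
            p = x / x.sum()
            r = p.sum(axis=1)
            c = p.sum(axis=0)
            if (r == 0).any() or (c == 0).any():
                raise ValueError("CCA requires positive sample and feature totals")
            expected = np.outer(r, c)
            self.y = (p - expected) / np.sqrt(expected)
            self.row_scale = np.sqrt(r)
            self.weights = r
        self.total = float((self.y**2).sum())
        if self.total <= 0:
            raise ValueError("response has zero total variance/inertia")

    def design(self, x: np.ndarray) -> np.ndarray:
        """Weighted-centered, row-scaled predictor columns."""
        mean = self.weights @ x
        return (x - mean) * self.row_scale[:, None]

    def basis(self, x: np.ndarray) -> tuple[np.ndarray, int]:
        """Orthonormal basis of the design space; rank via pivoted QR."""
        z = self.design(np.asarray(x, dtype=float))
        q, rmat = np.linalg.qr(z, mode="reduced")
        diag = np.abs(np.diag(rmat))
        scale = diag.max() if diag.size else 0.0
        keep = diag > _RANK_TOL * max(scale, 1.0)
        if keep.size and not keep.all():
            warnings.warn(
                "collinear predictor set: fitting in the pseudo-inverse sense "
                f"(rank {int(keep.sum())} of {z.shape[1]} columns)",
                stacklevel=2,
            )
            # re-orthonormalize the independent subspace
            q2, r2 = np.linalg.qr(z[:, np.flatnonzero(keep)], mode="reduced")
            d2 = np.abs(np.diag(r2))
            q = q2[:, d2 > _RANK_TOL * max(d2.max(), 1.0)]
        return q, q.shape[1]

    def r2(self, x: np.ndarray, y: np.ndarray | None = None) -> tuple[float, int]:
        """(explained fraction, predictor rank) for design columns ``x``."""
        if x.size == 0 or x.shape[1] == 0:
            return 0.0, 0
        y = self.y if y is None else y
        q, rank = self.basis(x)
        if rank == 0:
            return 0.0, 0
        fitted = q.T @ y
        return float((fitted**2).sum() / self.total), rank

    def adjusted_r2(self, x: np.ndarray) -> tuple[float, int]:
        """Ezekiel-adjusted explained fraction: 1 - (1-R2)(n-1)/(n-1-p)."""
        r2, rank = self.r2(x)
        if rank == 0:
            return 0.0, 0
        if self.n - 1 - rank <= 0:
            raise ValueError("more predictors than residual degrees of freedom")
        return 1.0 - (1.0 - r2) * (self.n - 1) / (self.n - 1 - rank), rank


def _added_r2(model: _ConstrainedModel, q_current: np.ndarray, x_cand: np.ndarray,
              y: np.ndarray) -> float:
    """Explained-fraction gain from adding one candidate to the current basis."""
    z = model.design(x_cand[:, None])[:, 0]
    if q_current.shape[1]:
        z = z - q_current @ (q_current.T @ z)
    norm = np.linalg.norm(z)
    if norm < _RANK_TOL:
        return 0.0
    u = z / norm
    return float(((u @ y) ** 2).sum() / model.total)


def forward_select(
    response_table: AbundanceTable,
    candidates: pd.DataFrame,
    model: str = "rda",
    alpha: float = 0.05,
    n_perm: int = 199,
    rng: np.random.Generator | int | None = None,
) -> list[str]:
    """Greedy forward selection of predictors under a constrained ordination.

    At each step the candidate with the largest conditional explained
    fraction is admitted iff its selection-adjusted permutation p-value is
    below ``alpha``. The null distribution is that of the *maximum*
    conditional gain over all remaining candidates, computed on
    reduced-model residual permutations of the response (so that picking
    the best of many candidates does not inflate the type-I error).
    A plateau rule guards against over-selection in near-saturated
    problems: once the selected set explains at least 99% of what the full
    candidate model can explain, remaining candidates are deemed "no
    improvement" and selection stops. Selection also stops when no
    candidate is admitted; an empty first step returns an empty list, not
    an error.
    """
    rng = np.random.default_rng(rng)
    m = _ConstrainedModel(response_table, model)
    names = list(candidates.columns)
    x_all = candidates.to_numpy(dtype=float)
    selected: list[str] = []
    remaining = list(range(len(names)))
    q_current = np.empty((m.n, 0))

    r2_full, _ = m.r2(x_all)
    r2_selected = 0.0

    while remaining:
        if r2_full > 0 and r2_selected >= 0.99 * r2_full:
            break
        gains = np.array(
            [_added_r2(m, q_current, x_all[:, j], m.y) for j in remaining]
        )
        best_pos = int(np.argmax(gains))
        best_gain = gains[best_pos]
        if best_gain <= _RANK_TOL:
            break
        # reduced-model residual permutation of the response
        fitted = q_current @ (q_current.T @ m.y) if q_current.shape[1] else np.zeros_like(m.y)
        resid = m.y - fitted
        count = 0
        for _ in range(n_perm):
            y_star = fitted + resid[rng.permutation(m.n)]
            perm_max = max(
                _added_r2(m, q_current, x_all[:, j], y_star) for j in remaining
            )
            if perm_max >= best_gain - 1e-15:
                count += 1
        p = (count + 1) / (n_perm + 1)
        if p >= alpha:
            break
        j = remaining.pop(best_pos)
        selected.append(names[j])
        cols = [names.index(s) for s in selected]
        q_current, _ = m.basis(x_all[:, cols])
        r2_selected, _ = m.r2(x_all[:, cols])
    return selected


@dataclass
class VpaResult:
    """Variation-partitioning fractions from adjusted R-squared values.

    a = pure environment, b = shared, c = pure space, d = unexplained;
    a + b + c + d = 1 by construction. Slightly negative pure fractions are
    an adjusted-R-squared artifact: reported as-is and flagged.
    """

    a: float
    b: float
    c: float
    d: float
    adj_env: float
    adj_space: float
    adj_both: float
    env_selected: list[str] = field(default_factory=list)
    space_selected: list[str] = field(default_factory=list)
    model: str = "rda"

    @property
    def total_explained(self) -> float:
        return self.adj_both

    @property
    def negative_fractions(self) -> list[str]:
        return [name for name, v in (("a", self.a), ("b", self.b), ("c", self.c)) if v < 0]

    def as_dict(self) -> dict:
        return {
            "a_pure_env": self.a,
            "b_shared": self.b,
            "c_pure_space": self.c,
            "d_unexplained": self.d,
            "adj_r2_env": self.adj_env,
            "adj_r2_space": self.adj_space,
            "adj_r2_both": self.adj_both,
            "env_selected": self.env_selected,
            "space_selected": self.space_selected,
            "model": self.model,
            "negative_fractions": self.negative_fractions,
        }


def variation_partition(
    response_table: AbundanceTable,
    env_selected: pd.DataFrame | None,
    space_selected: pd.DataFrame | None,
    model: str = "rda",
) -> VpaResult:
    """Partition community variation between environment and space.

    ``env_selected`` / ``space_selected`` are DataFrames whose columns are
    the forward-selected environmental variables and PCNM axes (either may
    be empty/None). Fractions: a = [env+space] - [space],
    c = [env+space] - [env], b = [env] + [space] - [env+space],
    d = 1 - [env+space], all on Ezekiel-adjusted R-squared.
    """
    m = _ConstrainedModel(response_table, model)
    env = env_selected if env_selected is not None else pd.DataFrame(index=response_table.sample_ids)
    spa = space_selected if space_selected is not None else pd.DataFrame(index=response_table.sample_ids)
    if env.shape[1] == 0 and spa.shape[1] == 0:
        raise ValueError("both predictor sets empty; nothing to partition")
    xe = env.to_numpy(dtype=float)
    xs = spa.to_numpy(dtype=float)
    xb = np.hstack([xe, xs]) if xe.size and xs.size else (xe if xe.size else xs)
    adj_env, _ = m.adjusted_r2(xe) if xe.size else (0.0, 0)
    adj_spa, _ = m.adjusted_r2(xs) if xs.size else (0.0, 0)
    adj_both, _ = m.adjusted_r2(xb)
    a = adj_both - adj_spa
    c = adj_both - adj_env
    b = adj_env + adj_spa - adj_both
    d = 1.0 - adj_both
    return VpaResult(
        a=a, b=b, c=c, d=d,
        adj_env=adj_env, adj_space=adj_spa, adj_both=adj_both,
        env_selected=list(env.columns), space_selected=list(spa.columns),
        model=model,
    )
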