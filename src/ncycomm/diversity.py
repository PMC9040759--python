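"""Alpha diversity, Bray-Curtis beta diversity and ordination.

Within-sample (alpha) diversity is summarized by the Shannon-Wiener index,
observed richness and Chao1; between-sample (beta) diversity by Bray-Curtis
dissimilarity, with community similarity defined as 1 - dissimilarity.
Ordination is either principal coordinates analysis (PCoA) on a Bray-Curtis
distance matrix or classical PCA on centered abundances; the first-axis
scores feed the environmental-driver regressions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.diversity.alpha import chao1 as _skbio_chao1
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .tables import AbundanceTable

__all__ = [
    "shannon",
    "chao1",
    "richness",
    "alpha_diversity",
    "bray_curtis",
    "similarity_from",
    "OrdinationResult",
    "ordinate",
]


def _as_row(x) -> np.ndarray:
    row = np.asarray(x, dtype=float).ravel()
    if (row < 0).any():
        raise ValueError("abundances must be non-negative")
    return row


def shannon(abundance_row, base: float = np.e) -> float:
    """Shannon-Wiener index H = -sum p_i log p_i over positive features.

    Natural log by default (vegan's convention); pass ``base=2`` for bits.
    """
    row = _as_row(abundance_row)
    total = row.sum()
    if total <= 0:
        raise ValueError("Shannon index undefined for an all-zero sample")
    p = row[row > 0] / total
    return float(-(p * np.log(p)).sum() / np.log(base))


def chao1(count_row) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1) / (2(F2+1)).

    Requires integer read counts, since the singleton (F1) and doubleton
    (F2) tallies are meaningless on normalized abundances.
    """
    row = _as_row(count_row)
    if not np.allclose(row, np.round(row)):
        raise ValueError(
            "Chao1 needs raw integer counts; normalized/fractional abundances "
            "have no singletons or doubletons"
        )
    return float(_skbio_chao1(row.astype(np.int64), bias_corrected=True))


def richness(abundance_row) -> int:
    """Observed richness: number of features with abundance > 0."""
    row = _as_row(abundance_row)
    return int((row > 0).sum())


def alpha_diversity(table: AbundanceTable) -> pd.DataFrame:
    """Per-sample richness and Shannon index (Chao1 added for count tables)."""
    out = pd.DataFrame(
        {
            "richness": [richness(r) for _, r in table.data.iterrows()],
            "shannon": [shannon(r) for _, r in table.data.iterrows()],
        },
        index=table.data.index,
    )
    vals = table.values()
    if not table.normalized and np.allclose(vals, np.round(vals)):
        out["chao1"] = [chao1(r) for _, r in table.data.iterrows()]
    return out


def bray_curtis(table: AbundanceTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity D_ij = sum|x_ik - x_jk| / sum(x_ik + x_jk)."""
    if table.shape[0] < 2:
        raise ValueError("Bray-Curtis needs at least two samples")
    x = table.values()
    totals = x.sum(axis=1)
    if (totals == 0).sum() >= 1:
        bad = [table.sample_ids[i] for i in np.flatnonzero(totals == 0)]
        raise ValueError(f"Bray-Curtis undefined for all-zero samples: {bad}")
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(d, ids=[str(s) for s in table.sample_ids])


def similarity_from(dissimilarity: DistanceMatrix) -> pd.DataFrame:
    """Community similarity C = 1 - D, as a labelled square DataFrame."""
    sim = 1.0 - dissimilarity.data
    return pd.DataFrame(sim, index=dissimilarity.ids, columns=dissimilarity.ids)


@dataclass
class OrdinationResult:
    """Sample scores and variance explained per ordination axis."""

    scores: pd.DataFrame          # samples x axes, ordered by eigenvalue
    eigenvalues: np.ndarray       # descending; PCoA may include negatives
    proportion_explained: np.ndarray  # over non-negative eigenvalues only
    method: str

    @property
    def axis1(self) -> pd.Series:
        return self.scores.iloc[:, 0]


def ordinate(
    source: AbundanceTable | DistanceMatrix,
    method: str = "pcoa_on_distance",
) -> OrdinationResult:
    """Ordinate samples by PCoA on a distance matrix or PCA on abundances.

    ``pcoa_on_distance`` accepts a ``DistanceMatrix`` (or an
    ``AbundanceTable``, from which Bray-Curtis is computed first) and
    performs metric multidimensional scaling; negative eigenvalues are kept
    in ``eigenvalues`` but excluded from variance fractions.
    ``pca_on_abundance`` performs covariance-eigendecomposition PCA of the
    centered abundance matrix.
    """
    if method == "pcoa_on_distance":
        dm = bray_curtis(source) if isinstance(source, AbundanceTable) else source
        if dm.shape[0] < 3:
            raise ValueError("ordination needs at least 3 samples")
        res = _skbio_pcoa(dm, method="eigh", dimensions=dm.shape[0], warn_neg_eigval=False)
        eig = res.eigvals.to_numpy()
        pos = np.clip(eig, 0, None)
        prop = pos / pos.sum() if pos.sum() > 0 else pos
        scores = res.samples.copy()
        scores.index = list(dm.ids)
        return OrdinationResult(scores, eig, prop, "pcoa_on_distance")
    if method == "pca_on_abundance":
        if not isinstance(source, AbundanceTable):
            raise TypeError("PCA requires an AbundanceTable, not a distance matrix")
        if source.shape[0] < 3:
            raise ValueError("ordination needs at least 3 samples")
        x = source.values()
        xc = x - x.mean(axis=0)
        cov = np.cov(xc, rowvar=False)
        eigval, eigvec = np.linalg.eigh(cov)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        eigval = np.clip(eigval, 0, None)
        k = min(x.shape[0] - 1, x.shape[1])
        scores = pd.DataFrame(
            xc @ eigvec[:, :k],
            index=source.data.index,
            columns=[f"PC{i + 1}" for i in range(k)],
        )
        prop = eigval[:k] / eigval.sum() if eigval.sum() > 0 else eigval[:k]
        return OrdinationResult(scores, eigval[:k], prop, "pca_on_abundance")
    raise ValueError(f"unknown ordination method {method!r}")
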