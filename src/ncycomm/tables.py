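"""Core data model and I/O for feature-abundance tables and sample metadata.

The toolkit operates on two derived-data products of a shotgun-metagenome
profiling workflow: a samples x taxa abundance matrix and a samples x
gene-family ("functional trait") abundance matrix, paired with per-sample
geographic and environmental metadata.  This module holds the containers,
delimited-text readers/writers, sequencing-depth normalization, feature
aggregation (gene family -> pathway, taxon -> phylum), archaea/bacteria
domain ratios and ocean-layer grouping used by every downstream stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "PATHWAYS",
    "LAYERS",
    "EPIPELAGIC_LAYERS",
    "AbundanceTable",
    "SampleMetadata",
    "GeneFamilyMap",
    "read_table",
    "write_table",
    "read_biom_json",
    "read_metadata",
    "normalize_depth",
    "aggregate",
    "domain_ratio",
    "split_layers",
]

#: The nine nitrogen-cycle pathways a gene family may be assigned to.
PATHWAYS = frozenset(
    {
        "nitrification",
        "denitrification",
        "DNRN",  # dissimilatory nitrate reduction to nitrite
        "DNRA",  # dissimilatory nitrite reduction to ammonia
        "ANRN",  # assimilatory nitrate reduction to nitrite
        "ANRA",  # assimilatory nitrite reduction to ammonia
        "nitrogen fixation",
        "anammox",
        "ammonification",
    }
)

#: Water-column layer labels: surface, deep chlorophyll maximum, mesopelagic.
LAYERS = ("SRF", "DCM", "MES")
#: The epipelagic zone is the union of the SRF and DCM layers.
EPIPELAGIC_LAYERS = frozenset({"SRF", "DCM"})

#: Default per-sample total used for sequencing-depth normalization.
DEFAULT_NORMALIZATION_TARGET = 100_000_000


@dataclass
class AbundanceTable:
    """A samples x features non-negative abundance matrix.

    Parameters
    ----------
    data:
        DataFrame with samples as rows (index = sample ids) and features as
        columns (taxa or gene-family traits). Entries are read counts or
        normalized abundances; never negative.
    feature_kind:
        ``"taxon"`` or ``"trait"``.
    normalized:
        True once rows have been rescaled to a common total.
    """

    data: pd.DataFrame
    feature_kind: str = "taxon"
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.feature_kind not in ("taxon", "trait"):
            raise ValueError(f"feature_kind must be 'taxon' or 'trait', got {self.feature_kind!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("abundance table must be numeric")
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative abundance at sample {self.data.index[i]!r}, "
                f"feature {self.data.columns[j]!r}"
            )

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_samples(self, sample_ids: Iterable) -> "AbundanceTable":
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self.data.index]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        return AbundanceTable(self.data.loc[ids], self.feature_kind, self.normalized)

    def relative(self) -> "AbundanceTable":
        """Rows rescaled to fractions summing to 1."""
        totals = self.data.sum(axis=1)
        if (totals <= 0).any():
            bad = list(totals.index[totals <= 0])
            raise ValueError(f"samples with non-positive total: {bad}")
        return AbundanceTable(self.data.div(totals, axis=0), self.feature_kind, True)


@dataclass
class SampleMetadata:
    """Per-sample coordinates, depth, layer label and environmental variables.

    ``frame`` is indexed by sample id with required columns ``latitude``
    (degrees, [-90, 90]), ``longitude`` (degrees, [-180, 180]), ``depth``
    (meters, >= 0) and ``layer`` (one of SRF/DCM/MES); any further numeric
    columns are treated as named environmental variables (temperature,
    oxygen, nitrate, ...).
    """

    frame: pd.DataFrame

    REQUIRED = ("latitude", "longitude", "depth", "layer")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"metadata missing required columns: {missing}")
        if self.frame.index.has_duplicates:
            raise ValueError("duplicate sample ids in metadata")
        lat = self.frame["latitude"].to_numpy(dtype=float)
        lon = self.frame["longitude"].to_numpy(dtype=float)
        if (np.abs(lat) > 90).any():
            raise ValueError("latitude outside [-90, 90]")
        if (np.abs(lon) > 180).any():
            raise ValueError("longitude outside [-180, 180]")
        if (self.frame["depth"].to_numpy(dtype=float) < 0).any():
            raise ValueError("negative depth")
        bad_layers = set(self.frame["layer"]) - set(LAYERS)
        if bad_layers:
            raise ValueError(f"unknown layer labels: {sorted(bad_layers)} (allowed: {LAYERS})")

    @property
    def sample_ids(self) -> list:
        return list(self.frame.index)

    @property
    def env(self) -> pd.DataFrame:
        """The named environmental variables (all non-required numeric columns)."""
        extra = [c for c in self.frame.columns if c not in self.REQUIRED]
        env = self.frame[extra].select_dtypes("number")
        return env

    @property
    def layers(self) -> pd.Series:
        return self.frame["layer"]

    def zone(self) -> pd.Series:
        """Epipelagic (SRF u DCM) vs mesopelagic label per sample."""
        return self.frame["layer"].map(
            lambda l: "epipelagic" if l in EPIPELAGIC_LAYERS else "mesopelagic"
        )

    def align_to(self, sample_ids: Iterable) -> "SampleMetadata":
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self.frame.index]
        if missing:
            raise KeyError(f"samples missing from metadata: {missing}")
        return SampleMetadata(self.frame.loc[ids])


@dataclass
class GeneFamilyMap:
    """Mapping of gene families to N-cycle pathways, with optional domain tags.

    ``pathway`` maps each gene-family id to exactly one of the nine pathways
    in :data:`PATHWAYS`; ``domain`` optionally tags families as ``archaeal``
    or ``bacterial`` (used for the amoA archaea:bacteria ratio).
    """

    pathway: dict[str, str]
    domain: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {p for p in self.pathway.values()} - PATHWAYS
        if bad:
            raise ValueError(
                f"pathway labels outside the nine-pathway vocabulary: {sorted(bad)}"
            )
        bad_dom = set(self.domain.values()) - {"archaeal", "bacterial"}
        if bad_dom:
            raise ValueError(f"domain tags must be archaeal/bacterial, got {sorted(bad_dom)}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneFamilyMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        cols = {c.lower(): c for c in df.columns}
        for req in ("gene_family", "pathway"):
            if req not in cols:
                raise ValueError(f"gene-family map needs a '{req}' column")
        pathway = dict(zip(df[cols["gene_family"]], df[cols["pathway"]]))
        domain = {}
        if "domain" in cols:
            sub = df.dropna(subset=[cols["domain"]])
            domain = dict(zip(sub[cols["gene_family"]], sub[cols["domain"]]))
        return cls(pathway, domain)

    def families(self, pathway: str | None = None) -> list[str]:
        if pathway is None:
            return list(self.pathway)
        return [g for g, p in self.pathway.items() if p == pathway]


# ---------------------------------------------------------------------------
# Readers / writers


def read_table(
    path: str | Path,
    orientation: str = "samples_as_rows",
    feature_kind: str = "taxon",
    sep: str | None = None,
) -> AbundanceTable:
    """Read a delimited abundance table into samples-as-rows form.

    ``orientation`` declares what the file's rows are (``samples_as_rows`` or
    ``features_as_rows``); the returned table always has samples as rows.
    The delimiter is inferred from the suffix (.csv -> comma, otherwise tab)
    unless given explicitly.
    """
    path = Path(path)
    if orientation not in ("samples_as_rows", "features_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate row ids {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate column ids {dups}")
    # locate non-numeric / negative cells with file coordinates for the error
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric cell at line {i + 2}, row {df.index[i]!r}, "
            f"column {df.columns[j]!r}: {df.iat[i, j]!r}"
        )
    if (numeric.to_numpy() < 0).any():
        i, j = np.argwhere(numeric.to_numpy() < 0)[0]
        raise ValueError(
            f"{path}: negative cell at line {i + 2}, row {df.index[i]!r}, "
            f"column {df.columns[j]!r}"
        )
    if orientation == "features_as_rows":
        numeric = numeric.T
    return AbundanceTable(numeric, feature_kind=feature_kind)


def write_table(table: AbundanceTable, path: str | Path, sep: str = "\t") -> None:
    """Write samples-as-rows; bit-stable for fixed input."""
    df = table.data
    if np.allclose(df.to_numpy(), np.round(df.to_numpy())) and np.isfinite(df.to_numpy()).all():
        df = df.round().astype("int64")
    df.to_csv(path, sep=sep, index_label="sample_id")


def read_biom_json(path: str | Path, feature_kind: str = "taxon") -> AbundanceTable:
    """Adapter for BIOM 1.0 JSON tables (dense or sparse).

    BIOM stores observations (features) as rows and samples as columns;
    the returned table is samples-as-rows like every other reader here.
    """
    import json

    with open(path) as fh:
        doc = json.load(fh)
    feature_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    shape = (len(feature_ids), len(sample_ids))
    data = np.zeros(shape)
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            data[int(i), int(j)] = v
    else:
        data[:] = np.asarray(doc["data"], dtype=float)
    df = pd.DataFrame(data.T, index=sample_ids, columns=feature_ids)
    return AbundanceTable(df, feature_kind=feature_kind)


def read_metadata(path: str | Path, sep: str | None = None) -> SampleMetadata:
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    return SampleMetadata(df)


def write_metadata(metadata: SampleMetadata, path: str | Path, sep: str = "\t") -> None:
    metadata.frame.to_csv(path, sep=sep, index_label="sample_id")


# ---------------------------------------------------------------------------
# Transformations


def normalize_depth(
    table: AbundanceTable, target_total: float = DEFAULT_NORMALIZATION_TARGET
) -> AbundanceTable:
    """Rescale each sample so its total abundance equals ``target_total``.

    Standard sequencing-depth normalization (in place of rarefaction): every
    row is multiplied by ``target_total / row_sum``. Idempotent at a fixed
    target.
    """
    if target_total <= 0:
        raise ValueError("target_total must be positive")
    totals = table.data.sum(axis=1)
    zero = list(totals.index[totals == 0])
    if zero:
        raise ValueError(f"cannot normalize samples with zero total: {zero}")
    out = table.data.mul(target_total / totals, axis=0)
    return AbundanceTable(out, table.feature_kind, normalized=True)


def aggregate(
    table: AbundanceTable,
    mapping: Mapping[str, str] | GeneFamilyMap,
    unassigned: str | None = "unassigned",
) -> AbundanceTable:
    """Sum features that share a mapping target (pathway, phylum, trait, ...).

    Features absent from the mapping are pooled under the ``unassigned``
    label (dropping them would bias compositions, since in real N-cycle
    profiles a majority of reads carry no taxonomy); pass ``unassigned=None``
    to drop them instead. Per-sample totals are conserved when unmapped
    features are retained.
    """
    if isinstance(mapping, GeneFamilyMap):
        mapping = mapping.pathway
    if not mapping:
        raise ValueError("empty mapping")
    targets = []
    for f in table.feature_ids:
        t = mapping.get(f)
        if t is None:
            if unassigned is None:
                continue
            t = unassigned
        targets.append((f, t))
    if not targets:
        raise ValueError("mapping covers no feature in the table")
    cols, labels = zip(*targets)
    grouped = table.data[list(cols)].T.groupby(list(labels)).sum().T
    return AbundanceTable(grouped, table.feature_kind, table.normalized)


def domain_ratio(
    table: AbundanceTable,
    gene_map: GeneFamilyMap,
    feature_subset: Iterable[str],
) -> pd.DataFrame:
    """Per-sample archaea:bacteria abundance ratio over a gene-family subset.

    Returns a DataFrame with columns ``archaeal``, ``bacterial``, ``ratio``
    and ``defined``. The ratio is +inf when only the bacterial sum is zero
    and NaN (``defined=False``) when both sums are zero; undefined samples
    should be excluded from summaries.
    """
    subset = list(feature_subset)
    missing = [f for f in subset if f not in table.data.columns]
    if missing:
        raise KeyError(f"features absent from table: {missing}")
    untagged = [f for f in subset if f not in gene_map.domain]
    if untagged:
        raise ValueError(f"features without a domain tag: {untagged}")
    arch = [f for f in subset if gene_map.domain[f] == "archaeal"]
    bact = [f for f in subset if gene_map.domain[f] == "bacterial"]
    a = table.data[arch].sum(axis=1)
    b = table.data[bact].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = a / b
    ratio[(b == 0) & (a > 0)] = np.inf
    ratio[(b == 0) & (a == 0)] = np.nan
    return pd.DataFrame(
        {"archaeal": a, "bacterial": b, "ratio": ratio, "defined": ~((a == 0) & (b == 0))}
    )


def split_layers(
    table: AbundanceTable,
    metadata: SampleMetadata,
    grouping: str = "by_layer",
) -> dict[str, AbundanceTable]:
    """Partition samples by water-column layer.

    ``grouping="by_layer"`` yields one sub-table per SRF/DCM/MES layer;
    ``grouping="epi_vs_meso"`` yields the epipelagic (SRF u DCM) vs
    mesopelagic split. Every sample lands in exactly one sub-table.
    """
    if grouping not in ("by_layer", "epi_vs_meso"):
        raise ValueError(f"unknown grouping {grouping!r}")
    missing = [s for s in table.sample_ids if s not in metadata.frame.index]
    if missing:
        raise ValueError(f"samples missing metadata: {missing}")
    meta = metadata.align_to(table.sample_ids)
    labels = meta.layers if grouping == "by_layer" else meta.zone()
    out: dict[str, AbundanceTable] = {}
    for name, ids in labels.groupby(labels).groups.items():
        out[str(name)] = table.subset_samples(list(ids))
    return out
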