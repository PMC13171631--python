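"""Marker-gene cluster census: provenance stratification and species conversion.

A *cluster* is a set of marker-gene sequences grouped at a fixed identity
cutoff (96.5% by convention in this workflow; the clustering itself happens
upstream) and serves as a species proxy.  Each sequence carries a provenance
label: isolate reference genome (``PROGENOMES``), reference catalogue genome
or MAG (``GTDB``), study MAG (``SPIRE_MAG``) or unbinned assembled contig
(``UNBINNED``).  Clusters are attributed hierarchically to the highest-tier
source they contain, and the number of clusters is converted to a number of
species via regression-estimated conversion factors.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

TABLE_COLUMNS = [
    "seq_id",
    "marker_gene",
    "cluster_id",
    "source",
    "sample_id",
    "contig_id",
    "habitat",
]

#: Sources that correspond to a genome (isolate or MAG) rather than a loose contig.
GENOME_SOURCES = frozenset({"PROGENOMES", "GTDB", "SPIRE_MAG"})


class SourceLabel(str, enum.Enum):
    """Provenance of a single marker-gene sequence."""

    PROGENOMES = "PROGENOMES"
    GTDB = "GTDB"
    SPIRE_MAG = "SPIRE_MAG"
    UNBINNED = "UNBINNED"


class SourceCategory(str, enum.Enum):
    """Hierarchical provenance category of a whole cluster.

    The five categories overlap hierarchically: a cluster is attributed to
    the highest tier present among its members, and unbinned-only clusters
    are split into non-singletons (two or more sequences from different
    contigs, i.e. independently observed) versus the remainder (singletons).
    """

    PROGENOMES = "PROGENOMES"
    GTDB = "GTDB"
    SPIRE_MAG = "SPIRE_MAG"
    UNBINNED_NONSINGLETON = "UNBINNED_NONSINGLETON"
    UNBINNED_ALL = "UNBINNED_ALL"


#: Disjoint attribution order used for stratified counting.
CATEGORY_ORDER = [
    SourceCategory.PROGENOMES,
    SourceCategory.GTDB,
    SourceCategory.SPIRE_MAG,
    SourceCategory.UNBINNED_NONSINGLETON,
    SourceCategory.UNBINNED_ALL,
]


class GeneClusterTable:
    """Sequence-level census table (one row per marker-gene sequence).

    Thin wrapper around a :class:`pandas.DataFrame` with the columns
    ``seq_id, marker_gene, cluster_id, source, sample_id, contig_id,
    habitat``.  Empty strings mark inapplicable fields (genome-derived
    records have no ``sample_id``; only unbinned records carry a
    ``contig_id``).
    """

    def __init__(self, df: pd.DataFrame, habitats: Iterable[str] | None = None):
        missing = [c for c in TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        df = df[TABLE_COLUMNS].copy()
        for col in TABLE_COLUMNS:
            df[col] = df[col].astype(str).replace("nan", "")
        bad_source = ~df["source"].isin([s.value for s in SourceLabel])
        if bad_source.any():
            lines = (df.index[bad_source] + 2).tolist()[:5]
            raise ValueError(f"unknown source values at data lines {lines}")
        unbinned = df["source"] == SourceLabel.UNBINNED.value
        if (unbinned & (df["contig_id"] == "")).any():
            raise ValueError("UNBINNED records must carry a contig_id")
        if habitats is not None:
            declared = set(habitats)
            seen = set(df.loc[df["habitat"] != "", "habitat"])
            unknown = seen - declared
            if unknown:
                raise ValueError(f"undeclared habitats: {sorted(unknown)}")
        if df["seq_id"].duplicated().any():
            dup = df.loc[df["seq_id"].duplicated(), "seq_id"].iloc[0]
            raise ValueError(f"duplicate seq_id: {dup}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def markers(self) -> list[str]:
        return sorted(self.df["marker_gene"].unique())

    def subset(self, marker: str | None = None, habitat: str | None = None) -> pd.DataFrame:
        """Rows for one marker and (optionally) one habitat; genome-derived
        rows (empty sample_id) are habitat-agnostic and always retained."""
        df = self.df
        if marker is not None:
            df = df[df["marker_gene"] == marker]
        if habitat is not None:
            df = df[(df["habitat"] == habitat) | (df["sample_id"] == "")]
        return df

    def cluster_categories(self, marker: str) -> dict[str, SourceCategory]:
        """Hierarchical provenance category for every cluster of a marker."""
        sub = self.subset(marker)
        return {
            cid: assign_source_category(grp)
            for cid, grp in sub.groupby("cluster_id", sort=True)
        }

    def cluster_sources(self, marker: str) -> dict[str, set[str]]:
        sub = self.subset(marker)
        return {
            cid: set(grp["source"]) for cid, grp in sub.groupby("cluster_id", sort=True)
        }


def assign_source_category(cluster: pd.DataFrame) -> SourceCategory:
    """Attribute a cluster to its highest-tier provenance category.

    A single isolate-reference member makes the whole cluster a reference
    cluster, irrespective of the origin of other sequences; next in line are
    reference-catalogue genomes, then study MAGs.  Clusters built solely
    from unbinned contigs are non-singletons only if they contain at least
    two sequences from different contigs.
    """
    if len(cluster) == 0:
        raise ValueError("empty cluster")
    sources = set(cluster["source"])
    if SourceLabel.PROGENOMES.value in sources:
        return SourceCategory.PROGENOMES
    if SourceLabel.GTDB.value in sources:
        return SourceCategory.GTDB
    if SourceLabel.SPIRE_MAG.value in sources:
        return SourceCategory.SPIRE_MAG
    contigs = set(cluster.loc[cluster["contig_id"] != "", "contig_id"])
    if len(cluster) >= 2 and len(contigs) >= 2:
        return SourceCategory.UNBINNED_NONSINGLETON
    return SourceCategory.UNBINNED_ALL


@dataclass(frozen=True)
class ConversionFit:
    """Zero-intercept regression of species count on gene-cluster count.

    ``factor`` is the number of species discovered per newly discovered
    marker-gene cluster; the regression ``species ~ clusters`` is forced
    through the origin (slope = sum(xy)/sum(x^2)).
    """

    marker_gene: str
    factor: float
    std_error: float
    n_points: int
    source: str = "pooled"

    def __post_init__(self):
        if not self.factor > 0:
            raise ValueError("conversion factor must be positive")


def _origin_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """OLS slope through the origin and its standard error."""
    sxx = float(np.dot(x, x))
    if sxx == 0:
        raise ValueError("all cluster counts are zero")
    slope = float(np.dot(x, y)) / sxx
    resid = y - slope * x
    n = len(x)
    if n > 1:
        se = float(np.sqrt(np.dot(resid, resid) / ((n - 1) * sxx)))
    else:
        se = float("nan")
    return slope, se


def conversion_fit_from_points(
    clusters, species, marker: str = ""
) -> ConversionFit:
    """Fit a conversion factor from recorded (clusters, species) pairs.

    For trajectories already tabulated (e.g. saved rarefaction records),
    this applies the same zero-intercept regression as
    :func:`estimate_conversion_factor` without re-sampling.
    """
    x = np.asarray(clusters, dtype=float)
    y = np.asarray(species, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need matched (clusters, species) arrays of length >= 2")
    slope, se = _origin_slope(x, y)
    return ConversionFit(marker_gene=marker, factor=slope, std_error=se, n_points=len(x))


def estimate_conversion_factor(
    table: GeneClusterTable,
    species_labels: Mapping[str, str],
    marker: str,
    n_iter: int = 10,
    seed: int | None = None,
    sources: Iterable[str] | None = None,
) -> ConversionFit:
    """Estimate the cluster-to-species conversion factor for one marker.

    Genome-derived sequences (those with a species label) are downsampled
    along a logarithmic grid with ``n_iter`` random draws per step; at each
    draw the number of distinct clusters and distinct species represented is
    recorded, and the zero-intercept least-squares slope of species on
    clusters is returned.

    Parameters
    ----------
    species_labels:
        Map seq_id -> species name for every genome-derived sequence of the
        marker (isolate genomes, catalogue genomes and MAGs).
    sources:
        Restrict to these source labels (default: all genome sources),
        allowing per-data-source fits.
    """
    from microcensus.rarefaction import log_grid

    if sources is None:
        sources = GENOME_SOURCES
    sub = table.subset(marker)
    sub = sub[sub["source"].isin(set(sources))]
    unlabeled = set(sub["seq_id"]) - set(species_labels)
    if unlabeled:
        raise ValueError(
            f"{len(unlabeled)} genome-derived sequences lack a species label"
        )
    if len(sub) == 0:
        raise ValueError(f"no genome-derived sequences for marker {marker!r}")
    seqs = sub["seq_id"].to_numpy()
    clusters = sub["cluster_id"].to_numpy()
    species = np.array([species_labels[s] for s in seqs])
    rng = np.random.default_rng(seed)
    grid = log_grid(len(seqs))
    xs, ys = [], []
    for n in grid:
        reps = 1 if n == len(seqs) else n_iter
        for _ in range(reps):
            idx = rng.choice(len(seqs), size=n, replace=False)
            xs.append(len(np.unique(clusters[idx])))
            ys.append(len(np.unique(species[idx])))
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if len(np.unique(x[x > 0])) < 3:
        raise ValueError("fewer than 3 distinct nonzero cluster counts on the grid")
    slope, se = _origin_slope(x, y)
    return ConversionFit(
        marker_gene=marker, factor=slope, std_error=se, n_points=len(x)
    )


def estimate_species_counts(
    cluster_counts: Mapping[str, int], fits: Mapping[str, ConversionFit]
) -> dict:
    """Convert per-marker cluster counts to species estimates.

    Returns per-marker estimates plus their median and standard deviation
    across markers (the cross-marker summary statistic used throughout).
    """
    if not cluster_counts:
        raise ValueError("empty marker set")
    if set(cluster_counts) != set(fits):
        raise ValueError("marker sets of counts and fits differ")
    per_marker = {
        m: cluster_counts[m] * fits[m].factor for m in sorted(cluster_counts)
    }
    vals = np.array(list(per_marker.values()), dtype=float)
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return {
        "per_marker": per_marker,
        "median": float(np.median(vals)),
        "sd": sd,
        "n_markers": len(vals),
    }


def filter_marker_genes(
    estimates: Mapping[str, float],
    redundant: Iterable[str] = (),
    max_dev: float = 0.2,
) -> set[str]:
    """Drop redundant markers, then markers deviating from the median.

    Redundant markers (e.g. shared between domain-specific marker sets and
    hence prone to cross-mappings) are removed first; the median species
    estimate is computed over the remainder and markers deviating from it
    by more than ``max_dev`` (default 20%) are excluded.
    """
    if len(estimates) < 3:
        raise ValueError("need at least 3 markers")
    redundant = set(redundant)
    kept = {m: v for m, v in estimates.items() if m not in redundant}
    if not kept:
        raise ValueError("all markers redundant")
    med = float(np.median(list(kept.values())))
    out = {m for m, v in kept.items() if abs(v - med) / med <= max_dev}
    if not out:
        raise ValueError("all markers dropped by deviation filter")
    return out
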