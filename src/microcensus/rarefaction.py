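"""Sample-based rarefaction (species-discovery) and habitat-accumulation curves.

Rarefaction is over metagenomic *samples*: at each point N of a logarithmic
grid, N samples are drawn without replacement and the marker-gene clusters
discovered in them are counted, attributed hierarchically by provenance and
converted to species via per-marker conversion factors.  Genome-derived
records never act as samples; they only contribute provenance to the
clusters they sit in.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from microcensus.census import (
    CATEGORY_ORDER,
    ConversionFit,
    GeneClusterTable,
    SourceCategory,
)


def log_grid(n_max: int) -> list[int]:
    """Logarithmic rarefaction grid: 10, 20, ..., 100; 200, ..., 1000; ...

    Per decade d >= 1 the grid holds the multiples of 10^d up to the next
    decade; it is capped at and always includes ``n_max``.  For ``n_max``
    below the first grid point the grid is just ``[n_max]``.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    if n_max < 10:
        return [n_max]
    grid: list[int] = []
    d = 1
    while 10**d <= n_max:
        step = 10**d
        for m in range(1, 10):
            v = m * step
            if v > n_max:
                break
            grid.append(v)
        d += 1
    if grid[-1] != n_max:
        grid.append(n_max)
    return [int(v) for v in grid]


@dataclass
class RarefactionCurve:
    """Species-vs-samples trajectories, stratified by provenance.

    ``df`` has one row per (N, permutation, stratum) with discovered
    ``clusters`` and converted ``species``; stratum ``"all"`` is the
    unstratified total, the remaining strata are the disjoint provenance
    categories.
    """

    df: pd.DataFrame
    marker_gene: str
    habitat: str = "global"
    seed: int | None = None

    @property
    def grid(self) -> list[int]:
        return sorted(self.df["N"].unique())

    def mean_curve(self, stratum: str = "all", value: str = "species") -> pd.Series:
        sub = self.df[self.df["stratum"] == stratum]
        return sub.groupby("N")[value].mean()

    @classmethod
    def from_series(
        cls, series: pd.Series, marker_gene: str = "synthetic", habitat: str = "global"
    ) -> "RarefactionCurve":
        """Wrap a plain cumulative N -> species series as a one-permutation curve."""
        df = pd.DataFrame(
            {
                "N": series.index.astype(int),
                "permutation": 0,
                "stratum": "all",
                "clusters": series.to_numpy(dtype=float),
                "species": series.to_numpy(dtype=float),
            }
        )
        return cls(df=df, marker_gene=marker_gene, habitat=habitat)


def _incidence(
    sub: pd.DataFrame,
) -> tuple[list[str], list[str], np.ndarray]:
    """Cluster x sample boolean incidence over metagenomic records."""
    met = sub[sub["sample_id"] != ""]
    samples = sorted(met["sample_id"].unique())
    clusters = sorted(sub["cluster_id"].unique())
    s_idx = {s: i for i, s in enumerate(samples)}
    c_idx = {c: i for i, c in enumerate(clusters)}
    inc = np.zeros((len(clusters), len(samples)), dtype=bool)
    for cid, sid in zip(met["cluster_id"], met["sample_id"]):
        inc[c_idx[cid], s_idx[sid]] = True
    return clusters, samples, inc


def _count_strata(
    inc_subset: np.ndarray, categories: np.ndarray
) -> dict[str, int]:
    """Discovered clusters per disjoint provenance stratum for one subset."""
    discovered = inc_subset.any(axis=1)
    out = {"all": int(discovered.sum())}
    for cat in CATEGORY_ORDER:
        out[cat.value] = int(np.sum(discovered & (categories == cat.value)))
    return out


def rarefy_samples(
    table: GeneClusterTable,
    marker: str,
    habitat: str | None = None,
    n_perm: int | str = 5,
    seed: int | None = None,
    conversion: ConversionFit | None = None,
    grid: Sequence[int] | None = None,
) -> RarefactionCurve:
    """Rarefaction curve for one marker (optionally restricted to a habitat).

    At each grid point N, ``n_perm`` uniform subsets of samples are drawn
    without replacement (``n_perm="all"`` enumerates every subset — only
    sensible for tiny sample counts).  Cluster provenance is evaluated on
    the *full* cluster membership, including genome-derived records, so a
    cluster discovered via an unbinned sequence still counts as a reference
    cluster if a reference genome sits in it.
    """
    if marker not in table.markers:
        raise ValueError(f"marker {marker!r} absent from table")
    sub = table.subset(marker, habitat)
    clusters, samples, inc = _incidence(sub)
    if len(samples) == 0:
        raise ValueError("no samples after filtering")
    cat_map = {
        cid: cat.value for cid, cat in table.cluster_categories(marker).items()
    }
    categories = np.array([cat_map[c] for c in clusters])
    factor = conversion.factor if conversion is not None else 1.0
    if grid is None:
        grid = log_grid(len(samples))
    rng = np.random.default_rng(seed)
    rows = []
    for n in grid:
        if n > len(samples):
            raise ValueError(f"grid point {n} exceeds sample count {len(samples)}")
        if n_perm == "all":
            subsets = [list(c) for c in itertools.combinations(range(len(samples)), n)]
        else:
            reps = 1 if n == len(samples) else int(n_perm)
            subsets = [
                rng.choice(len(samples), size=n, replace=False) for _ in range(reps)
            ]
        for p, cols in enumerate(subsets):
            counts = _count_strata(inc[:, list(cols)], categories)
            for stratum, c in counts.items():
                rows.append(
                    {
                        "N": n,
                        "permutation": p,
                        "stratum": stratum,
                        "clusters": c,
                        "species": c * factor,
                    }
                )
    df = pd.DataFrame(rows)
    return RarefactionCurve(
        df=df,
        marker_gene=marker,
        habitat=habitat if habitat is not None else "global",
        seed=seed,
    )


@dataclass
class CurveSummary:
    """Cross-marker summary: per-N median species and per-marker CV."""

    median: pd.DataFrame  # columns: N, stratum, species (median across markers)
    cv: pd.DataFrame  # columns: marker_gene, N, stratum, cv


def summarize_across_markers(curves: Sequence[RarefactionCurve]) -> CurveSummary:
    """Median species count per grid point across markers, plus per-marker
    coefficients of variation (s.d./mean over permutations)."""
    grids = {tuple(c.grid) for c in curves}
    if len(grids) != 1:
        raise ValueError("curves must share a common grid")
    means = []
    cvs = []
    for c in curves:
        g = c.df.groupby(["N", "stratum"])["species"]
        mean = g.mean()
        sd = g.std(ddof=0)
        m = mean.reset_index()
        m["marker_gene"] = c.marker_gene
        means.append(m)
        cv = (sd / mean.replace(0, np.nan)).fillna(0.0).rename("cv").reset_index()
        cv["marker_gene"] = c.marker_gene
        cvs.append(cv)
    allmeans = pd.concat(means, ignore_index=True)
    median = (
        allmeans.groupby(["N", "stratum"])["species"].median().rename("species").reset_index()
    )
    return CurveSummary(median=median, cv=pd.concat(cvs, ignore_index=True))


def incremental_habitat_accumulation(
    table: GeneClusterTable,
    habitat_order: Sequence[str],
    marker: str,
    seed: int | None = None,
    conversion: ConversionFit | None = None,
) -> tuple[RarefactionCurve, dict[str, float]]:
    """Habitat-blocked species accumulation.

    Samples are appended habitat block by habitat block in the given order,
    with discovery order randomized within each block; the per-habitat
    increment is the number of species first discovered within that block.
    Returns the cumulative curve and the increments.
    """
    sub = table.subset(marker)
    met = sub[sub["sample_id"] != ""]
    present = sorted(met["habitat"].unique())
    unknown = set(habitat_order) - set(present)
    if unknown:
        raise ValueError(f"unknown habitats in order: {sorted(unknown)}")
    if set(present) - set(habitat_order):
        raise ValueError("habitat_order must cover all habitats present")
    factor = conversion.factor if conversion is not None else 1.0
    sample_hab = met.drop_duplicates("sample_id").set_index("sample_id")["habitat"]
    members: dict[str, set[str]] = {}
    for cid, grp in met.groupby("cluster_id"):
        for sid in grp["sample_id"]:
            members.setdefault(sid, set()).add(cid)
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    rows = []
    increments: dict[str, float] = {}
    n_cum = 0
    for hab in habitat_order:
        block = sorted(sample_hab.index[sample_hab == hab])
        order = rng.permutation(len(block))
        before = len(seen)
        for i in order:
            sid = block[i]
            seen |= members.get(sid, set())
            n_cum += 1
            rows.append(
                {
                    "N": n_cum,
                    "permutation": 0,
                    "stratum": "all",
                    "habitat_block": hab,
                    "clusters": len(seen),
                    "species": len(seen) * factor,
                }
            )
        increments[hab] = (len(seen) - before) * factor
    curve = RarefactionCurve(
        df=pd.DataFrame(rows), marker_gene=marker, habitat="accumulation", seed=seed
    )
    return curve, increments
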