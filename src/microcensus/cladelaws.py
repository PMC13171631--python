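"""Willis power laws and Yule-Simon fits to clade-size distributions.

Taxonomic clade sizes follow hollow curves: the count C of clades
containing S subunits decays as C = a * S^-omega (Willis' law), and the
generative rich-get-richer explanation is the Yule process, whose
stationary size law is the Yule-Simon distribution

    f(S) = rho * B(S, rho + 1),

with B the beta function and rho > 0 the shape parameter.  Low rho means
stronger preferential attachment (heavier tail, dominance of a few large
clades); for large S the pmf approximates a power law with exponent
omega ~ rho + 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special


class DegenerateDistributionError(ValueError):
    """Raised when a size distribution sits on the fit boundary (all 1s)."""


@dataclass
class CladeSizeDistribution:
    """Histogram of clade sizes: map size S -> count of clades of size S."""

    counts: dict[int, int]
    parent_rank: str = "clade"
    child_unit: str = "species-tip"
    stratum: str = "global"

    def __post_init__(self):
        if not self.counts:
            raise ValueError("empty size distribution")
        clean = {}
        for s, c in self.counts.items():
            if s < 1 or c < 1:
                raise ValueError("sizes and counts must be >= 1")
            clean[int(s)] = int(c)
        self.counts = dict(sorted(clean.items()))

    @classmethod
    def from_sizes(cls, sizes: Sequence[int], **meta) -> "CladeSizeDistribution":
        vals, cnts = np.unique(np.asarray(sizes, dtype=int), return_counts=True)
        return cls(counts=dict(zip(vals.tolist(), cnts.tolist())), **meta)

    @property
    def sizes(self) -> np.ndarray:
        return np.array(list(self.counts.keys()))

    @property
    def n_clades(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def total_units(self) -> int:
        """Total subunits = sum over sizes of size * count."""
        return int(sum(s * c for s, c in self.counts.items()))


def yule_simon_pmf(size, rho: float):
    """Yule-Simon pmf: rho * B(size, rho + 1), computed in log space."""
    size_arr = np.asarray(size)
    if np.any(size_arr < 1):
        raise ValueError("size must be >= 1")
    if rho <= 0:
        raise ValueError("rho must be positive")
    logp = np.log(rho) + special.betaln(size_arr, rho + 1.0)
    out = np.exp(logp)
    return float(out) if np.isscalar(size) else out


@dataclass(frozen=True)
class WillisFit:
    """Power-law fit C = a * S^-omega on a log-log plot of the histogram."""

    a: float
    omega: float
    r_squared: float
    n_sizes: int


def fit_willis(
    dist: CladeSizeDistribution, binning: str | None = None, s_min: int = 1
) -> WillisFit:
    """Least-squares slope of log(count) on log(size).

    Only observed sizes enter the regression (zero-count sizes are not
    fabricated).  ``binning="log2"`` first pools counts into geometric
    size bins of ratio 2 and regresses bin densities at the geometric bin
    centre, which tames the count-1 tail noise that otherwise flattens
    the raw slope on heavy-tailed data.  ``s_min`` drops sizes below it
    before fitting; the power-law form is only the asymptote of hollow
    curves, and the smallest sizes can deviate from it systematically.
    """
    S = dist.sizes.astype(float)
    C = np.array([dist.counts[int(s)] for s in dist.sizes], dtype=float)
    keep = S >= s_min
    S, C = S[keep], C[keep]
    if binning == "log2":
        edges = [float(max(s_min, 1))]
        while edges[-1] <= S.max():
            edges.append(edges[-1] * 2.0)
        xs, ys = [], []
        for lo, hi in zip(edges[:-1], edges[1:]):
            mask = (S >= lo) & (S < hi)
            if mask.any():
                xs.append(np.sqrt(lo * (hi - 1.0)))
                ys.append(C[mask].sum() / (hi - lo))
        S, C = np.array(xs), np.array(ys)
    if len(S) < 3:
        raise ValueError("need at least 3 distinct observed sizes")
    slope, intercept = np.polyfit(np.log(S), np.log(C), 1)
    pred = slope * np.log(S) + intercept
    y = np.log(C)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if sst == 0 else 1.0 - float(np.sum((y - pred) ** 2)) / sst
    return WillisFit(
        a=float(np.exp(intercept)),
        omega=float(-slope),
        r_squared=r2,
        n_sizes=len(S),
    )


@dataclass(frozen=True)
class YuleSimonFit:
    """Maximum-likelihood Yule-Simon fit."""

    rho: float
    log_likelihood: float
    std_error: float
    n_clades: int


def _neg_loglik(rho: float, sizes: np.ndarray, counts: np.ndarray) -> float:
    return -float(
        np.sum(counts * (np.log(rho) + special.betaln(sizes, rho + 1.0)))
    )


def fit_yule_simon(dist: CladeSizeDistribution) -> YuleSimonFit:
    """Fit rho by one-dimensional maximum likelihood.

    The likelihood is optimized over rho in log space; the starting value
    is the method-of-moments estimate rho0 = mean/(mean - 1) (the
    Yule-Simon mean is rho/(rho-1) for rho > 1), falling back to 5 when
    the sample mean does not exceed 1.  The standard error comes from the
    observed information (numerical second derivative at the optimum).
    An all-singleton sample pushes rho to the boundary at infinity and is
    rejected as degenerate rather than fitted.
    """
    sizes = dist.sizes.astype(float)
    counts = np.array([dist.counts[int(s)] for s in dist.sizes], dtype=float)
    n = counts.sum()
    if n < 2:
        raise ValueError("need at least 2 clades")
    if sizes.max() == 1:
        raise DegenerateDistributionError(
            "all clades have size 1: rho is unbounded (degenerate boundary)"
        )
    mean = float(np.sum(sizes * counts) / n)
    rho0 = mean / (mean - 1.0) if mean > 1.0 else 5.0
    # optimize log(rho) on a wide bounded interval around the moment start;
    # bounded search is robust when the optimum sits far from rho0
    lo, hi = np.log(rho0) - 12.0, np.log(rho0) + 12.0
    res = optimize.minimize_scalar(
        lambda lr: _neg_loglik(np.exp(lr), sizes, counts),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-12},
    )
    rho = float(np.exp(res.x))
    ll = -float(res.fun)
    h = max(1e-5, 1e-5 * rho)
    d2 = (
        _neg_loglik(rho + h, sizes, counts)
        - 2.0 * _neg_loglik(rho, sizes, counts)
        + _neg_loglik(rho - h, sizes, counts)
    ) / h**2
    se = float(1.0 / np.sqrt(d2)) if d2 > 0 else float("nan")
    return YuleSimonFit(
        rho=rho, log_likelihood=ll, std_error=se, n_clades=int(n)
    )


def sizes_from_partitions(parent, child) -> CladeSizeDistribution:
    """Clade sizes as numbers of nested child clades per parent clade.

    ``child`` may be a finer :class:`CladePartition` (counting subclades
    at the subordinate rank) or the string ``"tips"`` (counting tips, the
    species-proxy unit).  The child partition must refine the parent.
    """
    if child == "tips":
        sizes = [len(c["tips"]) for c in parent.clades]
        return CladeSizeDistribution.from_sizes(
            sizes, parent_rank=parent.rank, child_unit="species-tip"
        )
    sizes = []
    for pc in parent.clades:
        n_nested = 0
        for cc in child.clades:
            if cc["tips"] <= pc["tips"]:
                n_nested += 1
            elif cc["tips"] & pc["tips"]:
                raise ValueError("child partition does not refine parent")
        if n_nested:
            sizes.append(n_nested)
    return CladeSizeDistribution.from_sizes(
        sizes, parent_rank=parent.rank, child_unit=f"subclade-{child.rank}"
    )


def sizes_from_taxonomy_table(
    taxonomy: pd.DataFrame, parent_rank: str, child_rank: str
) -> CladeSizeDistribution:
    """Count distinct child taxa per parent taxon in a flat taxonomy table.

    Rows with an empty or missing name at either rank are excluded (they
    are unlabelled placeholders, not taxa).
    """
    for col in (parent_rank, child_rank):
        if col not in taxonomy.columns:
            raise ValueError(f"missing rank column {col!r}")
    sub = taxonomy[[parent_rank, child_rank]].astype(str)
    sub = sub[(sub[parent_rank] != "") & (sub[child_rank] != "")]
    sub = sub[~sub[parent_rank].isin(["nan"]) & ~sub[child_rank].isin(["nan"])]
    sizes = sub.groupby(parent_rank)[child_rank].nunique()
    return CladeSizeDistribution.from_sizes(
        sizes.to_numpy(), parent_rank=parent_rank, child_unit=child_rank
    )


def stratified_fits(
    distributions: Mapping[str, Mapping[str, CladeSizeDistribution]],
) -> pd.DataFrame:
    """Per-stratum Yule-Simon rho, summarized as the median across markers.

    ``distributions`` maps stratum (habitat or phylum) -> marker -> size
    distribution restricted to that stratum.  Strata where a marker has
    fewer than 2 clades (or only singletons) are skipped for that marker.
    """
    rows = []
    for stratum in sorted(distributions):
        rhos = []
        for marker in sorted(distributions[stratum]):
            dist = distributions[stratum][marker]
            if dist.n_clades < 2:
                continue
            try:
                rhos.append(fit_yule_simon(dist).rho)
            except DegenerateDistributionError:
                continue
        if rhos:
            rows.append(
                {
                    "stratum": stratum,
                    "rho": float(np.median(rhos)),
                    "n_markers": len(rhos),
                }
            )
    return pd.DataFrame(rows)
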