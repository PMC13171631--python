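"""Species-discovery power law and saturation coefficients.

The marginal rate of species discovery is modelled as S = k * N^-gamma,
where S is the number of newly discovered species per sample at survey size
N.  The species discovery coefficient alpha = 1 - gamma rescales this to an
openness measure: alpha <= 0 means discovery is saturated (no new species
expected from more samples of the same kind), alpha -> 1 means discovery is
fully unsaturated, each added sample still contributing new species.  The
same functional form describes pangenome openness (Heaps' law).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from microcensus.rarefaction import RarefactionCurve

SATURATION_THRESHOLD = 0.8


@dataclass(frozen=True)
class DiscoveryFit:
    k: float
    gamma: float
    alpha: float
    r_squared: float
    n_points: int
    stratum: str = "all"
    habitat: str = "global"
    marker_gene: str = ""
    saturated: bool = False

    def __post_init__(self):
        if not self.saturated and abs(self.alpha - (1.0 - self.gamma)) > 1e-12:
            raise ValueError("alpha must equal 1 - gamma")


def alpha_from_gamma(gamma: float) -> float:
    """Species discovery coefficient: alpha = 1 - gamma."""
    return 1.0 - gamma


def classify_saturation(alpha: float, threshold: float = SATURATION_THRESHOLD) -> str:
    """Classify a discovery coefficient.

    ``saturated`` if alpha <= 0, ``near_unsaturated`` if alpha >= threshold
    (default 0.8, virtually no slowdown in discovery), ``open`` otherwise.
    """
    if alpha > 1:
        raise ValueError("alpha cannot exceed 1")
    if alpha <= 0:
        return "saturated"
    if alpha >= threshold:
        return "near_unsaturated"
    return "open"


def marginal_gains(N: np.ndarray, S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Finite-difference marginal discovery rates at geometric midpoints.

    Between consecutive grid points the gain (S_{i+1}-S_i)/(N_{i+1}-N_i) is
    placed at sqrt(N_i * N_{i+1}), the unbiased abscissa on a log grid.
    """
    N = np.asarray(N, dtype=float)
    S = np.asarray(S, dtype=float)
    g = np.diff(S) / np.diff(N)
    m = np.sqrt(N[:-1] * N[1:])
    return m, g


def _saturated_sentinel(stratum: str, habitat: str, marker: str) -> DiscoveryFit:
    return DiscoveryFit(
        k=0.0,
        gamma=1.0,
        alpha=0.0,
        r_squared=float("nan"),
        n_points=0,
        stratum=stratum,
        habitat=habitat,
        marker_gene=marker,
        saturated=True,
    )


def fit_discovery_law(
    curve: RarefactionCurve | pd.Series,
    stratum: str = "all",
    mode: str = "marginal",
) -> DiscoveryFit:
    """Fit S = k * N^-gamma to the marginal gains of a rarefaction curve.

    The permutation-mean cumulative curve is differenced; gains are placed
    at geometric midpoints and log(gain) is regressed on log(N).  Zero
    gains are excluded from the regression; if more than half of the
    marginals are zero the curve is treated as empirically saturated and a
    sentinel fit (alpha = 0, ``saturated=True``) is returned instead.

    ``mode="cumulative"`` instead fits the integrated form
    S_cum = k' * N^(1-gamma) directly on the cumulative curve, as a
    cross-check on the default marginal fit.
    """
    if isinstance(curve, RarefactionCurve):
        mean = curve.mean_curve(stratum=stratum)
        habitat, marker = curve.habitat, curve.marker_gene
    else:
        mean = curve
        habitat, marker = "global", ""
    N = mean.index.to_numpy(dtype=float)
    S = mean.to_numpy(dtype=float)
    if np.any(np.diff(S) < -1e-9):
        raise ValueError("cumulative curve must be nondecreasing")
    if mode == "cumulative":
        pos = S > 0
        slope, intercept = np.polyfit(np.log(N[pos]), np.log(S[pos]), 1)
        gamma = 1.0 - slope
        k = float(np.exp(intercept)) * abs(1.0 - gamma) if gamma != 1.0 else float(
            np.exp(intercept)
        )
        pred = slope * np.log(N[pos]) + intercept
        ss = np.log(S[pos])
        r2 = _r_squared(ss, pred)
        return DiscoveryFit(
            k=k,
            gamma=float(gamma),
            alpha=alpha_from_gamma(float(gamma)),
            r_squared=r2,
            n_points=int(pos.sum()),
            stratum=stratum,
            habitat=habitat,
            marker_gene=marker,
        )
    m, g = marginal_gains(N, S)
    zero = g <= 0
    if zero.all() or zero.sum() > 0.5 * len(g):
        return _saturated_sentinel(stratum, habitat, marker)
    m, g = m[~zero], g[~zero]
    if len(g) < 4:
        raise ValueError("need at least 4 positive marginal gains to fit")
    slope, intercept = np.polyfit(np.log(m), np.log(g), 1)
    gamma = float(-slope)
    k = float(np.exp(intercept))
    pred = slope * np.log(m) + intercept
    r2 = _r_squared(np.log(g), pred)
    return DiscoveryFit(
        k=k,
        gamma=gamma,
        alpha=alpha_from_gamma(gamma),
        r_squared=r2,
        n_points=len(g),
        stratum=stratum,
        habitat=habitat,
        marker_gene=marker,
    )


def _r_squared(y: np.ndarray, pred: np.ndarray) -> float:
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        return 1.0
    return 1.0 - float(np.sum((y - pred) ** 2)) / sst
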