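"""Statistics over simulated trajectories.

The central observable is the Information Space (IS): the standardized
phenotypic amplitude of the population,

    IS = (p_max - p_min) / sigma_r,

the model's operational stand-in for the "sloppy fitness space" of a
parasite lineage.  This module computes IS and related standardized
metrics, bins resolved colonization events into success-probability
curves and phase diagrams, and estimates the first-order partial
Spearman correlation used to relate population size and IS while
controlling for the time since the last host switch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PopulationMetrics",
    "SuccessSurface",
    "information_space",
    "population_metrics",
    "max_individual_distance",
    "success_curve",
    "phase_diagram",
    "spearman_partial",
    "attach_information_space",
]


@dataclass(frozen=True)
class PopulationMetrics:
    """Standardized summary of one population snapshot.

    IS is the phenotypic amplitude in sigma_r units; midpoint_distance
    is the standardized distance between the occupied resource optimum
    and the midpoint of the phenotype range; max_distance is the
    standardized distance between the optimum and p_max.
    """

    IS: float
    midpoint_distance: float
    max_distance: float


@dataclass
class SuccessSurface:
    """Binned colonization-success estimates over one or two covariates.

    ``attempts`` and ``successes`` are counts per bin (1D arrays for a
    curve, 2D for a phase diagram, indexed [x, y]); ``probability`` is
    their ratio, NaN where a bin holds no attempts (empty bins are
    flagged, never zero-filled).
    """

    covariates: tuple[str, ...]
    bin_edges: tuple[np.ndarray, ...]
    attempts: np.ndarray
    successes: np.ndarray

    @property
    def probability(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.attempts > 0, self.successes / self.attempts, np.nan
            )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per bin (or per cell)."""
        if len(self.covariates) == 1:
            (name,) = self.covariates
            (edges,) = self.bin_edges
            return pd.DataFrame(
                {
                    f"{name}_low": edges[:-1],
                    f"{name}_high": edges[1:],
                    "attempts": self.attempts,
                    "successes": self.successes,
                    "probability": self.probability,
                }
            )
        xname, yname = self.covariates
        xe, ye = self.bin_edges
        xi, yi = np.meshgrid(
            np.arange(len(xe) - 1), np.arange(len(ye) - 1), indexing="ij"
        )
        return pd.DataFrame(
            {
                f"{xname}_low": xe[xi.ravel()],
                f"{xname}_high": xe[xi.ravel() + 1],
                f"{yname}_low": ye[yi.ravel()],
                f"{yname}_high": ye[yi.ravel() + 1],
                "attempts": self.attempts.ravel(),
                "successes": self.successes.ravel(),
                "probability": self.probability.ravel(),
            }
        )


def information_space(phenotypes: Sequence[float], sigma_r: float) -> float:
    """IS = (p_max - p_min) / sigma_r; zero for a single individual."""
    phenotypes = np.asarray(phenotypes, dtype=np.float64)
    if phenotypes.size == 0:
        raise ValueError("invalid input: empty phenotype collection")
    if sigma_r <= 0:
        raise ValueError(f"invalid parameter 'sigma_r': {sigma_r!r}")
    return float((phenotypes.max() - phenotypes.min()) / sigma_r)


def population_metrics(
    phenotypes: Sequence[float],
    resource_optimum: float,
    sigma_r: float,
) -> PopulationMetrics:
    """IS, standardized midpoint distance and standardized max distance.

    The midpoint is taken in raw phenotype units, p_min + (p_max -
    p_min)/2, and only the distance to the optimum is standardized; the
    max distance uses p_max (the upper extreme, not the farthest
    individual — see :func:`max_individual_distance` for that variant).
    """
    phenotypes = np.asarray(phenotypes, dtype=np.float64)
    if phenotypes.size == 0:
        raise ValueError("invalid input: empty phenotype collection")
    if sigma_r <= 0:
        raise ValueError(f"invalid parameter 'sigma_r': {sigma_r!r}")
    p_min = phenotypes.min()
    p_max = phenotypes.max()
    midpoint = p_min + (p_max - p_min) / 2.0
    return PopulationMetrics(
        IS=float((p_max - p_min) / sigma_r),
        midpoint_distance=float(abs(resource_optimum - midpoint) / sigma_r),
        max_distance=float(abs(resource_optimum - p_max) / sigma_r),
    )


def max_individual_distance(
    phenotypes: Sequence[float],
    resource_optimum: float,
    sigma_r: float,
) -> float:
    """max_i |p_i - p_r| / sigma_r — the farthest-individual variant."""
    phenotypes = np.asarray(phenotypes, dtype=np.float64)
    if phenotypes.size == 0:
        raise ValueError("invalid input: empty phenotype collection")
    return float(np.abs(phenotypes - resource_optimum).max() / sigma_r)


def attach_information_space(records: pd.DataFrame, sigma_r: float) -> pd.DataFrame:
    """Add an ``IS`` column to a generations table (NaN for empty generations)."""
    out = records.copy()
    out["IS"] = (out["p_max"] - out["p_min"]) / sigma_r
    return out


def _resolved(events: pd.DataFrame, burn_in: int) -> pd.DataFrame:
    if len(events) == 0:
        return events
    if (events["outcome"] == "pending").any():
        raise ValueError("invalid input: unresolved (pending) events")
    return events[events["generation"] > burn_in]


def _edges(values: np.ndarray, bin_width: float) -> np.ndarray:
    if bin_width <= 0:
        raise ValueError(f"invalid parameter 'bin_width': {bin_width!r}")
    hi = values.max() if values.size else bin_width
    n_bins = max(1, int(np.ceil(hi / bin_width + 1e-9)))
    return np.arange(n_bins + 1) * bin_width


def success_curve(
    events: pd.DataFrame,
    covariate: str,
    bin_width: float,
    burn_in: int = 50,
) -> SuccessSurface:
    """Colonization success probability binned over one event covariate.

    Events are binned by the covariate recorded just before
    establishment; the per-bin probability is successes / attempts.
    Events occurring at generations <= burn_in are excluded.  Bins are
    ``[k*w, (k+1)*w)`` anchored at zero (all supported covariates are
    non-negative).
    """
    ev = _resolved(events, burn_in)
    values = ev[covariate].to_numpy(dtype=np.float64) if len(ev) else np.empty(0)
    edges = _edges(values, bin_width)
    idx = np.clip(np.digitize(values, edges) - 1, 0, len(edges) - 2)
    attempts = np.bincount(idx, minlength=len(edges) - 1)
    success_mask = (ev["outcome"] == "success").to_numpy() if len(ev) else np.empty(0, bool)
    successes = np.bincount(idx[success_mask], minlength=len(edges) - 1)
    return SuccessSurface(
        covariates=(covariate,),
        bin_edges=(edges,),
        attempts=attempts,
        successes=successes,
    )


def phase_diagram(
    events: pd.DataFrame,
    x_covariate: str,
    y_covariate: str,
    bin_widths: tuple[float, float],
    burn_in: int = 50,
) -> SuccessSurface:
    """2D success-probability surface over two event covariates."""
    ev = _resolved(events, burn_in)
    xv = ev[x_covariate].to_numpy(dtype=np.float64) if len(ev) else np.empty(0)
    yv = ev[y_covariate].to_numpy(dtype=np.float64) if len(ev) else np.empty(0)
    xe = _edges(xv, bin_widths[0])
    ye = _edges(yv, bin_widths[1])
    xi = np.clip(np.digitize(xv, xe) - 1, 0, len(xe) - 2)
    yi = np.clip(np.digitize(yv, ye) - 1, 0, len(ye) - 2)
    flat = xi * (len(ye) - 1) + yi
    size = (len(xe) - 1) * (len(ye) - 1)
    attempts = np.bincount(flat, minlength=size)
    success_mask = (ev["outcome"] == "success").to_numpy() if len(ev) else np.empty(0, bool)
    successes = np.bincount(flat[success_mask], minlength=size)
    shape = (len(xe) - 1, len(ye) - 1)
    return SuccessSurface(
        covariates=(x_covariate, y_covariate),
        bin_edges=(xe, ye),
        attempts=attempts.reshape(shape),
        successes=successes.reshape(shape),
    )


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)  # average ranks on ties
    ry = stats.rankdata(y)
    sx = rx.std()
    sy = ry.std()
    if sx == 0 or sy == 0:
        raise ValueError("undefined correlation: a ranked variable is constant")
    return float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))


def spearman_partial(
    x: Sequence[float],
    y: Sequence[float],
    z: Sequence[float],
) -> float:
    """First-order partial Spearman correlation of x and y controlling for z.

    rho_xy.z = (rho_xy - rho_xz * rho_yz) / sqrt((1 - rho_xz^2) * (1 -
    rho_yz^2)) with rho the Spearman coefficient (average ranks on
    ties); equivalent to correlating the residuals of rank-on-rank
    regressions.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    z = np.asarray(z, dtype=np.float64)
    if not (x.shape == y.shape == z.shape) or x.ndim != 1 or x.size < 3:
        raise ValueError("invalid input: x, y, z must be equal-length 1D, n >= 3")
    r_xy = _spearman(x, y)
    r_xz = _spearman(x, z)
    r_yz = _spearman(y, z)
    denom = np.sqrt((1.0 - r_xz**2) * (1.0 - r_yz**2))
    if denom == 0:
        raise ValueError("undefined correlation: control removes all variance")
    return float((r_xy - r_xz * r_yz) / denom)
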