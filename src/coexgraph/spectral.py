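"""Graph spectra, spectral densities, spectral entropy, and KL/JS divergences.

The spectrum of a graph is the set of eigenvalues of its adjacency matrix.
Its distribution, estimated by a Gaussian kernel density over the
eigenvalues rescaled by 1/n_V, characterises the graph's structure; the
spectral entropy -∫ρ log ρ dλ measures structural randomness, and the
Jensen-Shannon divergence between two spectral densities discriminates
graph classes.  The square root of the JS divergence is a metric.

Numerical conventions: natural logarithms throughout (so the JS divergence
is bounded by log 2), trapezoid quadrature on a 512-point grid, the
0 log 0 = 0 convention, and a 1e-12 floor on densities inside logarithms to
keep round-off from producing -inf.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .coexpression import CoExpressionGraph

__all__ = [
    "Spectrum",
    "SpectralDensity",
    "adjacency_spectrum",
    "kde_bandwidth",
    "gaussian_kde_on_grid",
    "spectral_density",
    "shared_grid",
    "density_pair",
    "spectral_entropy",
    "kl_divergence",
    "js_divergence",
    "LOG_EPS",
    "GRID_POINTS",
]

BandwidthCriterion = Literal["sturges", "silverman"]

#: Floor applied to densities inside logarithms (0·log 0 stays 0 via masking).
LOG_EPS = 1e-12
#: Default number of evaluation points for density grids.
GRID_POINTS = 512


@dataclass(frozen=True)
class Spectrum:
    """Eigenvalues of a graph adjacency matrix, sorted descending."""

    eigenvalues: np.ndarray
    n_vertices: int

    @property
    def rescaled(self) -> np.ndarray:
        """Eigenvalues divided by the vertex count, as used for the density."""
        return self.eigenvalues / self.n_vertices


@dataclass(frozen=True)
class SpectralDensity:
    """A kernel density on a strictly increasing grid, integrating to 1."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def __post_init__(self) -> None:
        if self.grid.shape != self.density.shape or self.grid.ndim != 1:
            raise ValueError("grid and density must be 1-D and conformable")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if (self.density < 0).any():
            raise ValueError("density must be nonnegative")


def adjacency_spectrum(graph: CoExpressionGraph) -> Spectrum:
    """Eigenvalues of the (symmetric) adjacency matrix, descending."""
    if graph.n_vertices < 2:
        raise ValueError("spectrum requires at least 2 vertices")
    eig = np.linalg.eigvalsh(graph.adjacency)
    return Spectrum(eig[::-1].copy(), graph.n_vertices)


# ---------------------------------------------------------------------------
# Kernel density estimation
# ---------------------------------------------------------------------------

def kde_bandwidth(values: np.ndarray, criterion: BandwidthCriterion = "sturges") -> float:
    """Gaussian-kernel bandwidth by Sturges' or Silverman's criterion.

    Sturges: the bin width of a Sturges histogram, range / ceil(log2 n + 1).
    Silverman: 0.9 * min(sd, IQR/1.34) * n^(-1/5) (sample sd, n-1 divisor).
    A degenerate zero result falls back to 1e-3 * max(1, |max value|).
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("bandwidth of an empty sample is undefined")
    n = v.size
    if criterion == "sturges":
        k = math.ceil(math.log2(n) + 1) if n > 1 else 1
        h = (v.max() - v.min()) / k
    elif criterion == "silverman":
        sd = v.std(ddof=1) if n > 1 else 0.0
        iqr = float(np.percentile(v, 75) - np.percentile(v, 25))
        h = 0.9 * min(sd, iqr / 1.34) * n ** (-0.2)
    else:
        raise ValueError(f"unknown bandwidth criterion {criterion!r}")
    if h <= 0.0:
        h = 1e-3 * max(1.0, abs(float(v.max())))
    return float(h)


def gaussian_kde_on_grid(values: np.ndarray, bandwidth: float, grid: np.ndarray) -> np.ndarray:
    """Raw Gaussian mixture (1/(n h)) Σ_j φ((x - v_j)/h) on the grid."""
    v = np.asarray(values, dtype=float).ravel()
    z = (grid[:, None] - v[None, :]) / bandwidth
    return np.exp(-0.5 * z * z).sum(axis=1) / (v.size * bandwidth * math.sqrt(2.0 * math.pi))


def _normalize(grid: np.ndarray, density: np.ndarray) -> np.ndarray:
    area = np.trapezoid(density, grid)
    if area <= 0.0:
        raise ValueError("density integrates to zero; cannot normalize")
    return density / area


def spectral_density(
    spec: Spectrum,
    criterion: BandwidthCriterion = "sturges",
    grid: np.ndarray | None = None,
) -> SpectralDensity:
    """Gaussian KDE of the rescaled spectrum, renormalized on its grid.

    Without an explicit grid, 512 evenly spaced points covering
    [min - 3h, max + 3h] of the rescaled eigenvalues are used.  When two
    graphs are compared, build a shared grid with :func:`shared_grid` first.
    """
    vals = spec.rescaled
    h = kde_bandwidth(vals, criterion)
    if grid is None:
        grid = np.linspace(vals.min() - 3.0 * h, vals.max() + 3.0 * h, GRID_POINTS)
    else:
        grid = np.asarray(grid, dtype=float)
        if np.any(np.diff(grid) <= 0):
            raise ValueError("grid must be strictly increasing")
    dens = gaussian_kde_on_grid(vals, h, grid)
    return SpectralDensity(grid, _normalize(grid, dens), h)


def shared_grid(
    values1: np.ndarray,
    values2: np.ndarray,
    criterion: BandwidthCriterion = "sturges",
    n_points: int | None = None,
) -> np.ndarray:
    """Common evaluation grid for comparing two samples.

    Each sample keeps its own bandwidth; the grid spans the pooled range
    padded by three times the larger bandwidth, so both densities are
    evaluated on one measure as the JS divergence requires.
    """
    if n_points is None:
        n_points = GRID_POINTS
    h = max(kde_bandwidth(values1, criterion), kde_bandwidth(values2, criterion))
    lo = min(float(np.min(values1)), float(np.min(values2))) - 3.0 * h
    hi = max(float(np.max(values1)), float(np.max(values2))) + 3.0 * h
    return np.linspace(lo, hi, n_points)


def density_pair(
    values1: np.ndarray,
    values2: np.ndarray,
    criterion: BandwidthCriterion = "sturges",
    n_points: int | None = None,
) -> tuple[SpectralDensity, SpectralDensity]:
    """KDEs of two samples on one shared grid (per-sample bandwidths)."""
    grid = shared_grid(values1, values2, criterion, n_points)
    h1 = kde_bandwidth(values1, criterion)
    h2 = kde_bandwidth(values2, criterion)
    d1 = _normalize(grid, gaussian_kde_on_grid(values1, h1, grid))
    d2 = _normalize(grid, gaussian_kde_on_grid(values2, h2, grid))
    return SpectralDensity(grid, d1, h1), SpectralDensity(grid, d2, h2)


# ---------------------------------------------------------------------------
# Information-theoretic functionals
# ---------------------------------------------------------------------------

def spectral_entropy(d: SpectralDensity) -> float:
    """Differential entropy H = -∫ ρ log ρ dλ (nats, trapezoid rule).

    May be negative; 0·log 0 contributes 0.
    """
    rho = d.density
    integrand = np.where(rho > 0.0, rho * np.log(np.maximum(rho, LOG_EPS)), 0.0)
    return float(-np.trapezoid(integrand, d.grid))


def _check_same_grid(d1: SpectralDensity, d2: SpectralDensity) -> None:
    if d1.grid.shape != d2.grid.shape or not np.array_equal(d1.grid, d2.grid):
        raise ValueError("densities must share the same grid (resample first)")


def kl_divergence(d1: SpectralDensity, d2: SpectralDensity) -> float:
    """KL(ρ1 | ρ2) = ∫ ρ1 log(ρ1/ρ2) dλ; +inf if ρ2's support misses ρ1's."""
    _check_same_grid(d1, d2)
    r1, r2 = d1.density, d2.density
    support = r1 > 0.0
    if np.any(support & (r1 > LOG_EPS) & (r2 <= 0.0)):
        return math.inf
    integrand = np.where(
        support,
        r1 * (np.log(np.maximum(r1, LOG_EPS)) - np.log(np.maximum(r2, LOG_EPS))),
        0.0,
    )
    return max(float(np.trapezoid(integrand, d1.grid)), 0.0)


def js_divergence(d1: SpectralDensity, d2: SpectralDensity) -> float:
    """Jensen-Shannon divergence, symmetric and bounded by log 2 (nats)."""
    _check_same_grid(d1, d2)
    mid = SpectralDensity(d1.grid, 0.5 * (d1.density + d2.density),
                          0.5 * (d1.bandwidth + d2.bandwidth))
    js = 0.5 * kl_divergence(d1, mid) + 0.5 * kl_divergence(d2, mid)
    return min(max(js, 0.0), math.log(2.0))
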