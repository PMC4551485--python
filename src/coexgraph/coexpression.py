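"""Pairwise gene association and co-expression graph construction.

A co-expression graph over a gene set has one vertex per gene and edges
quantifying the statistical dependence between expression profiles within
one phenotype.  Three association-degree scales map a dependence test onto
[0, 1]: the absolute correlation coefficient, one minus the test p-value,
and one minus the Benjamini-Hochberg-adjusted p-value.  The graph is either
kept fully weighted by the association degrees or thresholded to an
unweighted graph.

The default pipeline — used throughout the simulation experiments — is the
weighted graph with edges equal to one minus the Spearman p-value adjusted
for multiple testing over the gene set's pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import special, stats

__all__ = [
    "AssociationConfig",
    "CoExpressionGraph",
    "pairwise_association",
    "association_degree",
    "build_graph",
    "coexpression_adjacency",
    "benjamini_hochberg",
]

CorrelationMethod = Literal["pearson", "spearman", "kendall"]
AssociationScale = Literal["abs_corr", "one_minus_p", "one_minus_fdr"]
GraphMode = Literal["weighted", "unweighted"]


@dataclass(frozen=True)
class AssociationConfig:
    """How pairwise association degrees and the graph are built.

    ``threshold`` is required exactly when ``mode`` is ``unweighted``.
    """

    method: CorrelationMethod = "spearman"
    scale: AssociationScale = "one_minus_fdr"
    mode: GraphMode = "weighted"
    threshold: float | None = None

    def __post_init__(self) -> None:
        if self.method not in ("pearson", "spearman", "kendall"):
            raise ValueError(f"unknown correlation method {self.method!r}")
        if self.scale not in ("abs_corr", "one_minus_p", "one_minus_fdr"):
            raise ValueError(f"unknown association scale {self.scale!r}")
        if self.mode == "unweighted":
            if self.threshold is None:
                raise ValueError("unweighted mode requires a threshold")
            if not 0.0 <= self.threshold <= 1.0:
                raise ValueError(f"threshold must lie in [0, 1], got {self.threshold}")
        elif self.threshold is not None:
            raise ValueError("threshold is only meaningful in unweighted mode")


@dataclass
class CoExpressionGraph:
    """Symmetric weighted adjacency over an ordered gene set.

    Weights lie in [0, 1] with a zero diagonal; node order is the gene order
    of the defining set.
    """

    nodes: list[str]
    adjacency: np.ndarray

    def __init__(self, nodes: Sequence[str], adjacency: np.ndarray) -> None:
        self.nodes = [str(n) for n in nodes]
        A = np.asarray(adjacency, dtype=float)
        if A.shape != (len(self.nodes), len(self.nodes)):
            raise ValueError("adjacency shape does not match node count")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be exactly symmetric")
        if np.diagonal(A).any():
            raise ValueError("adjacency diagonal must be zero")
        if A.min() < 0.0 or A.max() > 1.0:
            raise ValueError("edge weights must lie in [0, 1]")
        self.adjacency = A

    @property
    def n_vertices(self) -> int:
        return len(self.nodes)

    @property
    def is_unweighted(self) -> bool:
        off = self.adjacency[~np.eye(self.n_vertices, dtype=bool)]
        return bool(np.isin(off, (0.0, 1.0)).all())


# ---------------------------------------------------------------------------
# Pairwise association
# ---------------------------------------------------------------------------

def _t_sf_pvalue(corr: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-value of a correlation via the t approximation, n-2 df."""
    df = n - 2
    r2 = np.clip(corr * corr, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(corr) * np.sqrt(df / (1.0 - r2))
    p = 2.0 * special.stdtr(df, -t)  # survival function of the t distribution
    p = np.where(r2 >= 1.0, 0.0, p)
    return np.clip(p, 0.0, 1.0)


def pairwise_association(
    values: np.ndarray,
    method: CorrelationMethod = "spearman",
) -> tuple[np.ndarray, np.ndarray]:
    """All pairwise correlations and dependence-test p-values among genes.

    Parameters
    ----------
    values
        Genes x samples matrix restricted to one phenotype's samples.
    method
        ``pearson`` and ``spearman`` use the t approximation on the
        coefficient with n-2 degrees of freedom (Spearman on average ranks);
        ``kendall`` is tau-b with the normal approximation.

    Returns
    -------
    (corr, pval)
        Symmetric matrices; ``corr`` has unit diagonal and ``pval`` zero
        diagonal.  Constant genes degrade to zero correlation / unit
        p-value with a warning rather than erroring, because label
        permutations can create constant subsets.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("expected a 2-D genes x samples matrix")
    n_genes, n_samples = values.shape
    if n_genes < 2:
        raise ValueError("at least 2 genes required")
    if n_samples < 3:
        raise ValueError("at least 3 samples required")

    constant = values.std(axis=1) == 0.0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant gene(s); associations set to zero",
            stacklevel=2,
        )

    if method == "kendall":
        corr, pval = _kendall_matrix(values)
    else:
        data = values if method == "pearson" else stats.rankdata(values, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = np.corrcoef(data)
        corr = np.nan_to_num(corr, nan=0.0)
        corr = np.clip(corr, -1.0, 1.0)
        pval = _t_sf_pvalue(corr, n_samples)

    if constant.any():
        corr[constant, :] = 0.0
        corr[:, constant] = 0.0
        pval[constant, :] = 1.0
        pval[:, constant] = 1.0

    corr = (corr + corr.T) / 2.0  # enforce exact symmetry against round-off
    pval = (pval + pval.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    np.fill_diagonal(pval, 0.0)
    return corr, pval


def _kendall_matrix(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = values.shape[0]
    corr = np.eye(n)
    pval = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            res = stats.kendalltau(values[i], values[j], variant="b", method="asymptotic")
            tau = 0.0 if np.isnan(res.statistic) else float(res.statistic)
            p = 1.0 if np.isnan(res.pvalue) else float(res.pvalue)
            corr[i, j] = corr[j, i] = tau
            pval[i, j] = pval[j, i] = p
    return corr, pval


# ---------------------------------------------------------------------------
# Association degrees and graph construction
# ---------------------------------------------------------------------------

def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserved)."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector of p-values")
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def association_degree(
    corr: np.ndarray,
    pval: np.ndarray,
    scale: AssociationScale = "one_minus_fdr",
) -> np.ndarray:
    """Map correlation/p-value matrices to association degrees in [0, 1].

    ``one_minus_fdr`` applies Benjamini-Hochberg over the n(n-1)/2 distinct
    off-diagonal pairs of this gene set only; the diagonal is forced to 0.
    """
    corr = np.asarray(corr, dtype=float)
    pval = np.asarray(pval, dtype=float)
    if corr.shape != pval.shape or corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("corr and pval must be conformable square matrices")
    n = corr.shape[0]
    if scale == "abs_corr":
        deg = np.abs(corr)
    elif scale == "one_minus_p":
        deg = 1.0 - pval
    elif scale == "one_minus_fdr":
        iu = np.triu_indices(n, k=1)
        adj = benjamini_hochberg(pval[iu])
        deg = np.zeros_like(pval)
        deg[iu] = 1.0 - adj
        deg = deg + deg.T
    else:
        raise ValueError(f"unknown association scale {scale!r}")
    deg = np.clip(deg, 0.0, 1.0)
    np.fill_diagonal(deg, 0.0)
    return deg


def build_graph(
    degrees: np.ndarray,
    config: AssociationConfig,
    nodes: Sequence[str] | None = None,
) -> CoExpressionGraph:
    """Build the weighted or thresholded co-expression graph from degrees."""
    degrees = np.asarray(degrees, dtype=float)
    n = degrees.shape[0]
    if nodes is None:
        nodes = [f"g{i}" for i in range(n)]
    if config.mode == "weighted":
        A = degrees.copy()
    else:
        A = (degrees >= config.threshold).astype(float)
        np.fill_diagonal(A, 0.0)
    return CoExpressionGraph(nodes, A)


def coexpression_adjacency(values: np.ndarray, config: AssociationConfig) -> np.ndarray:
    """Adjacency matrix of the co-expression graph for one phenotype's data.

    Fast path used inside permutation loops: association, scaling, and
    (optional) thresholding without constructing graph objects.
    """
    corr, pval = pairwise_association(values, config.method)
    deg = association_degree(corr, pval, config.scale)
    if config.mode == "unweighted":
        A = (deg >= config.threshold).astype(float)
        np.fill_diagonal(A, 0.0)
        return A
    return deg
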