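"""Permutation tests for differential co-expression of gene sets.

For one gene set, one co-expression graph is built per phenotype and a
distance statistic Θ ≥ 0 between the two graphs is computed.  The test of
H0: Θ = 0 against H1: Θ > 0 draws its null distribution from uniform random
permutations of the sample-phenotype labels (group sizes preserved).  The
reported p-value includes the observed statistic in the null set,
p = (1 + #{Θ_perm ≥ Θ_obs}) / (1 + B), which keeps the test valid and p
strictly positive.  Collection-level analysis filters gene sets by
post-intersection size, derives an independent seed per set, and attaches
Benjamini-Hochberg q-values across the surviving sets.

Single-gene differential expression (Welch t and Wilcoxon-Mann-Whitney) and
gene rankings by network importance round out the per-set analysis.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from . import features
from .coexpression import AssociationConfig, CoExpressionGraph, benjamini_hochberg, coexpression_adjacency
from .data_io import ExpressionMatrix, GeneSetCollection, PhenotypeLabels
from .features import GraphDistanceKind
from .spectral import BandwidthCriterion

__all__ = [
    "TestResult",
    "GeneDEResult",
    "observed_statistic",
    "permutation_test",
    "bh_adjust",
    "analyze_collection",
    "differential_expression",
    "rank_genes",
    "edge_difference_matrix",
]


@dataclass(frozen=True)
class TestResult:
    """Per-gene-set permutation test result."""

    set_name: str
    set_size: int
    statistic_name: str
    statistic: float
    p_value: float
    q_value: float = float("nan")


@dataclass(frozen=True)
class GeneDEResult:
    """Single-gene differential expression between the two phenotypes."""

    gene: str
    t_p: float
    wilcoxon_p: float
    mean_diff: float


# ---------------------------------------------------------------------------
# Observed statistic and permutation test
# ---------------------------------------------------------------------------

def _prepare(
    expr: ExpressionMatrix,
    labels: PhenotypeLabels,
    gene_set: Sequence[str],
) -> tuple[np.ndarray, list[str], np.ndarray, np.ndarray]:
    """Subset the matrix to the set's genes and split columns by phenotype."""
    present = [g for g in gene_set if g in set(expr.gene_ids)]
    if len(present) < 2:
        raise ValueError(
            f"gene set has {len(present)} gene(s) present in the expression matrix; "
            "at least 2 required"
        )
    index = {g: i for i, g in enumerate(expr.gene_ids)}
    values = expr.values[[index[g] for g in present]]
    g1, g2 = labels.groups(expr.sample_ids)
    if len(g1) < 3 or len(g2) < 3:
        raise ValueError("each phenotype needs at least 3 samples")
    return values, present, np.asarray(g1), np.asarray(g2)


def _statistic(
    values: np.ndarray,
    idx1: np.ndarray,
    idx2: np.ndarray,
    config: AssociationConfig,
    kind: GraphDistanceKind,
    criterion: BandwidthCriterion,
) -> float:
    a1 = coexpression_adjacency(values[:, idx1], config)
    a2 = coexpression_adjacency(values[:, idx2], config)
    return features.adjacency_distance(a1, a2, kind, criterion)


def observed_statistic(
    expr: ExpressionMatrix,
    labels: PhenotypeLabels,
    gene_set: Sequence[str],
    config: AssociationConfig = AssociationConfig(),
    kind: GraphDistanceKind = "spectral_js",
    criterion: BandwidthCriterion = "sturges",
) -> float:
    """Distance Θ between the two phenotypes' co-expression graphs."""
    values, _, g1, g2 = _prepare(expr, labels, gene_set)
    return _statistic(values, g1, g2, config, kind, criterion)


def permutation_test(
    expr: ExpressionMatrix,
    labels: PhenotypeLabels,
    gene_set: Sequence[str],
    config: AssociationConfig = AssociationConfig(),
    kind: GraphDistanceKind = "spectral_js",
    B: int = 1000,
    seed: int | np.random.SeedSequence = 0,
    criterion: BandwidthCriterion = "sturges",
    set_name: str = "",
) -> TestResult:
    """Label-permutation test of H0: Θ = 0 for one gene set.

    ``B`` label permutations preserving the group sizes are drawn from the
    seeded generator; p = (1 + #{Θ_b ≥ Θ_obs}) / (1 + B).
    """
    if B < 1:
        raise ValueError("at least one permutation required")
    values, present, g1, g2 = _prepare(expr, labels, gene_set)
    p, theta = _permutation_pvalue(values, g1, g2, config, kind, B, seed, criterion)
    return TestResult(
        set_name=set_name or ",".join(present[:3]) + ("..." if len(present) > 3 else ""),
        set_size=len(present),
        statistic_name=kind,
        statistic=theta,
        p_value=p,
    )


def _permutation_pvalue(
    values: np.ndarray,
    idx1: np.ndarray,
    idx2: np.ndarray,
    config: AssociationConfig,
    kind: GraphDistanceKind,
    B: int,
    seed: int | np.random.SeedSequence,
    criterion: BandwidthCriterion,
) -> tuple[float, float]:
    """Core loop shared with the simulation experiments."""
    rng = np.random.default_rng(seed)
    theta_obs = _statistic(values, idx1, idx2, config, kind, criterion)
    n1 = idx1.size
    columns = np.concatenate([idx1, idx2])
    count = 0
    for _ in range(B):
        perm = rng.permutation(columns)
        theta_b = _statistic(values, perm[:n1], perm[n1:], config, kind, criterion)
        if theta_b >= theta_obs:
            count += 1
    p = (1 + count) / (1 + B)
    return p, theta_obs


# ---------------------------------------------------------------------------
# Multiple testing and collection analysis
# ---------------------------------------------------------------------------

def bh_adjust(pvals: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    return benjamini_hochberg(np.asarray(pvals, dtype=float))


def set_seed(master_seed: int, set_name: str) -> np.random.SeedSequence:
    """Deterministic per-set seed independent of the other sets analyzed."""
    return np.random.SeedSequence([int(master_seed), zlib.crc32(set_name.encode())])


def analyze_collection(
    expr: ExpressionMatrix,
    labels: PhenotypeLabels,
    sets: GeneSetCollection,
    config: AssociationConfig = AssociationConfig(),
    kind: GraphDistanceKind = "spectral_js",
    B: int = 10000,
    min_size: int = 20,
    seed: int = 0,
    criterion: BandwidthCriterion = "sturges",
) -> list[TestResult]:
    """Permutation-test every sufficiently large gene set, with BH q-values.

    Each set is intersected with the expression matrix's genes first; sets
    smaller than ``min_size`` after intersection are dropped.  Per-set seeds
    derive from the master seed and the set name, so adding or removing sets
    does not perturb the other sets' p-values.  Results are sorted by
    ascending p-value.
    """
    if len(sets) == 0:
        raise ValueError("no gene sets to analyze")
    gene_index = set(expr.gene_ids)
    results: list[TestResult] = []
    for name, (_, genes) in sets:
        present = [g for g in genes if g in gene_index]
        if len(present) < min_size:
            continue
        res = permutation_test(
            expr, labels, present, config, kind, B,
            seed=set_seed(seed, name), criterion=criterion, set_name=name,
        )
        results.append(res)
    if not results:
        raise ValueError(f"no gene set has {min_size} or more genes in the expression matrix")
    qvals = bh_adjust([r.p_value for r in results])
    results = [replace(r, q_value=float(q)) for r, q in zip(results, qvals)]
    results.sort(key=lambda r: (r.p_value, r.set_name))
    return results


# ---------------------------------------------------------------------------
# Single-gene differential expression and rankings
# ---------------------------------------------------------------------------

def differential_expression(
    expr: ExpressionMatrix,
    labels: PhenotypeLabels,
    gene_set: Sequence[str],
) -> list[GeneDEResult]:
    """Welch t-test and two-sided Wilcoxon rank-sum per gene in the set.

    Nominal (unadjusted) p-values are reported.  A gene constant in both
    groups gets p = 1 with a warning.
    """
    values, present, g1, g2 = _prepare(expr, labels, gene_set)
    x, y = values[:, g1], values[:, g2]
    results: list[GeneDEResult] = []
    for i, gene in enumerate(present):
        xi, yi = x[i], y[i]
        if xi.std() == 0.0 and yi.std() == 0.0 and xi.mean() == yi.mean():
            warnings.warn(f"gene {gene!r} constant in both groups; p set to 1", stacklevel=2)
            t_p = w_p = 1.0
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                t_res = stats.ttest_ind(xi, yi, equal_var=False)
                t_p = 1.0 if np.isnan(t_res.pvalue) else float(t_res.pvalue)
                w_res = stats.mannwhitneyu(xi, yi, alternative="two-sided")
                w_p = 1.0 if np.isnan(w_res.pvalue) else float(w_res.pvalue)
        results.append(GeneDEResult(gene, t_p, w_p, float(xi.mean() - yi.mean())))
    return results


_RANK_KINDS = {
    "degree": features.degree_centrality,
    "eigenvector": features.eigenvector_centrality,
    "clustering": features.local_clustering,
}


def rank_genes(graph: CoExpressionGraph, kind: str) -> list[tuple[str, float]]:
    """Rank the set's genes by a network-importance score, descending.

    Ties break alphabetically by gene symbol.  Betweenness and closeness
    require an unweighted graph.
    """
    if kind in _RANK_KINDS:
        scores = _RANK_KINDS[kind](graph)
    elif kind in ("betweenness", "closeness"):
        scores = features.path_centrality(graph, kind)
    else:
        raise ValueError(f"unknown score kind {kind!r}")
    pairs = list(zip(scores.nodes, (float(v) for v in scores.values)))
    pairs.sort(key=lambda gv: (-gv[1], gv[0]))
    return pairs


def edge_difference_matrix(g1: CoExpressionGraph, g2: CoExpressionGraph) -> np.ndarray:
    """Elementwise difference of the two phenotypes' adjacency matrices."""
    if g1.nodes != g2.nodes:
        raise ValueError("graphs must share the same node set and order")
    return g1.adjacency - g2.adjacency
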