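"""Synthetic expression data and Monte Carlo experiments.

Two experiments characterise the permutation test with no external data:

* **False-positive rate.**  Two phenotype groups are repeatedly resampled
  with replacement from one pooled expression matrix (so the null Θ = 0
  holds by construction), a random gene set is drawn, and the permutation
  test is run; the fraction of p-values at or below each significance level
  α estimates the type-I error and should track α.

* **Power.**  Two equal groups are drawn from the pool and the expression
  values of a proportion γ of the set's genes are independently permuted
  across samples in one group only, destroying that group's co-expression
  structure; the fraction of rejections over many replicates, traced over
  a dense α grid, yields an empirical ROC curve whose area summarises
  power (0.5 at γ = 0, approaching 1 as γ grows).

The synthetic pool is a zero-mean multivariate normal with block-constant
correlation: genes inside a block share a common correlation and blocks are
mutually independent, mimicking tightly co-expressed gene modules.  The
default pool (50 genes in 5 blocks of 10 at ρ = 0.6, 200 samples) carries
enough correlation structure for the power experiment to have signal to
destroy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .coexpression import AssociationConfig
from .data_io import ExpressionMatrix
from .features import GraphDistanceKind
from .spectral import BandwidthCriterion
from .testing import _permutation_pvalue

__all__ = [
    "SimulationConfig",
    "ExperimentReport",
    "default_alphas",
    "generate_expression",
    "fpr_experiment",
    "power_experiment",
    "roc_auc",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the block-correlated Gaussian expression generator.

    Genes inside each block share pairwise correlation
    ``within_block_correlation``; genes outside all blocks (and pairs in
    different blocks) are independent.  ``noise_sd`` scales every gene's
    standard deviation.
    """

    n_genes: int = 50
    n_samples: int = 200
    block_sizes: tuple[int, ...] = (10, 10, 10, 10, 10)
    within_block_correlation: float = 0.6
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.block_sizes) > self.n_genes:
            raise ValueError("block sizes exceed the number of genes")
        if not 0.0 <= self.within_block_correlation < 1.0:
            raise ValueError("within-block correlation must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    def correlation_matrix(self) -> np.ndarray:
        C = np.eye(self.n_genes)
        start = 0
        rho = self.within_block_correlation
        for size in self.block_sizes:
            block = slice(start, start + size)
            C[block, block] = rho
            start += size
        np.fill_diagonal(C, 1.0)
        return C


@dataclass(frozen=True)
class ExperimentReport:
    """Rejection rates over an α grid, with the summarising ROC area."""

    alphas: np.ndarray
    rejection_rates: np.ndarray
    auc: float
    n_reps: int
    n_perms: int
    seed: int
    p_values: np.ndarray = field(default=None, repr=False)

    def rejection_rate(self, alpha: float) -> float:
        """Fraction of replicate p-values at or below ``alpha``."""
        return float(np.mean(self.p_values <= alpha))


def default_alphas() -> np.ndarray:
    """Dense α grid {0.005, 0.010, ..., 1.0} for ROC construction."""
    return np.arange(1, 201) / 200.0


def generate_expression(config: SimulationConfig) -> ExpressionMatrix:
    """Draw a block-correlated Gaussian expression matrix (genes x samples).

    Sampling goes through the Cholesky factor of the implied correlation
    matrix, so the draw is exact and fully determined by ``config.seed``.
    """
    C = config.correlation_matrix()
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise ValueError("implied correlation matrix is not positive definite") from exc
    rng = np.random.default_rng(config.seed)
    Z = rng.standard_normal((config.n_genes, config.n_samples))
    values = config.noise_sd * (L @ Z)
    genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    samples = [f"S{j + 1:04d}" for j in range(config.n_samples)]
    return ExpressionMatrix(values, genes, samples)


# ---------------------------------------------------------------------------
# Monte Carlo experiments
# ---------------------------------------------------------------------------

def _finish_report(
    pvals: np.ndarray,
    alphas: np.ndarray,
    n_reps: int,
    n_perms: int,
    seed: int,
) -> ExperimentReport:
    rates = np.array([(pvals <= a).mean() for a in alphas])
    return ExperimentReport(
        alphas=alphas,
        rejection_rates=rates,
        auc=roc_auc(alphas, rates),
        n_reps=n_reps,
        n_perms=n_perms,
        seed=seed,
        p_values=pvals,
    )


def fpr_experiment(
    pool: ExpressionMatrix,
    group_sizes: tuple[int, int] = (65, 30),
    set_size: int = 20,
    n_reps: int = 200,
    n_perms: int = 200,
    alphas: np.ndarray | None = None,
    kind: GraphDistanceKind = "spectral_js",
    config: AssociationConfig = AssociationConfig(),
    seed: int = 0,
    criterion: BandwidthCriterion = "sturges",
) -> ExperimentReport:
    """Null false-positive-rate experiment by resampling one pooled dataset.

    Per replicate, two groups of ``group_sizes`` columns are drawn with
    replacement from the pool, a random gene set of ``set_size`` is chosen,
    and the permutation test is run; the report's rejection rate at each α
    estimates the type-I error.  Replicate seeds derive from ``seed`` and
    the replicate index, so the result is independent of execution order.
    """
    if pool.n_genes < set_size:
        raise ValueError("pool has fewer genes than the requested set size")
    if alphas is None:
        alphas = default_alphas()
    n1, n2 = group_sizes
    pvals = np.empty(n_reps)
    for rep in range(n_reps):
        ss = np.random.SeedSequence([seed, rep])
        draw_seed, perm_seed = ss.spawn(2)
        rng = np.random.default_rng(draw_seed)
        cols1 = rng.integers(0, pool.n_samples, size=n1)
        cols2 = rng.integers(0, pool.n_samples, size=n2)
        genes = rng.choice(pool.n_genes, size=set_size, replace=False)
        values = pool.values[np.ix_(genes, np.concatenate([cols1, cols2]))]
        p, _ = _permutation_pvalue(
            values, np.arange(n1), np.arange(n1, n1 + n2),
            config, kind, n_perms, perm_seed, criterion,
        )
        pvals[rep] = p
    return _finish_report(pvals, np.asarray(alphas, float), n_reps, n_perms, seed)


def power_experiment(
    pool: ExpressionMatrix,
    gamma: float,
    set_size: int = 50,
    group_size: int = 40,
    n_reps: int = 200,
    n_perms: int = 200,
    alphas: np.ndarray | None = None,
    kind: GraphDistanceKind = "spectral_js",
    config: AssociationConfig = AssociationConfig(),
    seed: int = 0,
    criterion: BandwidthCriterion = "sturges",
) -> ExperimentReport:
    """Power experiment: γ of the set's genes are scrambled in one group.

    Per replicate, ``2 * group_size`` columns are drawn with replacement
    from the pool and split in half; ``ceil(gamma * set_size)`` randomly
    chosen genes have their expression values independently permuted across
    samples within the second group only, altering its co-expression graph.
    The report's ROC area summarises the empirical power over the α grid.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    if pool.n_genes < set_size:
        raise ValueError("pool has fewer genes than the requested set size")
    if alphas is None:
        alphas = default_alphas()
    n_altered = math.ceil(gamma * set_size)
    pvals = np.empty(n_reps)
    for rep in range(n_reps):
        ss = np.random.SeedSequence([seed, rep])
        draw_seed, perm_seed = ss.spawn(2)
        rng = np.random.default_rng(draw_seed)
        cols = rng.integers(0, pool.n_samples, size=2 * group_size)
        genes = rng.choice(pool.n_genes, size=set_size, replace=False)
        values = pool.values[np.ix_(genes, cols)].copy()
        if n_altered:
            altered = rng.choice(set_size, size=n_altered, replace=False)
            for g in altered:
                shuffle = rng.permutation(group_size)
                values[g, group_size:] = values[g, group_size + shuffle]
        p, _ = _permutation_pvalue(
            values, np.arange(group_size), np.arange(group_size, 2 * group_size),
            config, kind, n_perms, perm_seed, criterion,
        )
        pvals[rep] = p
    return _finish_report(pvals, np.asarray(alphas, float), n_reps, n_perms, seed)


def roc_auc(alphas: np.ndarray, power: np.ndarray) -> float:
    """Trapezoidal area under the power-vs-significance-level curve.

    The curve is anchored at (0, 0) on the left and extended flat to
    (1, power at the largest α) on the right.
    """
    a = np.asarray(alphas, dtype=float)
    pw = np.asarray(power, dtype=float)
    if a.shape != pw.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("alphas and power must be conformable 1-D vectors")
    if np.any(np.diff(a) <= 0):
        raise ValueError("alphas must be strictly increasing")
    if a.min() < 0.0 or a.max() > 1.0:
        raise ValueError("alphas must lie in [0, 1]")
    if a[0] > 0.0:
        a = np.concatenate([[0.0], a])
        pw = np.concatenate([[0.0], pw])
    if a[-1] < 1.0:
        a = np.concatenate([a, [1.0]])
        pw = np.concatenate([pw, [pw[-1]]])
    return float(np.trapezoid(pw, a))
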