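"""Permutation null, empirical p-values, resampling FDR and repeatability.

The null resamples class labels over subjects (never genes), preserving
gene-gene correlation. Every permutation recomputes t, t² and a fresh
standardization before pathway scoring, so observed and permuted global
statistics live on the same scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.stats

from acst import core_stats
from acst.consistency_engine import (
    WeightFn,
    compile_scorers,
    global_statistic,
    reciprocal_weight,
)
from acst.core_stats import (
    gene_universe,
    standardize_columns,
    welch_t_permutations,
)
from acst.expression_io import ExpressionDataset
from acst.pathway_io import PathwayGraph

logger = logging.getLogger(__name__)


@dataclass
class PermutationNull:
    B: int
    seed: int
    pathway_ids: list[str]
    stats: np.ndarray  # |pathways| × B permuted global statistics
    observed: np.ndarray  # length |pathways|


@dataclass
class PathwayResult:
    pathway_id: str
    name: str
    n_genes_measured: int
    n_subgraphs: int
    global_stat: float
    pvalue: float
    adj_pvalue: float
    significant: bool
    top_subgraph_nodes: list[str] = field(default_factory=list)
    subgraphs: list = field(default_factory=list)


def permute_labels(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Uniformly random relabeling preserving both group sizes."""
    return labels[rng.permutation(len(labels))]


def _permutation_masks(labels: np.ndarray, test_label, B: int, rng: np.random.Generator) -> np.ndarray:
    """subjects × B boolean test-group masks, one independent draw each."""
    base = np.asarray(labels == test_label)
    masks = np.empty((len(labels), B), dtype=bool)
    for b in range(B):
        masks[:, b] = base[rng.permutation(len(labels))]
    return masks


def permutation_null(
    dataset: ExpressionDataset,
    catalog: Sequence[PathwayGraph],
    B: int = 1000,
    seed: int = 0,
    weight: WeightFn = reciprocal_weight,
) -> PermutationNull:
    """Global statistics under B label permutations, plus the observed ones.

    Permutations are sampled with replacement from the permissible set.
    The observed vector runs through the identical code path (same t,
    same per-labeling standardization) with the true labels.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    universe = gene_universe(dataset, catalog)
    idx = dataset.gene_index()
    values = dataset.values[[idx[g] for g in universe], :]
    scorers = compile_scorers(catalog, universe, weight)

    def score_masks(masks: np.ndarray) -> np.ndarray:
        t = welch_t_permutations(values, masks)
        z = standardize_columns(t**2)
        out = np.empty((len(scorers), masks.shape[1]))
        for b in range(masks.shape[1]):
            tb, zb = t[:, b], z[:, b]
            for i, scorer in enumerate(scorers):
                out[i, b] = scorer.score(tb, zb)
        return out

    observed = score_masks(dataset.test_mask[:, None])[:, 0]

    rng = np.random.default_rng(seed)
    # all B labelings scored in one batch: t for every permutation comes
    # from two GEMMs, and identical inputs give bit-identical outputs
    masks = _permutation_masks(dataset.labels, dataset.test_label, B, rng)
    stats = score_masks(masks)
    return PermutationNull(
        B=B,
        seed=seed,
        pathway_ids=[g.pathway_id for g in catalog],
        stats=stats,
        observed=observed,
    )


def empirical_pvalue(observed: float, null_row: np.ndarray) -> float:
    """p = (1 + #{b : null_b >= observed}) / (B + 1); never 0."""
    null_row = np.asarray(null_row, dtype=float)
    if null_row.size < 1:
        raise ValueError("need at least one permutation")
    return float((1 + np.sum(null_row >= observed)) / (null_row.size + 1))


def fdr_point_estimate(observed: np.ndarray, stats: np.ndarray) -> np.ndarray:
    """Resampling-based FDR point estimate at each observed statistic.

    At threshold c_k = observed_k: R = #{j : observed_j >= c_k} and
    V̂ = (1/B)·Σ_b #{j : stats[j, b] >= c_k}. The raw estimate V̂/R is
    capped at 1 and monotonized step-up style: the adjusted value at c is
    the minimum of the capped raw values over all thresholds <= c, so the
    result is non-increasing in the observed statistic. Ties share one
    adjusted value; the output is invariant to pathway order.
    """
    observed = np.asarray(observed, dtype=float)
    stats = np.asarray(stats, dtype=float)
    m = observed.size
    if m < 1:
        raise ValueError("need at least one pathway")
    if stats.shape[0] != m:
        raise ValueError(f"stats has {stats.shape[0]} rows for {m} observed values")
    B = stats.shape[1]
    raw = np.empty(m)
    for k in range(m):
        c = observed[k]
        r = np.sum(observed >= c)
        v = np.sum(stats >= c) / B
        raw[k] = min(1.0, v / r)
    # running min from the smallest observed statistic upward
    order = np.argsort(observed, kind="stable")  # ascending
    adjusted = np.empty(m)
    running = np.inf
    for k in order:
        running = min(running, raw[k])
        adjusted[k] = running
    # ties share one value: same c gives same raw and same running min
    return adjusted


def repeatability(pvals_a: Sequence[float], pvals_b: Sequence[float]) -> tuple[float, float, float]:
    """Spearman rank correlation between two matched p-value lists, with an
    F-test of significance: F = rho²·(n-2)/(1-rho²) on (1, n-2) df.

    Returns (rho, F, pvalue); rho = ±1 gives F = inf and p = 0.
    """
    a = np.asarray(pvals_a, dtype=float)
    b = np.asarray(pvals_b, dtype=float)
    if a.size != b.size:
        raise ValueError("p-value vectors differ in length")
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 matched pathways")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValueError("constant p-value vector: rank correlation undefined")
    rho = float(scipy.stats.spearmanr(a, b).statistic)
    if abs(rho) >= 1.0:
        return rho, float("inf"), 0.0
    F = rho**2 * (n - 2) / (1 - rho**2)
    p = float(scipy.stats.f.sf(F, 1, n - 2))
    return rho, float(F), p


def bonferroni(pvalues: Sequence[float], k: int | None = None) -> np.ndarray:
    """Bonferroni correction across ``k`` comparisons (default: len(pvalues))."""
    p = np.asarray(pvalues, dtype=float)
    return np.minimum(1.0, p * (k if k is not None else p.size))


def analyze(
    dataset: ExpressionDataset,
    catalog: Sequence[PathwayGraph],
    B: int = 1000,
    seed: int = 0,
    weight: WeightFn = reciprocal_weight,
    alpha_adj: float = 0.25,
) -> list[PathwayResult]:
    """Full inference pass: permutation null → p-values → FDR → results.

    ``catalog`` must already be restricted to measured genes. Results come
    back in catalog order; subgraph detail is recomputed at the observed
    labeling for reporting.
    """
    null = permutation_null(dataset, catalog, B=B, seed=seed, weight=weight)
    pvals = np.array([empirical_pvalue(null.observed[i], null.stats[i]) for i in range(len(catalog))])
    adj = fdr_point_estimate(null.observed, null.stats)

    universe = gene_universe(dataset, catalog)
    stats = core_stats.gene_stats(dataset, universe)
    t_by_gene = {s.gene: s.t for s in stats}
    z_by_gene = {s.gene: s.z for s in stats}

    results = []
    for i, g in enumerate(catalog):
        score = global_statistic(g, t_by_gene, z_by_gene, weight)
        top = sorted(score.subgraphs[0].nodes) if score.subgraphs else []
        results.append(
            PathwayResult(
                pathway_id=g.pathway_id,
                name=g.name,
                n_genes_measured=g.n_nodes,
                n_subgraphs=len(score.subgraphs),
                global_stat=float(null.observed[i]),
                pvalue=float(pvals[i]),
                adj_pvalue=float(adj[i]),
                significant=bool(adj[i] < alpha_adj),
                top_subgraph_nodes=top,
                subgraphs=score.subgraphs,
            )
        )
    return results
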