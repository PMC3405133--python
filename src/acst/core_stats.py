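"""Per-gene Welch t statistics and the standardized local statistic.

The signed Welch t (test minus control) carries the direction of
expression change; its square, standardized across the catalog-wide gene
universe, is the local statistic summed inside consistent subgraphs.
Standardization is what makes scores comparable between the observed
labeling and the label-permutation null, where raw t statistics shrink.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: floor on the Welch standard error; keeps zero-variance genes finite
SE_FLOOR = 1e-12


@dataclass(frozen=True)
class GeneStats:
    gene: str
    t: float
    tsq: float
    z: float


def welch_t(x: Sequence[float], y: Sequence[float]) -> float:
    """Signed Welch t statistic of test group ``x`` minus control ``y``.

    t = (mean(x) - mean(y)) / sqrt(var(x)/nx + var(y)/ny) with sample
    (n-1) variances; the standard error is floored at ``SE_FLOOR`` so a
    gene constant in both groups with equal means returns exactly 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError(f"each group needs >= 2 values (got {x.size} and {y.size})")
    se = np.sqrt(x.var(ddof=1) / x.size + y.var(ddof=1) / y.size)
    return float((x.mean() - y.mean()) / max(se, SE_FLOOR))


def welch_t_matrix(values: np.ndarray, test_mask: np.ndarray) -> np.ndarray:
    """Row-wise Welch t for a genes × subjects matrix under one labeling."""
    return welch_t_permutations(values, np.asarray(test_mask, dtype=bool)[:, None])[:, 0]


def welch_t_permutations(values: np.ndarray, test_masks: np.ndarray) -> np.ndarray:
    """Welch t for every column of ``test_masks`` at once.

    values: genes × subjects; test_masks: subjects × B boolean. Returns a
    genes × B matrix. Group means/variances come from two matrix products,
    so the permutation null costs two GEMMs per batch.
    """
    values = np.asarray(values, dtype=float)
    masks = np.asarray(test_masks, dtype=float)
    n1 = masks.sum(axis=0)
    n2 = masks.shape[0] - n1
    if np.any(n1 < 2) or np.any(n2 < 2):
        raise ValueError("each group needs >= 2 subjects in every labeling")
    sum1 = values @ masks
    sumsq1 = (values**2) @ masks
    total = values.sum(axis=1, keepdims=True)
    totalsq = (values**2).sum(axis=1, keepdims=True)
    mean1 = sum1 / n1
    mean2 = (total - sum1) / n2
    # sample variances, clipped at 0 against rounding
    var1 = np.maximum(sumsq1 - n1 * mean1**2, 0.0) / (n1 - 1)
    var2 = np.maximum((totalsq - sumsq1) - n2 * mean2**2, 0.0) / (n2 - 1)
    se = np.sqrt(var1 / n1 + var2 / n2)
    return (mean1 - mean2) / np.maximum(se, SE_FLOOR)


def gene_universe(dataset, catalog: Iterable) -> list[str]:
    """Ordered (lexicographic) union of pathway genes measured in the dataset.

    This is the standardization universe: every gene of the pathway
    catalog that has an expression row.
    """
    pathway_genes: set[str] = set()
    for g in catalog:
        pathway_genes |= g.nodes
    measured = pathway_genes & set(dataset.genes)
    if not measured:
        raise ValueError("no pathway gene measured in the expression dataset")
    return sorted(measured)


def standardize(tsq_by_gene: Mapping[str, float]) -> dict[str, float]:
    """Center and scale squared t statistics over the gene universe.

    z_g = (tsq_g - mean) / sd with the sample (n-1) standard deviation.
    A degenerate universe (sd == 0) yields all-zero z with a warning.
    """
    genes = list(tsq_by_gene)
    if len(genes) < 2:
        raise ValueError("standardization needs >= 2 genes")
    tsq = np.array([tsq_by_gene[g] for g in genes], dtype=float)
    z = standardize_vector(tsq)
    return dict(zip(genes, z.tolist()))


def standardize_vector(tsq: np.ndarray) -> np.ndarray:
    tsq = np.asarray(tsq, dtype=float)
    if tsq.size < 2:
        raise ValueError("standardization needs >= 2 genes")
    sd = tsq.std(ddof=1)
    if sd == 0:
        logger.warning("degenerate gene universe: all squared t statistics equal; z set to 0")
        return np.zeros_like(tsq)
    return (tsq - tsq.mean()) / sd


def standardize_columns(tsq: np.ndarray) -> np.ndarray:
    """Column-wise standardization of a genes × B squared-t matrix."""
    tsq = np.asarray(tsq, dtype=float)
    if tsq.shape[0] < 2:
        raise ValueError("standardization needs >= 2 genes")
    sd = tsq.std(axis=0, ddof=1)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning("degenerate gene universe in %d permutation(s); z set to 0", int(degenerate.sum()))
    safe_sd = np.where(degenerate, 1.0, sd)
    z = (tsq - tsq.mean(axis=0)) / safe_sd
    z[:, degenerate] = 0.0
    return z


def gene_stats(dataset, universe: Sequence[str]) -> list[GeneStats]:
    """Observed-labeling t, t² and z for every universe gene."""
    idx = dataset.gene_index()
    rows = [idx[g] for g in universe]
    t = welch_t_matrix(dataset.values[rows, :], dataset.test_mask)
    tsq = t**2
    z = standardize_vector(tsq)
    return [GeneStats(g, float(t[i]), float(tsq[i]), float(z[i])) for i, g in enumerate(universe)]
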