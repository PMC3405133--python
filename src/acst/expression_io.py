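"""Expression matrix and two-group label loading/validation."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ExpressionDataset:
    """Gene × subject expression values with a two-group labeling.

    ``test_label`` names the tested (e.g. disease) group; the other label
    is the control. The subject is the permutation unit downstream.
    """

    genes: list[str]
    subjects: list[str]
    values: np.ndarray  # shape (len(genes), len(subjects)), float64
    labels: np.ndarray  # shape (len(subjects),), dtype object/str
    test_label: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.values.shape != (len(self.genes), len(self.subjects)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.genes)} genes × {len(self.subjects)} subjects"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene ids")
        if len(set(self.subjects)) != len(self.subjects):
            raise ValueError("duplicate subject ids")
        groups = set(self.labels.tolist())
        if len(groups) != 2:
            raise ValueError(f"expected exactly two groups, found {sorted(map(str, groups))}")
        if self.test_label not in groups:
            raise ValueError(f"test label {self.test_label!r} not among groups {sorted(map(str, groups))}")
        n_test = int(np.sum(self.labels == self.test_label))
        n_control = len(self.labels) - n_test
        if min(n_test, n_control) < 2:
            raise ValueError(f"each group needs >= 2 subjects (got {n_test} test, {n_control} control)")
        if np.isnan(self.values).any():
            raise ValueError("values contain missing entries")

    @property
    def control_label(self) -> str:
        return next(l for l in set(self.labels.tolist()) if l != self.test_label)

    @property
    def test_mask(self) -> np.ndarray:
        return np.asarray(self.labels == self.test_label)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}


def load_expression(
    matrix_source,
    labels_source,
    test_label: str,
    missing: str = "drop",
) -> ExpressionDataset:
    """Load an expression TSV (genes × subjects, header row of subject ids,
    first column of gene ids) and a labels TSV (``subject<TAB>group``).

    ``missing`` policy: ``"drop"`` removes genes with any missing value
    (logged); ``"strict"`` raises instead. Gzip-compressed paths are
    accepted (delegated to pandas).
    """
    if missing not in ("drop", "strict"):
        raise ValueError(f"unknown missing-value policy {missing!r}")
    matrix = pd.read_csv(matrix_source, sep="\t", index_col=0)
    if matrix.index.has_duplicates:
        dupes = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dupes[:5]}")
    try:
        matrix = matrix.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric expression value: {exc}") from exc

    bad = matrix.isna().any(axis=1)
    if bad.any():
        if missing == "strict":
            raise ValueError(f"{int(bad.sum())} gene(s) have missing values (policy 'strict')")
        logger.info("dropped %d gene(s) with missing values", int(bad.sum()))
        matrix = matrix.loc[~bad]

    label_df = pd.read_csv(labels_source, sep="\t", header=None, dtype=str, comment="#")
    if label_df.shape[1] < 2:
        raise ValueError("labels file must have two tab-separated columns: subject, group")
    label_df = label_df.iloc[:, :2]
    label_df.columns = ["subject", "group"]
    if list(label_df.iloc[0]) == ["subject", "group"]:
        label_df = label_df.iloc[1:]
    label_map = dict(zip(label_df["subject"], label_df["group"]))

    subjects = [str(c) for c in matrix.columns]
    missing_subjects = [s for s in subjects if s not in label_map]
    if missing_subjects:
        raise ValueError(f"subject(s) missing from labels file: {missing_subjects}")
    labels = np.array([label_map[s] for s in subjects], dtype=object)

    return ExpressionDataset(
        genes=[str(g) for g in matrix.index],
        subjects=subjects,
        values=matrix.to_numpy(dtype=float),
        labels=labels,
        test_label=test_label,
    )


def subset_genes(dataset: ExpressionDataset, genes: Sequence[str]) -> ExpressionDataset:
    """Row-subset of the dataset in the given gene order."""
    idx = dataset.gene_index()
    rows = [idx[g] for g in genes]
    return ExpressionDataset(
        genes=list(genes),
        subjects=dataset.subjects,
        values=dataset.values[rows, :],
        labels=dataset.labels,
        test_label=dataset.test_label,
    )
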