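"""Cell-type expression reference: averaged profiles plus category annotation.

The reference emulates a multi-tissue single-cell atlas collapsed to one
mean-expression profile per annotated cell type.  A biological cell type
sampled from several tissues appears as one reference row per tissue
(distinct ids), which is what the per-tissue deduplication rule downstream
operates on.  Expression values are used as given; the rank statistics
downstream are invariant to any monotone per-row rescaling, so no
re-normalisation is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger("cfrank")

CATEGORIES = [
    "monocytes",
    "lymphocytes",
    "granulocytes",
    "progenitor_erythroid",
    "endothelial",
    "other_tissue",
    "stromal",
    "hepatic",
]

#: categories counted as immune for feature-selection and classification
IMMUNE_CATEGORIES = ["monocytes", "lymphocytes", "granulocytes"]


@dataclass
class ExpressionReference:
    """cell_type x gene mean-expression matrix with per-type annotations.

    ``expr`` is indexed by cell-type id; ``annotation`` (same index) carries
    category, compartment and tissue columns.
    """

    expr: pd.DataFrame
    annotation: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.expr.index.duplicated().any():
            raise ValueError("duplicate cell-type ids in reference")
        if (self.expr.to_numpy() < 0).any():
            raise ValueError("negative expression in reference")
        if self.annotation is None:
            self.annotation = pd.DataFrame(index=self.expr.index)

    @property
    def cell_types(self) -> pd.Index:
        return self.expr.index

    @property
    def genes(self) -> pd.Index:
        return self.expr.columns

    def categories(self) -> pd.Series:
        if "category" not in self.annotation.columns:
            raise ValueError("reference has no category annotation")
        return self.annotation["category"]


def build_celltype_profiles(
    cell_matrix: pd.DataFrame, labels: pd.Series | dict
) -> ExpressionReference:
    """Average a cell x gene matrix into per-cell-type mean profiles.

    Every cell (row) must carry a label; e[t, g] is the arithmetic mean of
    gene g over the cells labelled t.
    """
    labels = pd.Series(labels)
    unlabeled = cell_matrix.index.difference(labels.dropna().index)
    if len(unlabeled):
        raise ValueError(f"unlabeled cells: {list(unlabeled[:5])}")
    grouped = cell_matrix.groupby(labels.reindex(cell_matrix.index)).mean()
    grouped.index.name = "cell_type"
    log.info("averaged %d cells into %d cell-type profiles", len(cell_matrix), len(grouped))
    return ExpressionReference(grouped)


def intersect_genes(reference: ExpressionReference, coverage_genes) -> list[str]:
    """Sorted intersection of the reference gene universe with coverage genes."""
    shared = sorted(set(reference.genes) & set(coverage_genes))
    if not shared:
        raise ValueError("no genes shared between reference and coverage")
    log.info("gene universe intersection: %d shared genes", len(shared))
    return shared


def assign_categories(
    reference: ExpressionReference,
    mapping: pd.DataFrame,
    allow_default: bool = False,
) -> ExpressionReference:
    """Attach category/compartment/tissue annotations to reference rows.

    ``mapping`` is indexed by cell-type id (or carries a cell_type column)
    with columns category, compartment and tissue.  Unmapped types raise
    unless ``allow_default`` sends them to category ``other_tissue``.
    """
    if "cell_type" in mapping.columns:
        mapping = mapping.set_index("cell_type")
    unmapped = reference.cell_types.difference(mapping.index)
    if len(unmapped):
        if not allow_default:
            raise ValueError(f"unmapped cell types: {list(unmapped)}")
        log.warning("%d unmapped cell types assigned category 'other_tissue'", len(unmapped))
    ann = mapping.reindex(reference.cell_types)
    for col in ("category", "compartment", "tissue"):
        if col not in ann.columns:
            ann[col] = pd.NA
    ann["category"] = ann["category"].fillna("other_tissue")
    bad = ~ann["category"].isin(CATEGORIES)
    if bad.any():
        raise ValueError(f"unknown category {ann.loc[bad, 'category'].iloc[0]!r}")
    return ExpressionReference(reference.expr, ann[["category", "compartment", "tissue"]])
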