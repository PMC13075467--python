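"""Cell-of-origin ranking from TSS coverage.

The core inference: each reference cell type's expression profile is
Spearman-correlated with a sample's per-gene TSS coverage; because
expressed TSSs are nucleosome-depleted, a stronger *negative* correlation
means a larger inferred cfDNA contribution.  Cell types are ranked 1..N
per sample, higher rank = greater contribution.  Ranks are per-sample
relative quantities — any strictly increasing transform of coverage or of
an expression row leaves them unchanged — and no cross-sample
normalisation is applied.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .reference import ExpressionReference

log = logging.getLogger("cfrank")


def spearman_rho(x, y) -> float:
    """Tie-aware Spearman correlation (Pearson on average ranks).

    Pairs with a missing entry are removed first; fewer than 3 complete
    pairs or a zero-variance ranked vector yields NaN (with a warning).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        log.warning("fewer than 3 complete pairs; Spearman undefined")
        return float("nan")
    rx, ry = rankdata(x), rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        log.warning("zero variance in ranked vector; Spearman undefined")
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


def correlate_celltypes(
    coverage: pd.Series,
    reference: ExpressionReference,
    shared_genes,
) -> pd.Series:
    """Spearman rho between each cell type's expression and the coverage.

    Genes with missing coverage are dropped pairwise; a cell type with
    fewer than 3 complete pairs or constant ranks gets NaN.
    """
    shared = list(shared_genes)
    cov = coverage.reindex(shared).to_numpy(dtype=float)
    expr = reference.expr[shared].to_numpy(dtype=float)
    ok = ~np.isnan(cov)
    if ok.sum() < 3:
        raise ValueError("coverage present for fewer than 3 shared genes")
    if ok.sum() < len(shared):
        log.info("%d shared genes dropped pairwise (missing coverage)",
                 len(shared) - int(ok.sum()))
    cov, expr = cov[ok], expr[:, ok]
    rc = rankdata(cov)
    re = rankdata(expr, axis=1)
    rc_c = rc - rc.mean()
    re_c = re - re.mean(axis=1, keepdims=True)
    denom = np.sqrt((re_c ** 2).sum(axis=1) * (rc_c ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, re_c @ rc_c / denom, np.nan)
    if rc_c.std() == 0:
        rho = np.full(len(rho), np.nan)
    n_missing = int(np.isnan(rho).sum())
    if n_missing:
        log.warning("%d cell types with undefined correlation", n_missing)
    return pd.Series(rho, index=reference.cell_types, name="rho")


def rank_celltypes(rhos: pd.Series) -> pd.DataFrame:
    """Rank cell types by strength of negative correlation.

    Rank is the average rank of (-rho) ascending: the most negative rho
    gets rank N (largest inferred contribution).  Missing rhos are
    excluded, reducing N for that sample.
    """
    valid = rhos.dropna()
    if len(valid) < 2:
        raise ValueError("need at least 2 non-missing correlations to rank")
    if len(valid) < len(rhos):
        log.warning("%d cell types excluded from ranking (missing rho)",
                    len(rhos) - len(valid))
    ranks = pd.Series(rankdata(-valid.to_numpy()), index=valid.index)
    out = pd.DataFrame({"rho": rhos, "rank": ranks.reindex(rhos.index)})
    out.index.name = "cell_type"
    return out


def group_rank(ranks: pd.Series, grouping: pd.Series) -> pd.Series:
    """Median member rank per group label (one sample's rank vector)."""
    grouping = grouping.reindex(ranks.index)
    out = ranks.groupby(grouping).median()
    out.name = "median_rank"
    return out


def rank_samples(
    coverages: dict[str, pd.Series],
    reference: ExpressionReference,
    shared_genes,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank every sample; returns (sample x cell_type ranks, rhos)."""
    rho_rows, rank_rows = {}, {}
    for sample_id, cov in coverages.items():
        rho = correlate_celltypes(cov, reference, shared_genes)
        rank_rows[sample_id] = rank_celltypes(rho)["rank"]
        rho_rows[sample_id] = rho
    ranks = pd.DataFrame(rank_rows).T
    rhos = pd.DataFrame(rho_rows).T
    ranks.index.name = rhos.index.name = "sample_id"
    return ranks, rhos


def category_ranks(ranks: pd.DataFrame, grouping: pd.Series) -> pd.DataFrame:
    """Per-sample median rank per group label (sample x label table)."""
    return ranks.T.groupby(grouping.reindex(ranks.columns)).median().T


def ranks_long(
    ranks: pd.DataFrame, rhos: pd.DataFrame, reference: ExpressionReference
) -> pd.DataFrame:
    """Long-format (sample, cell_type, tissue, category, rho, rank) table."""
    long = (
        ranks.stack().rename("rank").reset_index()
        .rename(columns={"level_1": "cell_type"})
    )
    long["rho"] = rhos.stack().to_numpy()
    ann = reference.annotation
    for col in ("tissue", "category"):
        if col in ann.columns:
            long[col] = long["cell_type"].map(ann[col])
    return long
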