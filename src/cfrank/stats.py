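"""Case-control and longitudinal statistics on cell-type ranks.

Two-sided Wilcoxon rank-sum tests (exact for small tie-free samples,
tie- and continuity-corrected normal approximation otherwise, matching R's
``wilcox.test``), Benjamini-Hochberg FDR, fold changes of median ranks,
per-tissue volcano deduplication, rank-change matrices with IQR feature
selection, and rank/covariate correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

log = logging.getLogger("cfrank")


def wilcoxon_rank_sum(
    a, b, paired: bool = False
) -> tuple[float, float]:
    """Two-sided rank-sum test; returns (U statistic of ``a``, p).

    Exact when min(|a|, |b|) <= 8 with no ties across the pooled sample,
    otherwise normal approximation with tie and continuity correction.
    ``paired=True`` switches to the signed-rank test (not the default used
    for cohort contrasts).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty group in rank-sum test")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test requires equal lengths")
        d = a - b
        if np.all(d == 0):
            return 0.0, 1.0
        res = sps.wilcoxon(a, b, alternative="two-sided")
        return float(res.statistic), float(min(res.pvalue, 1.0))
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(a), len(b)) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compare_groups(
    ranks_case: pd.DataFrame,
    ranks_control: pd.DataFrame,
    features=None,
) -> pd.DataFrame:
    """Per-feature case-vs-control contrast of rank distributions.

    Inputs are sample x feature tables.  Output rows carry the two group
    medians, log2 of their ratio, the rank-sum p and the BH q computed
    across all features tested in this call (one adjustment family per
    cohort contrast).
    """
    if len(ranks_case) == 0 or len(ranks_control) == 0:
        raise ValueError("empty arm in group comparison")
    if features is None:
        features = [f for f in ranks_case.columns if f in ranks_control.columns]
    rows = []
    for feat in features:
        if feat not in ranks_case.columns or feat not in ranks_control.columns:
            log.warning("feature %r absent in one arm; skipped", feat)
            continue
        x = ranks_case[feat].dropna().to_numpy()
        y = ranks_control[feat].dropna().to_numpy()
        if len(x) == 0 or len(y) == 0:
            log.warning("feature %r has no data in one arm; skipped", feat)
            continue
        med_case, med_ctrl = float(np.median(x)), float(np.median(y))
        _, p = wilcoxon_rank_sum(x, y)
        rows.append({
            "feature": feat,
            "median_case": med_case,
            "median_control": med_ctrl,
            "log2FC": float(np.log2(med_case / med_ctrl)) if med_ctrl > 0 and med_case > 0
            else np.nan,
            "p": p,
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def volcano_dedup(rows: pd.DataFrame) -> pd.DataFrame:
    """One row per cell type: keep the tissue instance with highest |log2FC|.

    Ties go to the smaller q, then tissue name ascending.
    """
    required = {"cell_type", "tissue", "log2FC", "q"}
    missing = required - set(rows.columns)
    if missing:
        raise ValueError(f"volcano rows missing columns {sorted(missing)}")
    ordered = rows.assign(_abs=rows["log2FC"].abs()).sort_values(
        ["cell_type", "_abs", "q", "tissue"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    return (ordered.drop_duplicates("cell_type", keep="first")
            .drop(columns="_abs").reset_index(drop=True))


def longitudinal_compare(
    values: pd.Series,
    cohort: pd.DataFrame,
    baseline_timepoint: str,
    paired: bool = False,
) -> pd.DataFrame:
    """Baseline-vs-timepoint rank-sum tests for one feature.

    ``values`` is a per-sample series (e.g. a group median rank) indexed by
    sample_id; ``cohort`` supplies sample -> (patient, timepoint).  Tests
    are unpaired by default.
    """
    meta = cohort.set_index("sample_id")
    tp = meta["timepoint"]
    base_vals = values[tp.reindex(values.index) == baseline_timepoint].dropna()
    if len(base_vals) == 0:
        raise ValueError(f"no samples at baseline {baseline_timepoint!r}")
    rows = []
    for t in [t for t in tp.unique() if t != baseline_timepoint]:
        tvals = values[tp.reindex(values.index) == t].dropna()
        if len(tvals) == 0:
            log.warning("timepoint %r has no samples; skipped", t)
            continue
        if paired:
            pats = meta.loc[base_vals.index, "patient_id"]
            pats_t = meta.loc[tvals.index, "patient_id"]
            common = pats[pats.isin(pats_t)].index
            x = base_vals.loc[common].to_numpy()
            y = tvals.loc[pats_t[pats_t.isin(pats)].index].to_numpy()
            _, p = wilcoxon_rank_sum(x, y, paired=True)
            n = len(x)
        else:
            _, p = wilcoxon_rank_sum(base_vals.to_numpy(), tvals.to_numpy())
            n = len(tvals)
        rows.append({"timepoint": t, "n": n, "p": p})
    if not rows:
        log.warning("only the baseline timepoint present; nothing to compare")
    return pd.DataFrame(rows, columns=["timepoint", "n", "p"])


def rank_change(
    ranks: pd.DataFrame, cohort: pd.DataFrame, t0: str, t1: str
) -> pd.DataFrame:
    """Per-patient, per-feature rank change rank(t1) - rank(t0).

    Patients missing either timepoint are excluded (count logged).
    """
    meta = cohort.set_index("sample_id")
    at = {}
    for t in (t0, t1):
        sel = meta.index[meta["timepoint"] == t]
        sel = [s for s in sel if s in ranks.index]
        sub = ranks.loc[sel]
        sub.index = meta.loc[sel, "patient_id"]
        at[t] = sub
    common = at[t0].index.intersection(at[t1].index)
    excluded = len(set(at[t0].index) | set(at[t1].index)) - len(common)
    if excluded:
        log.info("%d patients missing %s or %s excluded from rank change", excluded, t0, t1)
    if len(common) == 0:
        raise ValueError(f"no patient has both timepoints {t0!r} and {t1!r}")
    delta = at[t1].loc[common] - at[t0].loc[common]
    delta.index.name = "patient_id"
    return delta


@dataclass
class FeatureSelectionResult:
    iqr: pd.Series          # per-feature IQR of rank change
    selected: list[str]     # top-k feature ids


def iqr_select(
    delta: pd.DataFrame, k: int = 10, eligible=None
) -> FeatureSelectionResult:
    """Top-k features by interquartile range of rank change across patients.

    Quartiles use linear interpolation (R type-7); ties broken by feature
    id ascending.  Fewer than k eligible features reduces k with a warning.
    """
    feats = list(delta.columns if eligible is None
                 else [f for f in delta.columns if f in set(eligible)])
    if len(feats) == 0:
        raise ValueError("no eligible features for IQR selection")
    if len(feats) < k:
        log.warning("only %d eligible features; reducing k from %d", len(feats), k)
        k = len(feats)
    sub = delta[feats]
    q1 = sub.quantile(0.25, interpolation="linear")
    q3 = sub.quantile(0.75, interpolation="linear")
    iqr = (q3 - q1).rename("iqr")
    order = sorted(feats, key=lambda f: (-iqr[f], f))
    return FeatureSelectionResult(iqr=iqr, selected=order[:k])


def covariate_correlation(
    aggregated_ranks: pd.Series, covariate: pd.Series
) -> tuple[float, float]:
    """Spearman correlation of a per-sample rank aggregate with a covariate.

    Pairwise-complete; p from the t approximation.  Requires n >= 3.
    """
    joined = pd.concat([aggregated_ranks, covariate], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError(f"need >= 3 paired observations, got {len(joined)}")
    rho, p = sps.spearmanr(joined.iloc[:, 0], joined.iloc[:, 1])
    return float(rho), float(p)


def aggregate_ranks(ranks: pd.DataFrame, cell_types) -> pd.Series:
    """Per-sample median rank over a named cell-type set."""
    cols = [c for c in cell_types if c in ranks.columns]
    if not cols:
        raise ValueError("none of the named cell types present in rank table")
    return ranks[cols].median(axis=1)
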