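"""GC-corrected, sample-normalised cfDNA coverage in TSS windows.

Each fragment contributes its GC weight at every base it overlaps inside
the +/-window around a transcript's TSS (pileup).  Per-transcript window
means are normalised so the sample average over all annotated windows is 1,
then aggregated to genes by the arithmetic mean over transcripts.  Offsets
are oriented 5'->3' along transcription (minus-strand windows flipped).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import FragmentSet
from .stats import bh_fdr, wilcoxon_rank_sum

log = logging.getLogger("cfrank")


@dataclass(frozen=True)
class CoverageConfig:
    window_bp: int = 1000
    gc_bins: int = 50
    min_fragments_per_sample: int = 100

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if self.gc_bins < 2:
            raise ValueError("gc_bins must be >= 2")


@dataclass
class GCBiasModel:
    """Inverse-rate GC weights on equal-width bins over [0, 1].

    weight(bin) = global mean fragment rate / bin fragment rate, so the
    fragment-weighted mean of the weights is 1; unoccupied bins get weight 1.
    """

    bin_edges: np.ndarray
    weights: np.ndarray

    @classmethod
    def identity(cls, gc_bins: int = 50) -> "GCBiasModel":
        return cls(np.linspace(0, 1, gc_bins + 1), np.ones(gc_bins))

    def weight_for(self, gc: np.ndarray) -> np.ndarray:
        """Per-fragment weights; fragments without a GC value get weight 1."""
        gc = np.asarray(gc, dtype=float)
        idx = np.clip(np.digitize(gc, self.bin_edges[1:-1]), 0, len(self.weights) - 1)
        out = self.weights[idx]
        return np.where(np.isnan(gc), 1.0, out)


def estimate_gc_bias(
    fragments: FragmentSet,
    config: CoverageConfig,
    window_gc: pd.Series | None = None,
) -> GCBiasModel:
    """Fit inverse-rate GC weights from the sample's own fragment GC histogram.

    Without ``window_gc`` the bin rate is the raw fragment count, so the
    underlying fragment GC distribution is assumed uniform across occupied
    bins.  Passing per-window GC values (one per annotated TSS window, e.g.
    from :func:`window_gc_from_fragments`) switches to opportunity-
    normalised rates — fragments per window whose GC falls in the bin —
    which removes the windows-per-bin sampling noise that raw counts
    conflate with bias.

    Bins carrying fewer than 0.1% of the fragments (and empty bins) keep
    weight 1: an inverse rate estimated from a handful of fragments would
    blow up and distort the few windows whose GC lands there.  The global
    rate is taken over the remaining bins, which keeps the
    fragment-weighted mean of the weights at exactly 1.
    """
    gc = fragments.records["gc"].to_numpy()
    if np.isnan(gc).all():
        log.warning("fragments carry no GC values; using identity GC model")
        return GCBiasModel.identity(config.gc_bins)
    gc = gc[~np.isnan(gc)]
    if len(gc) < config.min_fragments_per_sample:
        log.warning("only %d fragments with GC; GC model may be unstable", len(gc))
    edges = np.linspace(0.0, 1.0, config.gc_bins + 1)
    counts, _ = np.histogram(gc, bins=edges)
    min_count = max(1, int(np.ceil(1e-3 * counts.sum())))
    reliable = counts >= min_count
    if window_gc is not None:
        wins, _ = np.histogram(window_gc.dropna().to_numpy(), bins=edges)
        reliable &= wins > 0
    if not reliable.any():
        log.warning("no GC bin reaches %d fragments; using identity GC model", min_count)
        return GCBiasModel(edges, np.ones(config.gc_bins))
    weights = np.ones(config.gc_bins)
    if window_gc is None:
        global_rate = counts[reliable].sum() / reliable.sum()
        weights[reliable] = global_rate / counts[reliable]
    else:
        rate = counts[reliable] / wins[reliable]
        global_rate = counts[reliable].sum() / wins[reliable].sum()
        weights[reliable] = global_rate / rate
    # occupied-but-unreliable bins borrow the nearest reliable bin's weight
    # (their own rate is too noisy); truly empty bins keep weight 1
    rel_idx = np.flatnonzero(reliable)
    for b in np.flatnonzero((counts > 0) & ~reliable):
        weights[b] = weights[rel_idx[np.argmin(np.abs(rel_idx - b))]]
    # rescale so the fragment-weighted mean of the weights is exactly 1
    occ = counts > 0
    weights[occ] /= (counts[occ] * weights[occ]).sum() / counts[occ].sum()
    return GCBiasModel(edges, weights)


def window_gc_from_fragments(
    fragments: FragmentSet, annotation: pd.DataFrame, config: CoverageConfig
) -> pd.Series:
    """Per-window GC estimated as the mean GC of overlapping fragments.

    A self-contained stand-in for sequence-derived window GC when only the
    fragment BED is available; windows without fragments come out NaN.
    """
    w = config.window_bp
    recs = fragments.records
    out = np.full(len(annotation), np.nan)
    for chrom, chrom_frags in recs.groupby("chrom", sort=False):
        starts = chrom_frags["start"].to_numpy()
        order = np.argsort(starts, kind="mergesort")
        starts = starts[order]
        ends = chrom_frags["end"].to_numpy()[order]
        gcs = chrom_frags["gc"].to_numpy()[order]
        max_len = int((ends - starts).max())
        ann_idx = np.flatnonzero((annotation["chrom"] == chrom).to_numpy())
        for ai in ann_idx:
            tss = int(annotation["tss"].iloc[ai])
            lo = np.searchsorted(starts, tss - w - max_len)
            hi = np.searchsorted(starts, tss + w + 1)
            sel_gc = gcs[lo:hi][ends[lo:hi] > tss - w]
            sel_gc = sel_gc[~np.isnan(sel_gc)]
            if len(sel_gc):
                out[ai] = sel_gc.mean()
    return pd.Series(out, index=annotation["gene_id"].to_numpy(), name="window_gc")


def windowed_depth(
    fragments: FragmentSet,
    annotation: pd.DataFrame,
    gc_model: GCBiasModel | None,
    config: CoverageConfig,
) -> tuple[pd.DataFrame, np.ndarray]:
    """GC-weighted pileup depth in every annotated TSS window.

    Returns (per-transcript table with raw window means and fragment
    counts, transcript x offset depth matrix oriented along transcription).
    Windows reaching below position 0 are clipped with a warning.
    """
    if len(annotation) == 0:
        raise ValueError("empty TSS annotation")
    if gc_model is None:
        gc_model = GCBiasModel.identity(config.gc_bins)
    w = config.window_bp
    width = 2 * w + 1
    recs = fragments.records
    frag_w = gc_model.weight_for(recs["gc"].to_numpy())
    depth = np.zeros((len(annotation), width))
    n_frags = np.zeros(len(annotation), dtype=int)

    clipped = 0
    for chrom, chrom_frags in recs.assign(_w=frag_w).groupby("chrom", sort=False):
        starts = chrom_frags["start"].to_numpy()
        order = np.argsort(starts, kind="mergesort")
        starts = starts[order]
        ends = chrom_frags["end"].to_numpy()[order]
        wts = chrom_frags["_w"].to_numpy()[order]
        max_len = int((ends - starts).max())
        ann_idx = np.flatnonzero((annotation["chrom"] == chrom).to_numpy())
        for ai in ann_idx:
            tss = int(annotation["tss"].iloc[ai])
            win_lo = tss - w
            if win_lo < 0:
                clipped += 1
            hi = np.searchsorted(starts, win_lo + width, side="left")
            lo = np.searchsorted(starts, win_lo - max_len, side="left")
            sel = slice(lo, hi)
            keep = ends[sel] > max(win_lo, 0)
            if not keep.any():
                continue
            a = np.clip(starts[sel][keep] - win_lo, 0, width)
            b = np.clip(ends[sel][keep] - win_lo, 0, width)
            inside = b > a
            a, b, ww = a[inside], b[inside], wts[sel][keep][inside]
            delta = np.zeros(width + 1)
            np.add.at(delta, a, ww)
            np.add.at(delta, b, -ww)
            depth[ai] = np.cumsum(delta[:-1])
            n_frags[ai] = int(inside.sum())
    if clipped:
        log.warning("%d TSS windows clipped at chromosome start", clipped)

    minus = (annotation["strand"] == "-").to_numpy()
    depth[minus] = depth[minus, ::-1]
    table = annotation[["gene_id", "transcript_id"]].copy()
    table["raw_mean"] = depth.sum(axis=1) / width
    table["n_fragments"] = n_frags
    return table, depth


def compute_tss_coverage(
    fragments: FragmentSet,
    annotation: pd.DataFrame,
    gc_model: GCBiasModel | None,
    config: CoverageConfig,
) -> pd.DataFrame:
    """Per-transcript normalised window means (sample average forced to 1)."""
    table, _ = windowed_depth(fragments, annotation, gc_model, config)
    norm = table["raw_mean"].mean()
    if norm == 0:
        raise ValueError("no fragment coverage in any annotated window")
    table["mean_cov"] = table["raw_mean"] / norm
    log.info("coverage computed for %d transcripts (%d without fragments)",
             len(table), int((table["n_fragments"] == 0).sum()))
    return table


def aggregate_transcripts(per_transcript: pd.DataFrame) -> pd.Series:
    """Gene value = mean over its transcripts that saw any fragments.

    Genes whose transcripts all lack fragments come out missing (NaN) and
    are excluded pairwise downstream.
    """
    covered = per_transcript[per_transcript["n_fragments"] > 0]
    dropped = per_transcript["gene_id"].nunique() - covered["gene_id"].nunique()
    if dropped:
        log.info("%d genes had no overlapping fragments (missing coverage)", dropped)
    gene_cov = covered.groupby("gene_id")["mean_cov"].mean()
    return gene_cov.reindex(per_transcript["gene_id"].unique()).rename("mean_cov")


def gene_coverage(
    fragments: FragmentSet,
    annotation: pd.DataFrame,
    gc_model: GCBiasModel | None,
    config: CoverageConfig,
) -> pd.Series:
    """Convenience: per-gene normalised TSS coverage from fragments."""
    return aggregate_transcripts(compute_tss_coverage(fragments, annotation, gc_model, config))


def metaprofile(
    fragments: FragmentSet,
    annotation: pd.DataFrame,
    gene_set,
    gc_model: GCBiasModel | None,
    config: CoverageConfig,
) -> pd.Series:
    """Position-wise mean normalised coverage across a gene set.

    Offsets run -window..+window in transcription orientation; the
    normaliser is the sample-wide mean window depth, as for gene means.
    """
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("empty gene set")
    unknown = set(gene_set) - set(annotation["gene_id"])
    if unknown:
        raise ValueError(f"genes not in annotation: {sorted(unknown)[:5]}")
    table, depth = windowed_depth(fragments, annotation, gc_model, config)
    norm = table["raw_mean"].mean()
    if norm == 0:
        raise ValueError("no fragment coverage in any annotated window")
    gene_ids = table["gene_id"].to_numpy()
    # transcript -> gene positional means, then mean across the gene set
    profiles = []
    for g in gene_set:
        rows = depth[gene_ids == g]
        profiles.append(rows.mean(axis=0))
    prof = np.vstack(profiles).mean(axis=0) / norm
    offsets = np.arange(-config.window_bp, config.window_bp + 1)
    return pd.Series(prof, index=pd.Index(offsets, name="offset"), name="mean_cov")


@dataclass
class ExpressionClassReport:
    """Coverage of bulk-expression classes (unexpressed / top-n expressed)."""

    classes: pd.Series            # gene -> {unexpressed, expressed, other}
    medians: pd.Series            # per-class median normalised coverage
    difference: float             # median(expressed) - median(unexpressed)
    p_value: float
    q_value: float
    separated: bool


def expression_class_report(
    gene_cov: pd.Series, bulk_tpm: pd.Series, top_n: int = 2000
) -> ExpressionClassReport:
    """Partition genes by bulk expression and compare their TSS coverage.

    Unexpressed: mean TPM == 0.  Expressed: the top_n genes by TPM
    (ties broken TPM descending then gene id ascending).  The separation
    flag requires Wilcoxon q < 0.05 between the two classes' coverage.
    """
    bulk = bulk_tpm.reindex(gene_cov.index)
    nonzero = bulk[bulk > 0]
    if len(nonzero) < top_n:
        log.warning("only %d genes with TPM > 0; reducing top_n from %d",
                    len(nonzero), top_n)
        top_n = len(nonzero)
    ordered = nonzero.reset_index()
    ordered.columns = ["gene_id", "tpm"]
    ordered = ordered.sort_values(["tpm", "gene_id"], ascending=[False, True])
    top = set(ordered["gene_id"].head(top_n))
    classes = pd.Series(
        np.where(bulk == 0, "unexpressed",
                 np.where(bulk.index.isin(top), "expressed", "other")),
        index=gene_cov.index, name="class",
    )
    cov_expr = gene_cov[classes == "expressed"].dropna()
    cov_unexpr = gene_cov[classes == "unexpressed"].dropna()
    medians = gene_cov.groupby(classes).median()
    _, p = wilcoxon_rank_sum(cov_expr.to_numpy(), cov_unexpr.to_numpy())
    q = float(bh_fdr(np.array([p]))[0])
    diff = float(medians.get("expressed", np.nan) - medians.get("unexpressed", np.nan))
    return ExpressionClassReport(
        classes=classes, medians=medians, difference=diff,
        p_value=float(p), q_value=q, separated=bool(q < 0.05),
    )
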