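"""Synthetic cfDNA data with known cell-of-origin ground truth.

The generator emulates the statistical structure the rank-based
deconvolution assumes, at desk scale:

* a cell-type expression reference with disjoint marker blocks per type
  (marker expression lognormal around ``expr_scale``, background zero);
* per-sample mixture weights ``w`` on the simplex, Dirichlet-distributed
  around a hematopoietic base composition;
* TSS coverage depleted monotonically in the mixture-weighted expression
  ``x_g = sum_k w_k e_{k,g}`` through a bounded depletion score
  ``s_g = log1p(x_g) / max_h log1p(x_h)``;
* multiplicative gene-level GC bias and lognormal noise;
* optionally, individual cfDNA fragments whose midpoint density around each
  TSS follows a Gaussian nucleosome-depletion dip, so the full
  fragment -> coverage -> rank path can be exercised.

Closed-form per-gene coverage (coverage mode) is

    cov_g = B * (1 + a*(GC_g - mean GC)) * (1 - d*s_g) * eps_g,

with ``d`` the depletion depth, ``a`` the GC-bias amplitude and ``eps_g``
lognormal(0, sigma^2).  Fragment mode draws midpoints with acceptance
``1 - d*s_g*exp(-u^2/(2*300^2))`` at offset ``u`` from the TSS; its
windowed pileup mean therefore carries the window-averaged kernel rather
than the full depth ``d`` — :func:`expected_window_profile` is the exact
numeric expectation used to test that the two routes agree.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .io import FragmentSet
from .reference import CATEGORIES, ExpressionReference

log = logging.getLogger("cfrank")

#: sd (bp) of the Gaussian nucleosome-depletion kernel around the TSS
DEPLETION_KERNEL_SD = 300.0

TISSUES = ["blood", "spleen", "lymph_node", "thymus", "bone_marrow", "liver"]

#: base category shares of the healthy cfDNA pool (hematopoietic dominance:
#: monocytes > lymphocytes > granulocytes; remainder split over the rest)
BASE_CATEGORY_SHARES = {
    "monocytes": 0.30,
    "lymphocytes": 0.25,
    "granulocytes": 0.20,
}


@dataclass(frozen=True)
class SimulationConfig:
    n_celltypes: int = 12
    n_genes: int = 600
    n_marker_genes_per_type: int = 30
    expr_scale: float = 50.0
    depletion_depth: float = 0.7
    noise_sd: float = 0.1
    gc_bias_amplitude: float = 0.0
    baseline_coverage: float = 1.0
    window_bp: int = 1000
    fragment_length_mean: float = 167.0
    fragment_length_sd: float = 20.0
    n_fragments_per_sample: int = 20000
    gc_range: tuple[float, float] = (0.3, 0.7)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_celltypes < 2:
            raise ValueError("need at least 2 cell types")
        if self.n_genes < self.n_celltypes * self.n_marker_genes_per_type:
            raise ValueError("n_genes < n_celltypes * n_marker_genes_per_type")
        if not 0.0 <= self.depletion_depth <= 1.0:
            raise ValueError("depletion_depth outside [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd < 0")
        if not 0.0 <= self.gc_bias_amplitude < 1.0:
            raise ValueError("gc_bias_amplitude outside [0, 1)")
        if self.baseline_coverage <= 0:
            raise ValueError("baseline_coverage <= 0")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    weights: pd.DataFrame            # sample x cell_type mixture weights
    gene_gc: pd.Series               # per-gene GC fraction
    reference: ExpressionReference
    samples: pd.DataFrame            # per-sample group/patient/timepoint/relapse


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    """One reproducible RNG stream per (seed, sample_id)."""
    return np.random.default_rng([seed, zlib.crc32(sample_id.encode())])


def simulate_reference(
    config: SimulationConfig, seed: int | None = None
) -> ExpressionReference:
    """Marker-block expression reference with category/tissue annotations.

    Type k's markers occupy a disjoint gene block with lognormal expression
    centred on ``expr_scale``; all other entries are zero.  Categories and
    tissues cycle through fixed label lists.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    K, G, m = config.n_celltypes, config.n_genes, config.n_marker_genes_per_type
    genes = [f"g{i:05d}" for i in range(G)]
    names, cats, tissues = [], [], []
    expr = np.zeros((K, G))
    for k in range(K):
        expr[k, k * m:(k + 1) * m] = rng.lognormal(np.log(config.expr_scale), 0.5, m)
        cats.append(CATEGORIES[k % len(CATEGORIES)])
        tissues.append(TISSUES[(k // len(CATEGORIES)) % len(TISSUES)])
        names.append(f"ct{k:02d}_{cats[-1]}_{tissues[-1]}")
    ann = pd.DataFrame(
        {
            "category": cats,
            "compartment": ["immune" if c in ("monocytes", "lymphocytes", "granulocytes")
                            else c for c in cats],
            "tissue": tissues,
        },
        index=pd.Index(names, name="cell_type"),
    )
    return ExpressionReference(pd.DataFrame(expr, index=ann.index, columns=genes), ann)


def simulate_gene_gc(genes, config: SimulationConfig, seed: int | None = None) -> pd.Series:
    """Per-gene GC fractions, uniform over ``gc_range``.

    Uniform marginals make inverse-rate GC weighting an exact inverse of the
    simulated multiplicative bias.
    """
    rng = np.random.default_rng((config.seed if seed is None else seed) + 101)
    lo, hi = config.gc_range
    return pd.Series(rng.uniform(lo, hi, len(genes)), index=genes, name="gc")


def _check_weights(weights: pd.Series, reference: ExpressionReference) -> pd.Series:
    weights = pd.Series(weights).reindex(reference.cell_types)
    if weights.isna().any():
        raise ValueError("weights missing for some reference cell types")
    if (weights < 0).any():
        raise ValueError("negative mixture weight")
    if abs(float(weights.sum()) - 1.0) > 1e-9:
        raise ValueError(f"weights sum to {weights.sum()}, not 1")
    return weights


def depletion_scores(reference: ExpressionReference, weights: pd.Series) -> pd.Series:
    """s_g = log1p(x_g) / max_h log1p(x_h) for x = w @ e; in [0, 1]."""
    weights = _check_weights(weights, reference)
    x = weights.to_numpy() @ reference.expr.to_numpy()
    lx = np.log1p(x)
    top = lx.max()
    s = lx / top if top > 0 else np.zeros_like(lx)
    return pd.Series(s, index=reference.genes, name="s")


def simulate_sample_coverage(
    reference: ExpressionReference,
    weights: pd.Series,
    config: SimulationConfig,
    seed: int | np.random.Generator = 0,
    gene_gc: pd.Series | None = None,
) -> pd.Series:
    """Closed-form per-gene coverage for one sample (coverage mode)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s = depletion_scores(reference, weights).to_numpy()
    cov = config.baseline_coverage * (1.0 - config.depletion_depth * s)
    if gene_gc is not None and config.gc_bias_amplitude > 0:
        gc = gene_gc.reindex(reference.genes).to_numpy()
        cov = cov * (1.0 + config.gc_bias_amplitude * (gc - gc.mean()))
    if config.noise_sd > 0:
        cov = cov * rng.lognormal(0.0, config.noise_sd, len(cov))
    return pd.Series(cov, index=reference.genes, name="coverage")


def make_annotation(genes, config: SimulationConfig) -> pd.DataFrame:
    """One-transcript-per-gene TSS annotation with windows spaced far apart."""
    genes = list(genes)
    pad = _midpoint_pad(config)
    spacing = 2 * (config.window_bp + pad) + 1000
    return pd.DataFrame(
        {
            "gene_id": genes,
            "transcript_id": [f"{g}.t1" for g in genes],
            "chrom": "chrS",
            "tss": [spacing * (i + 1) for i in range(len(genes))],
            "strand": (["+", "-"] * (len(genes) // 2 + 1))[: len(genes)],
        }
    )


def _midpoint_pad(config: SimulationConfig) -> int:
    """Midpoints are drawn this far beyond the window so edge pileup is flat."""
    return int(np.ceil((config.fragment_length_mean + 4 * config.fragment_length_sd) / 2)) + 1


def _acceptance(u: np.ndarray, s_g: float, d: float) -> np.ndarray:
    return 1.0 - d * s_g * np.exp(-(u ** 2) / (2.0 * DEPLETION_KERNEL_SD ** 2))


def simulate_fragments(
    reference: ExpressionReference,
    weights: pd.Series,
    annotation: pd.DataFrame,
    config: SimulationConfig,
    seed: int | np.random.Generator = 0,
    gene_gc: pd.Series | None = None,
    sample_id: str = "sim",
) -> FragmentSet:
    """Draw cfDNA fragments around each gene's TSS (fragment mode).

    Midpoint offsets follow the nucleosome-depletion acceptance
    ``1 - d*s_g*exp(-u^2/(2*300^2))``; per-gene fragment masses carry the
    lognormal noise and (through the multinomial allocation) the GC bias;
    fragment lengths are normal(mean, sd) floored at 50 bp; per-fragment GC
    is drawn tightly around the gene GC so inverse-rate correction can undo
    the bias.
    """
    if config.n_fragments_per_sample <= 0:
        raise ValueError("n_fragments_per_sample must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    weights = _check_weights(weights, reference)
    ann = annotation.set_index("gene_id")
    genes = ann.index.to_numpy()
    s = depletion_scores(reference, weights).reindex(genes).to_numpy()
    if gene_gc is None:
        gene_gc = simulate_gene_gc(genes, config)
    gcv = gene_gc.reindex(genes).to_numpy()
    d = config.depletion_depth
    pad = _midpoint_pad(config)
    span = config.window_bp + pad
    u_grid = np.arange(-span, span + 1)

    # expected per-gene fragment mass: noise * mean acceptance * GC bias
    mean_accept = np.array([_acceptance(u_grid, si, d).mean() for si in s])
    eps = rng.lognormal(0.0, config.noise_sd, len(genes)) if config.noise_sd > 0 else 1.0
    bias = 1.0 + config.gc_bias_amplitude * 2.0 * (gcv - 0.5)
    mass = eps * mean_accept * bias
    counts = rng.multinomial(config.n_fragments_per_sample, mass / mass.sum())

    rows_chrom, rows_start, rows_end, rows_gc = [], [], [], []
    for gi, n_g in enumerate(counts):
        if n_g == 0:
            continue
        # rejection-sample midpoint offsets from the acceptance profile
        offsets = np.empty(0, dtype=int)
        while len(offsets) < n_g:
            cand = rng.integers(-span, span + 1, size=2 * (n_g - len(offsets)) + 8)
            keep = rng.random(len(cand)) < _acceptance(cand.astype(float), s[gi], d)
            offsets = np.concatenate([offsets, cand[keep]])
        offsets = offsets[:n_g]
        lengths = np.maximum(
            50, np.rint(rng.normal(config.fragment_length_mean,
                                   config.fragment_length_sd, n_g))
        ).astype(int)
        mid = int(ann["tss"].iloc[gi]) + offsets
        start = mid - lengths // 2
        frag_gc = np.clip(rng.normal(gcv[gi], 0.02, n_g), 0.0, 1.0)
        rows_chrom.append(np.repeat(ann["chrom"].iloc[gi], n_g))
        rows_start.append(start)
        rows_end.append(start + lengths)
        rows_gc.append(frag_gc)
    records = pd.DataFrame(
        {
            "chrom": np.concatenate(rows_chrom),
            "start": np.concatenate(rows_start).astype(int),
            "end": np.concatenate(rows_end).astype(int),
            "gc": np.concatenate(rows_gc),
        }
    ).sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    return FragmentSet(records, sample_id=sample_id)


def expected_window_profile(
    s_g: float, config: SimulationConfig
) -> np.ndarray:
    """Expected (unnormalised) pileup depth over window offsets -w..+w.

    Exact expectation of the fragment generator for one gene: the midpoint
    acceptance profile convolved with the fragment-length coverage kernel
    P(L >= 2|delta|), L ~ max(50, Normal(mean, sd)).
    """
    w, pad = config.window_bp, _midpoint_pad(config)
    span = w + pad
    u = np.arange(-span, span + 1, dtype=float)
    density = _acceptance(u, s_g, config.depletion_depth)
    delta = np.arange(-pad, pad + 1, dtype=float)
    x = 2.0 * np.abs(delta)
    kern = np.where(
        x <= 50,
        1.0,
        stats.norm.sf(x, loc=config.fragment_length_mean, scale=config.fragment_length_sd),
    )
    depth = np.convolve(density, kern, mode="same")
    return depth[pad:pad + 2 * w + 1]


def expected_window_mean(s_g: float, config: SimulationConfig) -> float:
    """Window mean of :func:`expected_window_profile` (relative units)."""
    return float(expected_window_profile(s_g, config).mean())


def base_weights(reference: ExpressionReference) -> pd.Series:
    """Hematopoietic base mixture: category shares split evenly within category."""
    cats = reference.categories()
    present = list(dict.fromkeys(cats))
    named = {c: s for c, s in BASE_CATEGORY_SHARES.items() if c in present}
    rest = [c for c in present if c not in named]
    rest_share = (1.0 - sum(named.values())) / len(rest) if rest else 0.0
    shares = {**named, **{c: rest_share for c in rest}}
    total = sum(shares.values())
    w = cats.map(lambda c: shares[c] / total) / cats.map(cats.value_counts())
    return w / w.sum()


def shift_weights(
    weights: pd.Series,
    categories: pd.Series,
    delta: float,
    up: str = "lymphocytes",
    down: str = "monocytes",
) -> pd.Series:
    """Move mass ``delta`` from category ``down`` to category ``up``.

    Mass is redistributed proportionally within each category and the
    vector renormalised; a shift that would drive any weight negative is an
    error.
    """
    if delta == 0:
        return weights.copy()
    w = weights.copy().astype(float)
    up_mask = categories.reindex(w.index) == up
    down_mask = categories.reindex(w.index) == down
    up_tot, down_tot = w[up_mask].sum(), w[down_mask].sum()
    if down_tot - delta < 0 or up_tot + delta < 0:
        raise ValueError(f"shift {delta} drives {down if delta > 0 else up} weights negative")
    if up_tot > 0:
        w[up_mask] *= (up_tot + delta) / up_tot
    if down_tot > 0:
        w[down_mask] *= (down_tot - delta) / down_tot
    if (w < 0).any():
        raise ValueError("shift produced negative weights")
    return w / w.sum()


def simulate_bulk_expression(
    reference: ExpressionReference, weights: pd.Series | None = None
) -> pd.Series:
    """Bulk TPM-like profile: base-mixture expression rescaled to sum 1e6."""
    w = base_weights(reference) if weights is None else _check_weights(weights, reference)
    x = pd.Series(w.to_numpy() @ reference.expr.to_numpy(), index=reference.genes)
    tot = x.sum()
    return (x / tot * 1e6 if tot > 0 else x).rename("tpm")


@dataclass(frozen=True)
class CohortDesign:
    """Group sizes, effect sizes and longitudinal structure of a cohort."""

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"healthy": 30, "cancer_CRC": 30}
    )
    #: lymphocyte-up / monocyte-down mass shift applied to cancer groups
    delta: float = 0.15
    dirichlet_conc: float = 200.0
    #: timepoint label -> {category: mass offset}; first key is baseline
    timepoints: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"baseline": {}}
    )
    #: extra {category: offset} applied to relapse patients at non-baseline
    #: timepoints, scaled by relapse_effect
    relapse_rate: float = 0.0
    relapse_effect: dict[str, float] = field(default_factory=dict)
    mode: str = "coverage"  # "coverage" | "fragments"


@dataclass
class SyntheticCohort:
    cohort: pd.DataFrame                 # sample sheet
    data: dict[str, object]              # sample_id -> coverage Series | FragmentSet
    truth: GroundTruth
    annotation: pd.DataFrame | None
    reference: ExpressionReference
    gene_gc: pd.Series


def simulate_cohort(
    config: SimulationConfig,
    design: CohortDesign,
    seed: int | None = None,
) -> SyntheticCohort:
    """Full cohort with ground truth: per-sample mixtures, group shifts,
    longitudinal offsets and relapse labels, realised as coverage vectors or
    fragment sets.

    Healthy groups draw Dirichlet(conc * base) weights; groups whose name
    does not start with "healthy" get the lymphocyte-up / monocyte-down
    shift ``delta``; per-timepoint category offsets (and, for relapse
    patients, relapse offsets) are applied on top and renormalised.
    """
    seed = config.seed if seed is None else seed
    master = np.random.default_rng(seed)
    reference = simulate_reference(config, seed=master.integers(2 ** 31))
    gene_gc = simulate_gene_gc(reference.genes, config, seed=master.integers(2 ** 31))
    annotation = (
        make_annotation(reference.genes, config) if design.mode == "fragments" else None
    )
    cats = reference.categories()
    base = base_weights(reference)
    alpha = design.dirichlet_conc * base.to_numpy()
    tp_labels = list(design.timepoints)
    baseline = tp_labels[0]

    rows, data, wrows = [], {}, {}
    for group, n in design.n_per_group.items():
        is_cancer = not group.startswith("healthy")
        for i in range(n):
            patient = f"{group}_p{i:03d}"
            prng = _sample_rng(seed, patient)
            # truncated Dirichlet: redraw the rare base vector that cannot
            # absorb the group shift (the design applies it to every sample)
            for _attempt in range(100):
                w_pat = pd.Series(prng.dirichlet(alpha), index=reference.cell_types)
                try:
                    if is_cancer and design.delta != 0:
                        w_pat = shift_weights(w_pat, cats, design.delta)
                    break
                except ValueError:
                    if _attempt == 99:
                        raise
                    log.info("redrawing weights for %s (shift infeasible)", patient)
            relapse = (
                int(prng.random() < design.relapse_rate) if is_cancer else np.nan
            )
            if is_cancer:
                surv_event = relapse
                surv_time = (
                    float(prng.uniform(3, 30)) if relapse == 1
                    else float(prng.uniform(24, 48))
                )
            else:
                surv_event = surv_time = np.nan
            for tp in (tp_labels if is_cancer else [baseline]):
                w = w_pat.copy()
                # positive offset moves mass into cat from all other categories
                for cat, off in design.timepoints[tp].items():
                    w = _offset_category(w, cats, cat, off)
                if relapse == 1 and tp != baseline:
                    for cat, off in design.relapse_effect.items():
                        w = _offset_category(w, cats, cat, off)
                sample_id = f"{patient}_{tp}"
                srng = _sample_rng(seed, sample_id)
                if design.mode == "fragments":
                    data[sample_id] = simulate_fragments(
                        reference, w, annotation, config, srng, gene_gc, sample_id
                    )
                else:
                    data[sample_id] = simulate_sample_coverage(
                        reference, w, config, srng, gene_gc
                    )
                wrows[sample_id] = w
                rows.append(
                    {
                        "sample_id": sample_id,
                        "patient_id": patient,
                        "group": group,
                        "timepoint": tp,
                        "relapse": relapse,
                        "surv_time_months": surv_time,
                        "surv_event": surv_event,
                    }
                )
    cohort = pd.DataFrame(rows)
    weights = pd.DataFrame(wrows).T
    weights.index.name = "sample_id"
    truth = GroundTruth(weights, gene_gc, reference, cohort.copy())
    log.info("simulated cohort: %d samples, %d cell types, %d genes, mode=%s",
             len(cohort), config.n_celltypes, config.n_genes, design.mode)
    return SyntheticCohort(cohort, data, truth, annotation, reference, gene_gc)


def _offset_category(
    w: pd.Series, cats: pd.Series, category: str, offset: float
) -> pd.Series:
    """Add ``offset`` mass to ``category``, drawn proportionally from all others."""
    if offset == 0:
        return w
    mask = cats.reindex(w.index) == category
    tot = w[mask].sum()
    other = 1.0 - tot
    if tot + offset < 0 or other - offset < 0:
        raise ValueError(f"offset {offset} on {category} leaves negative mass")
    out = w.copy()
    if tot > 0:
        out[mask] *= (tot + offset) / tot
    if other > 0:
        out[~mask] *= (other - offset) / other
    return out / out.sum()
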