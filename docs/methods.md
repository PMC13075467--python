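# Methods

This note documents the models, conventions and numerical choices behind
`cfrank`, in the order data flows through the pipeline. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. Coverage model and the synthetic generator

The pipeline's premise is that cfDNA coverage around a TSS decreases with
the transcriptional activity of the contributing cells. The synthetic
generator (`cfrank.simulate`) encodes the minimal data-generating process
that premise implies.

**Expression reference.** K cell types over G genes; type *k* owns a
disjoint block of `n_marker_genes_per_type` marker genes with lognormal
expression centred on `expr_scale` (default 50, dispersion 0.5 on the log
scale); all other entries are exactly zero. Zero backgrounds give the bulk
profile a genuine unexpressed class (TPM = 0), which the expression-class
validation needs. Categories (monocytes, lymphocytes, granulocytes,
progenitor/erythroid, endothelial, other tissue, stromal, hepatic) and
tissues cycle through fixed label lists so every type is annotated.

**Mixtures.** A sample is a point *w* on the K-simplex. Cohort draws use
Dirichlet(conc·base) with concentration 200 and base category shares
monocytes 0.30, lymphocytes 0.25, granulocytes 0.20, remainder split evenly
— the hematopoietic dominance expected of plasma cfDNA, with
between-individual coefficients of variation around 10%, comparable to real
blood-count variability. Cancer arms move mass `delta` from the monocyte to
the lymphocyte category (proportionally within category, renormalised). A
rare base draw whose monocyte mass cannot absorb the shift is redrawn from
the same patient stream (a truncated Dirichlet): the design states that
every cancer sample carries the full shift, so infeasible bases are outside
the design's support. `shift_weights` itself still errors on an infeasible
shift, as callers that do not want truncation must see the failure.

**Coverage (closed form).** With mixture expression
`x_g = Σ_k w_k e_{k,g}`, the depletion score is
`s_g = log1p(x_g) / max_h log1p(x_h)` — monotone in x, bounded in [0, 1].
The functional form is a modelling choice; every downstream statistic is
rank-based, so any bounded monotone transform gives identical ranks.
Per-gene coverage is

    cov_g = B · (1 + a·(GC_g − mean GC)) · (1 − d·s_g) · ε_g

with baseline B (default 1), GC-bias amplitude a ∈ [0, 1), depletion depth
d ∈ [0, 1] (default 0.7) and lognormal noise ε (σ default 0.1). With σ = 0
and a = 0 the coverage is a deterministic, strictly decreasing function of
x_g.

**Fragments.** Fragment mode realises the same signal at read level.
Midpoint offsets *u* from the TSS are drawn by rejection from the
acceptance profile `1 − d·s_g·exp(−u²/(2·300²))` over the window plus a
margin, lengths are Normal(167, 20) floored at 50 bp, and per-gene fragment
masses carry ε_g and the GC-bias factor through a multinomial allocation of
`n_fragments_per_sample` (default 20,000). The 300-bp Gaussian kernel
width reproduces the qualitative nucleosome-depleted-region dip; its exact
shape is irrelevant to rank correctness. Note the *windowed mean* of the
acceptance profile is `1 − d·s_g·κ` with κ ≈ 0.38 the window average of
the kernel, so fragment-mode windowed means equal the closed-form model
with an effective depth d·κ, not d. `expected_window_profile` computes the
exact expectation (midpoint density convolved with the fragment-length
pileup kernel); the generator is tested against it at 10⁵ fragments with
5% tolerance.

**Gene GC.** Uniform on [0.3, 0.7] per gene; fragment GC is drawn tightly
(sd 0.02) around the gene value. Uniform gene GC makes the inverse-rate
correction an exact inverse of the simulated bias in expectation.

What the generator does **not** emulate: dinucleosome fragment-size
structure, sequence-level effects, mappability, tumour-derived (ctDNA)
mutational signal, batch effects, or realistic inter-gene expression
correlation. Passing tests therefore demonstrate that the pipeline recovers
the signal its own model class generates — they calibrate the machinery,
not the biology of any particular cohort.

## 2. TSS coverage computation

Fragments contribute their GC weight at every base they overlap inside the
±`window_bp` (default 1,000) window — a pileup, not midpoint counting —
robust for windows comparable to the fragment length. Windows reaching
below position 0 are clipped with a warning. Minus-strand windows are
flipped so offsets are transcription-oriented. Per-transcript window means
are divided by (2·window+1) and normalised by the sample-wide mean over all
annotated windows, forcing the sample average to 1 (genome-wide depth is
unavailable from window-restricted fragment files; ranks are invariant to
any per-sample monotone rescaling, so the choice of normaliser cannot
change results). Genes aggregate transcripts by the arithmetic mean over
transcripts that saw at least one fragment; genes with no fragments at all
are missing and excluded pairwise downstream.

**GC correction.** Weights live on 50 equal-width GC bins over [0, 1]:
weight = global mean fragment rate / bin fragment rate, so the
fragment-weighted mean of the weights is exactly 1. Two refinements keep
the inverse-rate idea stable:

* Bins holding fewer than 0.1% of fragments would get rate estimates from
  a handful of reads; occupied-but-sparse bins instead borrow the nearest
  reliable bin's weight, and truly empty bins keep weight 1 (no fragment
  ever queries them).
* Raw counts conflate bias with *opportunity* — how many windows happen to
  have GC in the bin. When per-window GC is available
  (`window_gc_from_fragments` estimates it as the mean fragment GC per
  window), rates are computed as fragments **per window** in the bin,
  which removes windows-per-bin sampling noise. The pipeline uses this
  mode; the plain-count mode remains for fragment sets without annotation.

The correction contract — corrected coverage decorrelated from GC where the
uncorrected signal is strongly confounded — is what downstream analysis
needs; a full fragment-level GC model is out of scope.

## 3. Ranking

Spearman correlation is Pearson on average ranks (tie-aware), computed
pairwise-complete per cell type; fewer than 3 complete pairs or constant
ranks give a missing ρ with a warning. Ranks are average ranks of (−ρ):
most negative ρ → rank N. Missing ρ excludes the type and reduces N for
that sample. No cross-sample normalisation is applied; rank distributions
are compared directly.

## 4. Cohort statistics

* Wilcoxon rank-sum: exact when min(n₁, n₂) ≤ 8 with no pooled ties,
  otherwise normal approximation with tie and continuity correction — the
  conventions of R's `wilcox.test`.
* BH-FDR per contrast: the adjustment family is all features tested in one
  `compare_groups` call.
* Fold changes are log2 ratios of median ranks; category medians are
  medians of member ranks within a sample.
* Volcano deduplication keeps, per cell type, the tissue instance with the
  highest |log2FC| (a volcano displays both directions, so the magnitude is
  the natural criterion); ties break by smaller q, then tissue name.
* Longitudinal baseline-vs-timepoint tests are **unpaired** rank-sum by
  default, matching the cohort-level presentation convention even though
  samples are patient-paired; a paired signed-rank variant sits behind
  `paired=True`.
* IQR feature selection uses linear-interpolation (type-7) quantiles — R's
  default — with ties broken by feature id.

## 5. Classifier and survival

The L1 logistic objective is mean negative log-likelihood + λ‖β‖₁ with an
unpenalised intercept, fit by IRLS plus cyclic soft-threshold coordinate
descent (numba-compiled), converged when no coefficient moves more than
1e−7 across an outer reweighting; weights w = μ(1−μ) are floored at 1e−5.
Predictors are standardised (zero-variance columns dropped with a
warning); at λ ≥ λ_max = max_j |x_jᵀ(y−ȳ)|/n the null model with intercept
logit(ȳ) is returned exactly, and KKT residuals at the solution are below
1e−6. The tuning grid is 100 log-spaced values on [1e−4, 1e1].

λ selection and performance reporting share one LOOCV: for every λ, each
sample is held out, the training fold is standardised and fit
(warm-started along the descending λ path), and the held-out probability
recorded; the chosen λ maximises the out-of-fold AUC (ties to the larger,
sparser λ) and its out-of-fold AUC is the reported performance. This
single-level procedure mirrors the common caret-style workflow; its known
optimistic bias under signal — the tuning choice has seen every held-out
prediction — is accepted deliberately, and a nested variant
(`nested=True`) tunes inside each fold for unbiased outer estimates.
Under the *null*, LOOCV AUC is instead pessimistically biased: with all
coefficients at zero, the held-out prediction is logit(ȳ_train), which
moves opposite to the held-out label, and with weakly varying features
this intercept artifact can push a single-cohort null AUC well below 0.5.
Null behaviour is therefore always assessed over replicate cohorts or
label permutations, never from one run.

AUC is the tie-aware Mann–Whitney statistic; its 95% CI uses the DeLong
placement-variance estimate with a Wald interval clipped to [0, 1].
Detection thresholds are the smallest control score leaving at most
(1−specificity) of controls at or above it. Median stratification sends
exact-median scores to "low". Survival uses the product-limit estimator
with follow-up administratively censored at 36 months (time zero is the
baseline/surgery date in the sample sheet) and the two-group log-rank
test; with no events the curves are flat and the p-value undefined.

## 6. Problem sizes

The validation battery runs at desk scale, chosen so the full suite
finishes in a few minutes while every check retains power: G = 400–2,000
genes, K = 8–12 cell types, 10⁵ fragments for depletion/GC validation,
2×10⁴ fragments per sample for the 60-sample end-to-end cohorts, 50
replicate cohorts for power, 1,000 features for type-I calibration, and
3 replicate cohorts per arm for the end-to-end AUCs (a single 60-sample
LOOCV AUC has a standard deviation of roughly 0.12 under the null).

## 7. Known limitations

* Ranks are relative: a rank shift in one category necessarily moves
  others (compositionality); absolute fractional deconvolution is out of
  scope by design.
* The inverse-rate GC model corrects bin-level multiplicative bias only;
  within-bin gradients (≲1% at the default bin width) remain.
* `window_gc_from_fragments` estimates window GC from the sample's own
  fragments; under extreme bias this estimate itself shifts slightly.
* The caret-style LOOCV reports optimistically biased AUCs under signal
  and pessimistic ones under the null (see §5); cross-cohort comparisons
  should use the nested mode.
* The generator's marker-block references make cell types better separated
  than real transcriptomes; recovery rates on synthetic data are upper
  bounds on real-data performance.
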