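# cfrank — cell-of-origin inference from cfDNA TSS coverage

Plasma cell-free DNA (cfDNA) is released mainly by dying blood cells, and its
fragmentation pattern remembers the chromatin of the cells it came from:
actively transcribed genes are nucleosome-depleted around their transcription
start sites (TSS), so cfDNA coverage dips there, while silent promoters stay
fully covered. `cfrank` turns that signal into per-sample *cell-type ranks* —
a relative ordering of how much each blood cell type contributes to the cfDNA
pool — and runs the downstream cohort analyses a liquid-biopsy study needs:
case–control contrasts, longitudinal treatment trajectories, an immune-score
classifier, and survival stratification. It is written for computational
biologists analysing plasma WGS cohorts, and ships a synthetic-data generator
with known ground truth so every stage of the pipeline is testable end to end.

## Method

For each sample, the mean GC-corrected coverage in the ±1,000 bp window
around every protein-coding TSS is computed from the fragment intervals
(pileup of GC-weighted fragments, normalised so the sample-wide mean over all
annotated windows is 1) and aggregated over transcripts to one value per gene,
`cov_g`. Given a reference of cell-type mean expression profiles `e_{t,g}`
(one row per cell type per tissue, averaged over single cells), the core
statistic is, per cell type *t*,

```
ρ_t = Spearman( e_{t,·} , cov_· )        over the shared gene universe
rank_t = rank of (−ρ_t)                  (1 … N, average ranks for ties)
```

Because expressed TSSs lose coverage, a *more negative* ρ means a *larger*
inferred cfDNA contribution, so the strongest negative correlation gets the
top rank N. Ranks are per-sample relative quantities: any strictly increasing
transform of coverage or of an expression row leaves them unchanged.

Downstream, cell types are grouped into categories (monocytes, lymphocytes,
granulocytes, …) by median member rank; cohorts are compared with two-sided
Wilcoxon rank-sum tests, BH-FDR, and fold changes of median ranks
(`log2FC = log2(median_case / median_control)`); an L1-regularised logistic
model on immune cell-type ranks is tuned over 100 log-spaced λ ∈ [1e−4, 1e1]
by leave-one-out cross-validation with AUC (DeLong 95% CI) and a
95%-specificity detection threshold; relapse models use the top-10 immune
features by IQR of the pre→on-treatment rank change; survival uses
Kaplan–Meier curves of recurrence-free survival censored at 36 months with a
two-group log-rank test, split at the median predicted probability.

## Worked example

Simulate a 20-vs-20 cohort whose cancer arm carries a lymphocyte-up /
monocyte-down shift of 0.15 in mixture weight, rank the samples, and compare
the groups:

```bash
cfrank simulate --seed 7 --out-dir sim --n-healthy 20 --n-cancer 20 \
    --delta 0.15 --n-genes 400 --n-celltypes 12 --noise-sd 0.1
cfrank rank --coverage sim/coverage.tsv \
    --reference sim/reference_expression.tsv \
    --reference-annotation sim/reference_annotation.tsv --out-dir ranks
cfrank compare --ranks ranks/ranks.tsv --sample-sheet sim/sample_sheet.tsv \
    --case-group cancer_CRC --control-group healthy --out-dir cmp
```

`cmp/comparison.tsv` (abridged):

```
feature       median_case  median_control  log2FC   p         q
lymphocytes   11.5         9.25             0.314   2.4e-08   1.8e-07
monocytes      7.5         11.0            -0.553   4.6e-08   1.8e-07
granulocytes   9.5         8.0              0.248   2.4e-03   6.4e-03
endothelial    4.0         4.0              0.0     0.82      0.82
```

The two truly shifted categories come out with the right signs at q < 0.05:
lymphocyte-derived cfDNA ranks are higher in the cancer arm, monocyte ranks
lower, while unshifted categories stay flat. The classifier on the immune
cell-type ranks separates the arms:

```bash
cfrank classify --ranks ranks/ranks.tsv --sample-sheet sim/sample_sheet.tsv \
    --case-group cancer_CRC --control-group healthy --out-dir clf
# {"auc": 1.0, "ci_low": 1.0, "ci_high": 1.0, "lambda": 0.272,
#  "threshold_95spec": 0.461, "detected_cases": 20, "n_cases": 20}
```

i.e. LOOCV AUC 1.0 at the selected penalty, and all 20 cancer samples called
at the 95%-specificity threshold set on the healthy out-of-fold scores. The
same library calls are available in Python (`cfrank.simulate`,
`cfrank.coverage`, `cfrank.deconvolve`, `cfrank.stats`, `cfrank.classify`);
`cfrank simulate --mode fragments` emits per-sample BED files to exercise the
fragment → coverage path, and `longitudinal`, `survive` and `report`
subcommands cover the remaining analyses.

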