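# Methods

This note documents the statistical model behind `phosdiff`, the defaults
and why they are set where they are, what the synthetic cohorts do and do
not emulate, and the numerical choices that affect reproducibility.

## Cohort model

The analysis assumes a four-group design: tumors with an EML4–ALK
rearrangement, an EGFR mutation, a KRAS mutation, or none of the three
(WT), with default group sizes 6 / 23 / 31 / 22 (82 samples). All
group-wise logic — presence filtering, imputation, testing — is driven by
a sample→group metadata table; the four canonical names are fixed and
free-form labels are normalized case-insensitively.

Intensities are modelled on the log2 scale throughout. An
`IntensityMatrix` carries an explicit missingness mask (`NaN`); zero and
blank cells in MaxQuant-style input both mean "not quantified" — the
standard reading of that dialect, since label-free zero intensities are
censored observations, not measurements of zero. Contaminant (`CON__`)
and reversed-decoy (`REV__`) rows are dropped at read time as ordinary
search-output hygiene.

## Presence filtering

A feature is kept when its observed fraction reaches `presence_fraction`
(default 0.5, boundary inclusive) in at least one of KRAS / EGFR / WT, or
when its observed count in the EML4–ALK group reaches
`eml4alk_min_present` (default 4 of 6). The count-based route exists
because a fractional rule is unstable in a six-sample group; the same rule
is applied to the phosphosite dataset. Phosphosites are additionally
restricted to localization probability ≥ `localization_min` (default
0.75, inclusive — the usual "class I" cut).

## Imputation

Missing values are imputed group-wise, because missingness in label-free
data is intensity-dependent (MNAR): a cell missing in a group where the
feature is otherwise well-observed is probably a random dropout, while a
feature missing in most of a group is probably below the detection floor
there.

**Proteins.** Per feature×group: if the observed fraction is below ½ the
missing cells get the *recipient sample's* 5th percentile of observed log2
intensities (`low_presence_percentile`, linear-interpolation percentile) —
a per-sample left-censoring floor; otherwise the cells get the mean over
the `knn_k` = 10 nearest features, with Euclidean distances computed over
that group's samples on pairwise-complete columns and rescaled by
√(n_total/n_shared) so sparsity does not deflate distances. Neighbours are
features, not samples: with 6–31 samples per group a sample-neighbourhood
is ill-defined, while a feature-neighbourhood is always well populated.
Only features observed in the recipient sample are eligible neighbours;
when fewer than k exist, all available are used and a warning logged.

**Phosphosites.** Two passes. Condition-specific: where the within-group
quantitation rate is ≥ `condition_rate_min` (0.5), missing cells are drawn
from `Normal(group mean, group SD)` of the observed values (single
observation → SD 0, i.e. an exact fill). Tail-based: remaining cells are
drawn from `Normal(sample mean − tail_shift·SD, tail_scale·SD)` over the
recipient sample's observed values, with `tail_shift = 1.8` and
`tail_scale = 0.3` — the widely used down-shifted-normal defaults for
left-censored fills; both are exposed in `AnalysisParams`. Draws come from
a caller-supplied seed; a `deterministic=True` mode fills distribution
means instead, for exact tests. Imputation never modifies an observed
cell, and both schemes leave zero missing cells.

After phospho imputation, samples are median-scaled *additively*: every
sample is shifted so its median equals the grand median of per-sample
medians; there is no multiplicative rescaling. Median scaling is applied
to the phosphosite dataset only.

## Adaptive test cascade

Per feature, normality is tested per group with Shapiro–Wilk and variance
homogeneity with Levene centred at the median (the robust variant), both
at `gate_alpha = 0.05`. Groups with fewer than 3 values or constant values
are treated as non-normal (the test is undefined there), which routes
small or degenerate groups to nonparametric branches automatically.

* Omnibus (all four groups): ANOVA if all groups normal and variances
  equal; Welch-ANOVA if normal but unequal; Kruskal–Wallis otherwise.
* Pairwise (each of the six ordered comparisons, sign convention
  `log2fc = mean(first) − mean(second)`): Student's *t* / Welch's *t* /
  Wilcoxon rank-sum under gates evaluated on the two groups alone.
  The rank-sum p is exact when both groups have ≤ 25 tie-free values,
  otherwise the normal approximation with continuity correction.

Pairwise tests run only for features with raw omnibus *p* below
`omnibus_alpha = 0.05`; gated-out features carry no pairwise results and
are non-significant everywhere. The variance gate is evaluated across all
four groups for the omnibus test and per pair for the pairwise tests —
the design was open here, and the per-pair reading matches what the
pairwise Levene actually conditions on.

BH adjustment is applied *within each feature* across its ≤ 6 pairwise
p-values — the literal reading of controlling FDR "separately for every
feature". This is a per-feature multiplicity correction, not a
transcriptome-wide one; a cross-feature mode can be had by adjusting the
long-format table externally. Significance requires adjusted *p*
strictly below `fdr_q = 0.05` **and** |log2 FC| strictly above
`log2(fc_threshold) = 1`. Fold-changes are computed on imputed log2
means, i.e. after the imputation that the tests also see.

## Specificity classification

The per-feature sign pattern over the six comparisons (+1/−1 where
significant, 0 otherwise) is classified as:

* **group-specific g** — all three comparisons involving *g* nonzero and,
  re-oriented as (g − other), of one sign. Direction UP/DOWN follows that
  sign. A feature can carry two group labels only on opposite sides
  (one group above everything, another below everything); same-side
  double labels are impossible by construction, which the test suite
  verifies by exhaustive enumeration of all 3⁶ = 729 patterns against an
  independent brute-force evaluator.
* **2-vs-2 partition** — evaluated only when no group matches: all four
  cross-partition comparisons nonzero with consistent orientation and
  both within-side comparisons zero. Deeper multi-group patterns are out
  of scope.
* **mixed** — some comparisons significant but neither pattern holds;
  **none** — nothing significant.

Per-group summary counts count a doubly-labelled feature in both groups;
the unique count deduplicates — this is why per-group counts can sum to
more than the number of specific features.

The phospho-vs-protein comparison joins each significant site's log2 FC
with its parent protein's on the same comparison. `protein_driven` flags
|protein FC| ≥ |site FC| with matching sign; `protein_driven_candidate`
uses a ratio of 0.75, catching cases like a 2.0-fold site change over a
1.7-fold protein change where protein abundance plausibly explains most
of the phosphorylation change.

## KSEA

For one comparison with site fold-changes `fc`, a kinase with substrate
set S (matched by exact `GENE;residue+position` keys) scores

    z = (mean(fc[S]) − mean(fc)) · √|S∩fc| / sd(fc)

with `sd` the sample (n−1) standard deviation over *all* quantified sites
— background and dispersion come from the full site population, not only
significant sites. The p-value is the two-sided normal tail of z;
significance requires m ≥ `ksea_min_substrates` = 3 and p <
`ksea_alpha` = 0.05. z is invariant to shifting or positively rescaling
all fold-changes, and kinases with no matched substrate are reported with
m = 0 and no score. Signed log2 fold-changes are the input; no
sequence-motif or site-window matching is attempted.

## Preranked GSEA

Genes are ranked by Cohen's *d* with the pooled-SD denominator; undefined
effect sizes (zero pooled SD with unequal means) are excluded with a
warning, and ties break by gene identifier for determinism. The
enrichment score is the classic weighted running sum (weight exponent 1):
member genes add |d|/Σ|d|, non-members subtract 1/(N−m), and ES is the
signed extreme deviation. The null is gene-set permutation — `gsea_nperm`
(default 1000) uniform same-size draws from the ranked universe, shared
across sets of equal size — because the input is a preranked list and no
sample-level exchangeability is available. p is the one-sided same-sign
tail frequency with a +1 pseudocount; NES divides ES by the mean |null ES|
of matching sign; BH runs across the reported sets. Set sizes are bounded
to [10, 500] after restriction to the ranked universe. The permutation
scheme was chosen over an adaptive multilevel estimator because it is
directly checkable against brute-force enumeration and its p-values are
calibrated (the suite KS-tests them against uniform under a null
ranking).

## Synthetic cohorts

`simulate_cohort` draws per-feature baselines μ_f ~ N(25, 2) log2 units,
adds group offsets from the spike design (single-group or one side of a
2-vs-2 partition; kinase effects add their shift to the first group of
their comparison for every substrate), adds residual noise
ε ~ N(0, 0.5), and exponentiates. A cell is missing with probability
`logistic((midpoint − log2 intensity) · slope)`; the defaults
(midpoint 22.5, slope 1.0) censor ≈ 18–19 % of cells, realizing the
intended ~20 % MNAR regime. Localization probabilities are
Beta(9, 1) (mean 0.9, most sites class I). All draws come from one seeded
generator: identical config + seed gives bit-identical cohorts.

What the generator does **not** emulate: batch effects, peptide-level
evidence, correlated features (co-regulated complexes), heavy-tailed
noise, or sample-quality gradients. Passing recovery tests therefore
demonstrates that the pipeline's logic is correct under its own
assumptions — not that real FFPE cohorts behave this way.

A consequence of the MNAR model worth stating plainly: a DOWN effect on a
low-baseline feature pushes the affected group into the censoring zone,
the surviving observations are upward-biased, and any imputation that
fills from the observed distribution (including the prescribed 5th
percentile floor) attenuates the measured fold-change — in these
conditions from 2 log2 units to ≈ 1, the strict significance boundary.
Measured spike-recovery sensitivity under the default conditions is
therefore ≈ 0.85–0.88 rather than ≳ 0.9, with the misses concentrated in
exactly those DOWN spikes; UP spikes and kinase shifts are recovered
essentially completely, and the false-call rate stays far below 5 %. This
is a property of left-censored data, not of the implementation, and it is
deliberately reported rather than hidden by simulating only UP effects.

## Problem sizes and runtime

The test suite and `scripts/acceptance.py` use 2000-feature protein
cohorts (3 seeds), 500-site phospho cohorts with one active and ten decoy
kinases (3 seeds), 200-feature null cohorts, and 200 random gene sets at
500 permutations for null calibration — sizes chosen so a full run
completes in about a minute on one CPU while keeping Monte-Carlo noise
well inside the asserted margins.

## Known limitations

* Covariates (sex, stage, smoking) are carried in metadata but not
  adjusted for; no mixed models or permutation feature tests.
* Per-feature BH across six comparisons controls within-feature FDR only.
* KSEA treats substrate fold-changes as exchangeable with the background;
  correlated substrates inflate |z|.
* The kNN imputation's O(F²) distance matrix is computed per group; fine
  to ~20k features, not engineered beyond that.
* Protein→gene mapping for GSEA input is the caller's responsibility.
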