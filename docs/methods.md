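# Methods

This note documents the statistical procedures implemented in `solshift`,
the defaults and why they were chosen, what the synthetic cohort generator
emulates, and the package's known limitations.

## Data model

The cohort is a features × samples abundance matrix (`QuantMatrix`) with
explicit missingness and a scale tag (`raw` linear LFQ, `log2`, or `modz`),
plus per-sample metadata (`SampleMeta`: case, disease, fraction, and the
covariates age, sex, post mortem delay). Every sample belongs to exactly
one disease × fraction group; a case contributes one soluble and one
insoluble sample. Missing cells are genuinely absent values — LFQ exports
encode non-detection variously as empty cells, `NA` strings or zeros, and
the reader maps all of these (and any non-positive raw intensity) to
missing.

## Preprocessing

**Normalization.** Per-sample modified z-score on log2 intensities:
`z = 0.6745 · (x − median_s) / MAD_s`, median and MAD over the observed
values of sample `s` only. The MAD is unscaled (no 1.4826 factor) because
the 0.6745 multiplier already plays the consistency role: under normality
`z` behaves like an ordinary z-score. By construction each sample has
median z = 0 and median |z| = 0.6745. The transform is invariant to
per-sample additive offsets and positive rescalings, which is exactly the
sample-to-sample technical variation it is meant to remove. A zero sample
MAD (degenerate input) is an error, not a silent fallback.

**Detection filter.** Features must be observed in at least half of all
measurements (default 0.5 over the whole 30-sample cohort, not per
group — a protein absent from one disease but well measured elsewhere
should survive to the presence-call analysis).

**Imputation.** k-nearest-neighbour over feature profiles (k = 10, the
common default for this method; the neighbour pool is features, not
samples). Distance between two features is the NaN-aware Euclidean
distance: computed over jointly observed samples and scaled up by the
proportion of shared observations. A missing cell becomes the mean of the
k nearest features observed in that sample. Observed cells are never
altered, and imputed values lie within the range of the donor values. A
feature sharing no observations with any other falls back to its own mean
with a warning. Backed by `sklearn.impute.KNNImputer`, whose
`nan_euclidean` metric is exactly this distance.

**Presence calls.** On the raw (unimputed) detections, per protein ×
(disease, fraction) group: *missing* when detected in at most 1 sample of
the group, *present* when detected in a majority (> half), *sparse*
otherwise. Proteins missing in at least one group and present in the
majority of another are flagged group-specific; a protein present in every
group of exactly one disease and missing everywhere else is
disease-specific (the pattern of a disease-exclusive aggregating protein).
The sparse-set abundance summary (mean log2 of sparse proteins vs all
proteins, observed values only) documents that MNAR dropout concentrates
in low-abundance proteins.

## Differential statistics

**Model.** Cell-means parameterization: one indicator column per
disease × fraction group (six groups for a three-disease two-fraction
cohort), so every published contrast is a plain zero-sum weight vector,
including the difference-of-differences solubility contrast
(+1, −1, −1, +1 on A-insoluble, A-soluble, B-insoluble, B-soluble).
Samples are treated as independent — no within-case correlation between a
case's soluble and insoluble samples is modelled (see Limitations).

**Empirical Bayes.** Per-protein residual variances `s²` with
`d = n − G` df are shrunk toward a prior `(d0, s0²)` estimated by moment
matching of `log s²` against its theoretical scaled-F log distribution:
`trigamma(d0/2) = var(log s²) − trigamma(d/2)` (solved by Newton
iteration), then `s0²` from the mean equation via digamma terms. When the
empirical log-variance dispersion does not exceed the theoretical χ²
contribution, `d0` is capped at 1e6 (effectively complete shrinkage to a
common variance). The posterior variance `s̃² = (d0·s0² + d·s²)/(d0 + d)`
feeds a moderated t with `d0 + d` df. The implementation agrees with the
reference R implementation (limma `lmFit`/`eBayes`) to ~1e-6 on shared
data; that cross-check is part of the test suite, not of the
implementation.

**Multiplicity and significance.** Benjamini–Hochberg step-up within each
contrast family separately (each volcano is its own family). Significant =
FDR < 0.05 and |log2FC| > 0.585 (fold change 1.5; the threshold is the
intended log2(1.5) rather than its 0.584 truncation).

**Rank shifts.** Per disease × fraction group, proteins are ranked 1..P by
descending mean abundance on the normalized, imputed matrix; ties break
lexicographically by protein id for determinism. The per-disease shift is
soluble rank − insoluble rank; shifts sum to zero within a group (rank
conservation), so large positive shifts single out proteins climbing the
abundance ladder in the pellet.

## Correlations and enrichment

**bicor.** Biweight midcorrelation with Tukey biweights
`w = (1 − u²)² · 1[|u| < 1]`, `u = (x − median)/(9 · 1.4826 · MAD)`. The
1.4826 consistency factor follows the reference R implementation (R's
`mad()` default inside WGCNA's `bicorAndPvalue`); with it, bicor tracks
Pearson within ~0.01 on average for clean Gaussian data while a gross
outlier is merely down-weighted. Zero-MAD vectors fall back to Pearson
with a warning. p-values use the t approximation with n − 2 df
(asymptotic; the reference function's default). Anchor scans correlate
every protein's combined soluble + insoluble profile within one disease
against an anchor (tau, α-synuclein) and count |rho| > 0.7; the anchor's
trivial self-correlation is excluded from tables and counts.

Note a genuine interaction between normalization and combined-fraction
correlation: because per-sample MADs differ systematically between
fractions, the modified z-score injects a protein-specific
fraction-pattern term proportional to a protein's distance from the sample
median, which attenuates combined-fraction correlations for proteins far
from the median. The test suite demonstrates both the attenuation (modz
scale) and clean recovery (log2 scale) on planted correlated blocks.

**GSEA.** Preranked, weighted KS running sum (weight exponent 1) over the
moderated t ranking (configurable to log2FC). Null by gene-label
permutation — random same-size sets, the standard preranked null and the
only feasible one at n = 5 per group. p uses a +1 continuity correction,
NES divides by the mean |ES| of same-sign null draws, q is BH across sets.
Sets are intersected with the ranked universe; minimum size 5. Term
redundancy is removed at 70% Jaccard similarity of member lists, keeping
the smaller-q term (ties: larger |ES|, then lexicographic id), scanning
pairs by descending similarity for determinism.

## Peptide-level analysis

Peptide abundances are summed over all mass detections of the same
sequence (charge states, modified forms) with **no normalization or
imputation** — group tests use available n. Peptides are located on the
packaged 2N4R tau reference (441 aa) by exact substring search with
1-based inclusive coordinates; a mapped peptide overlapping the second
microtubule-binding repeat (exon 10, residues 275–305) is 4R-defining —
present only when the 4R splice form exists — and any other mapped peptide
is constitutive. Group comparisons are normality-gated: if every disease
group passes Shapiro–Wilk (p > 0.05), one-way ANOVA with Tukey HSD
pairwise p-values (family-adjusted by construction); otherwise
Kruskal–Wallis with Dunn's pairwise z-tests (tie-corrected, BH-adjusted).
Values constant across all groups give omnibus p = 1.

## Synthetic cohorts

The generator emits the world the analysis assumes: three disease groups
(default labels CBD, PiD, PSP), five cases each, two fractions, log2
intensity

    baseline_p + fraction_effect_p·[insoluble] + δ_(p,disease)·[insoluble]
    + case_effect_case + N(0, residual_sd)

with defaults baseline N(18, 2) (log2 LFQ), per-protein fraction effect
N(0, 1.5) (so fraction dominates the PCA, as in real fractionated
cohorts), residual sd 0.5, case effect sd 0.3 shared between a case's two
samples (realistic pairing that deliberately stresses the model's
independence assumption), and MNAR dropout
`P(drop) = 1/(1 + exp(slope·(x − τ)))` with τ = 14, slope = 1 — roughly
7% missingness concentrated in low-abundance proteins. Planted solubility
shifts are per-protein, per-disease log2 deltas on the insoluble side;
correlated blocks share a latent factor with an anchor at a chosen latent
r. A companion peptide generator emits multi-detection peptide tables from
a parent protein profile with a 3R/4R pool split, so the 4R-defining
peptide is structurally absent when the 4R share is zero. Everything is a
pure function of the seed.

What a green synthetic test does **not** establish: real LFQ data have
correlated technical batches, non-Gaussian heavy-tailed noise,
peptide-to-protein roll-up artifacts and interference, none of which are
emulated. Recovery results quantify the statistical machinery, not
instrument behaviour.

Parameter-recovery evaluations (power/FDP/bias of planted shifts) are run
on the log2 scale (filter → impute → fit): the synthetic cohort has no
per-sample scale artifacts for the modified z-score to remove, and bias in
log2 units is only defined there — modz rescales estimates by
~0.6745/MAD per sample. The FDR-control evaluation, which is scale-free,
runs through the full modz pipeline.

A note on attainable power: with δ = 1.5, residual sd 0.5 and n = 5 per
group, the shift estimator's SE is √(0.25·4/5) ≈ 0.447 (noncentrality
≈ 3.35), while the BH cut at 50 planted among 2000 proteins sits near
|z| ≈ 3.4. Roughly half the planted proteins clear it — a ceiling shared
by any implementation of this model — and conditioning on significance at
that power induces a winner's-curse bias of ≈ +0.3 on flagged estimates.
Unconditional estimates over all planted proteins are unbiased.

## Numerical choices and degenerate inputs

- Trigamma inversion by Newton iteration with asymptotic endpoints
  (y > 1e7 → 1/√y, y < 1e-6 → 1/y); d0 capped at 1e6.
- Duplicate feature/sample ids, non-numeric cells, unknown groups,
  singleton groups, zero MADs, non-estimable or non-zero-sum contrasts and
  empty peptides are errors naming the offender; constant covariates and
  zero-MAD correlation vectors degrade with warnings.
- All tie-breaks (ranks, term simplification, GSEA walk) are deterministic;
  all randomness flows through explicit seeds.

## Limitations

- No within-case pairing in the linear model (the matching published
  analysis is also unpaired). The synthetic stress test shows this is
  conservative: shared case effects inflate the residual variance and cost
  power but do not inflate FDP.
- No covariate adjustment (the cohort-level QC — covariate ANOVA across
  groups and covariate × principal-component correlations — is the
  decision tool for whether adjustment is needed).
- No left-censored imputation families; kNN only.
- GSEA has no gene-set topology or annotation retrieval; gene sets come
  from user-supplied GMT files.
- Peptide isoform logic covers exact tryptic matches and the 4R-defining
  repeat; no PTM localization and no 3R-junction inference beyond
  absence-of-repeat reasoning.
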