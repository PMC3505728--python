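# Methods

## Scope and model

`mirfate` evaluates seed-based miRNA target predictions against expression
responses under bidirectional miRNA perturbation. The analysis chain is:
scan 3′-UTRs for seed-match sites; filter and normalise an intensity
matrix; call per-gene modulation by fold change; classify every retained
gene against a prediction table into TP/TN/FP/FN per stratum and
orientation; compare strata statistically; attribute modulated genes to
direct sites versus transcription-factor (TF) secondary regulation; and
recover construct effects from dual-luciferase data. A synthetic-data
module generates the full experimental design with known ground truth so
the pipeline's operating characteristics can be measured exactly.

## Seed-match sites

Site strings are derived purely from Watson–Crick complementarity to the
miRNA 5′ region: 8mer = reverse complement of positions 2–8 plus a literal
3′ `A`; 7mer-m8 drops the `A`; 7mer-1A pairs positions 2–7 plus the `A`.
The `A` opposite position 1 is a property of the target site, not of the
miRNA's first base. Decisions the field's conventions leave open are resolved as follows:

- Coordinates are 0-based half-open on the UTR sense strand; scanning is
  sense-strand only (miRNA targeting reads the mRNA sense sequence).
- Overlap precedence: an 8mer occurrence is a single site, never
  additionally reported as its embedded 7mers; when a degenerate miRNA
  makes the two 7mer patterns identical at one locus, 7mer-m8 wins.
- 6mer and offset-6mer sites are not reported; only the three classes
  above are evaluated.
- Input is case-insensitive; `U` is read as `T`; `N` never matches.
- The AU-rich-element scan counts left-greedy non-overlapping `ATTTA`
  pentamers, the minimal destabilisation motif; one or more pentamers
  marks a UTR ARE-positive. This is a deliberately simple stand-in for
  curated ARE databases and is used as a negative-control annotation.

Mature sequences for miR-181b-5p, miR-107 and miR-20a-5p ship as package
data; they are the public mature sequences.

## Expression processing

Intensities are non-negative array-style values over
{control, miR, anti_miR} × ≥2 replicates per cell type.

- **Background filter**: a gene is excluded per cell line when below the
  background threshold in more than half of that line's samples; exactly
  half retains. The comparison uses raw intensities and is inclusive at
  the threshold.
- **Normalisation**: per chip, each sample is scaled so its median over
  retained genes is 1; per gene, each gene is divided by the median of its
  control samples within the cell type. Each step is exactly idempotent on
  its own; the composition is idempotent only up to the interaction of the
  two reference sets, so `normalize` is defined as one pass and the
  retained set is always decided on raw intensities.
- **Modulation calls**: fold change is the ratio of linear means of
  normalised replicates (means, not medians — with n=2 replicates the
  median is the mean). The 1.5-fold threshold is inclusive, avoiding
  float-equality fragility. In `fc_and_p` mode a pooled-variance
  two-sample t-test on log₂ values gates the call (Welch df degenerate at
  n=2/group); p-values are never multiplicity-corrected — the exploratory
  convention of array-era workflows. `fc_only` mode drops the gate, as
  used for the stringent bidirectional gene lists.
- Genes with a zero control mean or zero control median are excluded with
  a logged reason rather than silently coerced.

A consequence of median normalisation worth stating: when planted (or
real) effects are direction-asymmetric, the treatment sample's median
moves, which biases *every* normalised fold change coherently by the
median shift. This is a genuine property of median scaling under heavy
differential expression, not an artifact of the simulator; the analytic
oracle models it explicitly (below).

## Concordance evaluation

Per stratum (modulation model × cell type × prediction parameter ×
orientation) every retained gene is tallied exactly once. The expected
direction is fixed by orientation and arm (canonical: down under miR, up
under anti-miR; non-canonical reversed). A gene modulated in the
orientation-inconsistent direction counts as "not differentially
expressed" for that orientation: predicted → FP, non-predicted → TN —
the only reading consistent with defining TP/FN via the expected
direction. For a parameter stratum (e.g. 8mer) the positive class is
"predicted with that parameter"; all other retained genes, including
genes predicted under other parameters, form the negative class. The
bidirectional model counts a gene responsive iff it is in the
intersection of both arms' direction-consistent sets. Rates with zero
denominators are reported as absent, never as 0 or 1.

Statistical comparisons use closed-form parametric tests: paired
two-tailed t; one-way within-subject ANOVA with (k−1, (k−1)(n−1)) df
implemented from the classical sums of squares (the closed form handles
the degenerate all-equal input, F=0, p=1, and is cross-checked against
statsmodels' AnovaRM in the tests); and squared Pearson correlation for
canonical/non-canonical parallelism (sign-blind by construction).
Orientation comparisons average each statistic across cell types per
(modulation, parameter) before correlating, the natural pairing unit
for a multi-cell-line design. The PCT summary counts
scores strictly below the cutoff (0.1), with a score exactly at the
cutoff in the upper bin.

## Attribution and enrichment

Categories are assigned in a fixed preferential order (conserved site;
non-conserved site PCT < cutoff; non-conserved PCT ≥ cutoff;
alternative-algorithm only; TF motif only; unexplained); the order
reflects increasing indirectness of the evidence; no external convention
fixes a precedence. Records without a PCT fall into the ≥ bin.
Over-representation is the hypergeometric upper tail
P(X ≥ k) for overlap k between set (n) and term (K) in universe (N),
replacing service-bound Bayes-factor scoring with the equivalent fixed
threshold p < 1e-4 for TF-motif terms (p < 0.05 for pathway-style terms);
no multiple-testing correction across terms, matching the fixed-threshold
convention. The default universe is the post-filter expressed gene set.

## Reporter statistics

The experiment-level unit is deliberate: wells are internal triplicates,
so replicates are pooled by mean per (oligo, experiment) first and the
t-test runs across the four experiment-level normalised ratios against 1,
paired across experiments (pairing is a choice; with shared transfection
batches per experiment it is the better-powered one) and one-tailed in
the observed direction — such screens report
both repression and elevation as one-sided findings. Zero
variance across experiments yields an absent p-value and an unvalidated
record, never a fabricated zero. The bundled validation table stores fold
changes as signed percents and censored p-values (`<0.0001`) verbatim;
parsers handle both.

## The synthetic study generator

The generator emulates: 3 cell lines × {control, miR over-expression,
anti-miR inhibition} × 2 replicates; ~20 % predicted targets with site
classes split evenly and 25 % conserved; planted responders among targets
(default 40 % canonical, 10 % non-canonical); per-cell-line
below-background genes (10 %); a 150-gene TF regulon of non-target genes
responding secondarily (the TF is itself a planted, preferentially
responding target); spurious transfection-style background calls; and
dual-reporter readings with planted percent changes.

Model: intensities are log-normal — per-gene baseline × condition effect
× `2^N(0, noise_sd_log2)` — with effects multiplicative on the linear
scale, matching fold-change thresholding on array intensities. Baselines
are drawn once per (gene, cell) in `generate_truth` (log-uniform over
8–256 × the background level for expressed genes; 0.2–0.6 × the level for
below-background genes, so they stay under threshold at any plausible
noise) and are part of the ground truth. Parameter choices:

- `effect_fold_range` default (2.5, 4.0): the anti-miR arm sees
  `fold^attenuation` with attenuation 0.5 (inhibiting an endogenous miRNA
  perturbs it far less than transfecting a synthetic one, as the order-of-
  magnitude gap between over-expression and inhibition fold changes in
  such experiments shows). The fold floor is set so that attenuated
  effects (√2.5 ≈ 1.58) still clear the 1.5-fold call threshold —
  otherwise noiseless recovery of the planted response modes, a defining
  property of the generator, would be impossible. Planting effects at the
  detection threshold would be a degenerate design.
- `background_de_rate` (default 0.05) is a per-direction rate: each
  unresponsive non-target gene is independently pushed down with this
  probability and up with the same probability, per cell and arm, using
  effect sizes from the responder range. Defining it per direction makes
  a non-target's probability of *mimicking* a response equal to the rate
  itself, which is the quantity the confusion analysis sees.
- `noise_sd_log2` default 0.15: bead-array replicate noise varies by platform
  and lab; 0.15 gives replicate CVs around 10 %, typical of
  bead-array intensities, and is exposed in the config.
- PCT scores: conserved sites uniform on (0.3, 1); non-conserved sites
  below 0.1 with probability 0.9 — emulating the strong skew of poorly
  conserved sites among expressed targets.
- One miRNA per simulation; miRNA–miRNA feedback and ceRNA dynamics are
  out of scope.

Non-target UTRs are rejection-sampled until scanner-clean, and target
UTRs until they contain exactly their assigned class, so truth labels are
exact by construction.

### The analytic oracle

`expected_confusion` converts planted parameters into expected confusion
statistics without running the pipeline. Per gene and arm the normalised
log₂ fold is modelled as N(d − Δ, σ√(2/r)): d is the planted log₂ effect,
r the replicates, σ the replicate noise, and Δ the chip-median shift —
computed by bisection of the noise-smoothed empirical CDF of the planted
sample distribution, conditional on the planted baselines. Spurious genes
enter as their three-state mixture. Call probabilities are normal tails
against the inclusive log₂ 1.5 threshold (exact indicators at σ=0);
bidirectional probabilities multiply per gene (the arms are conditionally
independent given the planted effect; over-expression detection is
saturated at the default folds, so the shared-control correlation between
arms is negligible). Reported standard errors combine independent
per-gene Bernoulli variance with the coherent component propagated (delta
method) from the remaining fluctuation of the chip-median shift, whose
variance comes from the binomial fluctuation of the spurious-effect
states.

Tolerances in the recovery tests are 3 oracle standard errors plus a
fixed 2.5-gene discreteness allowance (scaled by the denominator for
rates): sums of near-0/1 Bernoulli variables have skewed tails for which
a Gaussian 3-SE band is slightly anti-conservative. The type-I check of
the regulon enrichment compares the observed significance rate to the
exactly attainable level of the discrete hypergeometric test,
Σₖ P(p(k) ≤ α), not to nominal α.

### What passing tests do and do not show

The generator reproduces the *structure* of a transfection study —
direction-asymmetric effects, below-background censoring, secondary
regulons, background responders — but not probe-level artifacts, dye or
batch effects, correlated gene programs, transfection toxicity, saturated
signal, or sequence-driven cross-hybridisation. Passing parameter
recovery therefore shows the analysis chain is correct and calibrated
under its stated model, not that real-array error rates will match; the
published headline figures from such experiments depend on unreleased
raw data and version-bound prediction snapshots and are treated here as
directional properties only (bidirectional > inhibition >
over-expression accuracy; conservation trades FPR for FNR; canonical and
non-canonical responses mirror each other; stringency raises the
explained fraction). All of these hold on the synthetic runs.

## Problem sizes and determinism

Default analyses use 2000 genes × 3 cell types × 18 samples; the
type-I-error study uses 200 runs of 400 genes; the scanner audit uses
1000 random sequences up to 2 kb. Everything derives from a single seed:
the generator splits it into fixed independent streams (truth, UTRs,
expression, annotations, reporter), so identical configuration + seed
gives bit-identical outputs end to end.

## Known limitations

- The normalisation stand-in is one defensible reading of "default
  per-chip and per-gene normalisation"; other array pipelines (quantile,
  lowess) are intentionally out of scope.
- With extreme responder loads the chip-median shift can push weak,
  attenuated effects below the call threshold; the oracle models this,
  but users planting folds near 1.5 should expect attenuated-arm
  detection to degrade — as it would on a real array.
- `evaluate_stratum` requires calls for every retained gene; partial call
  tables raise rather than silently shrinking the universe.
- The hypergeometric replaces service-specific enrichment scores; ranks
  agree for planted signals but absolute p-values are not comparable to
  Bayes factors.
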