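# Methods

## Model and assumptions

The package treats a population, not an individual, as the unit of
analysis. Its core quantity is the population-specific polygenic risk
score, psPRS = Σ<sub>k</sub> p<sub>k</sub>, the unweighted sum of
risk-allele frequencies over a SNP set. The underlying assumptions are:

* **additivity** — variants contribute to prevalence independently and
  additively; no epistasis or gene–environment terms enter the score;
* **frequency–prevalence proportionality** — if a variant's direction of
  effect is shared across populations, its contribution to prevalence
  scales with its local risk-allele frequency;
* **no effect-size weighting** — GWAS effect sizes are cohort-specific and
  transfer poorly across ancestries, and many associated SNPs lack usable
  effect estimates, so the score is a pure frequency sum.

This is an ecological regression: associations at the population level do
not license individual-level conclusions, and unmodelled environmental
differences between populations load directly onto the fit.

## Regression models

Prevalence (a proportion) or a population mean (e.g. height in cm) is
regressed on the psPRS across populations:

| model | form | fit | minimum n |
|---|---|---|---|
| linear | y = a + b·s | OLS | 3 |
| poly2 | y = a + b·s + c·s² | OLS on (s, s²) | 4 |
| exponential | y = exp(a + b·s) | OLS on log y | 3 |

The exponential model is fit by ordinary least squares on the
log-transformed phenotype rather than by iterative nonlinear least
squares: the log-OLS fit is closed-form, deterministic, and has no
starting-value or convergence ambiguity. Its r² is therefore reported on
the log scale, and the back-transformed growth factor exp(b) is exposed
alongside the log-scale coefficients. Reported r² values are plain
(unadjusted), and p-values are overall-model F-tests, which for the
single-predictor models coincide with the slope t-test. Per-super-
population fits run the same machinery within each continental group,
skipping groups smaller than the model minimum with a logged note.

## r²-maximization pruning

For every SNP in the current set the procedure computes the linear-fit r²
of the score with that SNP excluded. Because the single-predictor r²
equals the squared Pearson correlation between score and phenotype, all
leave-one-out values are computed vectorised from the full-score column
sums; one iteration costs O(n_snps × n_populations).

The default **single** mode is steepest-ascent backward elimination:
remove the one SNP whose exclusion maximises r², accept while the new r²
is ≥ the current one, stop otherwise or at one remaining SNP. The ≥ rule
removes plateau SNPs that contribute exactly nothing; single removal
cannot overshoot the maximum, so the r² trace is monotone non-decreasing
by construction. A **batch** mode (remove every SNP whose exclusion
beats the current r², then refit) is provided for sensitivity; it can
overshoot, so its trace carries no monotonicity guarantee. Exact ties
break toward the earliest input position and are logged; consequently the
trace is deterministic given the input order, and shuffling the input
changes the removal order only at exact-tie steps while the final r² is
invariant. An exhaustive best-subset search (≤ 15 SNPs, 2ⁿ enumeration)
serves as a ground-truth oracle in the tests; greedy never exceeds it.

Numerical choices: a reduced score whose spread across populations is
below 10⁻⁹ (frequencies are O(1)) is treated as constant and its fit as
undefined, rather than letting floating-point residuals of the column-sum
subtraction masquerade as correlation; a constant phenotype is rejected
before iteration; the retained set never empties.

## Follow-up statistics

**Significance enrichment.** A 2×2 table cross-tabulates genome-wide
significance (discovery p ≤ 5 × 10⁻⁸, inclusive) against membership in
the unfiltered versus the retained set — the filtered column is compared
against the full set, not against the removed complement. The two-sided
Fisher exact p-value is computed by point-probability enumeration of the
hypergeometric support (sum of probabilities of all margin-fixed tables
whose point probability does not exceed the observed one, with the
customary 10⁻⁷ relative tie slack), in log space via log-gamma for
stability at the thousands-of-SNPs scale. This is the convention of
mainstream statistical software, and the tests cross-check it against
both an exact-rational enumeration and an independent library
implementation.

**Frequency means.** The unit of analysis is the per-SNP mean frequency
across all populations; full and pruned sets are compared with a
two-sided Welch (unequal-variance) t-test. The test family behind the
published comparison is unstated, so the most assumption-light standard
choice was taken. With a singleton set the means are reported and the
p-value is NaN.

**Discovery ancestry.** The percentage of SNPs whose association was
discovered in European-descent cohorts, rounded to two decimals.

## Genomic spacing

"Average physical distance between SNPs" is interpreted as the mean gap
between position-adjacent SNPs within each chromosome (an all-pairs mean
would be dominated by chromosome length rather than local clustering);
the overall mean pools adjacent gaps across chromosomes. Proximity counts
use an inclusive threshold, default 30,800 bp, over all same-chromosome
pairs; distances are never computed across chromosomes, chromosomes with
fewer than two SNPs contribute no gaps, and the X chromosome participates
when annotated.

## Input handling

* TSV dialect: tab-separated, UTF-8, mandatory header; "." or empty cell
  means missing. Round-tripping a frequency matrix preserves values and
  missingness.
* Association tables: rows with discovery p ≥ 10⁻⁵ (the GWAS-Catalog
  inclusion threshold used throughout) are dropped with a logged count;
  duplicate rsids collapse to the smallest discovery p. Chromosome labels
  are normalised by stripping a `chr` prefix; positions are 1-based as in
  VCF.
* Missing-data policy: a SNP lacking a frequency in any scored population
  is excluded from the psPRS for all populations, keeping scores
  comparable; per-population imputation is deliberately not offered.
* VCF frequencies: only GT is consumed; the frequency is risk alleles over
  called alleles per population. The GWAS risk allele is oriented against
  REF/ALT, reporting 1 − ALT frequency when the risk allele is REF.
  Multi-allelic records and records matching neither allele are excluded
  and logged. Strand-ambiguous (A/T, C/G) variants are not specially
  resolved; ambiguity handling is the caller's responsibility and is
  flagged as a limitation rather than guessed at.

## Synthetic data generator

The generator emulates the structure of a 1000-Genomes-style frequency
panel and an additive trait, with these defaults (all overridable):

| parameter | default | meaning |
|---|---|---|
| n_populations / n_super | 26 / 5 | panel shape; real 1000 Genomes codes used when counts match |
| n_snps | 100 | SNPs in the panel |
| frac_universal | 0.5 | fraction of SNPs with a shared effect |
| fst | 0.1 | super-population differentiation (continental scale) |
| within_sd | 0.01 | population-level jitter around the super-population frequency |
| beta / intercept | 0.02 / 0.1 | prevalence change per unit summed frequency; baseline |
| noise_sd | 0.01 | additive phenotype noise |
| link | linear | linear, poly2 or exponential |
| decoy_beta | 0 | magnitude of population-specific decoy effects |

Frequencies follow a Balding–Nichols hierarchy: ancestral p ~ U(0.05,
0.95); each super-population draws from Beta(p(1−F)/F, (1−p)(1−F)/F),
whose variance is F·p(1−p); populations add clamped Gaussian jitter. The
default beta and intercept keep linear-link prevalences strictly inside
(0, 1) for the default panel (≈ 0.6 ± a few hundredths); values outside
[0, 1] are clipped with a logged count.

Decoy SNPs carry effects whose sign alternates across super-populations,
with the phase alternating across decoys. The double alternation matters:
it makes every decoy inconsistent between ancestries while leaving the
aggregate decoy contribution with no net alignment with the phenotype. (A
single shared sign pattern leaves a majority of populations on one sign,
so the decoy load as a whole correlates with the trait and decoys stop
being harmful — the failure mode this design removes.) Noise is additive
on the natural scale after the link, so the log-scale exponential fit is
exact only in the noiseless case.

All randomness flows through one seeded generator per artifact
(independent streams for frequencies, phenotype, annotations derived from
the same config seed); every artifact is a pure function of the config.

What the generator does **not** emulate: linkage disequilibrium between
SNPs (frequencies are independent across SNPs), admixed populations,
site-frequency-spectrum realism, phenotype measurement error structure,
or environmental covariates. Passing tests therefore demonstrate the
machinery's statistical behaviour under the stated model, not the
faithfulness of that model to any real trait.

## Problem sizes and verification

The test and acceptance runs use panels of 10–26 populations and 4–100
SNPs, 46,375-table exhaustive Fisher verification (all 2×2 tables with
n ≤ 30 against exact rational arithmetic), 200-instance pruning property
sweeps, and 200-replicate slope-recovery simulations — sizes at which
exhaustive oracles are feasible while the estimates they check are
stable. Published per-trait r² reproductions (lactase persistence,
melanoma, multiple sclerosis, height) additionally require the
supplementary per-SNP allele-frequency panels, which are not
redistributed with the package; the corresponding checks look for
locally downloaded copies under `data/external/` and report their absence
otherwise.

## Known limitations

* Ecological design: population-level fits cannot support individual
  prediction, and confounding by environment or ancestry structure is
  unaddressed by construction.
* The pruning objective optimises in-sample r² with no cross-validation;
  it is a sensitivity analysis, not a selection procedure with
  generalisation guarantees (greedy search also need not find the global
  best subset).
* LD is handled only through the physical-proximity heuristic; no
  genotype-based r² is computed.
* The exponential model's r² (log scale) is not directly comparable to
  the linear and polynomial r² (natural scale).
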