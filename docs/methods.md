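# Methods

This note documents the statistical procedures `tfburden` implements, the
choices made where the design was genuinely open, what the synthetic-data
generator does and does not emulate, and the numerical details that matter
for reproducing its outputs.

## Coordinates and data model

Intervals are 0-based half-open (BED convention); mutation positions and
summits are 1-based (VCF/ICGC convention). Conversion happens only inside
operations, never in stored types. When a peak carries no caller summit, the
interval midpoint is used, ties resolved to the lower coordinate.

Mutation catalogs keep single-base substitutions and insertions/deletions up
to 200 bp; multi-base substitutions and longer indels are dropped with
logged counts. Mutation types are inferred from allele lengths when the
column is absent.

## Analysis windows and exclusion filters

Sites are extended to summit ± 1 kb for substitution analyses and ± 5 kb for
indels. Three exclusion sets — coding sequence, browser blacklist, and
low-mappability regions (all consumed as user-supplied BED intervals; no
mappability computation is in scope) — mask any window position they
overlap, and a site whose ± 200 bp core touches one of them is dropped
entirely (a flag keeps such sites instead). Binding sites of *other*
transcription factors mask only flank positions (|offset| > core
half-width): that exclusion is positional, pruning flank contamination
without discarding the site under study. All per-offset rates are normalized
by the number of *valid* positions at that offset; an offset with zero valid
positions is reported as missing, never as a zero rate.

## Observed and context-expected rates

The observed profile counts mutations per offset over valid positions
(indels at their 1-based start). The expected profile is the resampling
null: every substitution inside the windows is assigned to one of 96
strand-collapsed trinucleotide classes `X[R>A]Y` (purine-centered changes
reverse-complemented so the reference center is a pyrimidine; contexts
containing N are excluded and counted), and each resample places exactly the
observed count of each class uniformly at random, without replacement,
among valid window positions whose reference trinucleotide matches. The
default is 1000 resamples with the 96 class counts held fixed in every
resample; the expected rate at an offset is the mean placed count divided by
the valid-position count.

*Numerical choice.* Only per-offset counts enter the expected rate, and
positions within one trinucleotide pool are exchangeable, so the placement
is drawn per pool as a multivariate hypergeometric over offset bins. This is
distributionally identical to drawing positions uniformly without
replacement and reduces the cost per resample from the number of window
positions to the number of offset bins. Without-replacement placement (at
most one placed mutation per position per resample) avoids double-counting;
at realistic densities the difference from with-replacement is negligible.
A class whose count exceeds its matching-position pool raises an error
naming the class.

## Enrichment statistic

Core (±200 bp of the summit) versus flank (> 200 bp and ≤ 1 kb) mutation
counts and valid-position totals form a 2×2 table tested with a Pearson
chi-square *without* continuity correction (counts are large in intended
use; Yates is available behind a flag). The fold change is the ratio of
per-position rates; a zero flank count leaves it undefined and flagged
rather than infinite. P-values are Benjamini–Hochberg adjusted within one
analysis family — all groups of one stratified run are corrected together.
Stratifications: intensity quantiles (edges at i/k sample quantiles, stable
order on ties with a warning), patient-sharing classes (default
patient-specific = 1, shared by 2–3, shared by > 3; sharing 3 is placed in
the middle class, and the edges are configurable because the boundary is a
labeling convention, not a finding), genomic context (promoter defined as
TSS − 2000 … TSS + 500 by default, configurable, precedence promoter >
intronic > intergenic), outcome classes, and control-tissue donor
subgroups. The outcome burden comparison samples 100 sites per group, 50
times, and applies two-sided t-tests to the repetition means. The intensity
quartile analysis reports the Pearson correlation between group mean
intensity and group core rate.

## Count regression and covariate correction

NB2 regressions (log link, variance μ + αμ²) are fitted by maximum
likelihood with the dispersion α estimated jointly (statsmodels; BFGS with a
method-of-moments α start, Nelder–Mead fallback; tolerance and iteration
caps are the library defaults, non-convergence raises with diagnostics).
Wald z = coefficient/SE against a normal reference; nested models are
compared by likelihood ratio against a chi-square with df equal to the
parameter difference. When α is driven to the zero boundary
(equidispersed counts) the joint Hessian is singular and the coefficient
standard errors are taken from a GLM refit with α held fixed.

Covariate correction regresses the response on the covariates alone and
keeps residuals. **Pearson residuals are the default**: the contract of the
corrected values is near-zero linear association with the removed
covariates, and Pearson residuals satisfy it by construction. Deviance
residuals — the default extractor of common GLM software — retain a small
systematic correlation with strong covariates under heavy overdispersion
(about −0.05 at slope 1.2, dispersion 2, n = 2000) because the deviance
transform is asymmetric around the fitted mean; they remain available,
along with raw response residuals, for sensitivity analysis, and the
residual type is recorded in output metadata. Model-based prediction
simulates each predictor independently from its empirical marginal
(resampling with replacement; the appropriate simulation distribution is
application-specific, so it is deliberately the simplest one).

## Topological target genes and expression comparison

A loop "touches" a site at ≥ 1 bp anchor overlap (no anchor padding by
default; slop is configurable); a loop touching both anchors is counted
once. Targets of a site are genes overlapping the distal anchor of a
touching loop *and* overlapping the TAD that contains the site summit (TAD
membership by summit for sites, by any-overlap for genes; the appropriate
granularity is not canonical, and these are the least surprising choices).
A site outside every TAD has no targets.

The expression comparison groups sites by core mutation count (0, 1, 2,
≥ 3), samples 500 regions per group 10 times, pools the deduplicated target
genes across all sampled regions (pooling avoids weighting genes by loop
multiplicity; a per-rep mode exists), then draws 200 genes 100 times —
without replacement within a draw — recording mean expression per draw, and
compares groups with two-sided t-tests on the draw means. The
linear-proximity control assigns genes within 50 kb (or 100 kb) of the
summit with no loop/TAD condition and runs the identical sampling, so any
topological contrast has a matched baseline.

## ChIP-seq variant screen

Allele counts at catalog positions come either from a documented per-read
pileup TSV (chrom, pos, base, baseq, mapq, sample) or from SAM/BAM
iteration via aligned pairs (no index required): each read contributes its
aligned base once; deletions/reference skips at the position count as
"other"; secondary/supplementary and flagged-duplicate reads are skipped.
Default thresholds are base quality ≥ 13 and mapping quality ≥ 0, mirroring
common readcount defaults, and are configurable since the original
thresholds are unstated. Merged-group analysis concatenates per-sample
pileups before counting. A candidate passes when depth ≥ 10 and both the
catalog reference and alternative alleles are observed at least once; the
per-outcome-class summary is the fraction of sites containing ≥ 1 passing
call, with an empty class reported as missing, not zero.

## Motif shifts

PWMs are per-position probability matrices; JASPAR-style count matrices are
converted with pseudocount 0.8 split by background frequencies (uniform by
default). The score of a window is the product over positions of
p(base)/background(base), computed in log space and maximized over windows
and both strands; windows containing N are skipped. Allele comparison
restricts scoring to windows overlapping the mutation — the alleles are
identical elsewhere, and genome-wide best-hit drift is irrelevant to the
contrast. The ratio mutant/reference classifies the motif as created
(> 1 + ε), disrupted (< 1 − ε), or unchanged (ε = 0.05 by default); a call
is confident when either allele's score clears the empirical
(1 − 10⁻³)-quantile of best-window scores on background-generated sequences
of the query length. These likelihood-ratio scores are this package's own
scale — an affine "motif score ≥ 100" convention used elsewhere is not
reproduced; the comparable outputs are the classifications and ratio
rankings. Log-space and direct-product scoring agree to 1e-9 relative
error on toy matrices (tested).

## Synthetic data generator

One master seed fixes every emitted byte (derived streams for genome,
sites/mutations, topology, pileups). The generator emulates:

- an i.i.d. random genome at configurable GC (default 0.41, human-like);
- binding sites on a jittered grid with ≥ 2.1 kb spacing so ± 1 kb windows
  do not overlap; log-normal binding intensity;
- per-donor site inclusion with probability logistic in standardized log
  intensity (defaults give a majority of patient-specific sites and a
  long shared tail, and induce the sharing–intensity confound);
- somatic substitutions drawn from a 96-class signature (default
  APOBEC-weighted: 60% of mass on T[C>G]N / T[C>T]N) and placed only at
  matching reference trinucleotides; cohort background 5 × 10⁻³ per bp by
  default so contingency tests at desk scale have realistic power;
- a planted core enrichment within ± 200 bp of summits whose per-site
  factor is modulated by intensity, a direct sharing effect, and outcome
  class, then normalized so the mean factor equals the configured
  cohort-level enrichment (1.25 by default) — stratified analyses see
  gradients while the overall fold change stays at the configured value;
- indels with a protective core factor (0.8) matching their depleted
  profile;
- TADs tiling the genome (300–700 kb), compact gene units (1–3 kb) with
  log-normal expression (σ = 0.5), NB contact counts with log-mean linear
  in log intensity and core mutation count, loops to distinct distal
  (> 60 kb) same-TAD genes with narrow anchors (summit ± 100 bp,
  TSS ± 500 bp) so anchor-overlap counting round-trips, and an expression
  shift (e¹) for loop targets of ≥ 3-mutation sites;
- per-outcome pileups with planted variant alleles (depth Poisson 30, alt
  fraction 0.35; variant presence 10% at good vs 25% at poor/met sites).

It does **not** emulate: mappability structure, replication timing or
repair-coupled covariates of real mutation rates, read errors or fragment
models, overlapping/isoform gene structure, inter-chromosomal loops, or
copy-number change. Passing tests therefore demonstrate that the statistics
recover what was planted under their own model assumptions — not that those
assumptions hold in real tumor data.

## Problem sizes used in validation

The validation suite runs the full stack at 5000 sites on a ~10.6 Mb
single-chromosome genome (the default scale, chosen so every stage completes
in minutes on one CPU), with smaller fixtures (≈ 600 sites, 1.5 Mb) for
per-module tests; type-I calibration uses 200 regenerated null mutation sets
over one fixed genome and window set, and planted-enrichment recovery uses
100 regenerated mutation sets — the genome and site layout are held fixed
because the mutation process is the stochastic component under test. The
topology comparison runs at the published sampling depths (500 regions × 10,
200 genes × 100) with cohort background 2.5 × 10⁻³ per bp, the rate at which
all four mutation-count groups hold the ≥ 500 sites that region sampling
requires. Expected-rate validation compares 10⁴ resamples on ≤ 100-position
toys against the closed-form placement probability.

## Known limitations

- `multi_intersect` is a pure-Python sweep; fine for tens of thousands of
  intervals, not for multi-million-interval catalogs.
- The NB dispersion boundary (α → 0) is handled by a fixed-α refit for
  standard errors; a profile-likelihood interval would be better near the
  boundary.
- Expression comparisons inherit the fixed-pool caveat of the repeated
  gene-sampling design: with many draws from one pool, the t-test detects
  arbitrarily small pool differences, so its p-values are meaningful only
  against the matched proximity control.
- PWM threshold calibration is per query length; scores for different
  sequence lengths are not directly comparable.
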