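# tfburden

Localized somatic mutation burden at transcription-factor binding sites.

Whole-genome sequencing of tumors shows that somatic mutations are not spread
evenly across non-coding DNA: binding sites of lineage transcription factors
— the motivating case is the estrogen receptor (ER) in ER-positive breast
cancer — accumulate substitutions at an elevated rate right around the
ChIP-seq peak summit. `tfburden` is a tested, reusable implementation of the
computational analyses behind that observation, for genomicists who want to
run them on their own peak/mutation catalogs or on fully synthetic data:

- **Rate profiles.** Per-nucleotide observed mutation rates in summit ± 1 kb
  windows (± 5 kb for indels), after excluding coding, blacklisted,
  low-mappability, and other-TF-bound positions; and a *context-expected*
  profile obtained by re-placing the observed counts of the 96
  strand-collapsed trinucleotide substitution classes `X[R>A]Y` uniformly
  among context-matching positions, 1000 times, holding the class counts
  fixed per resample.
- **Enrichment statistics.** Core (±200 bp) versus flank (200–1000 bp)
  contrast as a 2×2 contingency table: fold change
  `FC = (m_core/n_core)/(m_flank/n_flank)`, Pearson chi-square p-value, and
  Benjamini–Hochberg q within one analysis family; stratified by binding
  intensity quartile, patient-sharing class, genomic context, outcome label,
  and control-tissue subgroup; the six-class substitution spectrum
  (APOBEC-style C>G/C>T excess); per-site burden ranking with recurrent
  (≥ 2 donors, allele-exact) flags.
- **Covariate-corrected regression.** Negative binomial (NB2, log link) GLMs
  with jointly estimated dispersion, Wald tests, likelihood-ratio model
  comparison, and residual-based correction of a response (e.g. chromatin
  contact frequency) for a covariate (e.g. binding intensity).
- **Topological target genes.** A gene is a target of a site when it
  overlaps the distal anchor of a chromatin loop from the site *and* lies in
  the same TAD; repeated region/gene sampling compares target-gene
  expression across site groups with 0, 1, 2, ≥ 3 core mutations, with a
  linear-proximity (50/100 kb) control.
- **ChIP-seq variant screening.** Allele counting at catalog positions from
  alignments or text pileups, with the filter *depth ≥ 10 and both alleles
  observed*.
- **Motif shifts.** PWM likelihood-ratio scoring of reference vs mutant
  alleles restricted to windows overlapping the mutation; created /
  disrupted / unchanged calls with an empirically calibrated P ≤ 1e-3
  confidence threshold.
- **Synthetic data.** A seeded generator that emits every input the pipeline
  reads (FASTA, narrowPeak, mutation TSV, BEDPE, BED, gene TSV, pileup TSV)
  with planted core enrichment, intensity-coupled sharing, loop/expression
  structure, and variant alleles, plus a ground-truth sidecar.

## Worked example

```python
import numpy as np
from tfburden import (SimConfig, build_analysis_windows, enrichment_from_windows,
                      fit_trinucleotide_model, expected_rate_profile)
from tfburden.simulate import simulate_genome, simulate_sites_and_mutations

cfg = SimConfig(genome_length=2_200_000, n_sites=1000, n_donors=30, seed=0)
genome = simulate_genome(cfg)
sites, mutations, truth = simulate_sites_and_mutations(cfg, genome)

windows = build_analysis_windows(sites, flank=1000)
res = enrichment_from_windows(windows, mutations)
print(f"observed core rate : {res.core_rate:.5f} per bp")
print(f"observed flank rate: {res.flank_rate:.5f} per bp")
print(f"fold change        : {res.fold_change:.3f}")
print(f"chi-square p       : {res.p_value:.3g}")

model = fit_trinucleotide_model(mutations, genome, windows)
expected = expected_rate_profile(windows, genome, model, n_resamples=200, seed=1)
off = np.abs(expected.offsets)
core, flank = off <= 200, (off > 200) & (off <= 1000)
exp_fc = (expected.expected_counts[core].sum() / expected.n_valid[core].sum()) / \
         (expected.expected_counts[flank].sum() / expected.n_valid[flank].sum())
print(f"context-expected fold change: {exp_fc:.3f}")
```

Output:

```
observed core rate : 0.00632 per bp
observed flank rate: 0.00495 per bp
fold change        : 1.277
chi-square p       : 5.15e-27
context-expected fold change: 1.007
```

The generator planted a 1.25× core enrichment; the observed fold change
recovers it (1.277 at this scale and seed, chi-square p ≈ 5e-27), while the
trinucleotide-context expectation stays at 1.007 — sequence composition
alone does not produce the excess, which is the core claim the statistic is
built to test.

## Command line

```bash
tfburden simulate --out-dir data --seed 4 --n-sites 600 \
    --genome-length 1500000 --background-rate 0.0025
tfburden all --data-dir data --out-dir results --seed 7
```

`tfburden all` writes profile tables, enrichment and stratification TSVs,
NB model summaries, corrected contact frequencies, expression comparisons,
variant calls, and a `manifest.json` recording the seed, config hash, and
per-stage summaries. Individual stages (`rates`, `enrich`, `stratify`,
`regress`, `topology`, `variants`, `motif`) run independently; reruns with
the same config and seed are byte-identical.

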