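# methsig

Quality evaluation for differential-methylation (DM) signatures.

DM analysis of bisulfite sequencing (RRBS/WGBS) or methylation arrays
yields a *signature*: an ordered list of differentially methylated
cytosines (DMCs) or probes (DMPs) separating two phenotype groups.
Different statistical methods frequently return signatures of very
different length and content from the same dataset, and no experimental
gold standard exists to arbitrate. `methsig` is for analysts who need a
quantitative, gold-standard-free answer to "how good is this signature
on this dataset?", plus the simulation machinery to benchmark DM
callers with known ground truth.

## The H-score

Given a site × sample methylation matrix, a signature *S*, and group
labels, samples are represented by their methylation levels at the
sites of *S* and all n(n−1)/2 pairwise Euclidean distances are ranked
ascending (average ranks for ties). With *b* between-group pairs, *w*
within-group pairs, and *R* the rank sum over the between-group pairs,

    H = (R − b(b+1)/2) / (b·w)  ∈  [0, 1].

H = 1 means every between-group distance exceeds every within-group
distance (perfect separation); H ≈ 0.5 is the exchangeable-null level.
H equals the Mann–Whitney U statistic of between- versus within-group
distances scaled to [0, 1], so it depends only on the ordering of the
distances. Significance comes from an empirical permutation p-value
against random same-length signatures drawn from the same dataset, with
a pseudo-count: p = (#{H_null ≥ H_obs} + 1) / (n_used + 1).

Conventions: an empty or single-site signature scores 0
(`zero_short_signature`), as does a signature whose distance matrix has
an undefined entry because two samples share no jointly covered site
(`zero_na_rule`).

Around the score, the package provides:

- **I/O** — Bismark coverage files (`.cov`/`.cov.gz`), bedGraph counts,
  TSV beta matrices and sample sheets, TSV/BED signature export, and an
  adapter for external DM result tables (methylKit/DSS/limma/HMM-DM
  style).
- **Filters** — coverage > 5 reads per cell, group-presence rule,
  count → methylation-ratio conversion.
- **DM tests** — Welch t-test on methylation levels, a beta-binomial
  likelihood-ratio test with method-of-moments dispersion, and a pooled
  two-proportion chi-square with optional overdispersion correction;
  Benjamini–Hochberg and Storey q adjustment.
- **Signatures** — adjusted p < 0.05 and |Δ| ≥ 0.15 selection, sorted
  with deterministic tie-breaks; top-100/top-10 subsets.
- **Simulation** — RRBS-like spike-in counts (island-structured sites,
  negative-binomial coverage, beta-binomial noise, known DMC truth) and
  a microarray-like beta-matrix analogue.
- **Benchmarking** — precision/recall/accuracy against truth,
  label-permutation FPR, the precision→H-score relation, and a
  cross-method Shapiro–Wilk + Friedman comparison.

## Worked example

Simulate a spike-in benchmark dataset (16 case / 16 control samples, 60
spiked CpG islands at Δ = 0.2), run the count-based pipeline, and score
the resulting signature:

```python
import methsig as ms
from methsig.cli import spikein_pipeline

cfg = ms.SimulationConfig(n_regions=60, delta=0.2, seed=1)
counts, groups, truth = ms.simulate_spikein_counts(cfg)

sig, filtered = spikein_pipeline(counts, groups, "beta_binomial")
m = ms.confusion_metrics(sig, truth, filtered.site_keys)
print(f"signature length: {len(sig)}")
print(f"precision={m.precision:.3f} recall={m.recall:.3f} accuracy={m.accuracy:.3f}")

ratios = ms.methylation_ratios(filtered)
report = ms.evaluate_signature(ratios, groups, sig,
                               subsets=("full", 100, 10), n_null=1000, seed=1)
print(report.to_string(index=False))
```

Output:

```
signature length: 771
precision=0.991 recall=0.850 accuracy=0.981
subset  length       h status  p_value  n_null
  full     771 1.00000     ok 0.000999    1000
   100     100 1.00000     ok 0.000999    1000
    10      10 0.99821     ok 0.000999    1000
```

The beta-binomial test recovers the spiked DMCs almost without false
positives (precision 0.991), and the signature separates the two groups
perfectly (H = 1 for the full signature and the top-100 subset), far
above anything achieved by 1000 random signatures of the same length
(p ≈ 1/1001, the smallest value attainable at that null sample size).

The same pipeline is available from the shell:

```sh
methsig --seed 1 simulate --delta 0.2 --n-regions 60 --out-prefix sim
methsig filter --counts sim.counts.tsv --groups sim.groups.tsv --out filtered.tsv
methsig test --method beta_binomial --counts filtered.tsv --groups sim.groups.tsv --out dm.tsv
methsig signature --dm dm.tsv --out sig.tsv
```

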