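# Methods

This note documents the statistical models behind `methsig`, the
defaults and why they were chosen, what the simulators do and do not
emulate, and the numerical conventions a careful user should know.

## 1. The H-score

**Definition.** For a dataset with n samples in two or more groups and
a signature of sites, each sample is the vector of its methylation
levels (array beta values or NGS methylation ratios) at the signature
sites. All N = n(n−1)/2 pairwise Euclidean distances are ranked
ascending with average ranks for ties. With b between-group pairs, w =
N − b within-group pairs, and R the sum of the between-group ranks,

    H = (R − b(b+1)/2) / (b·w).

This is the normalized Mann–Whitney rank-sum of between- versus
within-group distances: H = U/(b·w) where U counts (between, within)
pairs with d_between > d_within, plus ½ per tie. Consequences that the
test-suite pins down:

- H ∈ [0, 1]; H = 1 iff every between-group distance exceeds every
  within-group distance; H = 0 for the reverse ordering.
- All-equal distances give exactly H = 0.5 (a consequence of average
  ranks), and the expectation under exchangeable labels is ≈ 0.5.
- H depends on the distances only through their order, so it is
  invariant under strictly increasing transforms, sample reordering,
  and group-label swaps.

**Why ranks.** Ranking makes the score insensitive to the distance
scale and to outliers; it measures order, not magnitude, of the
group-separation signal.

**Degenerate inputs.** Two conventions map pathologies to a zero score
while preserving the reason in a status field: `zero_short_signature`
for signatures with fewer than two sites (including empty signatures —
a method that returns nothing provides no stratification), and
`zero_na_rule` when any pairwise distance is undefined because two
samples share no jointly covered signature site. Distances are computed
pairwise-complete: each sample pair uses the signature sites where both
are non-missing. Reporting can either include or exclude zero scores
when summarizing across methods; both summaries are legitimate and the
status column makes either reproducible.

**Empirical p-value.** The null is the H distribution of random
signatures of the same length drawn from the dataset's own site
universe (by default the post-filter universe the evaluated method
saw). Draws whose H is zero by rule are discarded. Sampling continues
until `n_null` (default 5000) retained values or a cap of
`max_attempts` (default 50 000) draws; if the target cannot be reached
the p-value is reported undefined rather than extrapolated. A
strict-attempts mode that stops at exactly `n_null` draws is available.
The p-value uses a pseudo-count,

    p = (#{H_null ≥ H_obs} + 1) / (n_used + 1),

so it is never exactly zero; ties with the observed value count as
extreme (conservative). Within one random signature sites are drawn
without replacement so its length is well defined; a literal
with-replacement mode (where duplicate draws collapse) is provided as a
flag.

## 2. Site filters

- **Coverage:** cells with coverage ≤ 5 reads are masked (strictly
  greater than five survives). The strictness and threshold are
  parameters (`min_reads`, `strict`) because the inclusive reading
  (≥ 5) is also common in practice.
- **Group presence:** the default rule discards a site when the number
  of uncovered samples exceeds `max_uncovered_per_group` (default 1) in
  *every* group — i.e. at least two uncovered samples in each group.
  The stricter alternative, requiring at least two *covered* samples
  per group, is selectable (`rule="min_covered_per_group"`). Both
  readings circulate in pipelines, so the choice is explicit rather
  than silent; groups too small for the rule to be decidable raise.
- **Ratios:** methylation ratio = methylated/total per cell; zero
  coverage is missing (NaN), never 0, because 0 is a valid methylation
  level.

Filters only remove sites or mask cells, are idempotent, and are
invariant to sample order and label swaps.

## 3. Differential methylation tests

The package ships one self-contained representative per method family;
outputs of external tools enter through the adapter
(`io.read_external_dm_table`) for faithful comparisons.

**Welch t-test** (array-style): two-sided, unequal variances,
Welch–Satterthwaite degrees of freedom, computed on beta values or
ratios. Degenerate conventions: both group variances zero with equal
means → p = 1; zero variances with different means → p = 0; fewer than
two non-missing values in a group → p undefined. An M-value transform
M = log2((β + ε)/(1 − β + ε)) with ε = 10⁻⁶ is provided for users who
prefer testing on the logit scale.

**Beta-binomial likelihood-ratio test** (count-based family): per site,
methylated counts follow BetaBinomial(n_j, μ_g, φ) with group mean μ_g
and a shared per-site dispersion φ (intra-class correlation
parametrization; φ → 0 is binomial). The LRT compares per-group means
against a common mean; the statistic is referred to χ²(1). The mean
MLEs are found by vectorized golden-section search over (0, 1), which
is reliable because the likelihood is unimodal in the mean at fixed
dispersion. φ is a method-of-moments estimate pooled across groups,
floored at 10⁻⁶ and capped at 0.5, optionally shrunk halfway in log
space toward the genome-wide median (`shrink_dispersion=True`) to
stabilize low-replicate estimates. At φ ≤ 10⁻⁶ the implementation
switches to the exact binomial likelihood, which the tests use to
cross-check against a closed-form two-proportion binomial LRT.

**Overdispersed proportion test** (pooled family): reads are pooled per
group into a 2×2 methylated/unmethylated table and the Pearson χ²(1)
statistic computed. With correction enabled, the statistic is divided
by a per-site variance-inflation scale — squared Pearson residuals of
per-sample counts around their group proportion, divided by (covered
samples − 2), floored at 1 — so corrected p-values are never smaller
than uncorrected ones. Under the package's own overdispersed null
(φ = 0.05) the uncorrected test is visibly anti-conservative
(Kolmogorov distance ≈ 0.25 from uniform) while the corrected test and
the beta-binomial LRT are near-calibrated (≈ 0.06–0.08); the test suite
asserts bounds of 0.12 fixed from repeated null simulations before the
bounds were frozen.

**Adjustment:** Benjamini–Hochberg step-up by default (NaNs pass
through); Storey's q-value with a λ-grid π₀ estimate (0.05…0.95, cubic
polynomial evaluated at the grid end) as an option.

**Reported effect size:** group means are means of per-sample ratios
(not pooled-count ratios), matching how the signature threshold |Δ| ≥
0.15 is applied to array data; `diff = mean(group2) − mean(group1)`
with groups in sorted label order unless specified.

## 4. Signature construction

Sites enter a signature when adjusted p < α (default 0.05, strict) and
|Δ| ≥ 0.15 (non-strict), both configurable; the absolute difference is
used for both hyper- and hypomethylated sites. Posterior-based inputs
(HMM-DM style) instead use posterior > 0.95 and sort descending.
Sorting ties on the score are broken lexicographically by site key —
top-10 subsets are sensitive to tie-breaks, so determinism across runs
is mandated and tested. `top_n` preserves relative order and is a
subset of its input; `build_signature` is idempotent on its own output.

## 5. Spike-in simulators

**Count simulator** (`simulate_spikein_counts`). The generative model,
replacing an external read-level RRBS simulator with an explicit
count-level one so no external genome or tool is needed:

- *Layout:* `n_regions` spiked island-like regions plus `n_null_regions`
  unspiked islands (sites 50 bp apart within a region, Poisson-sized
  with mean `sites_per_region_mean` = 15, min 3) and `n_background`
  scattered background sites, all on one synthetic chromosome.
- *Baselines:* bimodal, emulating CpG-island hypomethylation against a
  methylated background — island sites draw from Beta(2, 8) (mean 0.2),
  background from Beta(8, 2) (mean 0.8). Hypo-spiked regions draw from
  the high mode so a downward shift is observable.
- *Coverage:* negative-binomial, mean 30, dispersion 0.3 (var = μ +
  0.3μ²); zero-coverage draws are genuine missing cells.
- *Counts:* beta-binomial via p_ij ~ Beta with mean μ and intra-class
  correlation φ = 0.05, then Binomial(cov, p_ij).
- *Spike:* case-group means are clip(p₀ ± δ, 0, 1) in spiked regions,
  sign per region; exactly round(frac_hyper·n_regions) regions are
  hypermethylated (default half of 300). Defaults are 16 case / 16
  control samples and δ on the benchmark grid {0.1, 0.15, 0.2, 0.3}.
  Clipping at the boundaries means the realized difference can be below
  the nominal δ; the per-region *effective* delta after clipping is
  recorded in the truth object so metrics can condition on it, and a
  degenerate configuration in which all spiked sites clip to the same
  boundary in both groups warns.

The coverage mean/dispersion and φ defaults are this package's own
declared choices of realistic RRBS-like values; they are asserted by a
parameter-recovery test (empirical spiked difference within ±0.03 of
nominal at the default size) rather than inferred from any external
dataset.

**Array simulator** (`simulate_beta_matrix`): site means from the same
two-mode Beta mixture; per-sample beta values drawn Beta(μκ, (1−μ)κ)
with concentration κ = 60 (sd ≈ 0.05 at μ = 0.2); DMP case means
shifted by ±δ and clipped to [10⁻³, 1−10⁻³] to keep the Beta parameters
proper.

**Mixed signatures** (`make_mixed_signature`): exactly
round(tp_fraction × length) sites sampled without replacement from the
truth, the remainder from the non-truth universe — the substrate for
the precision→H-score relation.

Both simulators are bit-reproducible from their config seed.

**What the simulators do not emulate:** read-level artifacts (quality,
bisulfite conversion errors, mapping bias), chromosome-scale CpG
density variation, spatial correlation of methylation beyond the
region-level mean shift, batch effects, and covariates. Passing
benchmarks on these simulations therefore demonstrates correctness of
the pipeline's statistics under a clean two-group model, not
performance on the full complexity of real bisulfite data — on real
data, method disagreement is substantially larger than these
simulations suggest, which is precisely why signature-level quality
scoring is needed.

## 6. Benchmark metrics

Confusion counts are computed over the post-filter site universe:
tp = |sig ∩ truth|, fp = |sig \ truth|, fn = |truth \ sig|, tn = the
rest; precision is undefined (None) for empty signatures rather than 0.
The label-permutation FPR permutes the group labels (multiset
preserved), reruns the full filter→test→signature pipeline, and counts
every called site as a false positive: fpr = |sig|/|universe|. The
default is a single permutation, mirroring common practice, but a
single permutation is statistically weak, so `n_perm` is configurable
and each permutation is reported as its own row. The cross-method
comparison screens each method's H-scores with Shapiro–Wilk and
compares methods with the Friedman rank test (tie-corrected, asymptotic
χ²(k−1); the exact small-sample distribution is not implemented). A
block in which every dataset ranks all methods identically (complete
ties) is reported as statistic 0, p = 1, where the textbook formula is
0/0. Zero H-scores are kept in the block: a method that returned
nothing was still evaluated.

## 7. Problem sizes and numerical choices

The shipped benchmark (`run_spikein_benchmark`, also driven by
`scripts/acceptance.py`) uses 60 spiked regions, 300 null regions and
2000 background sites per dataset (≈ 7500 sites), 16/16 samples, and
one dataset per δ in {0.1, 0.15, 0.2, 0.3} — a desk-scale design chosen
so the whole grid completes in well under a minute while leaving
several hundred to several thousand truth sites per dataset. Golden
section runs 80 iterations (bracket ≈ 10⁻¹⁷); LRT statistics are
clipped at 0 against floating-point negatives; H is clipped to [0, 1]
only against floating error. Random draws all flow through
numpy Generator objects seeded explicitly; every public simulation or
resampling function takes a seed or Generator.

## 8. Known limitations

- The beta-binomial LRT uses a moment dispersion estimate, not a joint
  MLE, and χ²(1) asymptotics; with very few replicates its p-values are
  only approximately calibrated (the suite bounds the deviation).
- DMR-level (region) scoring is out of scope; the H-score is defined
  for site-level signatures.
- Euclidean distance is the only metric currently wired through
  (rank-robustness dulls sensitivity to the choice, and a metric hook
  exists but is untested).
- Oversensitivity is possible: a signature of false positives with a
  tiny but systematic stratification effect can still score highly
  because ranking amplifies weak orderings; inspecting the unranked
  distances (the distance-matrix export) distinguishes these cases.
- The adapter trusts external tools' site identifiers; no liftover or
  coordinate harmonization is attempted.
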