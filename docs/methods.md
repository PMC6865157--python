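# Methods

This note records the statistical model behind `genolrt`, the choices made
where the design was genuinely open, and what the simulation evidence does
and does not establish.

## 1. Disease model (SCC calculus)

A complex disease occurs when any one *sufficient cause* completes; the
studied gene is a single component of one such cause, which accounts for a
proportion `y ∈ [0, 1]` of the population lifetime incidence (PLI, default
0.01). Genotype triples are ordered by disease-allele count `(dd, Dd, DD)`.
For a dominant gene the disease genotypes are `{Dd, DD}`, for a recessive
one `{DD}`. Case genotype frequencies mix as

```
case = (1 - y) * control          on normal genotypes
case = (1 - y) * control + y * control / mass    on disease genotypes,
```

where `mass` is the total control frequency of the disease genotypes — the
causal mass `y` is apportioned by the genotypes' population shares. Because
the PLI is small, control genotype frequencies are taken equal to
population frequencies (no PLI correction of controls).

The **odds ratio** is the allelic odds ratio between case and control
disease-allele frequencies. The case allele frequency is linear in `y`,
`p' = (1 - y) p + y c`, with `c` the disease-allele frequency within the
disease-genotype class (`c = 1` for recessive), which yields a closed-form
inverse `y(OR)`. For dominant genes `y ≤ 1` bounds the odds ratio at
`2 (1 - P_DD) / P_Dd - 1`; requesting more raises an infeasibility error.
Only the allelic reading reproduces both the worked value OR ≈ 1.3 at
(q = 0.3, y = 0.2) and this bound simultaneously.

**Penetrance** assumes the focal cause (probability `y·PLI/mass` for a
disease-genotype carrier) and the aggregate of all other causes
(probability `(1 - y)·PLI`) strike independently:
`pen = f + b - f·b`. At `y = 0` this reduces to the PLI, and at fixed
`y·PLI` it decreases in the disease-genotype mass — rare variants are the
high-penetrance ones.

## 2. Virtual disease variant

A candidate model is a set of variant columns assumed to damage the gene
identically. A haplotype is a disease haplotype if it carries a minor
allele at *any* member (two disease alleles on one haplotype count once),
so the members collapse into one virtual variant by a bitwise OR over
haplotypes; individual genotypes are the sum of the two haplotype
indicators. Collapsing on haplotypes (not genotypes) makes compound
heterozygotes come out with the correct genotype 2.

## 3. The genotypic likelihood-ratio test

For candidate G and virtual disease variant D, expected case genotype
frequencies follow from genotype-level LD,
`pi_a = Σ_j P(G_a D_j)/P(D_j) · P(D'_j)`, with the joint and the D-margin
estimated from the control sample and `P(D')` estimated from the case
sample's virtual-variant genotype frequencies (the test conditions on them;
no effect size is assumed, which also makes the test independent of the
dominance mode). Genotype-level conditioning — rather than allele-level LD
plus Hardy–Weinberg — carries the panel's natural random-union-of-gametes
deviations from HWE into the expectation.

The per-variant statistic is the multinomial log-likelihood ratio
`G = 2 Σ o_a log(o_a / (n π_a))` with a variance correction for the fact
that the controls are themselves a sample: `lrt_statistic` implements the
analytic form `T = G · (|Σ|/|σ|)^(1/(k-1))` (model multinomial covariance
determinant over the first k−1 categories versus the resampled one; the
correction is 1 when they agree).

**Resampling calibration.** Inside the model search the correction is
applied on the likelihood scale, as a full replay of the pipeline. If the
tested model is true, a case and a control with the same D genotype are
exchangeable — both are draws from the population conditional on that
genotype (this holds exactly in the simulation design, and approximately
for real cohorts). Each replicate therefore re-partitions every D-genotype
stratum's individuals at random into pseudo-control and pseudo-case roles
(observed per-stratum counts preserved), recomputes every candidate's
statistic on the pseudo data, maps each observed statistic onto the
chi-square(k−1) scale through its mid-rank among the resampled ones, and
takes the model-level `p_lower` as the rank of the observed total among the
resampled totals. Exchanging whole individuals preserves the LD-induced
correlation between candidate statistics, so the model-level probability is
calibrated even though the per-variant statistics are dependent; for plain
multinomial pseudo-counts the rank calibration reduces to the determinant
ratio. The chi-square behaviour of the summed statistic under the true
model is the property that pins this construction down, and is verified
directly by the test suite (Kolmogorov–Smirnov distance 0.03–0.05 across
independent panel draws).

**Sparse-data rules.** All are standard minimum-count practice and were
validated against the null calibration:

- Genotype classes with expected case count `n·π < 5` are pooled with the
  nearest retained class, so a rare variant is analysed as
  non-carrier/carrier with one degree of freedom.
- A D-homozygote stratum with fewer than 5 control individuals cannot
  support a conditional estimate and is analysed jointly with the
  heterozygote stratum.
- Candidates with fewer than 8 carriers (or non-carriers) across both
  samples are skipped: too sparse to anchor a resampling null. Candidates
  monomorphic in the control sample are likewise skipped — with no control
  carriers no LD expectation exists.
- The model's own members drop out automatically: their resampled
  statistic is degenerate at zero (the expectation reproduces the observed
  counts exactly), so they carry no information about the model's truth.
- In `lrt_statistic` (the stand-alone analytic form), a class with zero
  expected and nonzero observed count rejects the model outright rather
  than being smoothed.

**Degrees of freedom.** `total_df` is the sum of (k−1) over the candidates
actually tested; `p_lower` is the resampling rank probability, with
granularity 1/(reps + 1). The default resampling depth is `reps = 1000`
(tests use 100–200 with correspondingly coarser p-granularity).

## 4. Exhaustive search

All C(M, s) models of size s = 1, 2, … are tested in turn; a model is
accepted when `p_lower < 1 - alpha` (default α = 0.05) — i.e. its total
statistic is *not* in the upper α tail, the only reading consistent with a
Type I error of ~α. At the first size with any acceptance, the accepted
model with the smallest `p_lower` is returned (ties broken by the
lexicographically smallest index set, logged). Models whose virtual variant
is monomorphic in the controls are untestable and never accepted.
Per-model randomness is keyed on (seed, member indices), so results do not
depend on enumeration order.

## 5. Synthetic reference panel

`apoe_like_config()` emulates the LD architecture of the APOE gene region
in a large reference sequencing panel: 33 biallelic variants (tags
no1–no33) spanning minor-allele frequencies ~0.001–0.51, with the
benchmark frequencies 0.00412, 0.00592, 0.00870, 0.082, 0.149, 0.325 and
0.510 present, designated pairs at r² ≈ 0.768, 0.502, 0.446 and 0.410, and
the remaining rare alleles riding on common haplotype backgrounds (D′ = 1
with low r²) — the regime in which synthetic associations arise. LD is
encoded as explicit haplotype-class pools organized in independent blocks,
so target frequencies and r² are analytic properties of the pool and every
downstream test runs without downloads. Panels are sampled by multinomial
draws of 2N haplotypes paired at random into N individuals (default
N = 1092), which produces exactly the small HWE deviations the genotypic
test is designed around; identical seeds give identical panels.

What the fixture does **not** model: recombination and mutation (haplotype
classes are fixed), demography, genotyping error, unphased or missing
calls, and the full empirical LD matrix of any real region beyond the
designated pairs. Passing tests therefore demonstrate the method's
statistical behaviour under its own assumptions — complete, phased,
correctly typed genotypes — not robustness to data artefacts.

## 6. Case–control simulation

Controls are drawn with replacement from the panel's individuals (a
without-replacement option exists); each replicate redraws them. Case
disease-genotype counts are multinomial with the SCC case triple applied to
the virtual variant; each case is a panel individual drawn conditioned on
that genotype, so cases carry full LD-consistent phased genotypes. When a
required genotype class is absent from the panel (rare homozygotes), the
individual is constructed by pairing independently sampled disease
haplotypes, and zero-count classes of the panel's disease-genotype triple
are filled with their random-mating expectation (q² for DD) before the
mixing — otherwise no recessive model on a rare variant would be
satisfiable. Type I error is the rejection rate of the true model;
Type II the failure of the full search to return exactly the true member
set, with partial identifications (a proper subset, typically the more
frequent member) and wrong identifications (a non-member accepted) tallied
separately, each with Clopper–Pearson 95% intervals.

Default study conditions: 500 cases, 500 controls, 1000 simulations, 1000
resampling replicates. The shipped tests and the acceptance script scale
down to 30–500 simulations and 60–200 resampling replicates; the Type II
checks are therefore ordering checks (error falls with odds ratio and case
sample size; rare dominant ≤ rare recessive; partial identification
dominates two-variant failures), not precise rate estimates.

## 7. Known limitations

- The method requires phased, complete, biallelic genotypes; missing data
  are rejected, not imputed.
- Power against models whose members are in strong r² with a more frequent
  non-member is intrinsically limited: the decoy's genotype frequencies
  rise with the causal variant's and the decoy model may be accepted first.
  This failure mode is reproduced, not solved, here.
- For rare recessive models the homozygote stratum is usually collapsed
  into the carrier stratum (sparse-data rules above), which costs some
  recessive-specific resolution.
- The within-stratum exchangeability behind the resampling null is exact
  for cohorts sampled from a common population; strong unmodelled
  structure (e.g. differently ascertained cases and controls) would break
  it for real data.
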