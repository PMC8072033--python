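# Methods

This note documents the models, estimators and numerical choices behind
`notchdose`, and what the synthetic study does and does not establish.

## Differential accessibility scores

A region is a fixed 4-kb window, binned at 20 bp (B = 200 bins). Profiles
are normalised to reads per million mapped reads (RPM) using each sample's
library size; all downstream statistics operate on RPM.

For two conditions A and B with n_A, n_B ≥ 2 replicates,

    TS_dnun = (1/B) Σ_b d(b)² / (w(b) + ε),
    d(b)    = ȳ_A(b) − ȳ_B(b),
    w(b)    = s²_A(b)/n_A + s²_B(b)/n_B,

with per-bin sample means and ddof-1 variances of the RPM profiles. The
Welch-type denominator allows unequal variance across samples and
conditions. `TS_kn` applies a Nadaraya–Watson smoother (Gaussian kernel on
the bp scale, default bandwidth 150 bp to match the 150-bp display windows
conventional for cut-density tracks) to both the mean-difference curve and
the Welch variance curve before forming the same quadratic form; as the
bandwidth → 0 the two scores coincide.

**Variance floor.** With 2–3 replicates, empty bins frequently have zero
sample variance, which would make the ratio blow up. ε is set to half the
median of w(b) over bins plus an absolute floor of 1e-12. The floor is
recomputed per label assignment, so permutation statistics remain
exchangeable with the observed one.

**Sensitivity.** A Gaussian bump of SD 300 bp present in one condition only
(peak/no-peak), a 2× height change, and a 300-bp positional shift all
displace the mean-difference curve away from zero and are detected by both
scores. The smoothed score gains substantially on these smooth alternatives
because averaging ≈ bandwidth/bin neighbouring bins suppresses per-bin
Poisson noise without attenuating bumps wider than the bandwidth; it is the
default statistic of the pipeline. The unsmoothed score remains the
appropriate choice for spiky or heavily heteroscedastic signals and is
always computed and reported alongside.

## Permutation null

Replicates are exchangeable across the two conditions under the null, so
the null distribution is built by permuting replicate labels across the
pooled samples. Per region, all C(n_A+n_B, n_A) assignments are enumerated
when the count is within `max_perms` (default 10000), otherwise identity
plus Monte-Carlo draws with the add-one estimator. Ties count as ≥
(conservative); with exhaustive enumeration the identity is included, so
p > 0 always. Both scores are invariant under swapping the two group
labels, so each complementary pair of assignments is evaluated once (sample
0 pinned to the first group when group sizes are equal); tail fractions over
the full enumeration are unchanged.

With 3v3 replicates the per-region enumeration has only 10 distinct splits,
so attainable p-values are multiples of 0.1 and no per-region test can reach
p ≤ 0.05. The batch route therefore pools the non-identity permutation
statistics of all regions of a run into a common null — valid in the
simulated design because regions are tested under a shared exchangeability
null, and in the spirit of genome-wide nonparametric screens that estimate
one null from many loci. A region's p is the add-one tail fraction of its
observed score in that pool. When fewer than 10 pooled values reach the
observation, the estimate is refined with a generalized-Pareto fit to the
exceedances over the pool's 95th percentile (the standard tail
approximation for permutation p-values); this extends resolution below
1/(pool+1) — needed to survive a 500-fold Bonferroni correction — without
touching calibration at moderate α. Empirically, on 1000 all-null regions
the rejection rate at p ≤ 0.05 sits at the nominal level, and the observed
null scores are indistinguishable from the pooled permutation scores
(two-sample KS). In a mixed batch the permutations of genuinely
differential regions inflate the pool's tail slightly, making the pooled p
conservative for null regions — the safe direction for a screen.

## Multiple testing: effective number of tests

Overlapping DHS windows retest the same signal, so plain Bonferroni over
regions overcorrects. Regions are merged into single-linkage clusters of
genomic overlap; the effective number of tests is the cluster count, the
cluster p is its minimum member p, and each member receives
`p_adjusted = min(1, max(p_member, cluster_p × n_clusters))`. The outer
`max` keeps the adjustment monotone (it never decreases any region's p)
while the cluster-level call is driven by the best member. With no overlaps
this reduces exactly to Bonferroni. The adjustment is applied within each
stage pair; significance is `p_adjusted < 0.05`.

## Accessibility calls

When per-stage hotspot BEDs are available, a region is accessible iff its
midpoint falls inside a hotspot. Otherwise a threshold rule stands in for
peak calling: accessible iff the mean RPM per bin over the central 1 kb is
at least τ = 3× a per-stage background estimate, taken as the 25th
percentile of per-bin mean RPM across all regions of that stage (robust
because the large majority of windows in any batch are background at any
given stage). The source of every call is recorded.

## Expression gates

Counts are CPM-normalised per sample (no between-sample normalisation such
as TMM: none is assumed by the design, and the simplest choice is recorded
in the effective config). Genes with CPM ≥ 1 in fewer than 2 samples (the
size of the smallest replicate group) are removed. Stage-pair fold-changes
are `log2((mean CPM_a + 0.5)/(mean CPM_b + 0.5))`; the pseudocount on the
CPM scale prevents infinite fold-changes for genes silent in the control,
exactly the regime high-dose genes occupy. Gates are inclusive at the
threshold (≥ 2): low requires DN1 vs ctrl; high requires DN2b vs ctrl AND
DN2b vs DN1 (the conjunction excludes genes already induced at low dose).

## Classification

Predicates are evaluated high → low_I → low_II on each (region, gene) pair;
the first satisfied class wins (high cannot co-occur with the low classes
at one region since it requires DN1 inaccessibility, but the order is fixed
for safety). "Increased in DN1" (low_II) is operationalised as a
significant LSK-vs-DN1 test AND a positive DN1 − LSK mean-RPM difference.
DN2a evidence is carried in the outputs but used by no predicate — the
high-dose criterion is specific to DN2b. Genes removed by the CPM filter
fail both gates. Per-class gene lists are deduplicated; a gene hit by
several DHSs can appear in more than one class, and the summary reports the
pairwise overlaps and the unique low-dose union.

## Promoters and CpG

Promoters are strand-independent 2-kb windows [TSS − 1000, TSS + 1000);
multi-TSS genes are expected to be collapsed upstream to the 5′-most TSS of
their protein-coding transcripts (a stated choice — gene-level promoter
sets do not define a canonical TSS). DHS-to-promoter assignment is by
midpoint containment, half-open at the right edge.

Observed CpG is the count of CG dinucleotides on the forward strand
(strand-invariant, since CG is its own reverse complement); expected CpG is
n_C · n_G / L. N bases count toward L but toward no base count, and an N
breaks the dinucleotides it touches. Sequences lacking C or G have
undefined ratio and are excluded from group means and tests with a warning
rather than coerced to 0, which would bias group means downward. The group
comparison is a two-sided Mann–Whitney U (one-sided available via flag):
exact enumeration when n_a + n_b ≤ 16 without ties, otherwise the normal
approximation with tie and continuity corrections.

## The synthetic study

The generator emulates the study design, not raw sequencing: five
conditions (LSK, DN1, DN2a, DN2b, no-Notch control), 3 replicates per
stage (the experimental design used 2–3 for DNase and 2–4 for RNA; 3 is the
fixture default for both), and per-bin Poisson cut counts — the analysis
consumes binned profiles, so read-level simulation would add nothing
testable. An accessible stage adds one centred Gaussian bump (apex 5 extra
cuts/bin = 10× the 0.5 cuts/bin background at the 1e7-read reference depth,
SD 300 bp); the planted classes express the design's contrasts:

| class        | LSK | DN1 | DN2a | DN2b | ctrl | expression (log₂ vs ctrl)     |
|--------------|-----|-----|------|------|------|-------------------------------|
| null         | 0   | 0   | 0    | 0    | 0    | 0 everywhere                  |
| low_I        | 0   | 1   | 1    | 1    | 0    | +3 from DN1 on                |
| low_II       | 0.4 | 1   | 1    | 1    | 0.4  | +3 from DN1 on                |
| high         | 0   | 0   | 0.5  | 1    | 0    | +3 at DN2b (+1.5 DN2a)        |
| height_only  | 1   | 2   | 2    | 2    | 1    | 0                             |
| shift_only   | 1 (centre shifted +300 bp after LSK) | | | | | 0          |

(numbers are apex multipliers of the peak amplitude). RNA counts are
gamma-Poisson with variance μ + 0.05 μ²; dose-responsive genes start from a
low baseline (20–50 counts) and nulls at 100. A backdrop of 2000 null
background genes emulates the rest of the transcriptome so that planted
fold-changes survive CPM renormalisation with only a small composition
bias. Promoter sequences come from a first-order dinucleotide Markov chain
constructed so that its stationary distribution matches the requested GC
content *and* its stationary CG dinucleotide frequency equals the target
observed/expected ratio exactly (infeasible pairs raise a configuration
error); class targets default to 0.43 (high), 0.60 (low) and 0.85
(backdrop), echoing the reported group means for real dose classes. One
master seed feeds deterministic child streams per component; fixtures are
byte-identical under a fixed seed.

What passing tests show: the statistics are calibrated and powerful under
the planted model, the classification rules recover the planted structure,
and the CpG machinery is exact. What they do not show: robustness to
mappability artefacts, replicate-specific digestion biases, copy-number
variation, overlapping and multi-peak DHS landscapes, or annotation errors
in real TSS catalogues — none of which the generator emulates.

## Problem sizes and defaults

The default study uses 500 regions (20 per dose class, 440 nulls), chosen
as the smallest design in which the Bonferroni-adjusted screen is
non-trivial (raw p < 1e-4 required) while a full run stays in the
low-seconds range on one core. Calibration checks use 1000 null regions;
power checks 500 regions per alternative. Defaults throughout: α = 0.05 on
the adjusted p, log₂FC threshold 2, CPM filter ≥ 1 in ≥ 2 samples,
pseudocount 0.5, 2-kb promoter window, 150-bp bandwidth, 20-bp bins,
max_perms 10000, statistic `kn` for the pipeline (both always reported).
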