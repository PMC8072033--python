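# notchdose

Discovery of Notch dose-responsive promoters from stage-resolved DNase
accessibility and RNA expression profiles.

## The problem

Early T cell development proceeds through a series of CD4⁻CD8⁻
double-negative stages (LSK → DN1 → DN2a → DN2b) that require increasing
Notch signal strength; ex vivo, hematopoietic stem/progenitor (LSK) cells
cultured on immobilized Delta1 ligand recapitulate this progression, with a
no-ligand culture serving as the control. Genes essential for T-lineage
commitment respond only to *high* Notch dose, and their promoters tend to be
DNA-inaccessible in the ground state and depleted of CpG dinucleotides
(low-CpG-content, LCG, promoters).

`notchdose` implements the inference chain that identifies such promoters
from genomics data alone:

1. **Spatial differential accessibility.** Each 4-kb DNase I hypersensitive
   site (DHS) window is summarised as binned (20 bp), reads-per-million
   normalised cut-count profiles per replicate. Two nonparametric scores
   compare the spatial profiles of two stages:

   - `TS_dnun = (1/B) Σ_b (ȳ_A(b) − ȳ_B(b))² / (s²_A(b)/n_A + s²_B(b)/n_B + ε)` —
     an unsmoothed Welch-standardised integrated squared difference, robust
     to heteroscedastic replicate noise;
   - `TS_kn` — the same quadratic form on Nadaraya–Watson kernel-smoothed
     (Gaussian, 150-bp bandwidth) condition means and variance curves.

   Both respond to all three alternatives of interest: peak/no-peak, peak
   height change, and peak position shift. Significance comes from
   replicate-label permutation; for small replicate groups, permutation
   statistics are pooled across the regions of a run into a common null
   (with a generalized-Pareto tail fit for extreme observations), and
   p-values are Bonferroni-adjusted on the *effective* number of tests —
   the number of single-linkage clusters of genomically overlapping regions.

2. **Dose-response classification.** A promoter-overlapping DHS (midpoint
   within TSS ± 1 kb) is classified on accessibility calls, adjusted
   p-values, and expression gates (log₂ fold-changes of mean CPM):
   - *low-dose-responsive I*: inaccessible in LSK, de-novo accessible in
     DN1, significant LSK-vs-DN1 change, log₂FC(DN1/ctrl) ≥ 2;
   - *low-dose-responsive II*: accessible in LSK, significantly increased
     in DN1, log₂FC(DN1/ctrl) ≥ 2;
   - *high-dose-dependent*: inaccessible in LSK and DN1, de-novo accessible
     in DN2b, significant DN1-vs-DN2b change, log₂FC(DN2b/ctrl) ≥ 2 **and**
     log₂FC(DN2b/DN1) ≥ 2.

3. **Promoter CpG content.** For each 2-kb promoter, the observed/expected
   CpG ratio `obs(CG) / (n_C · n_G / L)`; dose classes are compared with a
   Mann–Whitney U test (exact for small groups without ties).

Because re-processing the original sequencing data is a cluster-scale job,
the package ships a first-class synthetic-data generator that emulates the
study design — five conditions with replicated Poisson cut-count profiles
over 4-kb windows, negative-binomial expression with planted log₂
fold-changes, and Markov-chain promoter sequences with prescribed CpG
observed/expected ratios — so that every stage is testable against known
ground truth.

## Worked example

```python
from notchdose.pipeline import PipelineConfig, run_pipeline

bundle = run_pipeline(PipelineConfig(seed=1), "run1")
print(bundle["report"]["class_sizes"])
print(bundle["report"]["cpg_comparison"])
```

prints

```
{'low_I': 20, 'low_II': 20, 'high': 20}
{'n_high': 20, 'n_low': 40, 'mean_high': 0.4096786529922089,
 'mean_low': 0.5934353952140592, 'u_statistic': 6.0,
 'p_value': 6.804323107035198e-10, 'method': 'asymptotic'}
```

The default study simulates 500 DHS/gene pairs (20 planted per dose class,
440 nulls). All 60 planted genes are recovered into their classes, and the
high-dose promoters' mean CpG observed/expected ratio (≈ 0.41, planted
target 0.43) is decisively lower than the low-dose group's (≈ 0.59, target
0.60). `run1/` contains every intermediate as TSV/JSON plus a manifest with
checksums; reruns with the same seed are byte-identical.

The same pipeline is scriptable from the shell:

```bash
notchdose simulate --seed 1 --out fixtures/
notchdose run-all --seed 1 --fixtures fixtures/ --out run1/
notchdose report --run-dir run1/
```

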