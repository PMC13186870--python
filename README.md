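# trioknock

Knockoff-calibrated fine mapping of disease-associated variants in
parent–offspring trios.

Family-based association scans of a candidate region face a specific
obstacle: linkage disequilibrium (LD) spreads a causal signal over many
nearby variants, and classical transmission tests (TDT/FBAT) cannot tell
a driver from its correlated passengers. `trioknock` addresses this with
*knockoff genotypes* — synthetic copies of the phased haplotypes that
preserve the LD structure but are conditionally independent of the
phenotype — used as negative controls for window selection with false
discovery rate (FDR) control. It is aimed at statistical geneticists
working with ascertained trio cohorts (an affected offspring, or an
affected parent with spouse and child) in isolated populations, where
cohorts are small and LD blocks are long.

The pipeline:

- **Simulation** of phased trio cohorts with blockwise LD, an additive
  disease model and affected-proband ascertainment, with full ground
  truth (`build_haplotype_pool`, `simulate_trios`);
- **IO/QC**: phased VCF + PED reading and writing, Mendelian-error
  detection, exact Hardy–Weinberg test, MAF/missingness filters
  (`read_phased_vcf`, `apply_qc`);
- **LD blocks** from haplotype r² (`ld_r2_matrix`, `partition_blocks`);
- **Trio-aware knockoffs**: transmitted parental haplotypes are inferred
  per LD block, parental haplotypes are permuted within blocks
  conditional on their local context, and knockoff offspring are derived
  from knockoff parents and the original transmissions
  (`infer_transmission`, `generate_knockoff_cohorts`);
- **Multi-resolution scan**: overlapping windows of 500 bp – 20 kb get a
  LASSO-weighted burden FBAT score
  Z = Σᵢ(yᵢ−μ)(Bᵢ−E[Bᵢ|parents]) / √Σᵢ(yᵢ−μ)²Var[Bᵢ|parents],
  the same score Z* on each of M = 10 knockoff copies, the ratio
  W = |Z|/median|Z*|, and κ/τ knockoff selection at a target FDR
  (`scan_region`);
- **Effect sizes** by 1:3 case/pseudo-control conditional logistic
  regression on trios with a heterozygous parent (`estimate_effects`);
- **Analytic TDT power** over a MAF × odds-ratio grid with an exact
  convolution of the ascertained transmission distribution, plus a
  simulation oracle (`tdt_power`, `tdt_power_simulated`).

See `docs/methods.md` for the statistical details and design choices.

## Worked example

Simulate a study-sized cohort (97 trios with an affected child plus 60
with an affected parent) over 300 SNPs of a chr17-like region, plant one
causal variant with per-allele odds ratio 3 at MAF 0.2, and scan:

```python
import math
import numpy as np
import trioknock as tk

cfg = tk.PoolConfig(n_founders=300, n_variants=300,
                    region_start=30_820_506,
                    region_end=30_820_506 + 300 * 656, maf_min=0.01)
pool = tk.build_haplotype_pool(cfg, seed=11)
causal = int(np.argmin(np.abs(pool.maf() - 0.2)))   # pos 30,848,284
model = tk.DiseaseModel(causal_effects={causal: math.log(3.0)})
cohort, truth = tk.study_cohort(pool, model, seed=12)

res = tk.scan_region(cohort, sizes=(1000, 2000, 5000), M=10,
                     q_target=0.10, seed=13)
print(res.sort_values("p_burden").head(3)[
    ["chrom", "start", "end", "n", "Dir", "W", "Z", "p_burden"]])
```

The top-ranked windows (by burden p-value) are:

```
chrom    start      end   n  Dir     W      Z  p_burden
   17 30847602 30849601  10    1 5.845  2.929    0.0034
   17 30911102 30912101   1    1 3.248  2.774  0.005545
   17 30848102 30849101   5    1 3.323   2.57   0.01016
```

The leading window spans the planted causal variant: `Dir = +1` marks a
risk effect, `Z = 2.93` is the burden FBAT score (p.burden = 0.0034, the
two-sided normal tail), `n = 10` variants carry nonzero burden weight,
and `W = 5.8` says the observed score is nearly six times the median of
its ten knockoff scores — signal well beyond what LD structure alone
produces. The per-allele effect at the causal variant from the
conditional-logistic model:

```python
print(tk.estimate_effects(cohort, [pool.variants["id"].iloc[causal]]))
#    variant allele  n_informative    OR  ci_low  ci_high       p status
#   var00050    alt            106  2.73    1.67     4.45  5.7e-05     ok
```

106 trios had a heterozygous parent; the estimated odds ratio 2.73
(95% CI 1.67–4.45) recovers the planted effect of 3.

The design's analytic TDT power for 142 trios at α = 0.05
(`tk.power_grid(142, 0.05)`):

```
        OR=1.2    OR=1.9    OR=3.0
MAF
0.05  0.079790  0.452003  0.924132
0.10  0.099795  0.675109  0.989589
0.20  0.137718  0.832444  0.997867
0.30  0.157628  0.865000  0.997671
```

A `trioknock` command-line interface wraps the same steps
(`trioknock simulate | qc | blocks | scan | estimate | power`; see
`trioknock --help`).

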