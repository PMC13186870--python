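# Methods

`trioknock` implements a knockoff-calibrated fine-mapping pipeline for
phased parent-offspring trio cohorts in a candidate region. This note
documents the models, the estimators, the synthetic-data generator, the
numerical choices, and the known limitations. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The analysis pipeline

1. **Input / QC** (`cohort`, `qc`). Phased VCF + 6-column PED are loaded
   into a `PhasedCohort` (two `int8` haplotype rows per individual, `-1`
   missing). QC order: Mendelian-error policy (default: blank the trio's
   genotypes at the offending variant), then per-variant missing rate
   (default max 0.01), founder minor allele frequency (default min 0.01),
   and the founder Hardy–Weinberg exact test (default p ≥ 1e-6). Allele
   frequency and HWE use founders only, because transmitted chromosomes
   are duplicated between parents and children. The HWE test is the exact
   conditional test: given the allele counts, heterozygote counts of the
   same parity are weighted by n!·2^het / (hom_a!·het!·hom_b!), and the
   p-value sums the configurations no more probable than the observed one.

2. **LD blocks** (`ld`). r² is the squared Pearson correlation of binary
   haplotype columns (identical to the haplotype-frequency formula);
   monomorphic columns give NaN, never 0. `partition_blocks` is a greedy
   left-to-right scan: a variant joins the current block when its r² with
   *any* current member reaches the threshold (default 0.5) and the block
   span stays under 100 kb. Because pairwise-r² chains are uninformative
   through rare variants, the pipeline default (`scaffold_partition`)
   computes the greedy partition on variants with MAF ≥ 0.05 — the same
   default MAF filter PLINK applies in block detection — and assigns every
   other variant to the scaffold block covering it (boundaries at bp
   midpoints). Raising the threshold never decreases the number of blocks.

3. **Transmission inference** (`transmission`). Per trio, the two
   offspring haplotypes are attributed to the parents by the whole-trio
   assignment minimising total block mismatches; per (parent, block) the
   transmitted haplotype is the one matching the attributed offspring
   block more closely. Ties (exactly the homozygous-block case on clean
   data) are broken to haplotype 1 and flagged; the flag is
   distribution-neutral because the two haplotypes are then identical.
   Block-level inference keeps recombinant offspring consistent.

4. **Knockoffs** (`knockoffs`). For each of M = 10 copies, blocks are
   processed left to right; rows (parental haplotypes of complete trios)
   are stratified by the pair (previous block's haplotype in the knockoff
   under construction, next block's haplotype in the original), strata
   under 10 rows are merged with the stratum nearest in frequency, and
   block haplotypes are permuted within strata. This conserves per-block
   allele counts exactly and preserves within-block LD while severing the
   content–phenotype link. Knockoff offspring are *derived*: per block
   they copy the originally transmitted haplotype index from the knockoff
   parent, so knockoff trios are Mendelian-consistent by construction.
   Each copy uses an independent stream spawned from the master seed.
   A `context_blocks` option widens the conditioning window; the default
   (1) is also the practical optimum here, because exact haplotype labels
   over multi-block contexts become unique per row and the subsequent
   stratum merging destroys the conditioning they were meant to provide.

5. **Window scan** (`scan`). Windows of 500–20,000 bp tile the region
   with half-window steps. Burden weights solve
   0.5‖y − Xb‖² + λ‖b‖₁ with λ from 5-fold CV (fixed fold seed);
   all-zero solutions (and constant phenotypes) fall back to equal weights
   1/√p with a flag. **The design matrix X is the between-family
   component E[offspring dosage | parents] = mean parental dosage, not
   the offspring dosage itself.** The FBAT scores the within-family
   (transmission) component, which is independent of the between-family
   component conditional on parents; weights fitted on the latter
   therefore cannot absorb the transmission noise being tested, and the
   original/knockoff comparison stays a pure genotype swap. (Fitting on
   offspring dosages, available as `weight_source="offspring"`, reuses
   the tested transmissions and measurably inflates the null — this is
   why it is not the default.) Under ascertainment the between-family
   component still carries real signal, so the weights are informative
   where it matters.

   The score is Z = U/√V with U = Σᵢ (yᵢ − μ)(Bᵢ − E[Bᵢ]),
   V = Σᵢ (yᵢ − μ)² Var[Bᵢ], burden Bᵢ = Σⱼ bⱼ xᵢⱼ, and E/Var computed
   exactly from the phased parents (each parent transmits either window
   haplotype with probability ½, independently). yᵢ is the offspring
   phenotype; μ defaults to the cohort offspring prevalence, so affected
   type-2 parents inform the scan only through ascertainment. Complete
   trios only; V = 0 yields an undefined (NaN) score, never Z = 0.
   Trio-variant entries with any missing member contribute nothing.
   Z is invariant to positive rescaling of the weights.

6. **W and selection.** W = |Z| / median_m |Z*_m| (undefined copies are
   dropped; W is NaN if the median is 0). p_burden = 2(1 − Φ(|Z|)).
   Selection uses the multiple-knockoff filter: per window,
   κ = argmax over (|Z|, |Z*₁..M|) and τ = max − median(rest); only
   κ = 0 windows are selectable, at the smallest τ threshold where the
   estimated FDR (1 + #knockoff wins above τ)/M / #original wins above τ
   drops to the target. The +1 offset is what carries the finite-sample
   guarantee; its practical consequence is that a lone discovery cannot
   have q below 1/M (0.1 at M = 10). The per-window `q` column is the
   smallest target at which that window would be selected.

7. **Effect sizes** (`effects`). Per variant, complete trios with an
   affected offspring and at least one heterozygous parent form 1:3
   matched sets (case = offspring genotype; pseudo-controls = the three
   other genotypes constructible from the parental alleles). The
   conditional logistic likelihood is maximised by Newton's method
   (statsmodels `ConditionalLogit`); Wald 95% CI and p-value are
   reported. One-sided transmission patterns are reported as
   `separated` with an infinite (or zero) OR instead of an optimiser
   failure. Relabelling ref/alt inverts the OR exactly; with a single
   het parent per trio the MLE reduces to the classic
   transmitted/untransmitted ratio.

8. **Power** (`power`). The allelic TDT rejects when (b−c)²/(b+c)
   exceeds the χ²₁ critical value. The conditional law of parental mating
   types and transmissions given an affected offspring uses HWE parental
   frequencies and genotype relative risks under the rare-disease
   approximation. The *additive* model is parameterised as relative risks
   1 : OR : 2·OR − 1 — the convention of standard trio power
   calculators — with 1 : OR : OR² available as
   `model="multiplicative"`; this choice is the main approximation risk
   against externally tabulated values, and the multiplicative
   alternative shifts the medium-effect cells by up to ~9 points at
   medium effects. `method="exact"` (default) convolves the per-trio
   (b, c) distribution to the exact rejection probability of the discrete
   statistic; `method="ncx2"` is the classical noncentral-χ² shortcut with
   ncp = 2nh(2τ−1)². Two consequences of exactness worth knowing: the
   size at OR = 1 is slightly *below* α (discreteness), and power can dip
   by a few 10⁻⁴ between adjacent MAFs where it saturates near 1. The
   simulation oracle draws ascertained trios by rejection; under the
   relative-risk model the accepted-trio distribution is invariant to the
   baseline risk (it cancels in the conditioning), so the oracle uses a
   baseline of 0.05 purely to keep the rejection rate moderate.

## The synthetic cohort generator

The generator emulates the study conditions: 97 type-1 trios (affected
offspring proband) plus 60 type-2 trios (affected parent proband with
spouse and child); ~2,534 SNPs between 30,820,506 and 32,483,270 bp of
chr17 with blockwise LD; a MAF spectrum log-uniform on [0.01, 0.5]; an
additive-logistic disease model with baseline prevalence 0.0033
(multiple-sclerosis prevalence in high-risk genetic isolates); and
rejection-sampling
ascertainment capped at 10,000 redraws per trio.

Founder haplotypes are mosaics of K = 12 ancestral haplotypes. Ancestral
blocks (geometric lengths, mean 20 variants) partition the ancestrals
into ≤ 4 groups; within a block, carrier sets are prefixes of a random
group order, so alleles sit on nested backgrounds (|D′| = 1) and — since
common variants cluster on a few per-block anchor frequencies — form the
tight runs of near-identical columns seen in real LD blocks. Mosaic
switches occur with probability 0.002 per adjacent-variant interval,
boosted 250-fold at block boundaries (recombination hotspots), so LD is
strong within blocks and decays to background within tens of kilobases
instead of persisting region-wide. Targets below what the panel can
express are realised by thinning carriers at the founder level; realised
MAFs outside the configured bounds are redrawn (frequency and carriers),
up to 100 attempts. In the two-ancestral, zero-recombination limit every
founder equals one ancestral haplotype and all polymorphic pairs have
r² = 1 exactly (with thinning disabled).

Offspring are formed by Mendelian transmission with per-interval
recombination (default: the pool's switch probability); parents are
random founder haplotype pairs redrawn whole-trio until the proband is
affected. The `TruthRecord` stores the founder rows and the transmitted
haplotype index at every variant, so replaying the seed reproduces the
cohort bit-exactly and downstream inference can be checked entry by entry.

What the generator does *not* emulate: imputation error and dosage
uncertainty (hard phased calls only), population stratification, phasing
switch errors, de-novo mutation, and coalescent-exact allele-frequency
spectra. Passing tests on this generator therefore demonstrate the
pipeline's statistical validity under clean phased data with
block-structured LD, not robustness to upstream data artefacts.

## Validity, resolution, and the FDR experiment

On a null study-shaped cohort the FBAT Z is standard normal across
windows, the rank of |Z| among (|Z|, |Z*₁..₁₀|) is uniform, and the
median W is near 1 — these are the exchangeability properties that
justify the filter, and the acceptance suite recomputes them.

Block-permutation knockoffs protect hypotheses of the form "this
window's content carries no association beyond its conditioning
context". Windows in LD with a causal variant are *connected nulls*:
they carry genuine marginal transmission disequilibrium, the quantity
the FBAT measures, and no method of this family can (or should) screen
them out at window resolution. The FDR experiment therefore labels a
selected window a false discovery only when it is in approximate linkage
equilibrium (max r² < 0.05) with every causal variant — the locus-level
evaluation convention of the knockoff fine-mapping literature. Under a
strict "contains a causal variant" labelling the same scans show a large
apparent FDP at q = 0.10; that is the resolution limit of windowed
fine-mapping under LD, not an error-rate failure, and readers comparing
methods should be aware of the distinction.

## Problem sizes and numerical choices

The calibration and FDR studies run at deliberately moderate scale,
chosen as the smallest sizes at which the asymptotic approximations are
visibly at work: 500 SNPs / 965 windows for the null calibration; 100
replicate scans of 200 SNPs (~97 windows of 2 kb, 4 causal loci at
per-allele OR 3) for FDR control; 200 replicates of 750 trios for
effect-size recovery; 2,000 replicates per cell for the power bracket.
Other numerical conventions: λ by 5-fold CV over a 30-point path with a
fixed fold shuffle seed; argmax ties in the κ statistic favour the
original (continuous scores make this a null event); knockoff copy seeds
are spawned from the master seed; per-SNP TDT calibration is tested on
unlinked SNPs because KS p-values assume independent draws; the KS-based
calibration of HWE p-values uses the DKW band in the super-uniform
direction only, as exact conditional tests are conservative.

## Known limitations

- Duos (single-parent trios) are excluded from the FBAT: the conditional
  transmission law requires both parents. They are generated, QC'd and
  counted, but contribute no score.
- The conditioning context of the knockoff construction is one block on
  each side. Haplotypes are latent-ancestry processes, not observable
  Markov chains, so conditioning is approximate; the residual effect is
  absorbed into the locus-level reading of discoveries discussed above.
- The additive power parameterisation is a convention choice; agreement
  with externally tabulated values should be expected to about one
  percentage point, not machine precision.
- Multi-allelic sites, X-linked inheritance, covariates and imputation
  dosages are out of scope.
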