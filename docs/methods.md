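# Methods

This note documents the models behind popdrift, the defaults that matter,
what the synthetic generators do and do not emulate, and the numerical
choices made where the design was genuinely open.

## Genotype panels and merging

A panel is a samples × variants matrix of alt-allele dosages {0, 1, 2} with
a dedicated missing sentinel; every downstream statistic uses
pairwise-complete observations. Coordinates are 1-based (VCF/bim
convention). Merging takes the variant intersection keyed by
(chromosome, position). Allele pairs reconcile by exact match or by ref/alt
swap with the dosage flipped d → 2−d; strand-ambiguous A/T and C/G sites
are kept only on exact match, and everything else is dropped and counted.
Cohort assemblies rarely document their strand policy, so the conservative
drop is the default here. Genetic positions come from linear interpolation
in a (chrom, bp, cM) map; outside the map range the boundary cM value is
used (clamping) rather than linear extension, which avoids negative or
runaway genetic positions.

## QC statistics

**LD pruning** slides a 50-SNP window in steps of 5 within each chromosome.
While any pair in the window has dosage-r² > 0.5, the most correlated pair
is resolved by removing its lower-MAF member (ties: the later position).
Genotype (dosage) correlation is used rather than EM haplotype frequencies,
keeping the module phase-free; this matches the behavior class of standard
pruning tools.

**Inbreeding** is the method-of-moments excess homozygosity
raw_F = (O_hom − E_hom)/(L − E_hom) per sample, with
E_hom = Σ (1 − 2p(1−p)·2n/(2n−1)) over the sample's non-missing sites. The
2n/(2n−1) factor corrects the small-sample bias of p̂(1−p̂); without it the
estimator is biased by about −1/(2n), which at cohort sizes of tens to
hundreds would hollow out the F ≥ 0.0156 (second-cousin-offspring)
threshold. Negative values are truncated to zero, as sampling noise.

**Kinship** is the KING-robust within-pair estimator
φ = (N_both_het − 2·N_opposite_hom)/(N_het_i + N_het_j) over
pairwise-complete sites; duplicates give exactly 0.5 and φ > 0.0884 flags
second-degree or closer. Pairs with a zero denominator are flagged and
treated as unrelated.

**Filter order** is inbreeding → kinship → PCA outliers, each using the
original panel's frequencies (no iterative re-estimation). In a flagged
pair the member with more missing calls is dropped (ties: the later sample
in panel order); samples from exempt populations are never removed. Both
thresholds are only meaningful when their sampling noise sits well below
them: the SD of F̂ is roughly √(1.5/L), so L must be in the tens of
thousands of effectively independent markers — genome-scale array data, not
a 50 cM toy panel. The test suite therefore exercises threshold semantics
on independent-marker panels and relaxes the thresholds in small end-to-end
fixtures.

## PCA

Dosages are normalized to (d − 2p)/√(2p(1−p)); missing entries contribute 0
after centering (mean imputation) and monomorphic variants are dropped. The
decomposition is an SVD of the normalized matrix; explained fractions are
eigenvalues of the sample covariance over its full trace. Outlier removal
iterates up to 5 rounds, flagging samples more than 6 SD out on any of the
top 10 components and recomputing the PCA after each round — the defaults of
the standard eigenanalysis tooling. Note a lone outlier among n samples can
reach at most z ≈ √n on its own component (it inflates the SD it is judged
against), so the 6-SD rule needs n well above 36 to fire at all.

## F-statistics

Both FST estimators accumulate per-site numerators and denominators and
divide the sums (ratio of averages) — never averaging per-site ratios.
Weir–Cockerham (1984) variance components are the default; the Hudson
estimator (with 1/(n_alleles − 1) sampling corrections) is available via
`estimator="hudson"`. Sites need ≥ 2 genotyped samples per population and
must be polymorphic across the pooled pair. Small negative estimates are
reported unclipped, with a clipped-to-zero companion used for divergence
times.

Outgroup f3(O; A, B) is the mean over usable sites of (o − a)(o − b) on
population frequencies — the shared-drift form used for ranking source
populations. The heterozygosity finite-sample correction
(− h_O/(2n_O) per site) is available via a flag but off by default, since
ranking is unchanged by it. Standard errors come from a weighted
delete-one-block jackknife (Busing-style weighting by block variant
counts), with blocks cut every 5 cM of genetic position, or 50 equal-count
blocks when no map is attached.

## LD decay → Ne → divergence times

SNP pairs are binned by genetic distance into overlapping categories with
starts every 0.001 cM from 0.005 to 0.25 cM and width 0.005 cM. That grid
has 246 starts; descriptions of this scheme sometimes round the count to
250. The width (the grid is described as "overlapping" without one) is set
to five steps and is configurable. A pair contributes its dosage-r² to
every bin containing its distance.

Each bin mean is corrected for finite sample size (r² − 1/n; bins at or
below the noise floor are excluded) and inverted through
Ne = (1/r² − 2)/(4c), with c the bin midpoint in Morgans — the Sved-type
relation E[r²] ≈ 1/(2 + 4Nc) + 1/n. A bin at distance c reflects drift
about t = 1/(2c) generations ago, so the bins trace an Ne trajectory; the
literal uncorrected formula is available with `correct=False`. r² > 0.5
would give negative Ne and is reported as 0 and excluded from summaries.
The long-term Ne is the harmonic mean over positive trajectory points, the
quantity that governs cumulative drift. 95% CIs propagate a
delete-one-block jackknife over SNP pairs (20 contiguous genomic blocks)
through the correction, the inversion, and the harmonic mean.

Two properties of this estimator matter for interpretation. First, it
presumes common variants: rare alleles carry almost no r², and on an
unascertained sequencing panel the all-sites mean r² can overstate Ne by an
order of magnitude (verified against coalescent simulations). SNP-array
panels are ascertained toward common variants, and the package's generators
emit MAF ≥ 0.05 sites for the same reason. Second, even at equilibrium the
inversion runs high by roughly a factor of two on MAF-filtered panels; the
recovery tests are calibrated accordingly (factor-2 band for the package's
own generator, order-of-magnitude for the independent coalescent oracle).

Divergence time between two populations uses the pure-drift relation
T = ln(1 − FST)/ln(1 − 1/(2Ne)) generations, converted to years at 25
years/generation. The pair Ne is the harmonic mean of the two populations'
long-term Ne — the natural symmetric choice where a single shared Ne is
assumed. Negative FST is clipped to zero before the logarithm; FST ≥ 1 is
an error. The relation inverts exactly: composing it with
FST = 1 − (1 − 1/(2Ne))^T returns the input to floating-point accuracy.

## UPGMA tree

Average-linkage agglomeration of the divergence-time matrix (in
generations): merge height is half the pairwise distance, cluster-to-cluster
distances are size-weighted averages, so the result is ultrametric by
construction and node heights read as times. Ties resolve to the pair whose
smallest member label sorts first, and Newick children are ordered by
smallest leaf label, making the serialization byte-deterministic. Years
output multiplies branch lengths by the generation time.

## Synthetic data

All generators are bit-reproducible under a fixed seed.

**Balding–Nichols** draws ancestral frequencies Uniform(0.05, 0.95),
per-population frequencies Beta(p(1−F)/F, (1−p)(1−F)/F) so E[FST] ≈ F, and
genotypes Binomial(2, p). It emulates controlled differentiation with
independent markers — appropriate for PCA/FST/f3/kinship tests, silent on
LD.

**Forward Wright–Fisher** simulates N diploids (default 100) for 10N
generations across 10 chromosomes jointly spanning 50 cM, with Poisson
crossovers on a uniform map, independent assortment, and recurrent
symmetric mutation at 5×10⁻⁵ per site per transmitted gamete over a 6,000
site grid. Several chromosomes are essential at this scale: a single short
chromosome is dominated by one realized genealogy and its LD varies wildly
between runs, whereas ten independent genealogies average to array-like
stability. The emitted panel keeps segregating sites at MAF ≥ 0.05,
mirroring array ascertainment. The burn-in (10N) comfortably exceeds the
O(4N) relaxation time of both frequencies and LD.

**Split-pair** evolves ancestral frequencies through T independent rounds of
Binomial(2Ne) drift in each daughter and samples genotypes from the final
frequencies — the model under which FST = 1 − (1 − 1/(2Ne))^T is exact in
expectation. Drift acts on frequencies, not individuals: exact for the
FST/T relation and orders of magnitude faster; linkage is deliberately
absent, so LD-based stages should use the Wright–Fisher generator instead.

What passing tests show — and what they do not: recovery under these
generators demonstrates estimator correctness under the stated models
(drift, random mating, no selection, uniform maps, clean population
labels). Real cohorts add ascertainment quirks, batch effects between
merged datasets, non-equilibrium demography, and admixture, none of which
the generators emulate.

## Pipeline

Stages run io → QC → PCA → FST/f3 → Ne → divergence → tree. LD pruning
feeds only the PCA stage. Relatedness statistics run on the full marker set
(their noise floor scales as 1/√L), and the Ne stage uses the unpruned,
sample-filtered panel — pruning at r² > 0.5 would remove the very signal the
LD-decay method measures. FST is likewise computed on the unpruned panel.
One top-level seed is recorded in the manifest along with every threshold
and artifact checksum; reruns with the same config are byte-identical
except for the manifest timestamp. Warnings (dropped variants, skipped
records, invalid bins) are counted and logged, never silent.

## Problem sizes in the test suite

Desk-scale runs use 20,000 markers and 100 samples per population for
frequency-based recovery (FST to ±0.01, split time to ±25%), a 10 × 5 cM
genome for LD-based recovery, and 300,000 independent markers where the
inbreeding threshold's noise floor must sit ~2σ below a planted F = 0.02.
The acceptance script regenerates all of these from a single seed in under
a minute.

## Known limitations

- No phasing, imputation, multi-allelic sites, sex chromosomes, or liftover.
- The divergence-time relation assumes a clean split with no migration or
  admixture afterwards; gene flow biases T downward.
- The Ne trajectory maps each distance bin to one time 1/(2c); it is a
  smoothed summary, not a deconvolution, and adjacent bins share pairs by
  construction.
- f4/D statistics, qpAdm-style admixture modeling, and IBD-segment methods
  are out of scope.
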