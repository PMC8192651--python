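# Methods

This note documents the statistical models behind `ricepop`, the
defaults that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices a maintainer should know about.

## Genotype container and coordinates

All stages operate on a samples × sites matrix of ALT-allele dosages
{0, 1, 2} with a reserved missing sentinel (−1; never 0, which is a
legal dosage). Sites are biallelic SNPs; multi-allelic and non-SNP VCF
records are dropped (not split) and counted, so downstream site counts
stay interpretable. VCF and GFF3 coordinates are 1-based and inclusive
at both ends throughout — QTL intervals, gene spans and π windows all
share that convention, which removes a whole class of off-by-one
errors. Genotypes are treated as unphased everywhere: 0/1 and 1/0 both
code dosage 1.

## Synthetic panels

The generator (`ricepop.synthpop`) emulates the statistical structure
of an inbred crop diversity panel in four layers:

1. **Divergence** — per site an ancestral frequency
   p₀ ~ Uniform(0.05, 0.95); each of K populations draws its frequency
   from a Beta with mean p₀ and variance Fst·p₀(1 − p₀)
   (Balding–Nichols), clamped to [10⁻⁴, 1 − 10⁻⁴].
2. **Admixture** — individual ancestry rows q_i ~ Dirichlet(α, …, α).
   Small α (default 0.2) makes most individuals nearly pure, as in
   landrace panels.
3. **Inbreeding** — at each locus, with probability F the two gametes
   are identical by descent (dosage 2 with probability
   f_il = Σ_k q_ik p_kl, else 0); otherwise dosage ~ Binomial(2, f_il).
   This genotype-level IBD indicator reproduces exactly the moment the
   QC filter relies on, E[H_obs] = (1 − F)·2f(1 − f), without
   simulating pedigrees.
4. **Traits** — additive genetic values Σ effects × dosage (missing
   dosages contribute the site mean) plus Gaussian noise scaled so that
   Var(genetic)/Var(total) = h²; h² = 0 or an empty effect list yields
   pure unit-variance noise.

Site positions are drawn uniformly without replacement along configured
chromosome lengths (default two chromosomes, 10 and 8 Mb) and sorted.
Defaults — K = 3, n = 120, 5,000 sites, Fst = 0.15, α = 0.2, F = 0.88,
2% missing calls, seed 1 — are the "small" fixture on which the whole
pipeline runs in seconds; F = 0.88 and the strong near-pure admixture
structure mirror what inbred rice panels look like. Everything is
reproducible from (spec, seed).

**What is not emulated:** linkage disequilibrium (sites are independent
given ancestry), recombination maps, selection, genotyping error
correlated with depth, and real allele-frequency spectra. Pruning and
QTL-chaining tests therefore construct correlated or clustered sites
explicitly where needed; passing tests show the algorithms are correct
under the stated model, not that real data meet that model.

## Inbreeding estimation and the heterozygosity-excess filter

Per site: H_obs is the fraction of called genotypes that are
heterozygous, H_exp = 2p̂(1 − p̂) with p̂ the ALT frequency among called
alleles — deliberately without an n/(n − 1) finite-sample correction,
since any constant factor is absorbed into the F estimate the filter
consumes. F is the median of 1 − H_obs/H_exp over sites with defined
ratio < 1 and MAF > 5% (both parameters exposed); the median is the
standard midpoint-average for even counts. A site is removed when its
ratio exceeds factor·(1 − F), factor 5 by default — at the reference
panel value F = 0.882 that cutoff is 0.59. Monomorphic sites carry no
heterozygosity signal and pass this filter untouched.

Two caveats worth knowing. First, the ratio estimator measures *total*
homozygosity excess: on a structured panel the Wahlund effect adds to
true inbreeding (with the default K = 3/Fst = 0.15 fixture the bias is
≈ +0.03 at F = 0.5, shrinking as F grows). The recovery tests therefore
run on single-population panels, where the estimator is unbiased to
within ±0.01; on real structured data the estimate should be read as an
upper bound on within-population F — which is conservative in the
filter's direction of use. Second, the cutoff factor is a tolerance,
not an estimate: 5 simply declares "five times the expected
heterozygosity" implausible.

LD pruning slides a window of `window_snps` sites advancing by
`step_snps`; while any kept pair in the window has squared Pearson
correlation of (mean-imputed) dosages above `r2_max`, the lower-MAF
member of the worst pair is removed, ties broken toward the larger
coordinate. This removal rule is a deterministic choice of this
package; it satisfies the same post-condition as the classical
tool-based pruning (no kept within-window pair above the threshold,
verified against a brute-force oracle in the tests) without replicating
any tool's internal visit order. Mean imputation exists only inside the
r² computation and is never written back. The cascade accepts a *list*
of pruning rounds because published pipelines commonly chain two rounds
with different window sizes.

## Admixture inference

`AdmixtureEM` maximises the binomial admixture log-likelihood
Σ g log f + (2 − g) log(1 − f), f = QP, with the classical
multiplicative EM updates; missing genotypes are skipped in every sum,
and P is clamped to [10⁻⁶, 1 − 10⁻⁶]. EM guarantees a non-decreasing
likelihood (asserted to 10⁻⁶ in the tests). The reference tools for
this analysis are MCMC- or block-relaxation-based; EM was chosen
because it is deterministic given a seed, desk-scale, and optimises the
same likelihood — the quantity of scientific interest here is the
recovered Q, not any particular sampler's trajectory.

Label switching across replicate runs is resolved by exhaustive search
over column permutations (K ≤ 8) minimising Frobenius distance to a
reference run, falling back to greedy correlation matching for larger
K. The consensus Q averages up to 10 members of the largest cluster of
aligned runs (mean per-entry distance < 0.1 to the cluster seed, both
configurable) — the clustering rule is this package's concrete
operationalisation of "average the runs that agree".

Evanno's ΔK = |L″(K)| / sd(L(K)) is computed from replicate final
log-likelihoods over a consecutive K range; ΔK is left undefined (NaN,
never infinite) at the boundary K values, where fewer than two
replicates exist, or where the replicate sd is zero. Assignment
thresholds ship with the three presets used in practice: 0.75 for a
top-level Indica/Japonica split, 0.6 within a country panel, and 0.65
with a major-group fallback (samples under the per-column threshold
whose group-summed ancestry reaches 0.65 become `<group>-adm`, the rest
`admix`). Boundaries are inclusive (≥); argmax ties break to the lowest
column index and are flagged.

PCA standardises each polymorphic site by its binomial sd
√(2p̂(1 − p̂)) after centring at 2p̂ (missing → 0 after centring), takes
scores U·S from the SVD, and fixes signs by making each component's
largest-magnitude loading positive. Classical MDS double-centres the
squared distance matrix and embeds with the top non-negative
eigenpairs, warning about (and dropping) negative eigenvalues.

## Nucleotide diversity

Site diversity is c₀c₁/C(m, 2) over the called allele copies of the
chosen subset (m ≥ 2), i.e. the probability two copies drawn without
replacement differ; a heterozygote contributes one REF and one ALT
copy. Window π divides the summed site diversities by the *full window
length in bp* (100 kb windows, 10 kb steps by default), so monomorphic
and unassayed positions count as zero diversity — this is the
convention that puts per-bp π on the ~10⁻³ scale reported for rice
panels. Terminal windows truncated by the chromosome end keep their
true span and are flagged partial (droppable). The chromosome end
defaults to the last observed site unless physical lengths are given.

## Mixed-model GWAS

Single-variance-component MLM: y = Wα + xβ + g + e with
g ~ N(0, σ_g²K) and e ~ N(0, σ_e²I). W is an intercept plus ancestry
covariates with one column dropped (Q rows sum to 1; keeping all
columns is singular against the intercept). K is the VanRaden genomic
relationship matrix Z Zᵀ / (2Σp̂(1 − p̂)) over polymorphic sites
(missing → 0 after centring); under inbreeding its mean diagonal
approaches 1 + F, which the tests check at F = 0.88. The variance ratio
δ = σ_e²/σ_g² is estimated once on the null model by REML through the
eigendecomposition of K (coarse log-grid then bounded refinement), and
every SNP is then tested by generalised least squares on the rotated
data — the EMMAX approximation. Wald p-values use a t reference with
n − p − 1 degrees of freedom, which makes the model collapse *exactly*
to ordinary least-squares inference when K = I (asserted to 10⁻⁸).
Samples missing the trait or all genotypes are excluded listwise;
per-SNP missing dosages are mean-imputed; monomorphic SNPs report
effect 0, p = 1. A non-PSD kinship is shifted by a 10⁻⁶ ridge with a
warning. The reference pipelines use multi-locus refinements
(pseudo-QTN kinships); those are intentionally out of scope — the
calibration target here is uniform null p-values and genomic inflation
λ ∈ [0.9, 1.1] under the generator's structured null, which the
acceptance tests verify directly.

## QTL rules

Significant SNPs (−log₁₀ p ≥ 8.0, boundary inclusive) are chained per
chromosome while consecutive gaps are ≤ 250 kb; chains need ≥ 2 SNPs.
The 250 kb default is this package's choice of a chaining scale: it
keeps the two published chromosome-6 grain-length regions (separated by
263,777 bp) distinct while leaving multi-megabase regions intact, and
it is exposed as a parameter. Segments narrower than 100 kb are
replaced by [peak − 50 kb, peak + 50 kb] around the most significant
SNP (floored at position 1). Overlap of ≥ 1 bp (both ends inclusive)
merges segments of the same trait class on the same chromosome across
panels — grain length, grain width and length/width ratio share the
"grain size" class — by single-linkage union. Gene annotation counts
any gene whose span overlaps the region by ≥ 1 bp. The composition is
idempotent on its own output. Report aggregation sums per-QTL SNP and
gene counts and counts panels from the per-row flags; a QTL flagged for
several panels counts once per panel.

The bundled QTL report table ships with the package as a worked
example; its significant-SNP column sums to 643 associations over 21
QTLs, 17 of them in the full panel, with 1,730 genes over ten
chromosomes. Its printed per-QTL minimum p-values are on a different
scale than the genome-wide threshold (several exceed 10⁻⁸), so the
parser's significance floor is opt-in rather than enforced by default.

## Problem sizes and tolerances

The simulation-based checks run at the scales chosen for them: n = 500
× 20,000 sites for inbreeding recovery (±0.02 across F ∈ {0.5, 0.7,
0.9}, three seeds each); n = 150 × 3,000 sites, K = 3 for structure
recovery (consensus of 2 EM replicates, mean per-entry Q error < 0.08)
and Evanno selection over K = 2–6; n = 300 × 5,000 sites for GWAS
calibration (KS uniformity p > 0.01, λ ∈ [0.9, 1.1]) and power (an
h² = 0.5 locus is the top hit in ≥ 2 of 3 seeds). EM uses tol 10⁻⁵ and
≤ 300 iterations in the scans (the default estimator settings are
stricter: 10⁻⁶, 2,000); the likelihood is monotone to 10⁻⁶ throughout.

## Known limitations

* No LD in the generator means LD pruning's effect on downstream
  analyses (e.g. how much pruning changes Q) is not exercised.
* The admixture EM finds local optima; replicates plus consensus
  averaging mitigate but do not eliminate this, exactly as for the
  reference tools.
* The F estimator conflates structure with inbreeding on admixed
  panels (see above).
* π is genotype-based, not haplotype-based, and between-population
  statistics (Fst, Tajima's D) are out of scope.
* The MLM is single-locus, single-variance-component; no multi-locus
  conditioning, no dominance, no epistasis.
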