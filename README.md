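# ricepop

Population structure, diversity and GWAS toolkit for resequencing panels
of highly inbred crops, built around the analysis conventions of rice
(*Oryza sativa*) landrace collections.

Rice is predominantly selfing, so a diversity panel looks nothing like a
random-mating population: Wright's inbreeding coefficient sits near
F ≈ 0.9, heterozygous calls are rare, and a SNP showing many
heterozygotes is usually a collapsed paralog or alignment artefact
rather than biology. `ricepop` implements the full analysis chain that
such panels need:

* **Inbreeding-aware SNP QC** — at a site with ALT frequency *p* the
  expected fraction of heterozygous calls is (1 − F)·2p(1 − p), not the
  Hardy–Weinberg 2p(1 − p). The panel-level F is estimated as the median
  of 1 − H<sub>obs</sub>/H<sub>exp</sub> over sites with
  H<sub>obs</sub>/H<sub>exp</sub> < 1 and MAF > 5%, and every site whose
  ratio exceeds **5 · (1 − F)** is removed. Hard filters (QUAL, MAF,
  missingness, minor-allele count), within-window LD pruning on dosage
  r², and physical thinning complete the cascade.
* **Admixture-model structure** — the likelihood
  g<sub>il</sub> ~ Binomial(2, Σ<sub>k</sub> q<sub>ik</sub> p<sub>kl</sub>)
  is maximised by multiplicative EM (`AdmixtureEM`); replicate runs are
  aligned over label permutations, averaged, and the number of
  populations selected with the Evanno ΔK statistic. Samples are
  assigned to subpopulations by thresholding the averaged Q (0.6 within
  a panel; 0.65 with an Indica/Japonica major-group fallback), with PCA
  of standardised dosages and classical MDS (principal coordinates) as
  the geometric complement.
* **Nucleotide diversity** — sliding-window π per subpopulation: per
  site c₀c₁/C(m, 2) over called allele copies, summed per 100-kb window
  (10-kb step) and divided by the window length in bp.
* **Mixed-model GWAS and QTL rules** — y = Wα + xβ + g + e with
  g ~ N(0, σ<sub>g</sub>²K) for a VanRaden kinship K, REML variance
  components via the eigendecomposition of K, per-SNP GLS Wald tests;
  then SNPs with −log₁₀ p ≥ 8 are chained into segments (≥ 2 SNPs,
  ≤ 250 kb gaps), sub-100-kb segments are extended 50 kb either side of
  the peak SNP, and overlapping segments of one trait class (grain
  length/width/ratio → grain size) merge across panels into QTL regions
  annotated with overlapping genes.
* **Synthetic panels** — a Balding–Nichols + Dirichlet-admixture +
  genotype-level-IBD generator (`ricepop.synthpop`) produces structured,
  partially inbred panels with planted additive trait loci and truth
  tables, so the whole pipeline is testable from nothing but a seed.

## Worked example

```python
import numpy as np
import ricepop as rp

spec = rp.PopulationSpec()          # K=3, n=120, 5000 sites, F=0.88
sim = rp.simulate(spec, rp.TraitSpec((100, 2600), (1.0, 1.0), 0.5))
gm = sim.genotypes

est = rp.estimate_inbreeding(rp.site_stats(gm))
print(f"F-hat = {est.f:.3f} (true 0.88); cutoff = {est.cutoff:.3f}")

filtered, report, _ = rp.filter_cascade(gm, min_qual=30, min_maf=0.01,
                                        prune_rounds=((10, 1, 0.8),))
print(report.to_frame().to_string(index=False))

fit = rp.admixture_em(filtered, k=3, seed=0, max_iter=300)
aligned, _ = rp.align_runs([sim.q_true, fit.q])
print(f"mean |Q-hat - Q-true| = {np.abs(aligned[1] - sim.q_true).mean():.3f}")
```

prints

```
F-hat = 0.891 (true 0.88); het-excess cutoff = 0.546
           filter  removed  remaining
            input        0       5000
     hard_filters       76       4924
       het_excess        3       4921
              maf        0       4921
ld_prune_10_1_0.8        0       4921
mean |Q-hat - Q-true| = 0.021
```

The estimator recovers the simulated inbreeding coefficient to one
percent; 76 sites fail the hard filters (QUAL/MAC/missingness), three
carry heterozygosity in excess of 5·(1 − F̂), and the EM consensus
ancestry matrix lands within 0.02 per entry of the generating truth.

The bundled 21-row QTL report from a rice diversity-panel GWAS
aggregates back to its headline counts:

```python
>>> rp.qtl_report(rp.bundled_qtl_table())
{'n_qtls': 21, 'total_associations': 643, 'panel_counts': {'FP': 17, 'Ind': 4,
 'Jap': 7}, 'panel_only_counts': {'FP': 11, 'Ind': 0, 'Jap': 4},
 'n_chromosomes': 10, 'total_genes': 1730, 'total_span_bp': 11660166}
```

Every command is also exposed on the `ricepop` CLI: `simulate`,
`convert`, `validate`, `filter`, `structure`, `embed`, `pi`, `gwas`,
`qtl`, `report` (see `ricepop --help`).

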