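# pinescape

Landscape genomics of a wide-ranging conifer, as a tested, reusable Python
package. It targets the analysis chain used to dissect how **colonization
history, environment and geography** structure population genomic variation
in *Pinus tabuliformis*-like systems: population diversity and
differentiation statistics, isolation-with-migration (IM) demographic
inference from the folded joint site-frequency spectrum, dual outlier scans
for environment-associated loci, redundancy-analysis (RDA) partitioning of
among-population variance into isolation by environment / distance /
colonization (IBE/IBD/IBC), and niche overlap and background-divergence
tests — all exercisable on synthetic data with known ground truth.

Who it is for: population geneticists and landscape genomicists who want
these analyses scriptable end to end, and method developers who need a
ground-truthed sandbox for calibration and power studies.

## The statistics at the core

* **Weir–Cockerham F<sub>ST</sub>**: variance components a, b, c per locus;
  multilocus estimate Σa/Σ(a+b+c).
* **Unbiased haplotype diversity**: He = n/(n−1)(1 − Σp<sub>i</sub>²) for
  mitotype counts.
* **Folded joint SFS**: exact hypergeometric down-sampling projection of
  genotype counts; minor-configuration folding with half-frequency classes
  kept once; monomorphic mass excluded and reported.
* **IM model fitting**: multinomial composite likelihood
  Σ<sub>cells</sub> obs·log p against Monte-Carlo expected spectra from an
  authored structured-coalescent engine (demes, migration, merges, growth);
  nine models (3 branching orders × 3 size histories) compared by Akaike
  weights w<sub>i</sub> = exp(−Δ<sub>i</sub>/2)/Σexp(−Δ<sub>j</sub>/2);
  fragment-bootstrap percentile CIs; absolute-unit conversion including the
  rescaling t·(gen_new/gen_old)·(μ_old/μ_new).
* **Outlier scans**: a PCA scan (per-SNP Mahalanobis distance of
  PC-regression z-scores, chi-square p after genomic-inflation rescaling,
  Storey q-values at FDR 0.05) and an environment-association scan against
  a population-covariance null Ω (grid-integrated Bayes factors and
  Ω-whitened Spearman ρ); the robust set is the intersection under the
  top-1% BF, BF > 3, top-5% |ρ| rule.
* **RDA partition**: (partial) redundancy analysis on population allele
  frequencies with Ezekiel-adjusted R²; conditional fractions by nested
  subtraction so env|geog + geog|env + joint = total exactly;
  999-permutation significance; trend-surface geography with gated forward
  selection; mitotype-frequency PCs as the colonization proxy.
* **Niche tests**: correlation-matrix PCA (eigenvalue > 1), per-axis
  d<sub>n</sub>/d<sub>b</sub> resampling (75% × 1,000) with a permutation
  t-test, Schoener's D and Warren's I between normalized suitability
  surfaces, and reciprocal pseudoniche background tests.

See `docs/methods.md` for assumptions, parameter defaults and numerical
choices.

## Worked example

Generate a ground-truthed dataset (17 populations in three clusters under
the default IM history, 1,200 SNPs of which 15 carry an environmental
cline), filter it, and run both outlier scans:

```python
from pinescape.synthdata import SynthConfig, gen_im_dataset
from pinescape.popgen import (FilterSpec, filter_loci, wc_fst,
                              haplotype_diversity, pop_allele_freqs)
from pinescape.outliers import (pcadapt_scan, neutral_panel,
                                env_assoc_scan, robust_outliers)

cfg = SynthConfig(seed=42, n_loci=1200, n_adaptive=15)
bundle = gen_im_dataset(cfg)
G, rejected = filter_loci(bundle.genotypes, FilterSpec(), bundle.popmap)
print(f"retained {G.n_loci} of {bundle.genotypes.n_loci} loci "
      f"({len(rejected)} rejected)")
_, fst, _ = wc_fst(G, bundle.popmap, grouping=bundle.truth["group_labels"])
print(f"among-cluster FST = {fst:.3f}")
print(f"He for mitotype counts (7,1): {haplotype_diversity((7, 1))}")

scan = pcadapt_scan(G)
neutral = neutral_panel(G, scan)
env_res = env_assoc_scan(
    pop_allele_freqs(G, bundle.popmap), bundle.env,
    freqs_neutral=pop_allele_freqs(G.take_loci(neutral), bundle.popmap),
    seed=42)
outset = robust_outliers(scan, env_res)
truth = {bundle.genotypes.locus_ids[i] for i in bundle.truth["adaptive_loci"]}
print(f"scan K = {scan.K}; robust outliers: {len(outset.robust)} "
      f"(true spiked loci recovered: {len(outset.robust & truth)}"
      f"/{len(truth & set(G.locus_ids))})")
```

Output:

```
retained 1115 of 1200 loci (85 rejected)
among-cluster FST = 0.015
He for mitotype counts (7,1): 0.25
scan K = 2; robust outliers: 15 (true spiked loci recovered: 15/15)
```

The filter drops loci failing the MAF/missingness/heterozygosity rules;
among-cluster F<sub>ST</sub> of ~0.02 reflects the weak neutral structure
typical of high-gene-flow conifers; He = 0.250 is the unbiased mitotype
diversity of a population of 8 sequences with haplotype counts (7, 1); and
the intersection of the two scans recovers all 15 environment-associated
loci with no false positives in this run.

A command-line interface mirrors the library
(`pinescape synth|filter|stats|sfs|fit|compare|convert|scan-pca|scan-env|
outliers|partition|niche|run`); `pinescape run --outdir out --seed 1`
drives the whole pipeline and writes per-stage CSV/JSON reports with
provenance (seed, config hash).

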