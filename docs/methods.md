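# Methods

`pinescape` re-implements, as a tested library, the analysis chain of a
landscape-genomics study of a wide-ranging conifer (*Pinus tabuliformis*-like
system): 17 populations in three geographic clusters genotyped at a few
thousand GBS SNPs, with maternally inherited mitotypes, climate tables and
occurrence records. This note documents the models, the numerical choices,
and what the synthetic data do and do not capture.

## The structured-coalescent engine

All genotype simulation and all expected site-frequency spectra come from a
single structured-coalescent core (`demography._engine`). The state is a set
of sampled lineages distributed over demes; backward in time, lineages in
deme *d* coalesce in pairs at rate k(k−1)/2 / (2N_d(t)), migrate from deme
*i* to deme *j* at per-lineage rate M_ij/N_i (with M_ij the forward count of
migrant individuals per generation received by *i* from *j*, evaluated at
current sizes), and move wholesale at timed merge events that also silence
migration involving the emptied deme. Forward exponential growth makes
N_d(t) = N_d(0)·exp(−α·min(t, t_end)) shrink into the past; because the
coalescence rate is then non-decreasing between fixed time points, the
time-inhomogeneous process is simulated exactly by thinning against the rate
at the end of a window capped at ln(4)/α. Loci are unlinked single sites.

Two mutation conventions:

* **snp** — each locus is a segregating biallelic site. Genealogies are
  simulated in a pool; a locus picks a genealogy with probability
  proportional to its total branch length and then a branch proportional to
  its length. This makes the simulated data distributionally consistent with
  the expected SFS computed from mean branch lengths (E[b_i]/E[L]). An
  optional `min_maf` rejects sampled sites below a pooled minor-allele
  frequency, emulating a quality-filtered discovery panel. Determinism is
  preserved by a two-pass scheme: the engine re-simulates the same seeded
  genealogy stream, with branch-sampling uniforms supplied externally so the
  internal stream is identical in both passes.
* **poisson** — one genealogy per locus; a mutation occurs with probability
  1 − exp(−μL), at most one site retained; monomorphic loci are kept. Under
  this convention per-locus nucleotide diversity has expectation 4Nμ, which
  the test suite verifies against closed form and against an independent
  coalescent simulator (msprime is used only as a cross-check oracle).

The nine isolation-with-migration (IM) models are three branching orders
(which extant group split first) × three size histories (constant,
exponential growth since the split, recent exponential growth). Migration is
continuous between extant branches only; ancestral branches exchange no
migrants. The default parameter values of the synthetic study follow the
published inference for this system: extant diploid sizes 1.09×10⁵ (south),
2.10×10⁵ (north), 1.27×10⁵ (west); splits at 73,400 and 11,600 generations
(3.67 and 0.58 MYA at 50-year generations); south–west and north–west gene
flow at 19 and 14.5 migrants/generation (published range midpoints).
Ancestral sizes (1.5×10⁵, 2.0×10⁵) and the south–north rate (5) are not
pinned down by the published point estimates and were set once to round
intermediate values.

## Folded joint SFS and composite likelihood

Observed spectra are built by exact hypergeometric down-sampling projection:
a site with *a* alt alleles among *m* observed alleles in a population
contributes the expected hypergeometric mass over projected counts; sites
with fewer observed alleles than the target are skipped and counted.
Folding maps each joint cell onto the equivalence class {c, n−c}; the
representative is the configuration with the smaller total count
(lexicographic tie-break at exactly half frequency, where the class is a
singleton and keeps its mass once). The monomorphic class is excluded and
its mass reported. A flag drops all cells with joint minor count 1
(singleton exclusion).

The fit criterion is the multinomial composite log-likelihood
Σ_cells obs·log p over folded cells conditional on segregating, with the
expected spectrum estimated from mean genealogy branch lengths of `n_sims`
simulated trees, normalized to 1; zero-probability cells are floored at
1/(10·n_sims) — one tenth of a Monte-Carlo count — before the log.

**Scale anchoring.** A normalized segregating-sites-only spectrum identifies
parameter *ratios*, not absolute sizes and times: multiplying every Ne and T
by a constant (with migration in migrants/generation) leaves it unchanged.
As is standard for SNP-only SFS inference, one parameter must be fixed; the
recovery harness anchors the northern effective size at its true value.
A corollary is that a single-population constant-size spectrum carries no
information about Ne at all, so single-parameter recovery is demonstrated on
a split time instead.

**Optimizer.** Multi-start cycles of conditional one-dimensional bounded
Brent maximizations over log10-scaled parameters, with common random
numbers within a run so the objective is deterministic and the per-cycle
best likelihood is monotone. Pure coordinate descent crawls along the
strong size/time scale ridge, so each cycle adds one extra conditional
direction: a joint log-scale move over all free size and time parameters
(migration, being scale-free in migrants/generation, is excluded). Model
comparison re-evaluates each candidate's best fit at common random numbers
with a large `n_sims` before computing AIC = 2k − 2logL and Akaike weights
w_i = exp(−Δ_i/2)/Σexp(−Δ_j/2), so the comparison does not hinge on per-fit
Monte-Carlo noise.

**Bootstrap CIs.** Fragments (unlinked loci) are resampled with replacement
— with one SNP per fragment this equals a multinomial resample of SFS
cells — and each bootstrap spectrum is refitted from a fresh random start
with the same cheap settings as the point estimate. The percentile
interval therefore reflects the estimator *as computed*, including its
optimization and Monte-Carlo noise; warm-started refits produced
dishonestly narrow intervals and are not used.

**Desk-scale recovery study.** The acceptance harness simulates 4,000 SNPs
for 6 diploids per group under a south-first constant-size truth with
Ne 8–12×10³, splits at 60,000/6,000 generations and 1 migrant/generation
(a 10:1 split ratio and modest gene flow keep the branching order
identifiable at this panel size), projects to 12 haploids per group, fits
the three branching orders (1 start × 3 cycles, n_sims = 1,500, final
re-evaluation at 20,000), and draws 10 bootstrap refits (2 cycles,
n_sims = 800). These sizes are the package's desk-scale study design; the
published analysis used 50 starts, 10–40 cycles and 10⁵ simulations per
evaluation, which the same code reproduces by changing the arguments.

**Unit conversion.** Times in generations convert to years by the
generation time; published estimates rescale between (generation time,
yearly mutation rate) pairs as t_new = t_old·(gen_new/gen_old)·(μ_old/μ_new).

## SNP filtering and summary statistics

Genotype-level masking (GQ < 20 or depth < 5 → missing) precedes locus
filters, which follow the printed inequalities exactly: MAF < 0.05 dropped,
missing rate ≥ 0.3 dropped, observed heterozygote fraction > 50% dropped,
mean depth ≥ 400 dropped, and any population with fewer than 4 genotyped
individuals drops the locus. MAF is computed over all populations pooled,
after masking. The rejection report records the first failing rule per
locus in that fixed order.

%Poly counts loci with both alleles observed within the population; Het is
the observed heterozygote fraction among non-missing genotypes averaged
over loci (the expected-heterozygosity alternative is one flag away).
Differentiation uses the Weir–Cockerham (1984) variance components a, b, c
with the multilocus estimate Σa/Σ(a+b+c); loci with zero denominator are
excluded and counted, not zeroed. Mitotype diversity is the unbiased
He = n/(n−1)(1 − Σp_i²), reported at 3 decimals; among-group mitotype
differentiation is Nei's G_ST over group haplotype frequencies.

## Outlier scans

The structure scan regresses each locus's scaled dosages (centered, scaled
by √(p(1−p)), missing values mean-imputed for the decomposition only) on
the leading K principal-component score vectors; the K-vector of z-scores
is robustified (minimum covariance determinant; median/MAD when K = 1) and
its Mahalanobis distance converted to chi-square(K) p-values after
median-based genomic-inflation rescaling, then to Storey q-values (π₀ by
the cubic-spline smoother; π₀ = 1 for small panels). K is automated from
the scree: components up to where the slope flattens below 10% of the first
drop, examined over the first ten eigenvalues; a scree with no flattening
point has no marked elbow and the largest eigenvalue ratio locates it
instead. The automation is an override away (`K=` argument). Calibration
is honest only above the PCA detectability threshold (FST·n of order
several); the acceptance suite therefore calibrates at the full 17-population
design.

The environment-association scan standardizes population allele frequencies
per locus by √(p̄(1−p̄)) around the across-population mean and whitens both
frequencies and standardized environment by the inverse Cholesky factor of
Ω, the population covariance of standardized *neutral* frequencies (scan
hits removed, then window-based r² pruning at 50/5/0.05). Because Ω is
centered on the sample mean, independent populations show the structural
−σ²/k off-diagonals and identical populations collapse to jitter — the
matrix is PSD by construction. Per SNP × variable, a Bayes factor contrasts
a linear environmental effect against the null by deterministic integration
over the effect size on a fixed grid under a matched N(0, 1) prior with the
null-profiled residual scale — a reproducible replacement for MCMC
averaging. Run-to-run variability is emulated by re-estimating Ω from
bootstrap resamples of the neutral loci over five seeded runs whose BF and
whitened Spearman ρ are averaged. The decision rule is unchanged from the
study: BF in the top 1% (ties included) *and* BF > 3 *and* |ρ| in the top
5%, for at least one variable; the robust set is the intersection with the
q ≤ 0.05 structure-scan set.

## RDA variance partition

The dependent matrix is populations × loci allele frequencies, centered per
locus (no Hellinger transform, matching the untransformed convention; a
switch exists). Predictors: environment PCs (correlation-matrix PCA; PC1–2
by default), a trend surface of centered coordinates (x, y, xy, x², y²)
passed through forward selection (a global permutation pre-test gates the
stepwise phase — the standard guard against selecting from pure noise —
then candidates enter at permutation p < 0.05 with improving adjusted R²),
and PCs of the population × mitotype frequency table after removing
singleton mitotypes (axes to ≥75% cumulative variance).

R² is the fitted share of the total centered sum of squares; adjusted R²
is Ezekiel's 1 − (1−R²)(n−1)/(n−p−1) with p the predictor rank.
Conditional fractions come from subtraction of nested adjusted R² — the
convention whose arithmetic the published ledger satisfies to ±0.002 —
so env|geog + geog|env + joint = total holds exactly at full precision.
The confounded joint fraction carries no significance test. Permutation
tests permute rows of the (residualized) response freely, populations being
the exchangeable units, with p = (1 + #{F* ≥ F})/(1 + n_perm). The mitotype
matrix is reported marginally, as in the published table layout; a full
three-way partition is available programmatically.

## Niche divergence

Environmental space is reduced by correlation-matrix PCA over pooled
occurrence and background points; axes with eigenvalue > 1 are retained
(correlation PCA makes verdicts invariant to affine rescaling of any
variable). Per axis, dn is the absolute difference between mean occurrence
scores of 75% resamples of the two groups and db the same over resamples of
the two background clouds (backgrounds are subsampled at the same 75%
fraction; the source is ambiguous on this point), 1,000 resamples each.
Divergence on an axis requires the mean dn to exceed the db 95% interval
*and* a two-sided permutation t-test on occurrence scores at p < 0.05;
dn below the db interval indicates conservatism; anything else is
inconclusive. Overlap between normalized suitability surfaces uses
Schoener's D = 1 − ½Σ|p−q| and Warren's I = 1 − ½Σ(√p−√q)². The background
test fits the pluggable suitability stand-in (normalized Gaussian KDE by
default; any raster can be supplied) to draws of |occ_A| pseudo-occurrences
from the sister group's background, in both directions; observed overlap
below the null 2.5th percentile supports divergence, above the 97.5th
conservatism. With utterly disjoint background regions the null degenerates
to zero overlap and the verdict is deliberately inconclusive rather than
divergent.

## The synthetic-data generator

Defaults are the study conditions: the 17 named populations with their
published sample sizes (191 trees) and coordinates, three clusters (the two
single-population lineages are attached to their geographically nearest
cluster, since the IM model has three branches), 4,077 SNPs at 7.2%
uniform missingness, and the IM truth above. Populations are demes nested
inside their cluster (deme size = cluster Ne / number of demes; island
migration of 5 migrants/generation per within-cluster pair; demes merge
into the cluster ancestor 2,000 generations back). The SNP panel is
ascertained at pooled MAF ≥ 0.05 — the emulated panel is the *post-QC*
SNP set, which passed that filter during discovery — so the filtering
stage removes only a few percent of loci, as in the real panel.
Environmental variables are linear in the (standardized) coordinates plus
iid noise, the first variable running along latitude so it tracks cluster
membership; the slope/noise ratio controls how confounded environment and
geography are. Adaptive loci are spiked at the population-frequency level:
the new frequency is logistic(a₀ + β·z) with z the standardized first
environmental variable and a₀ preserving the locus's baseline, then
individual genotypes are redrawn binomially (missing calls stay missing) —
matching the frequency-level scans downstream. Mitotypes come from
cluster-specific haplotype pools with symmetric-Dirichlet(θ) frequencies
shared per pool and a small probability of drawing from the union pool;
θ = 0.03 and share = 0.05 were frozen from a pre-registered grid targeting
among-group G_ST ≈ 0.8 with minimal seed-to-seed spread (single-seed G_ST
has spread ±0.08, dominated by three Dirichlet draws, so recovery checks
average over seeds).

One global seed fans out to named per-stage child streams (genotypes,
missingness, environment, mitotypes, spiking, niche), so any stage can be
regenerated independently and bundles are bit-reproducible.

What the generator does *not* emulate: linkage within GBS fragments (loci
are unlinked; fragment labels exist only as bootstrap units), sequencing
depth/quality structure (the masking path is exercised with synthetic
layers in tests), non-uniform missingness, isolation-by-distance within
clusters beyond the island approximation, selection at linked sites, and
real climate covariance structure (14 variables share one linear field).
Passing tests therefore demonstrate correctness of the estimators and
calibration under these idealized conditions, not robustness to every
property of real GBS data.

## Known limitations

* The composite likelihood treats SFS cells as independent; with truly
  linked loci the bootstrap should resample multi-SNP fragments (supported
  via fragment labels) and model-comparison weights become approximate.
* The expected SFS is Monte-Carlo; fits below ~1,000 simulations per
  evaluation are noticeably noisy, which the bootstrap deliberately folds
  into the intervals.
* Growth-mode parameterizations (onset, rate) follow the verbal description
  of the model family; the source's exact supplementary parameterizations
  are not reproduced.
* The dn/db and background tests inherit the arbitrariness of background
  extent; verdicts are only meaningful relative to the chosen envelopes.
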