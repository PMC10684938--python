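# Methods

`obake` re-implements, as a tested library, the analysis pipeline used to
characterise population structure, diversity, and interspecific hybridization
in *Oryza longistaminata* panels genotyped alongside *O. sativa*,
*O. barthii*, and *O. glaberrima* outgroups. This note records the models,
the numerical choices, and what the synthetic panels do and do not emulate.

## Filter cascade

RAD-seq-style genotype matrices are cleaned in a fixed order: (1) per record,
only the two most common alleles are retained (ties broken toward the lower
allele index; calls carrying rarer alleles become missing; the reference
designation is preserved whenever the reference allele survives); (2) calls
whose summed allelic depth falls outside `[depth_min, depth_max]`
(default 7–400) are masked; (3) sites are dropped, in order, when the
heterozygous fraction among non-missing calls exceeds 0.5, when MAF < 0.01,
or when fewer than 66% of individuals carry a call. Each dropped site is
attributed to exactly the first rule that removed it, and the cascade is
idempotent. Individuals with more than 40% missing calls are removed by a
separate operation so that each analysis subset can recompute site statistics
(MAF and presence are intentionally subset-dependent). The heterozygosity cap
counts only non-missing calls in its denominator — the source protocol does
not state this, so it is an explicit package decision.

## Admixture model

The ancestry model is the standard no-linkage admixture model for diploid
biallelic dosages: allele copies originate independently from one of K
clusters with cluster frequencies `P[k, l]`; individual ancestries `Q[i, :]`
live on the K-simplex with a symmetric Dirichlet(α) prior, and frequencies
carry independent Beta(λ, λ) priors with λ = 1. The correlated-frequencies
variant is deliberately not implemented: the panels this package targets mix
strongly diverged species, where the independent-frequencies model is
adequate and simpler.

Inference is by Gibbs sampling over latent per-copy origins with conjugate
Beta/Dirichlet updates. A single shared α is updated by a Metropolis step
(uniform(0, 10) prior, Gaussian proposal with sd 0.05); fixed-α and
deterministic EM (MAP) modes exist for fast, exactly reproducible unit tests.
Reported Q and P are posterior means over post-burn-in sweeps; the model
evidence proxy is `mean(lnL) − var(lnL)/2`, matching the convention the
Evanno ΔK procedure expects. Cluster labels are canonicalized by descending
total Q mass, and replicate runs are aligned by greedy maximum-overlap
matching of Q columns; `lnP(data)` is invariant under cluster permutation.

Supervised (use-population-info) mode pins labeled individuals to indicator
ancestry (zero migration prior) and samples cluster frequencies only from
the flagged source individuals, whose allele origins are known — their
contribution reduces to fixed Beta counts, so P mixes immediately. Unlabeled
individuals receive ordinary admixture updates against the sampled P.

Run-length profiles: the full-scale profile is 10,000 burn-in + 50,000
recorded sweeps, 3 chains, K = 1–9. The package's test-scale default
(`RunConfig.reduced()`) is 1,000 + 5,000. The acceptance analyses use 400
burn-in + 1,200 recorded sweeps with 3 chains over K = 1–5 on ~120-individual,
500-locus panels: at the fixed species divergences involved (F ≈ 0.3) the
between-species log-likelihood differences are thousands of units, so chain
length affects ΔK margins, not the selected K; these sizes keep a full grid
under three minutes on one CPU.

### Evanno ΔK

`L(K)` is the replicate mean of `lnP(data)`; `ΔK = |L(K+1) − 2L(K) +
L(K−1)| / sd(L(K))` is defined for interior K with positive replicate sd
(sd 0 → reported missing; all missing → an error advising direct lnP
inspection). The optimum is the interior argmax.

## DAPC

PCA operates on the mean-imputed, column-centered dosage matrix without
variance scaling (thin SVD). The cluster search runs best-of-`n_start`
k-means (k-means++ seeding, scikit-learn backend) for each K and scores
`BIC(K) = n·ln(WSS/n) + K·ln(n)`, selecting the minimum. The search retains
n/3 principal components by default: enough to hold all between-group
structure while leaving isotropic noise dimensions that stabilise the WSS
curve against over-splitting (with only the top few PCs, WSS collapses so
fast in K that BIC keeps decreasing past the true cluster number).
Discriminant assignment uses between/within scatter of the retained PCs with
a ridge fallback for singular within-scatter; posteriors are Gaussian
class-conditional densities under the shared within covariance and uniform
priors, which for two groups reduces to the nearest-Mahalanobis-mean rule.

## Spatial PCA

Genotypes are pooled by collection site (exact coordinate equality after
rounding to 4 decimals) into per-site allele frequencies. The connectivity
network is the minimum spanning tree on great-circle distances (Earth radius
6371.0088 km), ties broken toward the lexicographically smaller site-id
pair. With row-normalized adjacency W and symmetrized Ω = (W + Wᵀ)/2, the
axes are eigenvectors of `(1/S)·fᵀΩf` for the centered site × locus
frequency matrix f; each eigenvalue factors exactly into score variance ×
Moran-type autocorrelation (asserted to 1e−8 in tests). Two axes are
retained by default. Lagged scores are W·scores; raster interpolation of
lagged scores is out of scope. Geographic thinning (default 25 km) operates
greedily in stable id order at the accession level — both individuals of an
accession are kept or dropped together, matching the sampling unit. The
admixture–geography r² regresses a coordinate on K−1 ancestry components
(the full Q is collinear); for K = 2 this is the squared Pearson correlation.

## Diversity statistics

Per locus, with groups s = 1..S (groups without calls at a locus excluded),
harmonic-mean sample size ñ, mean observed heterozygosity Ho, and group
frequencies p_s:

    Hs = (ñ/(ñ−1)) · (1 − mean_s Σ_a p_sa² − Ho/(2ñ))
    Ht = 1 − Σ_a p̄_a² + Hs/(ñS) − Ho/(2ñS)
    F_ST = 1 − Hs/Ht,  F_IS = 1 − Ho/Hs,
    Jost's D = ((Ht − Hs)/(1 − Hs)) · S/(S−1)

Gene diversity of a sample of n diploids is `(2n/(2n−1))(1 − Σ p²)`. All
statistics are means ± SE across loci, with per-locus undefined values
excluded per statistic and negative sampling-noise values retained
unclamped. Per-group F_ST (one value per group, as in grouped diversity
tables) is `1 − Hs_group/Ht_total` with Ht from all groups pooled —
"subpopulation differentiation from the total population". These formulas,
not any external implementation, are the package's contract; whether the
original study's script used identical Ht correction terms is unknown, so
Table-2-digit reproduction is explicitly not claimed.

## Trees and haplotype networks

The IBS distance at a locus is the probability that one allele drawn from
each individual differs (`p_i(1−p_j) + (1−p_i)p_j` with p = dosage/2),
averaged over shared non-missing loci. It is a pseudo-metric only — the
triangle inequality can fail — and NJ requires a complete matrix.
Neighbor joining follows Saitou–Nei with the Studier–Keppler Q-criterion;
ties break toward the lexicographically smallest descendant-leaf pair, and
negative branch lengths are clamped to zero with the deficit moved to the
sibling, preserving leaf-to-leaf path lengths on additive inputs (asserted
to 1e−9). Outgroup rooting places the root at the midpoint of the pendant
edge of the candidate leaf participating in the globally maximal pairwise
distance (member-of-max-pair; row-mean maximisation is a documented
alternative reading, exposed via `DistanceMatrix.max_pair` on demand).

Plastid SSR haplotypes are complete 7-locus allele-size vectors; distance
between haplotypes is the count of differing loci by default (stepwise
repeat-sum optional). The minimum spanning network is the union of all
minimum spanning trees: an edge of weight w is retained iff its endpoints
are in different components of the sub-threshold (< w) graph, so tied
alternatives are all kept.

## Hybrid classification

An entry's outgroup admixture is its total non-conspecific supervised
ancestry (1 − Q_own-species; a sativa-only variant is available). Putative
hybrids fall inside a symmetric band whose default (4.4%–95.6%) follows the
published definition; calibration from control values takes
`floor(min·1000)/1000 − 0.001` as the lower bound so the band always
contains the minimum control. The printed 4.4% bound vs the narrative 4.5%
minimum are both honoured: entries in [0.044, 0.045) are flagged
`borderline`. Generation bands compare the minority-parent fraction
`min(admix, 1 − admix)` against 0.5 (F1/F2), 0.25 (BC1), and 0.125 (BC2)
with half-width δ = 0.06, chosen to contain published F1/F2 controls
(minority ancestry 0.46–0.49); using the total-admixture minority rather
than `min(Q_sativa, Q_long)` makes the band invariant to permuting the two
non-focal components. The maternally inherited plastid haplotype names the
maternal parent; cytonuclear consistency requires the maternal species to
contribute nuclear ancestry.

## Synthetic panels

The generator draws an ancestral allele frequency per locus from
U(0.05, 0.95) and descends a Balding–Nichols hierarchy: species pools
(defaults: wild species and sativa each at divergence 0.30,
barthii–glaberrima at 0.35), three wild subpopulations (defaults F_sub =
0.02; inbreeding F_IS = 0.28/0.29/0.44), two sativa demes (split 0.10,
emulating indica/japonica) and a barthii/glaberrima pair (split 0.05).
The divergence parameter is calibrated: a Beta draw with concentration
parameter c produces an across-loci mean of per-locus F_ST well below the
naive c (averaging ratios is not the ratio of averages, and near-fixed loci
leave the sample), so the generator maps a requested F through a frozen
Monte-Carlo interpolation table (60k loci, two 50-diploid demes, scored by
this package's own estimators) to the c whose realized mean per-locus F_ST
equals F. Estimator-recovery tests hold to ±0.01 across F = 0.01–0.3 under
the calibration conditions.

Wild individuals sit in accession pairs on a jittered grid around their
subpopulation center; their ancestry vector mixes subpopulations by a
logistic function of great-circle distance (scale 800 km), giving the
Pan-Africa-style admixture gradient. The Southern-analog subpopulation
optionally blends a fixed 0.037 sativa-pool fraction into every member —
the ancient-introgression signature. Genotypes draw each allele copy's
origin from the ancestry vector and its allele from that deme's frequency;
with probability F_IS the second copy duplicates the first (allele and
origin), producing the expected heterozygosity deficit. Outgroup species are
near-selfers (duplication probability 0.95).

Pedigrees are simulated gamete-by-gamete with unlinked loci and per-copy
species-origin tracking, so "true ancestry" is the realized fraction of
allele copies, not the Mendelian expectation. Schemes compose F1,
selfing, and backcross steps (`F1`, `F2`, `BC1:<parent>`, `BC2:<parent>`,
`RILk`, or explicit chains like `F1-BC:sativa-SELF4`); the hybrid is always
the seed parent in backcrosses, so the plastid follows the original F1
mother. Default control RILs are backcross-derived (`F1-BC:sativa-SELF4`,
~12% wild ancestry), matching the published control set whose minimum
minority ancestry calibrates the hybrid band; default field hybrids (F1,
BC1, BC2 into the wild species) carry wild-species plastids. Plastid SSR
founder haplotypes differ at ≥ 3 of 7 loci between species; wild lineages
accumulate Poisson(0.5) ±1-repeat mutations, while pedigreed hybrids inherit
the maternal founder haplotype unchanged. The observation model masks calls
at the missing rate (default 0.05) and draws total read depth from a
negative binomial (mean 30, shape 6) split binomially into ref/alt counts.

Named designs fix the acceptance conditions: `two_cluster_spec` (80 wild
individuals in 3 subpops at F_sub = 0.02 plus a single 40-individual
pooled domesticated outgroup, 500 loci) for ΔK selection — with a second,
genuinely diverged outgroup species present, K = 3 is the correct optimum,
which is a different design than the two-cluster claim; and
`six_cluster_spec` (3 wild subpops at F_sub = 0.05, two sativa demes, one
outgroup pair from a common pool, 2,000 loci) for DAPC/BIC selection.

What the panels do not emulate: linkage and recombination maps (loci are
exchangeable, as the downstream analyses assume), realistic demography or
selection, allele-calling error beyond depth-dependent masking, and
sequencing batch structure. Passing recovery tests therefore demonstrates
estimator and pipeline correctness under the stated generative model, not
robustness to real-data artifacts.

## Pipeline

Pass 1 filters, runs the replicate admixture grid with ΔK selection, runs
DAPC, and screens longistaminata-labeled entries against thresholds
calibrated from the control hybrids' minority ancestry (defaults when no
controls are present). The screen uses the best K = 2 replicate — the
all-species wild-vs-outgroup contrast — with the wild cluster identified by
maximum mean Q among conspecifics. Pass 2 subsets to sub-threshold
conspecifics (< 4.5% by default, the narrative exclusion rule, deliberately
distinct from the 4.4% classification bound), re-filters sites on the
subset, and repeats structure analysis. The supervised pass fixes reference
individuals (conspecifics below 1% pass-1 admixture, plus all labeled
outgroups), runs three replicate supervised chains at K = 3, and averages Q.
Plastid groups are assigned per haplotype by majority species among its
non-hybrid carriers. Assignment comparisons between passes align cluster
labels by greedy maximum agreement before listing moved individuals.

## Known limitations

- The Gibbs sampler is vectorised numpy, adequate to ~10³ individuals ×
  10⁴ loci at reduced run lengths; it is not an ADMIXTURE-scale optimiser.
- α mixing is slow for near-pure panels (random-walk Metropolis); reduced
  runs can overestimate small minority ancestries by a few points in fully
  unsupervised fits. Supervised profiling, which the hybrid Q values rely
  on, pins the sources and is unaffected.
- Evanno ΔK is undefined at the grid edges and cannot select K = 1.
- IBS distances between individuals with no shared loci are missing; NJ
  then refuses the matrix rather than imputing.
- The F calibration table is computed for two 50-diploid demes under a
  uniform ancestral distribution; nested levels of the hierarchy (demes
  under a drifted pool) realize slightly smaller divergence.
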