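# Methods

`localadapt` implements the analysis chain of a landscape-genomics study of
local adaptation in a range-edge forest tree: common-garden evidence for
local adaptation, partitioning of genomic variance among climate, geography
and neutral ancestry, multivariate genotype–environment genome scans with
and without structure correction, and projection of the detected adaptive
variation across a climate grid.  This note records the models, the choices
that were genuinely open, and what the synthetic validation does and does
not demonstrate.

## Constrained ordination

Redundancy analysis (RDA) is computed as a PCA of the fitted values of a
multivariate least-squares regression of the response matrix `Y` on
predictors `X`.  `Y` (locality allele frequencies) is centred and never
standardized; `X` is standardized internally.  Inertia is defined as the
sum of squared centred values (vegan reports the same quantities divided by
`n − 1`; proportions are identical, and a unit test cross-checks the
eigenvalues against `vegan::rda`).  For a partial RDA both `Y` and `X` are
first residualized on the standardized conditioning matrix.  Least squares
uses an SVD with an absolute singular-value cutoff (`1e-8·√n`) so predictor
directions annihilated by the conditioning step cannot resurface as
numerical noise.  Axis orientation is fixed by making the largest-magnitude
loading on each axis positive.

Significance uses free permutation of response rows (residual permutation
under the reduced model for partial RDA), `p = (1 + #{perm ≥ obs}) / (1 +
n_perm)`, 999 permutations by default.

Variance partitioning fits the full model `F ~ climate + geography +
ancestry` and the three pure models, each conditioned on the other two
groups; confounded inertia is `full − Σ pure` and unexplained is `total −
full`.  Geography is proxied by the first three dbMEMs (distance-based
Moran's eigenvector maps) of the locality coordinates, with the truncation
threshold set to the longest minimum-spanning-tree edge — the smallest
value that keeps the locality graph connected.  Ancestry is proxied by
locality-averaged scores on the first two axes of a genetic PCA of
mean-imputed, centred genotype dosages.

## Genome scans

**RDA scan.**  Locus loadings on the first `K` constrained axes (default
`K = 2`, covering the two planted gradients; a scree of eigenvalues is
available from the fitted model) are scored by squared Mahalanobis distance
from the loading-cloud centre, using the classical covariance estimator by
default (minimum covariance determinant optional).  Distances are rescaled
by the genomic inflation factor `λ = median(D²)/median(χ²_K)` and converted
to upper-tail `χ²_K` p-values.  On null data (no genotype–environment
association) λ falls in [0.8, 1.2] and the p-values pass a
Kolmogorov–Smirnov uniformity test.

**Random-forest scan.**  Per locus, a random-forest regression of locality
frequencies on the 11 climate variables; the statistic is the out-of-bag
R², truncated below at zero.  The forest (CART trees on bootstrap samples,
`mtry = ⌊p/3⌋`, minimum node size 5) is implemented in numba because
general-purpose implementations carry ~0.2 s of per-model overhead at this
size, which is prohibitive for a 50 000-locus scan; behaviour is validated
against scikit-learn's `RandomForestRegressor` OOB score.  The estimator
default is 500 trees; the full-scale validation runs use 100 trees (the
enforced minimum), which keeps a two-scan run of 50 000 loci near seven
minutes on one CPU at an acceptable increase in OOB noise.

**Structure correction.**  The RDA scan conditions on the locality scores
of genetic PC1–2.  The random-forest scan instead runs on whitened
frequencies: per locus, frequencies are centred and scaled by
`√(p̄(1−p̄))`; the locality × locality covariance Ω of these standardized
frequencies is estimated across loci with ridge shrinkage toward its
diagonal (default weight 0.1) and the standardized matrix is premultiplied
by the inverse Cholesky factor of Ω.  Because each locus is centred with
the across-locality sample mean, the standardized matrix is exactly
zero-sum over localities: Ω is structurally rank `n − 1`, one eigenvalue of
the whitened covariance is pinned at zero, and the whitening property is
therefore assessed on the non-degenerate spectrum (all remaining
eigenvalues within 0.1 of one on a block-structured fixture with shrinkage
0.01).  This moment estimator stands in for MCMC-based Ω estimates used
with count data; it is a point estimate, not a posterior.

**Outlier selection.**  Per scan, the `⌊q·N⌋` largest statistics (default
`q = 0.002`, i.e. the top 0.2%; ties at the cutoff broken by ascending
locus index for determinism); the candidate set keeps loci found by at
least `m = 2` of the scans.

## Transfer functions

Climate transfer distance is the Euclidean distance between a seed source's
and a garden's climate in the full principal-component space of the jointly
standardized source + garden climate table — identical to the distance
between z-scored climate vectors and therefore invariant to affine
rescaling of any raw variable.  Family trait values are BLUPs from
`height ~ 1 + (1|bed-rack) + (1|family)` fitted by REML per garden
(statsmodels `MixedLM` with variance components; documented fallback to raw
family means if the optimizer fails, and to the intercept if the trait is
constant).  Locality values are unweighted means of member-family values,
and transfer functions are unweighted OLS fits of locality value on
distance (linear) or distance and distance² (quadratic), reporting R² and
the p-value of the highest-order term.

## Adaptive landscape

The adaptively-enriched RDA is an ordinary RDA of candidate-locus
frequencies on the climate table.  The per-cell adaptive index is the
projection of a standardized climate grid onto the constrained axes using
the axis regression coefficients on the standardized predictors, so a cell
with the climate of a training locality receives exactly that locality's
fitted site score; the index is linear in standardized climate by
construction.  A per-axis min–max rescaled copy in [0, 1] matches the
conventional map legend; a climatically constant grid is flagged
degenerate.  Candidate loci are clustered into modules by k-means
(k-means++ with 50 restarts, fixed seed) on the absolute loadings of the
first two axes — absolute values make the assignment invariant to axis sign
flips and to the arbitrary allele coding.  For cline summaries, loci whose
loading on the module's dominant axis is negative are polarized
(`p → 1 − p`) so that module-mean frequencies aggregate coherently, and the
locality means are fitted with a four-parameter logistic (lower and upper
plateau, slope, inflection) via nonlinear least squares; the slope's
initial sign is taken from the empirical trend because the lo/hi-swap and
slope-sign parameterizations are exchangeable.  Confidence intervals are
delta-method intervals from the fit covariance.

## Trait association

Per candidate locus and garden: `height ~ genotype` (fixed, dosage 0–2,
the mother tree's genotype) with a source-locality random intercept, REML.
The semi-partial R² is defined as `β̂²·Var(g) / (β̂²·Var(g) + σ²_locality +
σ²_residual)`; with zero locality variance this reduces to the classical
R² of the genotype term (unit-tested).  Candidate and background R²
distributions are compared with a two-sided Wilcoxon–Mann–Whitney test
(normal approximation with tie correction).

## Gene annotation

GFF3 genes (parsed with gffutils) are matched to point loci
(`contig:pos`, 1-based): containment beats proximity; within-gene loci are
exonic or intronic from the gene's exon features (a gene without exon
records counts as exonic throughout); otherwise the nearest gene with a gap
strictly below 5 kb is assigned, labelled upstream/downstream relative to
the gene's strand, with equidistant ties broken by lower gene start and
flagged.  Distances are measured to gene bounds, not transcript bounds.
Synonymous/nonsynonymous classification is out of scope — it requires
transcript sequence, and the category set deliberately stops at
exon/intron/flank/intergenic.  Term enrichment is a hypergeometric
upper-tail test per term with Benjamini–Hochberg FDR.

## Synthetic landscape generator

The generator is first-class, tested code; its defaults are the conditions
under which the package is validated.

* **Geography.**  64 localities on a latitudinal transect (35–47° N) with
  jittered longitudes and elevations drawn uniformly from 0–1500 m,
  independent of latitude.  Three gardens sit south, mid and north of the
  gradient.
* **Climate.**  Each of the 11 variables is an affine function of latitude
  and elevation plus Gaussian noise, with coefficients chosen to give
  realistic ranges (e.g. degree-days below 0 °C rising from ~300 in the
  south to ~1500 in the north; extreme maximum temperature driven mostly by
  elevation).  Latitude-driven variables are strongly mutually collinear by
  construction — that collinearity is the phenomenon under study, not a
  nuisance.
* **Neutral loci** (49 900 by default) follow a serial-founder random walk
  along the expansion order: each daughter frequency is the parent plus
  `N(0, 0.02²)`, clipped to [0.01, 0.99] to avoid fixation (which also
  keeps loci polymorphic enough to survive a 10% MAF filter).  A per-locus
  drift bias (`drift_alignment`, default 0.25) aligns part of the walk with
  the expansion direction; raising it monotonically increases the
  confounded fraction reported by variance partitioning, which is verified
  at three settings.  Under the defaults neutral PC1 correlates with
  latitude at |r| > 0.9.
* **Clinal loci** (60) follow a logistic cline in degree-days below 0 °C
  with steepness 0.02 per degree-day, inflection 700 ± 25 (jittered per
  locus), random polarity, plus one drift step of noise — adaptive signal
  strength is therefore controlled solely by the steepness.  **Threshold
  loci** (40) switch between plateau frequencies 0.15 and 0.85 across an
  extreme-heat threshold (30.5 °C), random polarity, same drift noise.
* **Sampling.**  340 mother trees (families) are distributed round-robin
  over localities; dosages are `Binomial(2, p)` draws.  All downstream
  analyses run on locality frequencies re-estimated from these mother
  trees, so the scans face realistic binomial sampling noise
  (5–6 trees/locality), not the generating frequencies.
* **Common garden.**  340 families × 5 blocks × 3 gardens × 1 seedling =
  5100 seedlings.  Height growth = 25 cm baseline − 0.5·(transfer
  distance)² + genotype effects + family (sd 2 cm) + bed-rack (sd 1 cm) +
  residual (sd 3 cm), truncated at zero; 2% of seedlings die and score
  zero.  Ten effect loci are hosted on drift-structured loci (the
  locality-level transfer penalty already expresses adaptation at the trait
  level, and clinal hosts would make single-locus effects statistically
  unidentifiable — they are mutually ~0.9 correlated at locality level).
  Effect sizes are calibrated by fixed-point iteration so each locus
  accounts for 2% of the total per-garden phenotypic variance, with the
  mortality inflation `(1−p)·V + p(1−p)·μ²` included analytically.
* **Reproducibility.**  One seed feeds named substreams (landscape,
  dosages, design, garden), so stages are independently reproducible and
  byte-identical across runs.

### What the synthetic validation shows — and what it does not

Passing recovery tests show that, under a landscape whose demographic
structure is strongly collinear with climate, the implemented scans rank
planted clinal loci above 49 900 structured neutral loci, that structure
correction trades those collinear true positives for robustness (corrected
scans recover at most as many clinal loci as raw scans, with little overlap
between the two candidate sets), and that the enriched ordination separates
the two planted modules and recovers the planted cline inflection within
10%.  The generator is deliberately minimal: allele-frequency walks instead
of coalescent or individual-based simulation, no linkage, no
missingness-by-depth structure, no spatially autocorrelated microclimate,
gardens drawn from the same climate surfaces as sources.  Recovery under
these conditions does not bound false-negative or false-positive rates on
real exome data.

## Problem sizes and numerical choices

The heavy validation runs use the full default landscape (50 000 loci, 64
localities, 5100 seedlings); random-forest scans there use 100 trees per
locus as noted above, and trait-association summaries use the 10 effect
loci against 20 neutral background loci.  Property suites run at small
sizes (50 random RDA instances, 200 permutation-test replicates, 10 null
scan replicates).  Numerical tolerances: RDA matches a brute-force oracle
to 1e-8; partition identities hold to 1e-6 relative; dbMEM orthogonality to
1e-10.  Degenerate inputs fail loudly: constant predictors, coincident
coordinates, monomorphic loci in the whitener, all-identical loadings in
clustering, and rank-deficient transfer designs each raise informative
errors rather than propagating NaNs.
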