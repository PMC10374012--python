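# Methods

## The model

`metstab` analyses balanced multi-environment trials (MET): the same g
genotypes grown at e locations with r replicates in a randomized block
design. The cell means Ȳ_ij obey the two-way model with multiplicative
interaction

    Ȳ_ij = μ + g_i + e_j + Σ_n λ_n γ_in δ_jn + ε_ij ,

where μ is the grand mean, g_i and e_j are centered additive genotype
and environment effects, and the doubly-centered interaction residual
Z_ij = Ȳ_ij − Ḡ_i − Ē_j + μ is decomposed by SVD into interaction
principal component axes (IPCA) with singular values λ_n and orthonormal
score vectors γ_n (genotypes), δ_n (environments).

### AMMI

`joint_anova` computes the combined ANOVA on the replicate scale:
SS(ENV) = r·g·Σ(Ē_j−μ)², SS(GEN) = r·e·Σ(Ḡ_i−μ)², SS(G×E) = r·ΣZ².
`ammi_decompose` retains all min(g, e) axes; the trailing axis of a
doubly-centered matrix is the zero axis and is reported as such, so
SS(PCn) = r·λ_n² sums exactly to SS(G×E). IPCA significance uses Gollob
degrees of freedom df_n = g+e−1−2n with F ratios against the pooled
within-cell residual (df = g·e·(r−1) when replicates are the error
unit). Percentages of the main rows use SS(GEN)+SS(ENV)+SS(G×E) as the
denominator; PC rows are percentages of SS(G×E), reported plain and
cumulative.

Known limitation (tested, not hidden): the Gollob F-test is liberal
under an additive null. r·λ_1² is the largest eigenvalue of an
(approximately) Wishart matrix, whose expectation well exceeds
df_1·σ²; Monte Carlo puts the true size of a nominal 5% PC1 test near
0.19 at g=8, e=5, r=3 and near 0.34 at g=16, e=6. The package keeps the
Gollob convention because it is the one fixed by the reproduced
analysis; resampling-based df systems are out of scope.

### GGE

`gge_decompose` centers the matrix by environment means (centring = 2,
no transform, no scaling) and takes the SVD, so genotype main effect
and interaction are analysed jointly. The default singular value
partition is row-metric preserving (genotype scores U·Λ, environment
scores V), matching the convention of the reproduced study; column-
metric and symmetric partitions are selectable. All geometry uses the
first two axes:

* **AEA** — the unit direction of the mean environment score vector,
  oriented so the highest-mean genotype projects positively. Genotype
  projections on it proxy mean performance; the orthogonal "AEC"
  distance proxies instability.
* **Ideal genotype** — the point on the AEA at the best observed
  projection (maximum for higher-is-better traits; minimum for
  lower-is-better ones such as phytic acid, controlled by
  `trait_direction` rather than by flipping the axis, so coordinates
  stay comparable across traits).
* **Environment evaluation** — vector length (discriminativeness) and
  cosine of the angle to the AEA (representativeness). The
  "desirability" composite multiplies min-max-normalized length by the
  cosine; the source analysis cites such an index without defining it,
  so this formula is our documented interpretation and is excluded from
  quantitative reproduction claims.
* **Which-won-where** — convex hull of genotype scores; because the
  winner for an environment maximizes a linear functional, sector
  boundaries are the lines through the origin perpendicular to hull
  edges, and environments sharing a winning vertex form a
  mega-environment. Projection ties break lexicographically.

### Bootstrap confidence limits

Replicates are resampled with replacement within each cell, cell means
and the GGE SVD recomputed, and each draw's stacked 2-D scores aligned
to the full-data scores by orthogonal Procrustes rotation (the SVD is
only defined up to rotation/reflection; without alignment percentile
intervals are meaningless). Percentile limits are taken per coordinate.

Known limitation: with r replicates the bootstrap variance of a cell
mean is deflated by (r−1)/r. At the trial's r = 3 this gives nominal
95% intervals a true per-coordinate coverage of about
2Φ(1.96·√(2/3))−1 ≈ 0.86, which our Monte Carlo confirms (≈ 0.85 at
g=8, e=5, σ=2, B=200). No inflation factor is applied; the plain
percentile recipe is kept deliberately and the undercoverage is
documented here and exercised by the test suite.

### Heritability

Per location, a genotype × block ANOVA yields MS_G and MS_E (blocks
removed by design and excluded from the phenotypic denominator), and

    σ²_g = max(0, (MS_G − MS_E)/r),   H² = σ²_g / (σ²_g + σ²_e/r),

clamped to [0, 1]. The entry-mean basis (error variance divided by r)
is used because selection among lines acts on genotype means; the
0.94–0.99 magnitudes reported for this trial are only attainable on
that basis. Known limitation: the plug-in ratio has a downward Jensen
bias, about −0.02/−0.055/−0.016 at true H² = 0.3/0.6/0.9 with 16
genotypes and r = 3 (independent direct simulation); estimates at
intermediate heritability are mildly conservative.

### Correlations and clustering

Environment-environment association is Spearman rank correlation
between environment columns over genotypes (average ranks for ties,
two-sided p); trait-trait association uses genotype means. Dendrograms
use Ward linkage on Euclidean distances via the standard
Lance-Williams recursion (scipy); tests verify the merge heights
against a hand-rolled recursion.

## The packaged fixture

`lentil_fixture()` returns the cell means of a published lentil
biofortification trial: 16 Indian cultivars × 6 locations (Delhi,
Kanpur, Sagar, Sehore, Samastipore, Sabour), three traits — grain Fe
and Zn (mg/kg) and phytic acid (g/100 g dry weight) — with r = 3
replicates. Values are transcribed at the printed 2-decimal precision;
replicate-level plots were not published, so the fixture is mean-level
and operations that need a residual stratum (F tests, heritability,
bootstrap) require replicate data or an explicit residual.

Transcription precision matters for reproduction tolerances: sums of
squares recomputed from 2-dp means match the published replicate-level
ANOVA to ≲0.01% for large SS but can deviate by ~0.6% for the smallest
one (phytic-acid environment SS ≈ 4.2 on a squared g/100 g scale), and
summary statistics computed by the original analysis from unrounded
data can differ in the second decimal. The test suite asserts the
strict tolerances and leaves the genuinely unreachable cases failing
rather than widening bands.

Some rankings read off the published biplot figures are not implied by
the printed cell means under any centring/SVP convention we tried
(environment-centered, grand-centered, genotype-centered,
double-centered, column-scaled; row/column/symmetric partitions) — for
example the Zn ideal-genotype call names a line whose printed mean is
below the grand mean, and the first-axis share of the Fe GGE
decomposition computes to 49.4% against a reported 62.6%. Those
figures evidently derive from the unpublished replicate-level data.
The package computes everything from the printed means and reports the
discrepancies instead of tuning toward the figure claims.

## Synthetic data

`synthetic.random_config` / `generate_met` draw balanced replicate-level
trials from the generating model with known μ, effects, low-rank
interaction (Haar-random centered orthonormal score matrices; columns
ordered by descending λ with the leading sign of each genotype column
made positive, matching the decomposition's sign policy so recovery is
comparable without alignment) and i.i.d. Gaussian plot error.
Defaults mirror the lentil Fe trial: g=16, e=6, r=3, μ=75 mg/kg,
additive effect SDs 7 mg/kg, interaction singular values (35, 25) on
the cell-mean scale, plot-error SD 2 mg/kg (entry-mean H² ≈ 0.97,
comparable to the reported per-location estimates).

What the generator does not emulate: spatial field trend, missing
plots, non-Gaussian error, multi-year structure, or correlated traits.
Passing recovery tests therefore demonstrate correctness of the
estimators under the stated model, not robustness to field
pathologies.

## Numerical choices

* Sample (n−1) variances throughout; the published summary rows are
  reproduced only under this divisor. The published "SD(E)" row equals
  SD/√n (the standard error of the column mean) and is exposed as `se`.
* SVD sign policy: first nonzero entry of each genotype score column
  positive; the matching environment column flips with it. Tied
  singular values keep the LAPACK axis order and are documented as
  non-unique; recovery tests under ties compare subspaces, not vectors.
* Degenerate inputs: constant matrices raise a degenerate-geometry
  error before any biplot op; collinear genotype scores refuse the
  which-won-where partition; a zero-length environment vector flags its
  representativeness as undefined instead of dividing by zero.
* Monte-Carlo problem sizes in the test suite (g=8, e=5 for null and
  coverage studies; 500 trials for recovery grids; B=200 bootstrap
  draws) were chosen as the smallest sizes at which the binomial/CLT
  error of the check is well below its tolerance.
* Negative variance components truncate at zero, so MS_G = MS_E maps
  to H² = 0.
* All randomness flows through `numpy.random.default_rng(seed)`; every
  CLI entry point takes an explicit seed and outputs are byte-stable
  under a fixed seed (matplotlib SVG hash salt pinned, no embedded
  dates).
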