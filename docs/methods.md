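# Methods

## Study design the package models

The cohort contrasts four groups of Holstein cattle sharing genotypes
across breeding methods: perinatal clones (foetuses and neonates that
died with hepatic lesions), adult clones from the same donor cells,
and age-matched perinatal/adult controls bred by artificial
insemination. Methylation is measured by MeDIP hybridised against input
DNA on a promoter tiling array; the analysis works from *binary*
per-probe enrichment calls rather than continuous ratios, which makes it
robust to per-sample scale differences at the cost of discarding
intensity information.

## Enrichment calls and regions

A probe is called enriched for a sample when the mean of its available
replicate log2(MeDIP/input) values is at least `threshold` (default 1.0,
i.e. two-fold) with at least `min_replicates` (default 2) observed
replicates; otherwise the call is missing. A probe is enriched in a
*condition* (one of the four groups) when strictly more than half of the
group's non-missing calls are 1 — the strict inequality is the
tie-break, so 2-of-4 is *not* enriched.

Regions of interest are built by anchor-extension over probes enriched
in at least one condition: consecutive anchors on a chromosome are
chained while `next.start − prev.end ≤ max_gap` (default 500 bp), and
chains with fewer than `min_probes` (default 3) anchors are dropped.
Coordinates are 0-based half-open; regions span first-probe start to
last-probe end. The operation is idempotent and never assigns a
non-anchor probe to a region.

## DMR inference

Within a region, calls are modelled as independent Bernoulli draws with
`logit p = β0 + β_age·1[adult] + β_clone·1[clone]`. The interaction is
deliberately excluded: with 26 animals, two effect parameters is the
robust choice. Because all probes of a sample share covariates, the
likelihood collapses onto success/trial counts of the four design cells.

* The full model is maximised by bounded L-BFGS-B (|β| ≤ 15, analytic
  gradient). The bound is the numerical device that keeps perfectly
  separated regions — common when an effect saturates — finite and
  deterministic; at |logit| = 15 the per-call probability is within
  3·10⁻⁷ of 0/1, so the clipped optimum is indistinguishable from the
  supremum at the tested resolution.
* The two reduced models are saturated on their single binary factor and
  are solved in closed form (cell proportions).
* LRT statistics are clipped at 0 and referred to χ²(1). Regions whose
  observed calls are constant are declared untestable (p = 1) rather than
  fitted, avoiding separation pathologies with no information.
* BH step-up is applied separately to the age family and the cloning
  family across all tested regions; classification at adjusted p < 0.05.

Probe-within-region dependence is ignored (an independence working
likelihood). Under the generator's model — truly independent probes —
null p-values are uniform (tested by KS); on real tiling arrays,
correlated probes would make the tests anti-conservative, which is the
main caveat when transferring conclusions.

Missing calls are excluded from the likelihood. In the per-individual
summary `P_ri = 100·E_ri/T_r` they count as *not enriched* while `T_r`
stays fixed, keeping `P_ri` comparable across individuals; a
`rescale_missing` flag divides by the observed probe count instead.

## Ordinations

**MCA** is correspondence analysis of the indicator matrix: with J
observed categories over Q variables, total inertia is J/Q − 1 and
variance percentages are raw eigenvalue shares (no Benzécri/Greenacre
adjustment). Before MCA, observed categories carried by fewer than four
animals are merged into the *adjacent severity grade, preferring the
next-higher observed grade, else the next-lower*, iterating rarest-first.
Preferring the higher grade keeps a rare present-grade from collapsing
into the absent grade, and on the packaged lesion table reproduces the
merged grades S1S2, C1C2, A2A3 and I1I2. Unobserved categories produce
no indicator column (so a merge with an unobserved grade is a relabel).

**Rank-PCA** replaces each variable by average-tie ranks, then performs
PCA on the correlation matrix; the result is invariant to any strictly
monotone transform of the inputs, which homogenises the very skewed
fatty-acid percentage distributions.

**MFA** centres and unit-scales every variable (population SD), divides
each set's variables by √λ1 of that set's own PCA, and runs a global PCA
(eigenvalues via SVD with 1/n weighting). The coordinate of active set j
on dimension s is `(1/λ1_j)·Σ_k cor²(x_k, F_s)` over the set's
variables; it lies in [0, 1] and sums over sets to λ_s. A categorical
illustrative variable is projected as η² (between-group over total sum
of squares) of each global axis — the adopted contract for the group
coordinate, which likewise lies in [0, 1]. Complete cases are taken per
analysis, not globally.

Numerical conventions: every axis is oriented so its largest-magnitude
loading is positive; in MFA, eigenvalues tied to within 10⁻⁹ (which
happen systematically for mutually orthogonal sets, since weighting
normalises every set's first eigenvalue to 1) have their basis rotated
to align with the variable sets in declaration order. Both are pure
tie-breaks for reproducibility across linear-algebra backends.

**Axis screens and ellipses.** Variables are screened against an axis by
Pearson correlation (axis scores are continuous constructs) with
two-sided t p-values and no multiplicity correction — the screen is
descriptive, feeding the downstream Spearman confirmation. Group
ellipses are confidence ellipses of the *mean*: centre at the centroid,
dispersion = sample covariance / n_g, scaled by the χ²(2) quantile at
0.95.

## Permutation tests and summaries

The two-sample statistic is the difference of group means, two-sided.
With at most 200,000 label assignments the null is enumerated exactly
(p = proportion of assignments at least as extreme, a valid exact test);
otherwise Monte-Carlo with the add-one estimator
`p = (1 + #{|t*| ≥ |t|})/(n_perm + 1)` (default 100,000 draws), which is
never zero. The stratified variant permutes labels only within strata
with per-stratum group counts fixed, conditioning out e.g. the
pre/postnatal stage; with a single stratum it reproduces the plain test
exactly, including the random stream. Extremeness comparisons use a
10⁻¹² absolute guard so float ties count as ties.

Spearman correlation is Pearson on average-tie ranks with the t
approximation (n − 2 df), pairwise deletion of missing pairs, minimum 3
pairs. Morphometric summaries are per animal × parameter mean and CV
(sample SD / mean, n − 1); CV is withheld for non-positive means since
all measured scales are positive.

Fatty-acid features are derived from the `C<carbons>:<bonds>ω<family>`
nomenclature: 0/1/≥2 double bonds give SFA/MUFA/PUFA, ω3/ω6 totals
cover those families, and six ratios are computed per lipid fraction,
with zero denominators yielding missing values. The core 13-FA panel in
two fractions gives 24 variables per fraction (48 total) for the MFA FA
set, and 22 variables for the rank-PCA after removing the four
cross-fraction near-duplicates (PL C18:1ω9, NL C20:3ω6, PL C22:4ω6,
NL C20:5ω3).

## Synthetic cohorts

`simulate_enrichment` inverts the inference model: calls are Bernoulli
with the same two-factor logit, effects zeroed outside planted DMRs.
Defaults are the study conditions used throughout the tests: 26 animals
(4 perinatal AI, 7 perinatal clones, 8 adult AI, 7 adult clones), 500
regions of 20 probes, baseline logit −1, age effect +2, clone effect −2,
10% age- and 10% cloning-DMRs (disjoint unless an overlap fraction is
set). Probes are 60 bp every 100 bp within a region; inter-region gaps
are 10× the default `max_gap`, so anchor-extension of the true
membership mask recovers the planted regions exactly — a layout
guarantee. Problem sizes (500 regions, 100k permutations, 2,000
calibration replicates) were chosen as the smallest at which the checked
properties are statistically sharp.

What the generator does *not* emulate: two-colour intensity artefacts,
dye-swap structure, CpG-density-dependent MeDIP efficiency, spatially
correlated probes, and realistic array layouts. Passing tests therefore
demonstrate correctness of the inference machinery under its own
assumptions, not performance on GEO data; in particular the region/DMR
counts of any real cohort are not reproduced here.

`simulate_phenotypes` draws each variable as group mean + coupling ×
(Pi_age or Pi_cloning) + Gaussian noise, renormalising FA fractions to
100%; group means follow the qualitative cohort patterns (glycogen-linked
cell size, nuclear heterogeneity in perinatal clones, elevated
C22:6ω3/C20:4ω6 in clones) with once-chosen liver-like magnitudes.

## Pipeline and provenance

`run_pipeline` chains the stages, persists every intermediate as TSV/CSV
with a provenance header (stage, master seed, config hash — the hash
excludes the output directory so runs into different folders compare
byte-identically), and writes a JSON report with counts, a
planted-vs-detected confusion matrix on synthetic runs, variance
fractions and permutation results. One master seed drives all stages
through fixed offsets. Note the pipeline's recovered regions are
*selected* by enrichment in at least one condition before testing; this
selection makes region-level p-values on recovered (as opposed to
planted) regions anti-conservative, which is visible in the report's
confusion matrix and is inherent to the regions-of-interest design.

## Known limitations

* Independence working likelihood across probes (see above).
* The enrichment-call rule (thresholded mean of replicate log-ratios) is
  a transparent, configurable stand-in for array-specific calling; all
  thresholds are exposed.
* MCA/MFA handle complete cases only; rows with missing cells must be
  dropped explicitly (the lesion table keeps its 6 unscored animals as
  NaN rows for transparency).
* Exact permutation p-values are discrete; at very small group sizes the
  achievable significance levels are coarse, which is a property of the
  test, not an implementation limit.
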