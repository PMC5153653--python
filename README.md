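# medipdmr

Differential DNA-methylation analysis for MeDIP tiling-array cohorts, with
multivariate integration of methylation and liver phenotype. The package
implements the analysis chain used to relate promoter methylation to
hepatic phenotype in cattle cohorts that contrast pathological perinatal
clones (somatic-cell nuclear transfer) with clinically normal adult clones
and age-matched controls bred by artificial insemination (AI) — a design
in which genotype is held constant, so phenotypic differences point at
epigenetic causes such as perinatal mortality risk.

## What it computes

**Region calling.** Per-probe log2(MeDIP/input) replicate ratios are
thresholded into binary enrichment calls; probes enriched in at least one
condition (the four age-class × clone-status groups, by strict majority)
seed an *anchor-extension* pass that chains nearby anchors (gap ≤ 500 bp,
≥ 3 probes) into regions of interest.

**DMR inference.** For each region *r* the probe × individual binary
calls are modelled as Bernoulli with

```
logit P(call = 1) = β0 + β_age · 1[adult] + β_clone · 1[clone]
```

(no interaction). Two likelihood-ratio tests compare the full model with
the age-only and clone-only reductions (χ², 1 df); Benjamini–Hochberg
adjustment across all regions (per test family) classifies each region as
an age-related and/or cloning-related DMR at α = 0.05.

**Per-individual summaries.** `P_ri = 100 · E_ri / T_r` is the percentage
of enriched probes in region *r* for individual *i* (*E_ri* enriched of
*T_r* probes); `Pi_age_i` and `Pi_cloning_i` average `P_ri` over the
age-related and cloning-related DMR sets and act as each animal's
methylation score for correlation with phenotype.

**Multivariate layer.** MCA of the severity-coded lesion table (rare
categories, < 4 animals, merged into the adjacent severity grade);
PCA on rank-converted fatty-acid percentages (correlation matrix);
MFA across the DMR / morphometry / fatty-acid variable sets, each set
scaled by the inverse of its first eigenvalue, with the animal group
projected as an illustrative variable (η² per dimension), axis–variable
correlation screens, and 95% confidence ellipses of group means.

**Group comparisons.** Exact or Monte-Carlo permutation tests on the
difference of group means (optionally stratified, e.g. by pre/postnatal
stage), Spearman correlations with pairwise deletion, per-animal
mean/CV morphometric summaries, and fatty-acid feature engineering
(family totals, ω3/ω6 and C22:6ω3/C20:4ω6 ratios, …).

A seeded generator (`simulate_enrichment`, `simulate_phenotypes`)
produces synthetic cohorts with planted DMRs and coupled phenotypes, so
the whole chain is testable without array data; the in-study lesion-score
table (36 animals, 7 lesion types) ships with the package.

## Worked example

```python
from medipdmr import (SimConfig, simulate_enrichment,
                      DifferentialMethylationModel,
                      load_lesion_fixture, merge_rare_categories, mca)

# MCA of the packaged lesion-score table (30 fully scored animals)
scores, meta = load_lesion_fixture()
print(mca(merge_rare_categories(scores.dropna())).summary())

# DMR inference on a synthetic cohort with planted effects
sim = simulate_enrichment(SimConfig(seed=1))
fit = DifferentialMethylationModel(sim.calls, sim.regions, sim.meta).fit()
print(fit.summary())
print(fit.pi_table().summary.head(4).round(2))
```

prints

```
MCA: 10 dimensions
  dim 1: eigenvalue 0.4945  (34.6% of variance)
  dim 2: eigenvalue 0.2480  (17.4% of variance)
  dim 3: eigenvalue 0.1859  (13.0% of variance)
  dim 4: eigenvalue 0.1450  (10.1% of variance)
  dim 5: eigenvalue 0.1246  (8.7% of variance)

Differential methylation: nested binomial-logit LRT
  regions tested:        500
  alpha (BH-adjusted):   0.05
  age-related DMRs:      51
  cloning-related DMRs:  54
  in both classes:       0

           Pi_age  Pi_cloning
animal_id
A01         28.53       27.96
A02         26.18       26.30
A03         28.14       28.70
A04         26.57       28.15
```

Dimension 1 of the MCA (≈ 35% of total inertia) is the axis that
separates animals with severe lesions — absent trabeculae (R2), marked
fibrosis (F3), steatosis (S1S2), anisocytosis (C1C2) — from the rest of
the cohort. In the synthetic run, 500 regions were planted with 10%
age-related and 10% cloning-related effects (log-odds ±2): the nested
tests recover them essentially completely at BH α = 0.05, and the Pi
columns give each animal's average enrichment over the two DMR sets.

The same stages are exposed as a CLI:

```bash
medipdmr simulate --seed 1 --out-dir run/
medipdmr regions --probes run/probes.bed.tsv --calls run/calls.tsv \
         --meta run/meta.csv --out run/regions.tsv
medipdmr dmrs --calls run/calls.tsv --regions run/regions.tsv \
         --meta run/meta.csv --out run/dmrs.tsv
medipdmr run --out-dir run/ --seed 1     # full pipeline + report.json
```

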