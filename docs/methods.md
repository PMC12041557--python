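# Methods

This note documents the statistical models, conventions, parameter defaults
and numerical design decisions implemented in `famscan`.

## 1. Phylogenetic model

**Tree.** A rooted ultrametric phylogeny with non-negative branch lengths in
time units. Internal representation is canonical: nodes stored in pre-order
with each node's children sorted by the lexicographically smallest tip label
in their clade, so identical trees always serialize to identical Newick
strings and all downstream outputs are byte-reproducible. Parsing is done
with dendropy; validation (single root, unique non-empty tip labels, branch
lengths present, ultrametricity within relative tolerance 1e-6) is ours.
Polytomies are accepted and, where an algorithm requires bifurcations,
resolved deterministically into zero-length bifurcations (first two children
joined first, in canonical order).

**Brownian covariance.** Under Brownian motion with rate σ², the trait (or
count) covariance between species i and j is σ²V_ij with V_ij the branch
length shared by the two root-to-tip paths, i.e. the depth of their most
recent common ancestor; V_ii is the root-to-tip distance. V is computed in
one post-order pass and is symmetric positive semi-definite by construction.

**Independent contrasts.** Felsenstein's pruning recursion: each internal
node contributes a contrast (x_left − x_right)/√(v_left + v_right), with the
node's value the precision-weighted average of its children and its effective
branch length inflated by v_left·v_right/(v_left + v_right). The contrast
correlation is computed through the origin (contrast signs are arbitrary) and
tested with t = r·√(df/(1 − r²)) on **df = n_contrasts − 1** degrees of
freedom — one degree is spent on the through-origin slope; this is the
convention used throughout. Monte-Carlo checks confirm the nominal type-I
rate (0.047–0.053 over 2,000 replicates).

## 2. Per-family PGLS scan

For family f with count vector y_f over n species, design X = [1, traits]:

- β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y, computed by Cholesky whitening (L⁻¹X, L⁻¹y with
  V = LLᵀ) for numerical stability; all families are fit in one batched
  matrix product.
- σ̂² (reported) is the ML estimate: whitened RSS / n. Standard errors use
  the unbiased scale RSS/(n − k), so on a star phylogeny (V ∝ I) the t, p
  values coincide exactly with textbook OLS — verified against statsmodels
  to 1e-8.
- Effect size: **r = t/√(t² + df)**, the t-to-partial-correlation
  conversion, bounded in (−1, 1) and signed like the slope. This is the
  definition used everywhere a per-coefficient effect size is reported.
- Multiple testing: Benjamini–Hochberg step-up per predictor across all
  scanned families (statsmodels `fdr_bh`). A family is called *expanding*
  (resp. *contracting*) for a predictor when q < α and r > 0 (resp. < 0);
  α defaults to 0.05 on adjusted values.
- Families with zero count variance over the analysis species are skipped
  and logged; the scan never silently drops data otherwise.

Note that BH adjusted values are **not idempotent** under re-adjustment
(counterexample: bh([1.0, 0.25]) = [1.0, 0.5], bh([1.0, 0.5]) = [1.0, 1.0]);
the implemented procedure is pinned instead by a brute-force step-up oracle
q_(i) = min_{j≥i} p_(j)·m/j, monotonicity in p, q ≥ p, clipping at 1, and
the fact that re-adjustment never decreases any q.

**Exact fits.** When a family's counts lie exactly in the design's column
space, the whitened residual is pure round-off. RSS values below 1e-24 times
the squared data norm are snapped to zero, giving se = 0 and then t = 0 for
a zero coefficient or ±∞ (r = ±1, p = 0) for a nonzero one, rather than
t = noise/noise.

**Degenerate-design guard.** Condition number of XᵀV⁻¹X above 1e12 raises a
collinear-design error instead of returning garbage coefficients.

**Total-count control.** The same GLS applied to per-species total gene
counts guards against a genome-wide gene-number trend masquerading as
family-specific expansion.

## 3. Trait preprocessing

- Completeness filter: species with genome completeness strictly greater
  than 0.80 are retained.
- Family filter cascade (order-independent conjunction per family): nonzero
  count variance; maximum count ≥ 3 in at least one species; nonzero count
  in at least ⌈0.8·n_species⌉ species.
- Traits are log10-transformed (MLSP, body mass, brain mass, gestation time,
  age at sexual maturity); **relative brain size** is the residual of an
  ordinary least-squares regression of log10 brain mass on log10 body mass
  across the analysis species. The residualization is deliberately
  non-phylogenetic: it defines the trait, while phylogeny enters through the
  regression's error structure.

## 4. Enrichment

**GO lifting.** A family carries a term when any member gene does (set
union). Term-size filtering (default: ≥ 50 families, or ≥ 200 genes for the
gene-level variant) happens *after* lifting — a term on 60 genes spread over
40 families correctly fails a 50-family threshold.

**Resampling Z-score.** For a focal set of k families, each term's observed
annotated proportion is compared with its mean and standard deviation over
1,000 uniform samples of size k drawn *without replacement* from the
background; z = (obs − mean)/sd, two-sided standard-normal p, BH across
terms; direction (over/under) reported separately. An empirical tail
p-value from the resampled null is reported as a diagnostic column.
Degenerate terms (resampling sd = 0, e.g. a term on every background
element): p = 1 when the observed proportion equals the null mean, else the
1/n_samples resolution floor, flagged. Because the null proportions are
multiples of 1/k, any sd below 1e-12 is round-off on a constant and treated
as zero.

Seed-to-seed stability: at 1,000 samples the estimated null sd itself has
≈ 2.2% relative noise, so z varies across seeds by ≈ 0.032 ⊕ 0.022·|z| —
below 0.15 absolute for moderate |z|, and proportionally (< 8% relative) for
strong signals with |z| ≈ 12. Null calibration is checked per repetition
with Kolmogorov–Smirnov at 1% (the resampled proportions have a lattice
support of spacing 1/k, so pooling thousands of p-values into a single KS
test would reject any correct implementation on discreteness alone).

**Gene-list overlap.** Pearson χ² (df = 1, no continuity correction) on the
2×2 table of list membership × focal membership, over a background
harmonized to the intersection of the study background with the list's own
background when one is supplied. Fold is log2(observed/expected) of the
in-list in-focal cell; any expected cell below 1 flags the result
unreliable.

## 5. Leave-one-out sensitivity

The reference is the full-data two-predictor scan (MLSP + relative brain
size). For each species: prune tree and data, re-run the scan **over the
reference family universe** (filters are not re-applied, so the family set
is held fixed), collect the MLSP-coefficient r values for families that were
significant in the reference scan, and compare them with the full-data r
values on the same families via Cohen's d (pooled-sd standardized mean
difference) and a two-sided Wilcoxon rank-sum test, BH-adjusted across
species. The two r vectors are treated as two samples; families degenerate
after removal are excluded pairwise. Exact Wilcoxon enumeration is used for
tie-free samples with combined n ≤ 12, otherwise the tie-corrected normal
approximation with continuity correction.

Interpretation caveat: dropping any species changes df and the design
inverse, so every LOO r vector is coherently shifted by that species'
genuine information share; "no influential species" is a statement that
those shifts are small against the between-family spread of r, not that the
vectors are identical.

## 6. Synthetic-data generator

What it emulates: the statistical structure of the real inputs — an
ultrametric mammal phylogeny (pure-birth Yule tree rescaled to unit height),
Brownian-correlated life-history traits with realistic raw magnitudes,
gene-family counts a stated fraction of which depend linearly on a trait at
a controlled effect size, GO terms with planted over-representation among
the associated families, curated gene lists with planted overlap, per-gene
expression with a planted shift, completeness scores with low-quality decoy
species, and missing trait entries. What it does not emulate: sequences,
birth–death gene gain/loss dynamics, or any real database's actual values.

Key defaults (`SimConfig`): 46 species, 4,000 families, 5% associated,
target effect r = 0.6, count baseline 8, Brownian count noise sd 1.5, trait
cross-correlations (MLSP with: body 0.6, relative brain 0.7, gestation 0.7,
maturity 0.8), 60 GO terms of which 5 planted with odds multiplier 8, 10% /
30% missingness in gestation / maturity, four decoy species with
completeness in (0.5, 0.8).

**Traits.** Latent matrix T = L_V Z L_Cᵀ (Z standard normal) gives Brownian
covariance across species and the target correlation matrix across traits;
latent axes are mapped to log10 scales with fixed offsets/spreads (e.g.
MLSP 10^(1.1 + 0.45·z) years) and brain mass is built allometrically as
log10(brain) = 0.75·log10(body) − 1.3 + 0.3·z_resid so that residualization
recovers the latent relative-brain axis. The rate multiplier scales L_V
outside the jittered Cholesky factor, so rate 0 collapses variation exactly.

**Counts and effect-size calibration.** Counts are rounded, zero-clipped
Gaussians y = baseline + b·(x − x̄) + σ·L_V z (a Poisson mode exists as a
misspecification stress test). The slope b for a target effect r inverts
r = t/√(t² + df) to t* = r·√(df/(1 − r²)) and sets b = t*·σ·√(A₁₁) with
A = (XᵀV⁻¹X)⁻¹ — exact for the latent Gaussian. Integer rounding perturbs
t in a tree-dependent way that admits no closed form: rounding error is
approximately white on long branches but behaves like extra Brownian noise
between near-identical sister values on short branches (the difference of
two roundings of values δ apart has variance ≈ |δ|, not 1/6). The analytic
slope is therefore refined by **pilot simulation**: two multiplicative
corrections b ← b·t*/mean(t̂), each estimated from 400 pilot families pushed
through the exact count-generation path. Calibration verified across tree
draws: median recovered r 0.59–0.60 for target 0.6; power 0.97 and FDR
0.015 on the 5% mixture; null type-I rate 0.040–0.059 at nominal 0.05 (the
residual tree-to-tree wobble is the rounding misspecification above).

A consequence worth noting for homogeneity constructions: at the default
noise sd 1.5, a tree with a near-zero-length cherry (e.g. pendant length
6e-4) lets integer rounding dominate that one contrast, coherently
depressing every family's t; dropping either sister species then shifts the
whole r vector (LOO |d| ≈ 0.45). Data intended to have *no* influential
species must therefore keep σ² well above the rounding variance 1/12 and
the baseline far from the clipping boundary (tests use noise sd 5, baseline
20), which restores |d| to the leverage-only level (≲ 0.15).

**Annotations.** Terms attach to families with base probability 0.15,
multiplied on the odds scale by `enrichment_odds` for planted terms on
associated families; term assignments are pushed down to a random non-empty
subset of member genes so gene-to-family lifting recovers the structure.
Gene lists: one with planted overlap with associated-family genes, one null.

## 7. Determinism

All generators take integer seeds and derive sub-stream seeds from a master
`numpy` Generator; the pipeline writes a seed-stamped report and its output
directory hashes identically across re-runs with the same inputs and seed.
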