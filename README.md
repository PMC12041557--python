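# famscan

A phylogenetic comparative-genomics toolkit that scans gene-family sizes for
associations with life-history traits — maximum lifespan potential (MLSP) and
relative brain size in particular — across a mammalian phylogeny.

## The scientific problem

Across mammals, species with long lifespans tend to have larger genomes in
specific places: particular gene families are systematically *expanded* (more
member genes) in long-lived lineages. Testing this family by family is a
comparative problem: species are not independent samples, because related
species inherit both their traits and their gene-family sizes from common
ancestors. Treating 46 mammals as 46 independent data points inflates false
positives badly.

`famscan` implements the standard remedy. For each gene family, the vector of
per-species gene counts *y* is regressed on one or more traits *X* by
**phylogenetic generalized least squares (PGLS)** under a Brownian-motion
model of evolution: errors are Gaussian with covariance σ²V, where V_ij is
the shared root-to-ancestor branch length of species *i* and *j* on an
ultrametric tree. The GLS estimator is

    β̂ = (XᵀV⁻¹X)⁻¹ XᵀV⁻¹ y

with t-tests on n − k degrees of freedom. Each coefficient is summarized by a
correlation-scale effect size r = t/√(t² + df), and a family is called
**expanding** (r > 0) or **contracting** (r < 0) when its Benjamini–Hochberg
q-value falls below α across the family-wide scan.

Around the core scan the package provides the full analysis loop:

- **phylo** — Newick I/O, tree pruning, the Brownian covariance matrix, and
  Felsenstein's independent contrasts for trait–trait correlations.
- **preprocess** — genome-completeness species filter (> 0.80), the
  three-part family filter (nonzero variance, max count ≥ 3, present in
  ≥ 80% of species), log10 trait transforms, and relative brain size as the
  residual of log-brain on log-body.
- **pgls** — `fit_gls`, the vectorized per-family scan, BH adjustment, and a
  total-gene-count control regression.
- **enrichment** — GO-term lifting from genes to families, resampling
  Z-score enrichment against equally sized background samples, and χ²
  2×2 overlap tests with curated gene lists.
- **robustness** — leave-one-out (LOO) refits of the two-predictor scan with
  Cohen's d and Wilcoxon rank-sum influence statistics, plus the
  expression/transcript-count group comparison.
- **synthetic** — a generator for the whole input bundle (Yule tree,
  multivariate Brownian traits, count matrices with planted effect sizes,
  annotations with planted enrichment, gene lists, expression tables) with
  ground truth, so every stage is testable at desk scale.
- **pipeline / cli** — a config-driven end-to-end runner with TSV outputs and
  a machine-readable JSON report.

## Worked example (Python API)

Simulate a 46-species world with 5% of 4,000 families planted at effect size
r = 0.6 against log-MLSP, then scan:

```python
import numpy as np
from famscan.synthetic import SimConfig, simulate_tree, simulate_traits, \
    simulate_family_counts
from famscan.preprocess import log10_traits, relative_brain_size
from famscan.pgls import scan_families

tree = simulate_tree(46, seed=11)
traits = relative_brain_size(log10_traits(simulate_traits(tree, seed=12)))
cfg = SimConfig(n_families=4000, frac_associated=0.05, target_effect_r=0.6)
counts, truth = simulate_family_counts(tree, traits["log10_mlsp"], cfg, seed=3)

scan = scan_families(counts, traits, tree, ["log10_mlsp"], alpha=0.05)
sig = scan.significant_families()
assoc = set(truth.index[truth["associated"]])
print("calls:", scan.call_counts())
print(f"power: {len(sig & assoc)/len(assoc):.3f}  FDR: {len(sig-assoc)/len(sig):.4f}")
print(f"median r (planted): {np.median(scan.effect_map().loc[sorted(assoc)]):.3f}")
print(scan.rows_for().head(3)[["family_id", "beta", "t", "p", "q", "r", "call"]]
      .to_string(index=False))
```

Output (deterministic for these seeds):

```
calls: {'expanding': 197, 'contracting': 0, 'none': 3803}
power: 0.970  FDR: 0.0152
median r (planted): 0.605
family_id      beta         t        p        q         r call
   F00001  0.452526  0.778628 0.440367 0.885219  0.116582 none
   F00002 -2.561654 -1.560874 0.125718 0.655141 -0.229054 none
   F00003 -1.912659 -2.734851 0.008961 0.156519 -0.381168 none
```

Of the 200 planted families, 194 are recovered at q < 0.05 (power 0.97)
with an empirical false-discovery rate of 0.015, and the median estimated
effect size among planted families is 0.605 against the target 0.6.

## Worked example (CLI)

```bash
famscan simulate --out data --seed 7 --set n_families=1200 --set frac_associated=0.1
famscan run --input-dir data --out results --seed 0 --set min_term_families=20
```

`results/report.json` then contains, stage by stage (real values from the
commands above):

- completeness filter: 46 of 50 species pass (> 0.80); the four low-quality
  decoys `X001…X004` are dropped;
- single-predictor MLSP scan: 117 expanding / 5 contracting / 1078 unchanged
  of 1,200 families;
- two-predictor scan (MLSP + relative brain size): 49 expanding for MLSP,
  47 shared with the single-predictor MLSP scan;
- GO enrichment: 6 of 60 terms significant — the planted terms;
- gene-list overlap: the planted-overlap list significant, the null list not;
- leave-one-out: 46 refits, max |Cohen's d| = 0.24, no influential species;
- expression comparison: expression level p = 4.7e-05, transcript count
  p = 1.2e-18 for the planted shift.

Per-family scan tables (`scan_*.tsv`), enrichment tables, the LOO table and
the expression comparison are written alongside the report.

## Reproduction

Everything is deterministic given seeds.

```bash
# full test suite (unit + property + acceptance), ~30 s on one CPU
python -m pytest -q

# acceptance report: headline quantities as JSON
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script reports, among others: null-scan type-I rate at
α = 0.05 (0.0705 for seed 1; 0.040–0.059 across other tree draws, nominal
0.05), PIC-correlation type-I rate (0.0465), median recovered effect size for
planted families (0.586 vs target 0.6), recovery power (0.97), empirical FDR
(0.049), maximum homogeneous LOO |Cohen's d| (0.065), planted-outlier
identification (1.0), and the planted gene-list overlap p (1.6e-13).

See `docs/methods.md` for the statistical methods, model assumptions,
parameter defaults, and the numerical design decisions (exact-fit detection,
degenerate-sd handling, and the pilot-simulation calibration of planted
effect sizes).
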