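# mesothresh

Threshold analysis of disturbance gradients in freshwater mesocosm
communities.

When terrestrial material (e.g. post-wildfire plant debris) washes into
ponds, microbial and zooplankton communities do not slide smoothly along the
loading gradient — they can cross into qualitatively new compositional
states. `mesothresh` implements the statistical machinery for locating and
testing such transitions in mesocosm experiments where a continuous
disturbance dose (grams of plant material, 0–400 g) is crossed with a
categorical treatment (burned vs unburned material) and repeated sampling
days, and exercises every stage against a synthetic experiment generator
with known ground truth. It is written for community ecologists and
microbiome researchers analysing dose–response mesocosm designs.

## What it computes

* **Sequential PERMANOVA** on Bray–Curtis dissimilarities
  (BC(x, y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ)): Type-I partition of the Gower-centered
  sum of squares over ordered terms (treatment, loading, time), pseudo-F per
  term, and p-values from free permutation of sample labels (999 by
  default), with restricted (within-mesocosm) permutation and exhaustive
  enumeration available.
* **Threshold scan**: one-term PERMANOVAs for every binary split
  "loading ≤ t vs > t" over observed loading values; the t maximising R² is
  the compositional threshold. A max-statistic permutation correction for
  the selection effect is available.
* **Ordination**: classical PCoA (eigendecomposition of −½·J·D²·J) and
  Kruskal NMDS (stress-1 minimised by isotonic regression + Guttman
  majorisation, PCoA-initialised), plus `envfit`-style vector fitting of
  environmental variables and genome traits with permutation R² tests.
* **Breakpoint models**: OLS on the hinge basis {1, x, (x−c)₊} with the
  breakpoint c profiled over a grid and refined by golden-section search,
  compared to the nested straight line by an F(2, n−4) test with the
  piecewise model selected when p < 0.01.
* **Community-weighted genome traits**: per-sample abundance-weighted means
  of genome size, coding-sequence count, growth rate (ln 2 / doubling time)
  and relative genomic plasticity (per-taxon mean difference between
  marker-gene and proteome dissimilarity to all other taxa).
* **Differential pathways**: pathway-level abundance (summed member-taxon
  counts), median-of-ratios normalisation, log2 fold change per SD of
  loading with permutation p-values, and the three-clause filter
  (p < 0.01, |log2FC| > 2, ≥ 5 member taxa).
* **Synthetic experiments**: a two-state Dirichlet-multinomial community
  generator (logistic state mixing at a planted threshold), hinge-shaped
  environmental responses whose nonlinearity decays over sampling days,
  host/detritus microbiomes as convex water/source mixtures, genome-trait
  tables with configurable state biases, and pathway incidence that tracks
  clades.

## Worked example

```python
import mesothresh as mt

exp = mt.generate_experiment(mt.SyntheticExperimentConfig(rng_seed=1))
rep = mt.analyze_experiment(exp, mt.RunConfig(n_permutations=199, rng_seed=1))

print({k: round(v, 3) for k, v in rep["permanova"]["r_squared"].items()})
print(rep["threshold_scan"]["best_threshold_g"],
      round(rep["threshold_scan"]["best_r_squared"], 3))
print(rep["breakpoints"][10]["loading_vs_environment"]["selected"],
      round(rep["breakpoints"][10]["loading_vs_environment"]["breakpoint_g"], 1))
```

prints

```
{'burning': 0.009, 'loading': 0.128, 'time': 0.225}
85.7143 0.256
piecewise 110.0
```

Read: burning treatment explains ~1% of community variation, loading ~13%
and sampling day ~22% (the remainder is residual); the binary split that
best separates communities lies at 85.7 g — one design-grid step from the
planted 100 g threshold — explaining 25.6% of day-10 variation on its own;
and the day-10 loading→environment relationship is better described by a
piecewise-linear model with a breakpoint near 110 g than by a straight
line, mirroring the planted hinge at 100 g. The same pipeline runs from the
shell:

```bash
mesothresh simulate --seed 1 --out scratch/exp
mesothresh report --dir scratch/exp --seed 1 --out scratch/report.json
```

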