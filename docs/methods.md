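# Methods

This note documents the statistical models implemented in `mesothresh`, the
choices made where the design was genuinely open, and what the synthetic
generator does and does not emulate.

## Dissimilarity and variance partitioning

Counts are rarefied (sampling without replacement, multivariate
hypergeometric, default depth 5258 reads) before Bray–Curtis is computed;
samples below the depth are dropped with a warning. Keeping the
rarefy-then-dissimilarity order makes all downstream sums of squares refer
to a common sequencing effort.

PERMANOVA decomposes the Gower-centered matrix G = −½·J·D²·J (total
SS = tr G = Σᵢ<ⱼ d²ᵢⱼ/n). Terms enter **sequentially** (Type-I): each term's
SS is the increase in tr(H·G) when its centered model-matrix columns are
appended to the design, so the order of terms is part of the declared
analysis (we use treatment, then loading, then day, matching the
experimental logic of adjusting the dose effect for treatment before
absorbing time). Factors enter as dummy columns, continuous covariates as a
single centered column (df = 1). Pseudo-F = (SSterm/dfterm)/(SSres/dfres);
p-values come from free permutation of sample identities (rows/columns of D
jointly), with the same permutation set reused across terms, reported as
(b+1)/(m+1). Alternatives: exhaustive enumeration of distinct relabelings
(used for small-n exactness guarantees) and restricted permutation within
mesocosms (`strata`) for repeated-measures caution. Free permutation with
day as a fixed term is the default because time is modelled, not blocked.

The **threshold scan** refits a one-term PERMANOVA for every binary split
loading ≤ t over observed loading values with ≥ 2 samples on each side, and
reports the R²/p profile and its argmax. Ties on R² break toward the
smaller threshold and are flagged. Because the argmax is selected *after*
seeing the profile, the raw p at the best split is optimistic; an optional
max-statistic correction re-runs the scan on each permutation and compares
the observed best R² to the null distribution of the scan maximum. Both
numbers are reported; the raw one matches common practice, the corrected
one is honest about selection.

## Ordination and vector fitting

PCoA is the exact eigendecomposition of G; eigenvalues are reported in
decreasing order including negative ones (Bray–Curtis is a semimetric), and
scores use only positive-eigenvalue axes. NMDS minimises Kruskal stress-1,
√(Σ(d̂−dist)²/Σdist²), alternating isotonic regression of configuration
distances on the input dissimilarities (primary/weak tie treatment: tied
dissimilarities are pre-ordered by current distances) with Guttman
majorisation steps. It is initialised from the PCoA configuration — a
deterministic, good start — and an iteration that would increase stress-1
is rejected, so the recorded trace is non-increasing by construction.
Axes are sign-aligned so their correlation with a covariate (loading by
default) is non-negative, which keeps ordination figures comparable across
days.

`envfit` regresses each (centered) variable on the ordination scores;
R² is the OLS coefficient of determination, the direction is the normalised
coefficient vector, and p is the permutation tail probability of R² under
row shuffling of the variable, (b+1)/(m+1).

## Breakpoint model selection

Environmental state per sample is summarised as PC1 of the nine z-scored
environmental variables (classical scaling of Euclidean distances, which
equals PCA on the correlation scale), sign-oriented by loading.
The piecewise model is OLS on {1, x, (x−c)₊}; c is profiled over the
observed interior x values and refined by golden-section search between the
best candidate's neighbours — a global, derivative-free optimiser that
reaches the same RSS minimum as iterative-linearisation fitters but cannot
diverge. The breakpoint is charged one parameter in addition to the slope
change, so the comparison against the nested line uses F = ((RSS_lin −
RSS_pw)/2)/(RSS_pw/(n−4)) on F(2, n−4), and the piecewise model is selected
when p < 0.01. Because c is estimated, the F reference is approximate and
slightly liberal under the null; the test suite measures the realised
selection rate on truly linear data (≈2% at the 1% rule) rather than
assuming it. The microbiome-side response for the environment→microbiome
comparison is NMDS axis 1 after orientation.

## Traits and pathways

Community-weighted means renormalise relative abundances over the taxa with
a non-missing trait value and report the retained read fraction as
coverage. Growth rate is ln 2 / doubling time. Relative genomic plasticity
of taxon i is mean over j≠i of (d_gene(i,j) − d_proteome(i,j)): positive
values mean the proteome diverges less than the marker gene predicts under
the literal definition. Since the interpretive convention in parts of the
literature is the opposite sign (proteome divergence *beyond* phylogenetic
expectation counted positive), both `flip_sign` and an absolute-value mode
are exposed; the default is the literal signed mean.

Pathway abundance is the summed counts of member taxa (count-weighted;
presence-weighting is a caller choice via a binarised table). Samples are
normalised by median-of-ratios size factors; the response is
log2(normalised abundance + 1) and the predictor is loading centered and
scaled to unit SD, so the slope is a log2 fold change per SD of loading
(+2 ⇒ 4× more abundant one SD above the mean loading than at the mean).
Inference is a permutation test on the slope — deliberately not a
negative-binomial shrinkage estimator, whose machinery is out of scope
here; the reproduced content is the fold-change scale and the three-clause
filter p < 0.01 ∧ |log2FC| > 2 ∧ ≥ 5 member taxa. The pseudocount (1) is
configurable. Note the slope statistic saturates: for a community that
steps between two states, the attainable |log2FC| per SD is roughly
0.4 × log2(between-state abundance ratio), so only pathways with
near-state-exclusive membership clear the |log2FC| > 2 bar.

The cross-source similarity analysis pairs samples of two sources at
identical loading, scores 1 − Bray–Curtis per pair, and fits both OLS and a
penalized cubic B-spline smoother (statsmodels GLMGam; penalty weight by
GCV), with an approximate F test on (RSS_lin − RSS_smooth) at the
smoother's effective df deciding whether the smooth term earns its keep.

## The synthetic generator

The generator's defaults encode the design under study: 30 mesocosms, 15
per burning treatment, loadings evenly spaced over 0–400 g, sampling days
10/59/89, ~150 taxa, sequencing depths negative-binomial around 15 000
reads (so nearly every sample survives rarefaction to 5258), and a
compositional threshold planted at 100 g.

Communities are a two-state mixture: two Dirichlet-drawn compositions
(geometrically interpolated so `effect_size = 0` collapses them to one)
mixed with logistic weight w(L) = 1/(1+exp(−0.1·(L−100))). A two-state
structure is the minimal one consistent with a single dominant threshold
and mutually similar high-loading communities. Burning is a small
log-abundance shift on 20% of taxa (targeting a ~1% R², i.e. a real but
weak treatment signal) and each day adds a shared log-abundance drift (no
quantitative temporal model was available to emulate, so drift magnitude
is a documented free parameter, default 0.5). Sample-level compositional
noise is Dirichlet (concentration 150) and counts are multinomial, so
multinomial totals equal the drawn depths exactly and, with
`effect_size = 0`, the generator is exchangeable across loading —
PERMANOVA rejects at the nominal rate, which the acceptance tests verify.

Environmental variables are hinge functions of loading (breakpoint 100 g)
with day-dependent slope attenuation e^(−0.03·(day−10)), so the day-10
relationship is strongly piecewise while days 59/89 are near-linear —
deliberately reproducing the "nonlinearity fades as the system
equilibrates" pattern. Signs and magnitudes follow browning chemistry
(oxygen halves over 0–100 g then flattens; DOC, aromaticity and freshness
indices rise; temperature is dose-independent).

Genome traits can be biased by state affinity (high-loading taxa smaller
genomes, faster growth, higher plasticity — genomic streamlining under
stress); pathway incidence is sparse (prevalence 0.05) and tracks state
affinity (niche strength 6), because pathway membership in reference
genomes is phylogenetically conserved. Host/detritus microbiomes are
convex mixtures of the water community and a source-specific composition
with per-source water affinity (Daphnia 0.7 > mosquito 0.3 > detritus
0.15), optionally loading-dependent.

**What the generator does not emulate:** phylogenetic correlation among
taxa beyond the pathway layer, zero-inflation beyond what
Dirichlet-multinomial sampling produces, temporal autocorrelation within a
mesocosm (days are exchangeable given the drift vectors), measurement
error in the environmental sensors beyond i.i.d. Gaussian noise, and any
raw-read-level artefacts (chimeras, placement uncertainty). Tests passing
on this generator therefore certify the statistical machinery — estimator
correctness, calibration, recovery power at realistic effect sizes — not
robustness to every artefact of real amplicon data.

## Numerical choices and problem sizes

Permutation p-values are (b+1)/(m+1) everywhere. Permutation counts default
to 999; the test suite uses 19–199 where only R² profiles or calibration
rates are needed, and simulation sizes (100 seeds for recovery, 500 for
calibration and uniformity, 1000 for the null selection rate) are chosen so
Monte-Carlo error is small relative to the asserted margins. QR-based rank
detection (tolerance 1e-9 relative) guards against confounded designs;
degenerate inputs (constant variables, single-level factors, all-zero
samples, memberless pathways) raise or warn explicitly rather than
propagating NaNs. Scan ties break toward the smaller threshold, flagged.

## Known limitations

The scan's raw best-p is selection-biased by design (the corrected variant
exists but is off by default to match common practice); the profiled-
breakpoint F test is nominal-only; CWMs ignore phylogenetic non-independence
of traits; and the pathway slope statistic compresses large fold changes,
as noted above.
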