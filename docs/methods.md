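# Methods

## The analysis problem

An arrayed knockdown screen in 3D epithelial culture yields, for each
construct, a population of segmented structures with two traits: area
(size) and circularity (symmetry, in [0, 1]). The screen is organised in
independent experimental sets acquired at different times; each set carries
its own internal control population, and every statistical comparison is
made within a set or after explicit cross-set normalization. Gene silencing
by shRNA is incompletely penetrant, so a perturbed population is a mixture
of affected and unaffected structures; its distribution changes shape, not
just location, and population distributions are the object of inference
throughout.

## Preprocessing

Area is log-transformed and circularity logit-transformed; both are
variance-stabilising, and the logit maps the bounded symmetry score to the
real line. The logit is undefined at 0 and 1, which segmented structures
can attain, so circularity is clipped to [ε, 1−ε] with ε = 10⁻⁶
(configurable, recorded in the `FeatureMatrix` for reproducibility).
Transformed features are divided by their sample standard deviation
(denominator n−1, the convention of common statistical software) over the
aggregate of all control and knockdown structures of one oncogene
condition; the two conditions (with / without MYC activation) are processed
completely independently. Features are deliberately *not* mean-centred:
rank tests are location-free, and all location handling for the kernel
statistics happens through control-centering in the RKHS, so an extra
centering step would silently double-correct.

## Univariate screen

Shapiro–Wilk and a Kolmogorov–Smirnov-type test with estimated parameters
(Lilliefors, via statsmodels) document per-population non-normality; this
motivates the non-parametric tests and is reported, not used as a gate.
Each knockdown is compared to its set control with the two-sided Wilcoxon
rank-sum test per trait, on the raw trait values (rank tests are invariant
to the monotone transforms, so this is consequence-free and keeps reported
statistics on the measured scale). The exact null distribution is used for
pooled samples of ≤ 25 without ties, otherwise the normal approximation
with continuity and tie correction. Hit direction comes from the median
difference, consistent with the rank test. BH-FDR at 0.05 is applied per
condition per trait across all constructs of all sets (screen-wide family;
a per-set family is available by configuration). Directional subcategories:
size hits are *small*/*large*, symmetry hits *loss of symmetry*/*improved
symmetry*; a population may carry one of each.

## Kernel MMD testing

The squared MMD between samples is estimated with the biased V-statistic —
exactly the squared RKHS norm of the difference of empirical mean
embeddings — because nonnegativity is required for the downstream distance
matrix; the unbiased U-statistic is available behind a flag for power
studies. The Gaussian kernel is parameterized k(u,v) = exp(−‖u−v‖²/2h²)
with h the median pairwise Euclidean distance over the condition's
aggregate sample (all pairs up to a 2×10⁶-pair cap, then a seeded uniform
subsample of pairs), so every test and distance within a condition shares
one length scale. Significance uses M label permutations (default 10 000)
of the pooled two samples, p = (#{MMD²ᵢ > MMD²} + 1)/(M+1); the strict
inequality makes ties favour smaller p and is configurable to "≥". The
observed statistic is evaluated through the same vectorised arithmetic
path as the permutation statistics so that permutations reproducing the
original labelling tie it bit for bit — with a different evaluation order,
1-ulp discrepancies systematically bias p upward by the probability of
redrawing the observed assignment, which is material for small groups.
Per-test generators are spawned from one master seed, so results are
independent of evaluation order. BH-FDR at 0.05 over all tests of a
condition defines the significant populations.

## Cross-set distances, clustering, network

For populations X, Y from different sets with controls A, B, the centered
statistic ‖(μ_X−μ_A) − (μ_Y−μ_B)‖ cancels any additive batch structure
shared by all populations of a set; with a shared control it reduces
algebraically to the plain MMD, and the implementation preserves this to
float cancellation error (≲ 10⁻¹²). Its square root is an RKHS norm of
embedding differences and therefore a metric, which the tests verify
empirically. Only MMD-significant populations enter the matrix (a flag
admits all). Clustering uses Ward's criterion applied to the distances as
given — the unsquared `ward.D` Lance–Williams update, implemented here
directly (R's `hclust(method="ward.D")` behaviour; scipy's `ward` is the
D2 variant and serves as an independent cross-check through the
sqrt-input/squared-heights identity). The phenotype network adds edges in
ascending distance order up to the pruning threshold, 0.1 on the MMD (not
MMD²) scale by default; the greedy order is decorative — the edge set
equals plain thresholding, which the tests assert — but it matches how the
network is naturally read. Exports are GraphML and SIF with an `mmd` edge
attribute, a node-attribute TSV, the distance matrix in dendrogram leaf
order, and a Newick dendrogram.

## PPI overlay

A local STRING-style edge list (geneA, geneB, combined score; 0–1000
scores auto-rescaled to [0, 1]) is filtered at confidence ≥ 0.7,
deduplicated keeping the maximum score, and stripped of self-edges. No
live database access: version pinning is the user's responsibility and is
recorded in the network metadata. Construct nodes are relabelled by target
gene; several constructs per gene collapse to one node, parallel edges
keeping the minimum MMD (closest-construct semantics; mean available).
Overlay classification partitions observed pairs into both / phenotype-only
/ PPI-only, with PPI-only pairs restricted by default to genes present in
the phenotype network. Anchor queries return the first neighbours of a
gene or gene pair, the starting point for hypothesis-guided hit picking.

## Synthetic screens

The generator emits raw-scale tables so synthetic data exercises the whole
pipeline, including preprocessing. Defaults state the screen design the
framework targets: 7 sets, 4–12 constructs plus one control per set, ~100
structures per population (Poisson-dispersed, floor 2). Control traits are
bivariate normal on the transformed scale — mean log-area 7.5 (median
≈ 1800 px², a realistic segmented acinus at typical magnification), SD 0.5;
mean logit-circularity 1.4 (circularity ≈ 0.80), SD 0.6; trait correlation
0 by default since no joint model is established. Per-set batch offsets,
N(0, 0.25 SD) on each transformed feature and shared by *all* populations
of a set including its control, model multi-year acquisition drift — the
exact structure control-centering removes. Effects are two-component
mixtures: with probability `penetrance` a structure comes from a component
shifted by a stated number of control SDs (optionally variance-inflated),
otherwise from the control component; canonical classes map onto the four
directional subcategories. Everything derives from one `numpy` generator
seeded from the config, so equal configs give byte-identical datasets.

What the generator does *not* emulate: segmentation artefacts and fused
structures, apoptotic debris beyond variance inflation, non-additive batch
effects, and any dependence of penetrance on structure size. A green
pipeline test therefore establishes correctness of the statistics under
the stated model, not robustness to imaging pathology.

## Numerical and design notes

- V-statistics are clipped at 0 against rounding before square roots.
- Permutation p-values are bounded below by 1/(M+1); BH significance at
  FDR 0.05 therefore needs M large enough that the floor, times the family
  size over its rank, clears the threshold — with screen-wide families of
  ~50 tests, M = 200 suffices only when many tests are small, and the
  default M = 10 000 is recommended for production runs.
- `ward.D` can in general produce non-monotone merge heights; on MMD
  matrices of this kind inversions have not been observed, and the test
  suite asserts nondecreasing heights on random Euclidean instances.
- Degenerate inputs fail loudly: zero aggregate variance, identical point
  sets under the median heuristic, populations below two structures, and
  missing or duplicate controls are errors, not warnings.
- Ties in the greedy edge ordering and in Ward merges break
  deterministically (lexicographic / lowest-index), so all outputs are
  reproducible bit for bit.
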