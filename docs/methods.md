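# Methods

`wirecon` implements a generative-network-model (GNM) analysis pipeline for
spatially embedded binary connectomes: synthetic cohort generation,
group/participant target construction, model simulation and fitting,
cohort-level statistics, stochasticity experiments, and transcriptomic
decoding of nodal model terms. This note records the models, conventions,
parameter choices and limitations that the API documentation does not cover.

## The generative model

A network grows from a sparse seed graph by adding one edge per iteration.
The probability that the unconnected pair (i, j) receives the next edge is

    P_ij ∝ D_ij^η · (K_ij + ε)^γ

with D the fixed Euclidean distance matrix (wiring *cost*), K a topological
*value* matrix recomputed after every addition, η the distance exponent
(negative = penalty on long connections), γ the value exponent, and ε a small
positive constant (default 1e-6) keeping the probability defined when
K_ij = 0. ε is added at every iteration because K can return to zero for any
pair at any step. Only the power-law kernel is implemented.

Five value rules: `spatial` (K ≡ 1), `neighbours` (shared-neighbour count),
`matching` (Dice-normalised neighbourhood overlap excluding the pair itself:
2|N_i ∩ N_j| / (|N_i\{j}| + |N_j\{i}|), defined 0 when both neighbourhoods
are empty), `clustering_average` and `degree_average` (mean of the two nodal
statistics). Sampling uses inverse-CDF over the lexicographically ordered
candidate list, so runs are bit-reproducible for a fixed integer seed across
platforms. Sub-seeds for grids, cohorts and experiments are derived by
hashing the base seed with stable labels (CRC-32), so duplicated grid points
replay identical streams.

Parameterised nodal terms collect, per node i, the mean over iterations of
Σ_j D_ij^η (wiring cost — constant, since D is fixed) and Σ_j (K_ij + ε)^γ
(wiring value). All iterations contribute, whether or not the node was
selected.

## Model-fit criteria

* **Energy** E = max(KS_k, KS_c, KS_b, KS_e): two-sample Kolmogorov–Smirnov
  statistics over nodal degree, clustering, betweenness and existing-edge
  lengths. Distribution-level: node relabelling leaves it unchanged. Input
  distributions are snapped to 9 decimals before comparison because
  shortest-path sums can differ in the final ulp under relabelling and the
  KS sup-statistic is discontinuous.
* **Topological fingerprint (TF)**: the 6×6 Pearson correlation matrix of
  degree, clustering, betweenness, mean incident edge length, local
  efficiency and eigenvector centrality across nodes; TF dissimilarity is
  the Frobenius norm of the difference. Zero-variance metrics (e.g. degree
  on a regular graph) have their row/column set to 0 so the 6×6 shape stays
  comparable.
* **Spatial similarity**: node-matched Pearson correlation of degree.

Metric conventions: betweenness is the raw shortest-path count
(fingerprints use correlations, which are affine-invariant); clustering of a
degree-<2 node is 0; local efficiency is the mean inverse shortest-path
length inside the neighbour-induced subgraph; eigenvector centrality is the
unit-norm absolute principal eigenvector from a dense symmetric
eigendecomposition (deterministic, defined on disconnected graphs);
disconnected pairs contribute efficiency 0; modularity Q is evaluated on a
Louvain partition with a fixed seed; global clustering is nodal clustering
averaged over nodes. Graph statistics run through python-igraph's C core;
the test suite pins every convention against networkx and brute-force
enumeration.

**Grid search** evaluates an equally spaced (η, γ) lattice with
floor(√budget) points per axis (a 100,000 budget gives 316² = 99,856 unique
pairs). With repeats, a grid point is judged on its mean energy; ties break
by the KS-component sum, then lexicographically. The best point and the
[min, max] window of the lowest-energy fraction (default 10%) are reported.
**Cumulative-rank selection** ranks the five rules on energy and TF
dissimilarity (ascending) and spatial correlation (descending) and picks the
smallest rank sum, ties broken by the energy rank.

**Maslov–Sneppen rewiring** performs degree-preserving double-edge swaps
drawn uniformly, rejecting self-loops and multi-edges, until one accepted
swap per edge (attempt budget 100·|E|); graphs too small to swap are
returned unchanged with a warning.

## Synthetic data

The generators emulate the study conditions end to end with no external
data.

* **Coordinates**: uniform points in an ellipsoidal shell, semi-axes
  (35, 85, 30) mm with inner radius 0.55 of the outer — an elongated,
  cortex-like geometry chosen so pairwise distances are right-skewed (many
  short, few long edges), which a near-spherical shell does not produce.
* **Seed graph**: a stack of 40 distance-dependent random graphs is
  thresholded at 95% prevalence. Edge probability decays exponentially in
  distance (scale: median distance / 8), anchored so the shortest ~25% of
  the target edge count is near-certain per draw; the surviving seed is the
  short-range core shared by all simulations, at roughly a quarter of the
  target density (cf. empirical seeds of ~1.6% density against ~6.5%
  targets).
* **Cohorts**: per participant, η ~ N(−3.007, 0.336) and γ ~ N(0.215,
  0.027) (the fitted cohort distributions; drawn independently, as no
  between-parameter covariance is reported), then a network is grown to
  round(density · n(n−1)/2) edges — exact halves round down — with the
  neighbours rule by default at 100 nodes and 6.5% density.
* **Scores**: a standardized score with planted standardized slope β on
  z(η): score = β·z(η) + √(1−β²)·noise, re-standardized; default β = 0.054.
  Additive Gaussian noise matches the linear model used downstream.
* **Expression**: region × gene matrices from Gaussian random fields over
  the coordinates with squared-exponential covariance (default length scale
  30 mm). Signal genes mix the standardized target map with an independent
  field so their expected correlation with the map equals the requested
  strength; remaining genes are pure spatially smooth noise.

What the generators do *not* emulate: tractography artefacts and
site/scanner effects, genotype-level structure (scores only), donor-level
expression variability, and any η–γ covariance. Passing tests therefore
demonstrate internal consistency of the pipeline under known ground truth,
not robustness to the failure modes of real diffusion or microarray data.

## Connectome construction

Four thresholding stages mirror group-connectome practice: (1) a prevalence
mask retains edges nonzero in ≥ ceil(p·participants) participants (p = 0.60
typical); (2) a distance-dependent consensus splits candidate edges into 10
equal-frequency length bins (count not prescribed by the source procedure;
10 is the package default), gives each bin a quota proportional to its share
of participant edge mass, and keeps the most prevalent edges per bin — ties
break by higher mean weight, then pair index — matching the mean participant
edge count to within rounding and tracking the typical edge-length
distribution far better than a global prevalence cut (verified by paired KS
in the tests); (3) participant targets binarise raw weights at a streamline
threshold (≥ 27 typical; an edge additionally requires nonzero weight);
(4) the simulation seed is the ≥95%-prevalence core of the binary
participant targets, which may legitimately be empty. The participant
threshold is applied to raw weights, not to the prevalence-masked stack.

## Cohort statistics and stochasticity experiments

Outlier removal drops participants whose η or γ lies outside mean ± k·SD
(k = 2), bounds computed once on the input table. The extreme-group
contrast takes the top and bottom ceil(10%·n) of the score distribution and
compares fitted parameters with the classic equal-variance t-test
(df = n₁+n₂−2) and pooled-SD Cohen's d, oriented top-minus-bottom. The
continuous analysis fits z(parameter) ~ z(score) + mean framewise
displacement + sex + age by OLS and reports the fully standardized slope
(both outcome and predictor standardized) with Bonferroni correction over
the two parameters tested (p_bonf = min(1, 2p)).

The **stochasticity experiment** contrasts two wiring regimes over repeated
simulations from a shared seed. Measures per group: (i) wiring-probability
variability — for each candidate pair, the coefficient of variation across
simulations of its iteration-averaged wiring probability (the pair-level
accumulated probability carries the trajectory-divergence signal; node-level
probability sums are dominated by the fixed distance term and become *more*
stable, not less, as η softens); (ii) embedding dissimilarity — mean
pairwise Jaccard distance between added-edge sets over up to 1,000 random
simulation pairs (seed edges excluded, since they are common by
construction); (iii) topological dissimilarity — pairwise TF dissimilarity
(optional); (iv) global efficiency per simulation. The two regimes are
compared with **common random numbers**: simulation k shares its RNG stream
across regimes, a standard variance-reduction pairing that leaves each
group's marginal distribution unchanged while stabilising the direction of
small contrasts (the efficiency effect is of order d ≈ 0.15, which
independent streams cannot resolve reliably at a few hundred simulations).

The **randomisation sweep** scales both optimal exponents by fractions
f ∈ [0, 1] (reported rounded to 3 decimals; f = 0 is pure random addition)
and reports, per fraction, mean simulated global efficiency and mean TF
dissimilarity to a Maslov–Sneppen-rewired copy of the target (one rewiring
per simulation). Loosening the constraints raises efficiency monotonically
and moves simulated topology toward the degree-preserving null; the latter
direction emerges reliably only for systems of ~100 nodes — at 60 nodes and
below the degree-heterogeneity mismatch between random simulations and the
rewired target can reverse it, which is why the packaged experiments run at
100 nodes.

## Transcriptomic decoding

Per participant, a PLS regression (scikit-learn NIPALS; X columns and y
centred and scaled; 3 components by default) relates the region × gene
expression matrix to a nodal vector of parameterised wiring cost or value
(left-hemisphere regions in the intended application). Scores are sign-fixed
to correlate positively with the response so gene loadings are comparable
across participants. Permutation p-values shuffle the response across
regions: p = (1 + #{|null loading| ≥ |observed|}) / (n_perm + 1) per gene on
component 1 (default 1,000 permutations in tests, 10,000 for full runs).
Cross-participant aggregation keeps genes significant in every participant
(`mode="all"`; `mode="any"` is also exposed), averages component-1 loadings
and ranks by descending mean loading, ties broken lexicographically.

Two caveats are worth stating because the tests measure them. First, the
uniform permutation null does not preserve spatial autocorrelation: when the
response map is itself spatially smooth, smooth noise genes correlate with
it legitimately and gene-level false positives exceed nominal. Second, when
planted signal genes are few and mutually highly correlated they form the
dominant covariance factor of X, and the permuted-y null *absorbs* that
factor (loadings on it are large under any response), destroying power; the
planted-signal tests therefore use many genes and moderate signal strength,
where per-gene calibration (≈5% at α = .05) and full recovery of the
planted set both hold.

## Problem sizes in the packaged experiments

The test suite and `scripts/acceptance.py` run reduced designs, chosen as
the smallest systems in which each qualitative result is stable: 30-node /
10%-density cohorts for parameter recovery (21×21 grid, η ∈ [−7, 7] with γ
restricted to its plausible fitted window [−0.067, 0.6]; 5 repeats per grid
point for the fitted rule, 2 for the alternatives; 20-repeat re-evaluation
at each best point); 100-node / 6.5%-density systems for the stochasticity
contrast (200 simulations per group, 20 experiment replicates) and the
randomisation sweep (10 fractions × 100 simulations); 1,000 null replicates
for t-test calibration; 200 cohorts of n = 1,399 for slope recovery. At 30
nodes the two homophily rules are statistically near-equivalent (as they
are in full-size applications); model selection is therefore summarised as
the modal per-target cumulative-rank winner across the cohort.

## Known limitations

Binary, static GNMs only: no weighted variants, growth models, genetic
seeding or pruning. Energy landscapes at small n are noisy, and single-run
argmin estimates of η scatter by one to two grid steps. The permutation-PLS
null is not spatial-autocorrelation-preserving. The distance-consensus bin
count and the Louvain partition seed are conventions, not fitted choices.
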