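# Methods

## Model

`beliefnet` treats a questionnaire as a Gaussian graphical model over
the p observed variables (Likert-type belief items, optionally joined by
a binary behavior coded 0/1). For precision matrix K = Σ⁻¹ the edge
weight between variables i and j is the partial correlation
ρᵢⱼ = −κᵢⱼ/√(κᵢᵢκⱼⱼ): the linear association between the two variables
after conditioning on all others. Zero entries of K are conditional
independences, so the sparsity pattern of K *is* the network topology.
Networks estimated from cross-sectional data are undirected; any talk of
"reinforcing loops" below is therefore about sign structure that is
*compatible with* feedback, not evidence of it.

Ordinal items are entered through Pearson correlations on their numeric
codes by default. This treats the codes as interval-scaled, which is the
robust standard choice when the latent-response assumption is not worth
its extra variance; a `polychoric_auto` mode estimates two-step
maximum-likelihood polychoric correlations for ordinal/binary pairs and
two-step polyserial correlations for mixed pairs, with a projection to
the nearest positive-semidefinite correlation matrix when latent
estimation breaks PSD. Spearman correlations are a third option.

## Estimation

**Single network.** The graphical lasso maximizes the L1-penalized
Gaussian log-likelihood; the penalty λ runs over a log-spaced grid of
`n_lambda` values (default 100) from 0.01·λmax to λmax, where λmax is
the largest absolute off-diagonal correlation (the smallest penalty that
yields an empty graph). Each candidate λ is scored by the Extended BIC,

EBIC(λ) = −2 log L + E log n + 4 γ E log p,

with E the number of selected edges and γ = 0.5 by default. Two details
matter:

* **Relaxed scoring and debiasing.** The penalized path determines only
  the candidate *edge sets*; each distinct support is then refit by
  unpenalized maximum likelihood restricted to that support
  (covariance-selection block-coordinate algorithm, numba-accelerated
  when available), and both the EBIC score and the reported edge weights
  come from the refit. Scoring shrunken estimates instead systematically
  favors slightly denser models, because the shrinkage bias at the
  correct support costs more likelihood than a few spurious edges cost
  penalty; with relaxed scoring the generating pattern is recovered in
  ≥ 90% of simulation runs at p = 10, n = 5000.
* **Early stopping.** Scanning from the sparse end, the search stops
  after three consecutive candidate supports without an EBIC
  improvement; the EBIC along the path is in practice unimodal, and the
  dense-end fits are by far the most expensive.

Edges with |ρ| < 1e−8 are treated as exactly absent so graph algorithms
see a true topology. Ties in EBIC go to the larger (sparser) penalty.

**Two groups.** The Fused Graphical Lasso minimizes

Σₖ nₖ(−log det Θₖ + tr(SₖΘₖ)) + λ₁ Σₖ Σᵢ≠ⱼ |θₖ,ᵢⱼ| + λ₂ Σᵢⱼ |θ₁,ᵢⱼ − θ₂,ᵢⱼ|

for k = 1, 2, solved by ADMM with closed-form proximal steps: the Θ
update is an eigendecomposition, and for two groups the fusion-plus-L1
prox decouples elementwise (shrink the pairwise difference toward
equality, then soft-threshold). The penalty parameter ρ starts at 1 and
adapts to keep primal and dual residuals balanced; convergence uses
absolute/relative tolerances 1e−5/1e−4 with at most 1000 iterations, and
non-convergence is a hard error reporting both residuals. λ₂ = 0
reproduces independent graphical lasso fits (at per-observation penalty
λ₁/nₖ, because the likelihood carries the nₖ weight); λ₂ → ∞ forces the
two precision matrices equal. Equal likelihood weighting is available by
flag. More than two groups is out of scope.

## Graph analyses

Centralities and paths use absolute weights. Strength is sᵢ = Σⱼ|wᵢⱼ|.
Distances use d = 1/|w| (an inverse-log transform is available but not
default); absent edges have *no* distance entry, so routes must go
around them. Closeness is inverse total distance to the reachable nodes
(harmonic closeness available for disconnected graphs); betweenness uses
Brandes accumulation with fractional credit split among tied geodesics,
endpoints excluded, unnormalized. Shortest paths to the focal behavior
node come from Dijkstra with a deterministic tie-break: among
equal-length paths the lexicographically smallest node sequence is
reported. Unreachable nodes carry infinite distance, rendered "-" in the
CSV output.

The sign split sends w > 0 edges to a "stimulating" subnetwork and
w < 0 edges (as |w|) to an "inhibiting" one; the two partition the edge
set exactly. Splitting only removes routes, so no node can be closer to
the focal node in a subnetwork than in the full network.

Communities come from greedy agglomerative modularity maximization on
|w| (signed-modularity variants are a known omission): starting from
singletons, the merge with the largest modularity gain is applied until
one community remains, the full merge history is kept as the dendrogram,
and the returned partition is the one with maximal Q along the way.
Ties prefer the smallest community-id pair, making the dendrogram
deterministic.

Cliques (complete subgraphs, any nonzero weight is an edge) and simple
cycles (rings) of a given size are enumerated separately — a four-cycle
need not be a four-clique, and the two answer different questions.
Cycles are canonicalized by smallest-label-first rotation with the
direction chosen toward the smaller second label; chords are allowed by
default, with a chordless-only switch. A cycle is classified reinforcing
when the product of its edge signs is positive (equivalently, an even
number of negative edges), inhibiting otherwise.

## Resampling

Edge accuracy uses a nonparametric bootstrap: rows resampled with
replacement, the *entire* estimation (EBIC selection included) repeated
per replicate — fixing λ would understate variance — and 95% percentile
intervals reported (BCa left as future work). Centrality stability uses
a case-dropping bootstrap over drop proportions 0.1–0.7 (step 0.1): for
each proportion q, B subsamples of size round((1−q)n) are re-estimated
and each centrality vector is Pearson-correlated with the full-sample
one; a replicate whose centrality vector is constant scores 0. The CS
coefficient per measure is the largest tested q at which that
correlation is ≥ 0.7 in at least 95% of replicates, 0 if none qualifies.
B defaults to 1000 for production use; tests and the acceptance script
use B = 100 and report the grid actually used. Every replicate draws its
own child seed from the master seed, so resampling is reproducible and
parallelizable.

## Network comparison test

With the behavior treated as emergent, the sample splits into the
with/without-behavior groups and the two networks are compared on
structure M = maxᵢⱼ |w₁,ᵢⱼ − w₂,ᵢⱼ| and global strength
S = |Σᵢ<ⱼ|w₁,ᵢⱼ| − Σᵢ<ⱼ|w₂,ᵢⱼ||. The null distribution permutes group
labels (preserving the group sizes, imbalance included, with no
reweighting) and repeats the identical estimation for each permutation;
p = (1 + #{perm ≥ obs})/(1 + n_perm), so p > 0 always and p = 1 is
attainable. The observed group networks are estimated *independently* by
default: fusing them would shrink exactly the differences under test.
The fused fit exists as a descriptive display option. Per-edge p-values
are computed on request and Holm-adjusted, with the correction recorded
in the output metadata. Calibration was checked by simulation: under an
identical-distribution generator (p = 8, n = 200 per group, 100
permutations, 200 replications) the rejection rate at α = 0.05 stays
near nominal, and a 0.4 perturbation of one partial correlation at
n = 500 per group is detected in well over 80% of runs.

## Synthetic data

The generator emulates the motivating organ-donation study, whose data
are not deposited: p = 25 five-level Likert items, n = 366, a binary
behavior with the study's 93/273 imbalance. Ground truth is a precision
matrix with unit diagonal and a requested sparsity pattern (chain,
random-sparse at a given density, or two-block), edge magnitudes drawn
from [0.15, 0.35] for the study emulation with a 30% negative share;
positive definiteness is enforced by scaling all off-diagonals under
strict diagonal dominance, which keeps the pattern exact (eigenvalue
clipping would not). Responses are multivariate normal draws from K⁻¹,
discretized at equal-probability normal quantiles into integer codes
1..L (L = 5 by default; the source questionnaire's response range is not
documented, so L is a parameter). The behavior operationalizes threshold
accumulation of stimulation: a Bernoulli draw with logit = intercept +
coefs·standardized(items); six items carry nonzero log-odds weights in
±[0.3, 0.8], and the intercept is set from the target marginal
prevalence with a logistic-normal correction for the variance the item
effects contribute. Two-group data draw group 1 from a perturbed
precision matrix, with deltas specified on the partial-correlation scale
and positive definiteness re-checked. Random streams are spawned per
stage (structure, responses, behavior, groups) from one master seed.

What the generator does *not* emulate: item-specific marginal
distributions and skew, measurement error beyond discretization,
missing data, longitudinal dependence, and any true causal directionality.
Passing tests therefore demonstrate that the pipeline recovers what a
Gaussian copula-like world generates, not that real questionnaire data
satisfy those assumptions.

## Problem sizes and numerical choices

Simulation-based tests use p = 6–10 with n = 200–5000 and B = 30–100
resamples, and the end-to-end checks run at the study scale
(p = 26, n = 366); these sizes make the full suite complete in minutes
while leaving every statistical conclusion comfortably powered.
Degenerate inputs fail loudly: zero-variance columns, non-positive-
definite constructions, unknown focal labels, non-binary split
variables, and ADMM or bootstrap failure rates above 10% (5% for
permutations) are all hard errors rather than silent repairs. Exact
zeros in edge weights use the 1e−8 threshold throughout; path-length
ties use 1e−12.

## Known limitations

Pearson correlations on ordinal codes attenuate latent associations;
the polychoric option mitigates but is slower and can require PSD
repair. Modularity on |w| ignores sign information. The NCT's M
statistic tests only the single largest edge difference; diffuse
many-edge differences are better caught by S. Berkson-type selection
effects from splitting on the behavior are not corrected. All inference
is cross-sectional; nothing here estimates temporal or causal structure.
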