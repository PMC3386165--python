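# Methods

This note records the statistical model implemented in `perturbnet`, the
choices made where the method leaves room, and what the synthetic-data
generator does and does not emulate.

## Phenotype preprocessing

Raw plate wells carry a reporter intensity B and a DRAQ5 (cell-count
proxy) intensity D. Normalisation is two-stage per plate:
M = (B/D) / mean over control wells of (B/D), so that M is a per-cell
signal and the controls of every plate average exactly 1. Z-scores then
standardise M within each plate. The standard deviation is the
population sd (divide by n) by default, with `ddof=1` available; the
choice only rescales all of a plate's Z-scores by a common factor
√(n/(n−1)) and is therefore invisible to the cosine association score.
Missing values are rejected rather than imputed: the mixture model
assumes complete profiles, and imputation would manufacture association.

## Association scores

The association of two genes is the cosine similarity of their phenotype
vectors over all replicate columns. The uncentred form is deliberate:
the magnitude of a loss-of-function effect is signal, not nuisance, so
two genes whose phenotypes share both direction and size should score
higher than two that merely co-vary around different baselines. Scores
are mapped to the beta support by a = (cc+1)/2, a fixed linear bijection;
before any beta likelihood is evaluated, scores are clipped into
[1e−6, 1−1e−6] to keep densities finite at the boundary.

## The permutation null

The no-association component is fixed from permuted screens: each
permutation destroys cross-gene association, a single beta is fitted to
its transformed scores by maximum likelihood, and the component is
pinned at the coordinate-wise medians over permutations (20 by default,
configurable; 100 reproduces the larger published setting). Three
permutation units are provided:

* `within_condition` (default): each condition block receives its own
  random re-assignment of gene rows, so a permuted gene's profile is a
  mosaic of different genes' intact condition sub-rows. This preserves
  the replicate structure within every condition while breaking
  cross-condition coherence. It requires at least two condition blocks:
  with a single block it reduces to a relabelling of genes, which leaves
  the multiset of pairwise scores unchanged.
* `whole_row`: permutes entire rows; a pure relabelling, kept only for
  diagnostics.
* `per_column`: shuffles every replicate column independently across
  genes. This is the appropriate null for single-condition screens and
  is what the simulation harness uses, since simulated screens are one
  condition.

Maximum-likelihood beta fitting is performed on sufficient statistics
(the weighted means of log a and log(1−a)) with a method-of-moments
start and BFGS on log-shapes with the analytic gradient; the same
routine serves the EM M-step, where only the sufficient statistics
change. Convergence is declared from the gradient norm (≤ 1e−4 per
observation) because BFGS reports spurious "precision loss" at
machine-precision optima.

## The beta-mixture model

Transformed scores follow a three-component beta mixture — negative
association (x−), none (x0), positive (x+) — with the x0 shapes fixed
from the permutation null. The component count is fixed at three by
design; it encodes the biology (a pair is positively associated,
negatively associated, or not) rather than a model-selection outcome.

With a prior interaction network the pairs are partitioned into strata
(prior / no-prior by default; any integer labelling works), each with
its own mixture coefficients π_k while the three densities are shared. A
Dirichlet prior on each π_k row gives MAP estimation; its
hyperparameters decompose as

  γ_km = 1 + Γ · (p_km − 1/3),

where p_k is a normalised prior-belief vector and Γ ∈ [0, 3) a strength.
This decomposition is chosen so that Γ = 0 *or* uniform p gives γ ≡ 1
exactly, for which the MAP coefficient update
π_km = (Σ z_ijm + γ_km − 1)/(|A_k| + Σγ_km − 3) provably reduces to the
ML update (the mean responsibility). The alternative γ = Γ·p is
available behind the `decomposition="scaled"` flag. Defaults are
uninformative (Γ = 0): in the stratified model the strata still differ
through their fitted coefficients, which is where the prior's value
enters; informative γ is an option, not a requirement.

EM details: the E-step is computed in log space with `logsumexp`; the
M-step updates coefficients in closed form and the two free shape pairs
by the weighted beta ML above (initialised at the current shapes, capped
at 100 inner iterations, so each M-step can only improve the objective —
a generalised-EM ascent). Label switching between x− and x+ is prevented
by swapping the two components (shapes and coefficient columns) whenever
their means disorder. Convergence is declared on the change of the
log-posterior (default tolerance 1e−6, maximum 1000 iterations); the
objective path is recorded and tested to be non-decreasing. Coefficients
are clamped to [1e−8, 1] and renormalised; a clamp is logged as a
warning because it means the Dirichlet prior overwhelmed a small
stratum.

Edge evidence is the posterior odds K = (P(x−)+P(x+))/P(x0), capped at
1e12 when P(x0) underflows to zero. The default network cutoff is
K ≥ 10 ("strong" on the Jeffreys scale); edge sign compares P(x+) with
P(x−), and exact ties are dropped and counted. Isolated genes stay in
the node set so module densities use the screened-gene universe; a
prune flag removes them for export.

## Module search

Genes are clustered on association profiles: the profile of gene u is
the vector cc(u, ·), and the distance between u and v is one minus the
Pearson correlation of their profiles with the entries involving either
gene excluded from both (so both vectors cover the same index set).
Average linkage is the default; complete and Ward are options. The
leave-two-out correlation is computed in closed form from full-row sums,
keeping the bootstrap inner loop in BLAS.

Cluster uncertainty comes from multiscale bootstrap: at each scale
r ∈ {0.5, 0.6, …, 1.4}, B resamples of round(r·q) replicate columns
(with replacement) rerun the whole cosine–distance–clustering pipeline,
and a cluster's bootstrap probability (BP) at scale r is the fraction of
replicate dendrograms containing an identical member set. The
approximately unbiased probability is obtained by weighted least squares
of Φ⁻¹(1−BP_r) on (√r, 1/√r) with binomial weights
B·φ(z)²/(BP(1−BP)); AU = 1 − Φ(v−c) and the module p-value is
1 − AU = Φ(v−c). Degenerate supports use documented fallbacks: BP ≡ 1
gives p = 0, BP ≡ 0 gives p = 1, and fewer than two usable scales fall
back to the BP at the scale nearest 1 (with a warning). B defaults to
1000 for desk-scale runs; 10000 reproduces the published setting.

Two calibration facts, both computed by the test suite, bound what the
AU p-value means here. On screens of independent, centred genes — the
exchangeability null — the fraction of clusters with p < 0.05 is at the
nominal level (about 5% at 15 replicates, tested against a 10% bound).
On generator output with noise proportion 1.0 the rate is much higher,
and correctly so: the "noise" correlation matrix is a real random
correlation structure and the shared mean directions are real cosine
association, so the detected clusters are genuine features of the
generated data even though they are independent of the planted modules
(which is why the same screens give edge-ranking AUC 0.5 against the
planted gold standard). AU p-values certify stability of structure, not
its biological origin.

Modules are clusters that pass four independent filters: p < 0.05; size
within [5, N/2]; PAN edge density ≥ 0.5 (the density cutoff is exposed
as mandatory configuration — published analyses used case-specific
values); and mean phenotype sign matching the direction of interest.
Survivors are nested by set inclusion.

## Pair-set enrichment

Whether a set of gene pairs (e.g. prior protein-complex interactions)
concentrates at the top of a posterior-probability ranking is tested
with a weighted Kolmogorov–Smirnov running sum over pairs ranked by the
chosen posterior column: hits step up proportionally to the phenotype
weight (exponent 1), misses step down uniformly, and the enrichment
score is the signed maximal deviation. Significance comes from permuting
set membership over pairs (the ranking stays fixed; the mixture is not
refitted), with add-one smoothing so p > 0 always. Because the weights
are the phenotype values themselves, a monotone transform of the
phenotype perturbs the statistic slightly even though the ranking is
unchanged; the permutation p-value is correspondingly stable only up to
small jitter, which the tests bound explicitly.

## The synthetic-screen generator

The generator emulates a plate-standardised perturbation screen with
two planted modules. N genes (default 100) are split into G+ (30,
positive effects), G− (30, negative) and G0 (40, background). A signal
correlation matrix S (+1 within G+ and within G−, −1 across, 0 for any
pair touching G0, unit diagonal) is blended with a random correlation
matrix R = WWᵀ (rows of W uniform on the sphere) as
C = (1−ε)·S + ε·R, ε the noise proportion. Gene means and standard
deviations come from surrogate distributions standing in for the
empirical distributions of a real screen: the mean *magnitude* is
|N(1.5, 0.5)| for every group, with sign + for G+, − for G−, and random
for G0; standard deviations are |N(1, 0.25)| floored at 0.05. C is
scaled to a covariance and n_rep replicate columns are drawn from the
multivariate normal (eigen-decomposition sampling, so the exactly
singular ε = 0 case works).

The shared magnitude distribution is a deliberate constraint, not an
oversight: the association score is an uncentred cosine, so any
group-specific magnitude would by itself separate planted from
background pairs, and a 100%-noise correlation matrix must carry no edge
information at all (the pure-noise baseline AUC of 1/2 is the anchor the
rest of the simulation study is read against). Background genes having
positive or negative effects at random is likewise part of the design.

The gold standard labels within- and cross-module pairs as true edges
(cross-module −1 entries are associations, not noise; a flag restricts
the gold standard to within-module pairs for sensitivity analysis) and
every pair touching G0 as a non-edge. Prediction quality is the
rank-based AUC of the posterior-odds ranking, ties counted ½. Prior
corruption removes exactly round(fnr·|true|) true edges and adds
round(fpr·|non|) non-edges, sampled without replacement.

What the generator does **not** emulate: plate structure and batch
effects (screens arrive already Z-scored), non-Gaussian phenotype noise,
reagent off-target structure, and — most importantly — mean-effect
*independence* from module membership found in real screens only
approximately. Two consequences of the design are worth knowing when
reading test results. First, at ε = 0 the planted correlations are
exactly ±1, so background pairs with aligned means carry genuinely high
cosine association; the network there achieves perfect recall of
planted edges rather than perfect edge-set equality. Second, a passing
simulation suite shows the pipeline recovers structure it was designed
to plant; it does not certify behaviour on screens whose noise violates
the multivariate-normal, single-condition design.

## Problem sizes and seeds

Simulation-based tests and the acceptance script use the reference
design (100 genes, 30/30/40, 8 replicates) with 5 permutations for the
null, EM tolerance 1e−4 and at most 300 iterations inside grids — sizes
chosen so a full run completes in minutes on one CPU while leaving the
reported averages' Monte Carlo error well inside the tolerances being
asserted (20 simulations for the pure-noise baseline, 24 per grid point
for noise calibration, 50 for the prior-corruption comparisons, with
each simulated screen reused across corruption settings to pair the
comparison). Unit fixtures are smaller (12–24 genes). Every source of
randomness flows from an explicit seed; the command-line interface fans
one master seed out to per-stage generators via
`numpy.random.SeedSequence.spawn`, so reruns are byte-identical.

## Known limitations

* The permutation null for single-condition screens (`per_column`)
  breaks within-gene replicate coherence; there is no scheme that both
  preserves it and destroys association when only one condition exists.
* The AU p-value inherits the small-sample behaviour of multiscale
  bootstrap: with very few replicate columns (q ≈ 8) it is mildly
  anticonservative even on exchangeable data, and clusters whose BP
  curves sit at 0 or 1 on most scales are handled by fallbacks rather
  than the regression.
* The mixture assumes the three-component family is adequate; screens
  whose association densities are multimodal within a component (e.g.
  several interaction strengths) will fold that structure into the
  nearest beta.
* Posterior odds are computed at the fitted parameters; parameter
  uncertainty (small screens, tiny strata) is not propagated into edge
  evidence.
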