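# Methods

## Model

A binary ensemble classifier is K submodels sharing a training pool. For
compound n, submodel j emits g_nj ∈ (0, 1); comparing g_nj to a threshold
turns it into a vote, and the positive-vote tally k_n ∈ {0..K} measures
consensus. The estimation target is P(error | k): the probability that a
prediction receiving k positive votes is wrong.

Writing φ(k) for the probability that a prediction receives k votes and
ε(k) for the distribution of tallies among *misclassified* predictions,
Bayes' theorem gives

    u(k) = MR · ε(k) / φ(k),

where MR is the pool misclassification rate from raw counts. Both φ and ε
are modelled as beta binomials, the natural family for tallies whose
per-compound success probability is itself heterogeneous (submodels are
correlated, compounds differ in difficulty). At α = β = 1 the beta binomial
is uniform on 0..K; α, β < 1 gives the convex (U-shaped) profiles typical of
well-performing ensembles, where most compounds sit at the consensus
extremes.

### Estimation protocol

1. Tally votes (strict `>` comparisons throughout; half-integer ensemble
   vote thresholds make ties impossible).
2. Classify each pool compound and mark it correct or erroneous.
3. Count predictions f(k) and errors e(k) per tally.
4. Continuity-correct: f(k)+1, e(k)+0.5. Sparse bins would otherwise pin
   rates at 0 or 1; the corrected rate is 0.5 for an empty bin, 0.25 for a
   single correct prediction, 0.75 for a single error.
5. Fit BB(K, α, β) to the corrected f and e separately, each by minimizing
   the Kolmogorov–Smirnov distance max_k |ECDF(k) − CDF(k)| over the shared
   discrete support. Cumulative matching tolerates the noisy, undersampled
   intermediate tallies that dominate pointwise (likelihood-based) fits.
6. Assemble u(k) = MR·ε(k)/φ(k), clipped to [0, 1] (the raw ratio can
   exceed 1 in thin tails; the unclipped vector is retained and satisfies
   Σ_k u_raw(k)·φ(k) = MR identically). Confidence is 1 − u(k).

### Decision rules

* **Voting** — positive iff k > vote threshold (default majority,
  ⌊K/2⌋ + 0.5). Refinement moves the threshold to ⌊K·α/(α+β)⌋ + 0.5 of the
  fitted error distribution, re-labels decisions (tallies, hence φ, are
  untouched — this is asserted bit-identically in the tests), refits ε, and
  stitches a composite profile: refined u(k) below the new threshold, naive
  above. The composite carries the discontinuity that a single smooth pair
  of distributions cannot.
* **Averaging** — positive iff mean_j g_nj > θ, with θ placed by maximizing
  Youden's J of the mean output (the J_max threshold). Tallies for
  uncertainty estimation count outputs above the same θ. Refinement moves
  the summed threshold K·θ to the geometric mean of K·θ and the ε mean
  (full substitution overcorrects); both tallies and classifications move,
  so both distributions are refitted. No composite is built: averaging
  profiles lack the threshold discontinuity.

### Reliability diagnostic

At the decision threshold the ensemble is guessing, so a trustworthy profile
crosses it near u = 0.5. We interpolate u linearly between the flanking
integer tallies and grade: ok ≥ 0.45 > warn ≥ 0.40 > unreliable. The 0.40
cut is the established flag for profiles whose middle is flattened by
undersampled or insufficiently diverse errors; 0.45 is this package's
conservative warning margin. When a profile is flagged, the class-average
fallbacks ū₀ = 1 − NPV, ū₁ = 1 − PPV are reported alongside (and always
serialized).

## Beta-binomial fitting: numerical choices

* pmf/cdf evaluated entirely in log space via `scipy.special.gammaln`;
  stable beyond K = 10⁴.
* K-S minimized in (log α, log β) by Nelder–Mead (positivity by
  parametrization; the objective is non-smooth, so derivative-free), started
  from method-of-moments estimates clamped to [0.05, 100]. If the simplex
  fails to improve on its start, a 25×25 log-grid over [0.05, 50]² restarts
  it. First minimizer found wins; with a fixed start the fit is
  deterministic.
* α, β bounded to [10⁻³, 10⁴]; a fit ending on a bound reports
  `converged=False` (degenerate counts, e.g. exactly binomial counts drive
  α = β → ∞).
* ECDF convention: right-continuous at integer k, ECDF(k) = Σ_{j≤k} c_j / Σc,
  matching the discrete CDF support, so the K-S sup runs over k = 0..K.
* Ties in Youden's J are broken toward the lowest threshold (within 1e-12,
  so floating-point ties behave like exact ones); candidate thresholds are
  midpoints of consecutive distinct scores plus below-min/above-max guards.

## The ANN ensemble trainer

One hidden tanh layer, logistic output
g = σ(Σ_j a_j tanh(w·x − t_j) − b), trained by full-batch gradient descent
(one iteration = one epoch, learning rate scaled by 1/N) on the
class-weighted squared loss Σ c₀(1−q)g² + c₁q(1−g)², where c₀ is the
fraction of positives and c₁ the fraction of negatives — the smaller class
always carries the larger weight. Early stopping keeps the weights with the
best verification objective and halts after 15 non-improving epochs. Each
network then gets a Youden threshold on its own training set. An ensemble
trains 165 candidates on independent stratified 2/3–1/3 pool splits and
keeps the 33 with the lowest combined training+verification objective (ties
by candidate index); both counts are configurable. Weights initialize
uniform in [−0.5, 0.5]; every split and initialization derives from the
single config seed via `SeedSequence.spawn`, so training is exactly
reproducible. Architecture search is out of scope: neuron and descriptor
counts are configuration. A preprocessing filter drops descriptors with
coefficient of variation < 1 %, fewer than 4 nonzero cases, or |r| > 0.98
against an already-kept descriptor. Input-gradient descriptor ranking uses
the analytic sensitivity ∂g/∂x_i = g(1−g)Σ_j a_j(1−f_j²)w_ij, ranked by mean
absolute value over the data.

## Synthetic data

The generator emulates a two-class screen judged by a correlated ensemble.
Compound n of class y gets a shared latent z_n ~ N(0,1); submodel j sees
s_nj = μ_y + √ρ·z_n + √(1−ρ)·e_nj and outputs σ(s_nj), with
μ_{0,1} = ∓difficulty/2. At ρ = 0 tallies are binomial within class; ρ > 0
makes per-compound correct-vote probabilities heterogeneous, producing
exactly the beta-binomial-like overdispersion the method targets (a latent
Gaussian copula is the simplest mechanism that does so). Class allocation is
exact (round(n·ratio)), then shuffled, for test determinism.

Defaults — K = 33, class_ratio = 0.5, difficulty = 2.0, ρ = 0.5 — give
per-submodel accuracy near 0.9 and ensemble MR near 0.08, comparable to a
good high-quality-data classifier; ratios 0.25 and 0.123 emulate 1:3 and
1:7 imbalanced regimes. What the generator does **not** emulate: real
descriptor spaces, label noise from assay irreproducibility, applicability-
domain drift between pool and prediction sets, and submodels whose
correlation varies by region of chemistry space. Passing calibration tests
on this generator therefore shows the estimator is self-consistent under
beta-binomial-like overdispersion, not that any particular laboratory data
set will calibrate equally well.

A note on what the calibration tests show: with a 2,000-compound pool the
held-out per-tally error rate is reproduced to a mean absolute deviation
≤ 0.05 over well-populated bins, but the smooth fitted profile still
underestimates uncertainty at the sparsely sampled middle tallies (observed
≈ 0.5 at the threshold vs fitted ≈ 0.27 at the default conditions). The
reliability diagnostic is designed to catch precisely this and fires
accordingly; the package reports it honestly rather than smoothing it away.

## Problem sizes

The test suite and acceptance script run entirely on synthetic data at desk
scale: fit-recovery checks use 10,000 sampled tallies per (α, β) over a 3×3
grid and 20 seeds; the end-to-end calibration check uses a 20,000-compound
vote matrix (2,000 fitted, 18,000 held out); ensemble-training tests use
~150-compound pools with 12 candidate networks. These sizes were chosen to
exercise every code path with comfortable statistical margins.

## Known limitations

* The K-S criterion returns a point estimate only; no uncertainty on (α, β)
  is propagated into u(k).
* u(k) for tallies the pool never visited rests entirely on the smoothness
  of the fitted distributions.
* The voting-refinement mean rule assumes the error distribution is
  unimodal toward one extreme; symmetric error distributions leave the
  majority threshold unchanged by construction.
* Scoring new data assumes the pool is representative of it; the method has
  no applicability-domain component.
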