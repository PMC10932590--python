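# Methods

This note records the modeling choices behind `ctdreg`: the generative
model the synthetic data implements, the deconvolutional regression and
its estimation, the statistical testing protocol, and the numerical
decisions that make the pipeline stable at desk scale. Nothing here
states an empirical result; the numbers the package produces come from
the test suite and `scripts/acceptance.py`.

## The response model

A reading time is modeled as exGaussian: `y = N + E`, `N ~ Normal(μ, σ)`,
`E ~ Exponential(τ)`. The density is evaluated in log space through
`scipy.special.log_ndtr`, so the `exp(σ²/2τ²)` factor and the Gaussian
tail probability cancel without overflow even for `τ ≪ σ`; analytic
gradients in (μ, σ, τ) drive maximum-likelihood fitting. The mean is
`μ + τ`: a pure change in the skewness parameter shifts the mean while
leaving the distribution's left flank in place, which is exactly the
signature the distributional analyses are after.

σ and τ are parameterized as `1 ms + softplus(η)`. The softplus keeps
them positive under unconstrained optimization; the 1 ms floor bounds the
likelihood's curvature when stacked negative effects drive a parameter
toward zero (sub-millisecond dispersion is physically meaningless for
reading times, and without the floor both the generator and the fitted
model can request it, with catastrophic gradient magnitudes). The
generator uses the identical link, so generative effect sizes and fitted
contributions live on the same pre-link scale, and — because baselines sit
far above zero, where softplus is essentially the identity — that scale is
effectively milliseconds.

## The synthetic generator

The generator emulates the structure of naturalistic reading corpora:

* **Events.** Each of 8 participants reads 10 texts of 250 words
  (20,000 word events by default). Inter-word intervals are exponential
  with mean 0.3 s (self-paced-reading pacing); texts are separated by 4 s.
  Word predictors are properties of the token, shared across participants;
  timing is per-participant. Sentences are 20 words, indexed for
  partitioning.
* **Predictors.** Frequency surprisal and contextual surprisal are
  bivariate Gaussian with correlation ρ = 0.4 on the surprisal scale
  (means/SDs 10±2 and 6±3 nats, typical of large-corpus unigram and
  transformer estimates); a word-length control (5±2) is independent.
* **Effects.** Standardized predictors act on the pre-link parameters
  through a decaying kernel `g(d)` (exponential with rate 4/s by default:
  13.5% of peak at 0.5 s, <2% at 1 s; a single-peaked gamma kernel is also
  available). Defaults place the effects on τ only — frequency 20,
  predictability 15, word length 5 ms/SD — reproducing the
  skewness-dominant pattern reported for reading-time distributions. A
  frequency × predictability product term (default 0) can be injected on
  τ to break additivity.
* **Mixed structure.** Per-participant offsets on (μ, σ̃, τ̃) with SDs
  (30, 5, 20) ms, centered so the population baseline is exact.
  Baseline exGaussian: μ = 300, σ = 50, τ = 150 ms (mean 450 ms).

What the generator does **not** emulate: oculomotor dynamics (saccade
planning, landing position, regressions arise only as region-index
sequences in the measures module's fixtures), lexical properties beyond
the three predictors, autocorrelated attention/fatigue processes, and
non-stationary effect shapes. Passing recovery tests therefore shows the
estimator recovers *this* class of generative structure from irregular
event streams — not that real reading obeys it.

## The deconvolutional model

Each network of a configuration maps standardized predictor features
(optionally plus pairwise products) and delay features `(d, log(1+d))`
through a tanh MLP to contributions for its target distributional
parameters; contributions are summed over the most recent 32 events
within 20 s (both configurable; reduced to 8 events / 4 s in the recovery
studies, ample for a kernel that is <2% by 1 s). Multiple networks over
predictor subsets express the null architectures. A "linear IRF"
configuration (no hidden layers, fixed exponential kernel) has a closed
form used for oracle tests and for simulation studies that need hundreds
of fits.

Design specifics:

* **No IRF output intercept.** The output layer's bias is frozen at zero,
  so an event contributes only through its feature values, never through
  its mere presence. With a free intercept, global σ corrections flowed
  through an implicit event-density channel during optimization and
  extrapolated catastrophically at dense event clusters out-of-sample.
  The cost is that a stimulus-rate main effect cannot be expressed; the
  generator contains none.
* **Zero-initialized output layer** — a fresh model predicts its baseline
  exactly; baselines start at method-of-moments exGaussian estimates.
* **Random effects.** By-participant offsets on the three baselines,
  by-participant multiplicative gains on each network's output (a compact
  stand-in for fully random network weights), and by-token-position
  intercepts on μ̃; all L2-shrunk toward zero (λ = 1e-4 per datapoint).
  Unseen participants at prediction time fall back to population effects.
* **Optimization.** Adam (lr 0.01 for neural configurations, 0.05 for the
  linear configuration), minibatches of 1024 responses, validation
  evaluation every 25–50 steps, early stopping on validation likelihood
  with the best checkpoint restored. Output contributions are scaled by
  10 so weights stay O(1). Per-datapoint score contributions are clipped
  at ±1e3 and parameter gradients elementwise at ±100: transient σ/τ
  excursions early in training otherwise produce unbounded gradients.
  A small L2 on network weights (1e-3 per datapoint) discourages
  coefficients the validation data cannot support.
* **Ensembles.** 10 independently seeded fits by default; the ensemble
  predicts as a uniform mixture, so its per-datapoint log-likelihood is
  the log of the mean of member densities. This makes the ensemble one
  predictive distribution and the permutation comparison between two
  ensembles well-defined.

## Testing protocol

The data partition cycles `i = (sentence + participant) mod 4`: train for
i ∈ {0, 1}, validation for 2, test for 3 — exactly 50/25/25 on complete
grids with both dimensions multiples of 4. Models never see test data;
comparisons use per-datapoint test log-likelihoods, paired by response.

The paired permutation test swaps the two models' likelihoods per
datapoint with probability ½; the statistic is the summed difference; p
is two-sided with the +1 correction (floor `1/(n_perm+1)`, default
n_perm = 10,000). Aggregate tests pool the per-datapoint difference
vectors across datasets and permute identically, reporting per-dataset
contributions. Null architectures follow three constructions: predictor
ablation from all networks; the two-network interaction null (each
critical predictor may interact with controls but not with the other,
against a matched two-redundant-network alternative); and the
three-network distributional null (one predictor removed from exactly one
parameter's network). Distributional-parameter interaction tests are not
run by default.

A caveat the simulation studies quantify: with small samples, the larger
model's extra overfitting makes the paired per-datapoint differences
consistently signed under H0, so the two-sided test runs hot — the
calibration studies measure ≈ 9% at α = 5% for the ablation comparison
(800-response replicates) and ≈ 12–15% for the matched two-network
interaction comparison (3,200-response replicates). The effect is
scale-invariant (the permutation z-statistic depends on the sign pattern
of the differences, not their magnitude, so shrinking the noise-fitted
coefficients does not remove it); it is a property of out-of-sample
nested-model comparison at small n, not of the permutation machinery,
which is exact under sign-symmetric exchangeability. The real analyses
this mirrors operate at hundreds of thousands of datapoints.

## Effect curves

Curves report deviations of the predicted response (the mean μ + τ, or a
named parameter) from a reference prediction. The reference convention —
recorded in every curve object — is: all predictors at their training-set
means, zero random effects, a single conditioning event at the probed
delay. Instantaneous curves probe delay 0 over ±2 SD (101 points);
interaction overlays condition the other predictor at mean and ±1 SD and
score additivity as the maximal spread between level curves;
timecourses probe a +1 SD step over delays 0–2 s (41 points).
Uncertainty bands are pointwise across-member percentiles, rounded
outward to order statistics (for ≤40 members this is the member min/max)
— conservative, and exactly monotone when members are added. They replace
variational credible intervals: an honest, testable substitute whose
interface leaves room for a posterior-based backend.

## Simulation studies (fixed designs)

* **Recovery**: default generator, 10-member reduced ensembles
  (1×16 hidden, 8-event/4-s window); scored by curve–truth correlation,
  per-parameter attribution, overlay additivity, timecourse decay, and
  the frequency-ablation permutation p at full scale.
* **Ablation calibration**: frequency effect set to 0; 200 replicates of
  800 responses; full linear-IRF configuration both sides.
* **Ablation power**: default effect sizes, 15 replicates at 20,000
  responses.
* **Interaction calibration/power**: τ-targeted linear networks with
  product features; 50 null replicates at 3,200 responses; power at
  interaction_coef = 30 ms/SD², 10 replicates at 20,000 responses.

Replicate sizes are the package's choices for desk-scale validation; the
generator's scientific defaults (effect sizes, correlation, kernel,
baseline) are never varied across studies.

## Predictors

All surprisals are natural-log. Unigram surprisal is the maximum-
likelihood `−ln c(w)/N` over observed types (so surprisal order equals
frequency order and the observed vocabulary normalizes exactly);
out-of-vocabulary queries fall back to an unknown-word score of
`−ln 1/(N+1)`. Bigram/trigram surprisal uses interpolated Kneser-Ney
with fixed discount 0.75: raw counts at the highest order, continuation
counts below, bottoming out at a proper base distribution over
vocabulary ∪ {end-of-sentence, unknown} (types by corpus count, EOS by
sentence count, unknown by one pseudo-count), so conditionals sum to one
exactly and unseen contexts reduce to the unigram-level estimate. This is
a simpler smoother than modified KN with estimated discounts; it is
oracle-tested exhaustively on small corpora. Word-level neural-LM
surprisal is the chain-rule sum of user-supplied subtoken surprisals;
the package never runs a language model.

## Reading measures

Scan-path, first-pass, and go-past durations are pure functions of the
fixation record. Visits merge maximal runs of same-region fixations;
durations run from region entry to the entry of the next different
region (saccade gaps belong to the visit they leave), the final visit
ending at its own last fixation. "From the left" means the previous
visit's region index is strictly lower, with record-initial entries
counting as leftward; go-past spans from first leftward entry to the
first entry of any higher region, and records ending before such an exit
leave that region's go-past unresolved (excluded, reported). Filters
apply to response vectors only — the event/predictor stream is never
filtered — in a fixed order (track quality → boundary → RT bounds →
accuracy/correctness → per-participant minimum), each exclusion
attributed to its first matching rule, with participant-level minima
evaluated on post-item-filter counts.

## Known limitations

* The IRF cannot express stimulus-rate effects (no output intercept).
* Ensemble-percentile bands understate posterior uncertainty for very
  small ensembles and carry no within-member parametric uncertainty.
* The small-sample anticonservatism of nested out-of-sample comparisons
  described above.
* Kneser-Ney here is the interpolated fixed-discount variant, not
  modified KN; absolute surprisal values differ slightly from production
  LM toolkits while orderings agree on the scales tested.
* Real-corpus ingestion expects the package's TSV formats; dataset
  download and raw eye-tracker parsing are out of scope.
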