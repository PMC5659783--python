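# Methods

## The model family

`vssm` implements a family of eight nested connectionist sequential-sampling
models of two-alternative value-based choice. Each alternative *x* is
represented by one accumulating decision signal *d_x(t)*, initialized to zero
at stimulus onset and updated in discrete 10-ms steps by the shared
recurrence

    d_x(t + Δt) = max{0, d_x(t) + f_x(t) + ε_x(t)},   ε_x ~ N(0, σ²) i.i.d.

The max operator rectifies negative activity (a threshold-linear activation);
the unit coefficient on *d_x(t)* means integration is perfect — recurrent
self-excitation and leakage are assumed balanced, so there is no
Ornstein–Uhlenbeck leak parameter. The first signal to reach the fixed
threshold *D* = 100 (an arbitrary scaling constant) determines the choice,
and the time of that step is the reaction time. No separate motor/nondecision
constant is added after crossing: the only nondecision component is the
predecision time *T₀* = 150 ms before which the value signal is zero,

    v_x(t) = 0 for t < T₀,   v_x(t) = V_x for t ≥ T₀

(and *v_x = V_x^a* in the SSCA model). Baseline input and noise act from
*t* = 0, so starting-point variability *emerges* from predecision
accumulation rather than being parameterized.

The drift term *f_x* distinguishes the models (two alternatives; *y* is the
other one):

| model | df | drift *f_x* | competition |
|-------|----|-------------|-------------|
| RACE  | 3  | b + g·v_x | none |
| NDD   | 3  | b + g·(v_x − v_y) | perfect subtractive input competition |
| SNFI  | 4  | b + g·(v_x − i_v·v_y) | imperfect subtractive input competition |
| DNFI  | 4  | g·(b + v_x)/(s + v_x + v_y) | divisive normalization (pool includes *x*) |
| CA    | 4  | b + g·v_x − i_d·d_y | lateral inhibition between accumulators |
| SCA   | 5  | SNFI drift − i_d·d_y | both, subtractive |
| DCA   | 5  | DNFI drift − i_d·d_y | both, divisive |
| SSCA  | 6  | SCA drift, v_x = V_x^a | plus static attentional power law |

Parameters and units: *b* (baseline/urgency input, activation units per
step), *g* (gain, activation per value unit per step), *σ* (noise SD per
10-ms step — simulations at another Δt must rescale σ by √(Δt/10 ms) and are
off-label), *i_v* ∈ [0, 1] and *i_d* ∈ [0, 1] (dimensionless inhibition
weights), *s* > 0 (semisaturation, value units), *a* ≥ 1 (attentional
exponent). The exact nesting relations (SNFI with *i_v*=1 ≡ NDD, SCA with
*i_d*=0 ≡ SNFI, SSCA with *a*=1 ≡ SCA, …) hold trial-for-trial under a
shared noise stream and are asserted as tests.

Latent values enter the model as raw rating ranks (1–4 for the default
design); the gain *g* absorbs the scale. Drift and noise are summed first
and rectified once, exactly as the recurrence is written — rectification is
never applied to inputs separately. When several signals cross *D* on the
same step, the winner is drawn uniformly at random (the models are
symmetric and no other convention is privileged). Trials that have not
crossed by *t_max* = 3000 ms (the task's response window) are flagged and
excluded downstream; at the bundled fitted parameter sets this affects
< 0.2 % of trials.

## Randomness

All randomness flows from one master seed through `numpy.random.SeedSequence`
children: one independent child stream per simulation batch (design cell or
subject), with all trials of a batch advanced in lockstep by a vectorized
update. Results are therefore reproducible bit-for-bit given the seed and
independent of the order in which batches are evaluated. Within each
optimizer restart the simulation seed is held fixed, so objective
evaluations share common random numbers and the objective is a
deterministic function of the parameters.

## Chi-square quantile fitting

Fitting follows the quantile-based chi-square method for simulation-only
models. The observed data are summarized per input vector (unordered value
pair): the frequency of either choice and, for any choice with ≥ 5 trials,
the 10/30/50/70/90 % RT quantiles (linear interpolation between order
statistics), defining six right-closed RT bins per choice. Trials faster
than 300 ms are removed first as contaminants. Two conventions deserve
note:

* **Empirical observed masses.** Observed bin proportions are counted from
  the data with the same binning convention used for predictions, rather
  than fixed at the nominal (.1, .2, .2, .2, .2, .1) masses. RTs live on a
  10-ms grid; with heavy ties the nominal masses are unattainable, whereas
  the empirical convention reduces to them in the continuous limit and
  makes the objective *exactly* zero when predicted and observed
  distributions coincide (so the saturated benchmark scores 0 in sample).
* **Tie pairs pool choices.** For equal-value pairs the two "choices" are
  the same event up to an arbitrary side label; their trials form a single
  pooled cell of frequency 1. This makes the objective exactly invariant to
  left/right relabeling, and loses nothing for these side-symmetric models.

The objective simulates 2,000 trials per input vector (20,000 total for the
default design), bins them by the observed edges, and accumulates

    χ² = Σ_vectors N_eff Σ_bins (p_obs − p_pred)² / max(p_pred, 10⁻⁴),

with a common effective count N_eff = (responded trials)/(number of
vectors), so every input vector carries equal weight regardless of how
often it was presented. Minimization is Nelder–Mead on transformed
parameters (log for positive parameters, logit for the unit-interval
inhibition weights, log(a−1) shifted for the exponent), with randomized
seeding in stages: a pool of random candidate starts is probed once each
(default 2× the restart count, drawn log-uniformly from broad plausible
ranges), the best become full simplex runs, and the overall winner is then
refined with progressively narrower fresh simplices (a collapsed simplex
cannot re-expand, so restarting it is the standard cure). The initial
simplex is deliberately wide (0.6 on the unconstrained scale ≈ ×1.8
natural-scale steps) so the search steps over the Monte-Carlo ruggedness
of the surface; with the default tight simplex the optimizer stalls far
from the optimum. Two further seeding/efficiency choices matter in
practice. For the divisive models the gain, baseline and semisaturation
are strongly coupled (the drift is g(b+v)/(s+Σv)), and independent random
draws almost never yield workable accumulation rates; starts therefore
sample the pre-onset drift g·b/s on a plausible scale (0.05–2.5 per step)
and solve for the gain. And an optional coarse stage runs the probing and
restart simplices with a reduced simulation size (e.g. 250 trials per
vector — cheap, noisier evaluations that still rank basins correctly),
reserving the full 2,000-trial objective for the refinement stage that
defines the reported fit. Library defaults are 20 restarts × 400
iterations with no coarse stage; the bundled experiments and tests use
3 restarts × 250 iterations with 24 probes and a 250-trial coarse stage,
which the parameter-recovery runs show is sufficient for this design.

Benchmarks: the *saturated* predictor reuses the training data directly
(maximal df, χ² = 0 in sample); the *null* predictor (three df) uses one
mean choice frequency and a single uniform RT distribution spanning the
mean per-cell minimum to the mean per-cell maximum. Model comparison uses
the χ² difference of nested fits referred to a χ² law with the df
difference (negative differences, possible under Monte-Carlo noise, clamp
to zero with a warning), and AICc = χ² + 2k + 2k(k+1)/(n−k−1),
BIC = χ² + k·ln n with the χ² objective standing in for the deviance and
*n* the number of scalar summary observations entering the objective (a
convention; it shifts all models' criteria jointly and cannot reorder
equal-*n* comparisons). For out-of-sample validation, datasets split
deterministically by parity: odd trials of odd subjects plus even trials
of even subjects form the training half.

## The regression battery

Trials are classified as *correct* (greater-valued option chosen),
*incorrect* (lesser chosen) or *indifferent* (equal values); non-responses
and RTs < 300 ms are dropped — the cutoff is applied identically to
empirical and simulated data so that model rows and data rows are computed
by the same pipeline. Values are normalized affinely so the scale minimum
is 0 and the maximum 1. Accuracy (indifferent trials excluded) is fitted by
maximum-likelihood logistic regression, RT in seconds by least squares per
category, each in two complementary parameterizations — (constant, greater,
lesser) and (constant, |difference|, sum) — which span the same column
space, so the second model's slopes are exactly the half-difference and
half-sum of the first's. Indifferent trials admit only the sum model. RT
coefficients are reported divided by the fitted intercept
("constant-normalized"); the SE is divided by the same intercept, with the
intercept's own uncertainty ignored — a first-order convention that matches
the scale of the reference SEs. Contrasts compare the absolute values of
two coefficients from the same fit with a two-tailed z test on the combined
standard error √(se₁² + se₂²); category RT comparisons use Welch's
two-sample t test, two-tailed throughout. Meta-analytic aggregation
averages coefficients across datasets with weights proportional to trial
counts; the aggregate SE is the weighted between-dataset dispersion
(unbiased weighted variance divided by the effective number of datasets) —
the between- rather than within-dataset choice is this package's
convention and is the one reported.

## The synthetic design generator

`DesignSpec` emulates the modeled food-choice paradigm: a 4-level value
scale, the 10 unordered pairs, 720 trials per subject. Balancing follows
the task's construction rule — trials are split evenly over the value
differences 0–3 first, then evenly over the pairs within each difference
bin (45/60/90/180 repetitions for differences 0/1/2/3 at 720 trials), with
remainders spread deterministically; a `balance="pair"` mode (72 per pair)
is available for uniform designs. The side of the greater value is
counterbalanced within each pair (±1), and no stimulus pair repeats on
consecutive trials. Subjects are homogeneous: the reference fits
concatenate trials across subjects, so per-subject parameter jitter is
deliberately absent (a hook for it would be a modeling change, not a
default).

What the generator emulates — balanced discrete designs, forced-choice
responses, a 3-s window, fast-guess contamination handled by the cutoff —
and what it does not: rating noise (latent values are exact ranks),
condition structure (response modalities are collapsed, as in the source
analyses), eye movements and fixation sequences, and trial-to-trial
parameter variability. Tests passing on synthetic data therefore validate
the *pipeline* (simulation → summary → objective → optimizer → regressions)
and the models' internal consistency, not the adequacy of any model for a
particular empirical population.

## Problem sizes and numerical choices

The battery reproductions use 20,000 trials per input vector (200,000
trials per model), matching the conditions under which the frozen reference
coefficients were produced; at that size the Monte-Carlo SE of each
coefficient is comparable to the reference SEs. Fitting and recovery
experiments use 2,000 trials per vector for both the generated data and the
objective's simulations. Recovery experiments refit a model to data
generated from itself and report signed relative errors per parameter.
Two caveats are documented rather than hidden. First, the divisive models
(DNFI/DCA) sit on a shallow (g, b, s) ridge — nearly proportional changes
of baseline, gain and semisaturation move the drift function less than the
Monte-Carlo noise at this problem size — so their raw parameter errors can
be large even when the fitted drift function, and hence behavior, is
essentially correct. Second, the 5–6-parameter hybrids (SCA, DCA, SSCA)
occupy narrow basins in a rugged landscape: fits seeded at the generating
parameters recover them to within ~10% median error, establishing local
identifiability, but global search at the reduced budgets used in the
bundled tests reaches the basin only unreliably; dependable de-novo fits
of these models need the full default budget (tens of restarts × hundreds
of iterations), which is hours rather than minutes of computation. The
four simpler models recover to within a few percent at every budget
tried.

Other numerical conventions: RT bins are right-closed at each quantile
edge (`searchsorted(..., side="left")`), used identically for observed and
predicted counts; predicted proportions are floored at 10⁻⁴ in the Pearson
denominator; quantiles use NumPy's `linear` interpolation; the logistic
fits flag (rather than report) perfectly separated data; RT fits require
≥ 10 trials per category. Degenerate inputs — zero noise, empty cells
after filtering, fewer than two input vectors — raise or flag explicitly
rather than returning numbers.

## Known limitations

* Only the two-alternative case is validated; the drift expressions follow
  the general *n*-alternative forms (NDD uses the max-minus-average
  generalization), but nothing above two alternatives is tested.
* The execution signal is reduced to the RT event; post-threshold motor
  dynamics and between-trial reset are out of scope.
* The chi-square objective is a fitting device, not a calibrated
  goodness-of-fit statistic; its absolute value depends on the binning
  conventions above, so only comparisons across models on the same summary
  are meaningful.
* The saturated benchmark scores exactly 0 in sample by construction;
  pipelines that predict via re-simulation would score slightly above 0.
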