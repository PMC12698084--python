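# Methods

This note documents the modelling choices behind `inequitylearn`: the task
generator, the seven choice models and their numerical treatment, the
fitting and validation pipeline, and known limitations.

## Task generator

**Offers.** Offers are splits of 100 cents; all amounts are the Receiver's
share `s` on a 0–100 scale with the fair point at 50. The five nominal
types (Receiver shares 10, 30, 50, 70, 90) are jittered per trial by an
integer drawn uniformly from [−9, 9]; whatever the Receiver gains the
Proposer loses, so shares always sum to 100. The jitter never moves a
nominal type across the fair point except for 50:50 offers, whose noisy
shares span 41–59.

**Schedules.** Baseline and Transfer present 5 trials of each type;
Experiment 1's Learning phase presents 20 of each (100 trials);
Experiment 2's Learning phase adds 25 extra trials of each moderate type
(45 × 70:30, 45 × 30:70) and withholds Teacher feedback on both extreme
types (90:10, 10:90). Order is fully randomized within phase. Fairness
ratings are elicited on a random 60% of trials within each offer type
(3 of every 5); the exact interleaving is not constrained. All counts and
the feedback-free set are configurable.

**Teacher.** Each condition's Teacher is a per-offer-type Bernoulli
rejection profile plus fixed 1–7 fairness ratings. Defaults: offer types
the condition is averse to are rejected with probability 0.9 — strong but
not perfectly deterministic — and fair offers plus all non-averse types
are always accepted (probability 0). The always-accept default matters for
the inference learner's dynamics: with a residual rejection probability on
non-averse advantageous offers, rare random rejections would ratchet the
learner's guilt estimate toward the large choice-implied bounds, and the
guilt trajectory under the Dis-I-Averse Teacher would no longer stay flat.
All probabilities and ratings are overridable via `TeacherProfile`.

## Choice models

Conventions shared by every model: actions are 1 = reject / 0 = accept;
feedback reward is 1 iff the learner's action matches the Teacher's
preferred action; the bin-indexed models (1, 3–5) key on the nominal offer
type, the Fehr–Schmidt models (2, 6) evaluate utilities at the noisy
share, and the similarity model (7) keys on the noisy integer share;
trials without feedback yield predictions but never state updates.

Parameters and fitting boxes:

| model | parameters (box) |
|-------|------------------|
| 1 random choice | p per type ∈ [0, 1] |
| 2 static preference | α, β ∈ [0, 10]; τ ∈ [10⁻⁴, 20] |
| 3 basic RL | η ∈ [0, 1]; τ |
| 4 offer-sensitive RL | η per type ∈ [0, 1]; τ |
| 5 free-initial RL | η; τ; Q₀(reject, type) ∈ [0, 1] |
| 6 preference inference | η ∈ [0, 5]; τ; α₀, β₀ ∈ [0, 10] |
| 7 similarity RL | η ∈ [0, 1]; τ; σ ∈ [10⁻², 200]; α, β ∈ [0, 3] |

τ has no natural upper bound; its fitting box [10⁻⁴, 20] spans effectively
random to fully deterministic choice on the 0–100 utility scale, and
random starts sample it log-uniformly. σ's lower edge is kept strictly
positive (10⁻²) because the Gaussian similarity kernel is degenerate at 0;
operationally σ = 10⁻² already confines updates to the experienced offer.

**Delta-rule models (3–5).** Q-values per (action, offer type), updated as
Q ← Q + η·(R − Q) for the taken action and experienced type only. Initial
values are 0.5 except model 5's free initial rejection values (initial
acceptance values stay at 0.5 — the free-parameter set covers rejection
only).

**Preference inference (6).** The learner assumes the Teacher rejects
exactly when U_accept < 0. A choice on a disadvantageous offer implies a
threshold s/(50−s) for envy (rejection: a lower bound; acceptance: an
upper bound); advantageous offers imply the threshold s/(s−50) for guilt,
derived from the same utility algebra. The running estimate moves a
fraction η toward the threshold only when it violates it, and is clipped
to [0, 10] after each update (η may exceed 1, so a single update can
overshoot the bound). Envy is touched only by disadvantageous offers,
guilt only by advantageous ones; exactly-fair shares (s = 50, possible
only for noisy 50:50 offers) are uninformative and produce no update. The
learner's own action is irrelevant to the update — only the Teacher's
revealed preference constrains the estimates. The update classifies the
offer by its *noisy* share, consistent with the model evaluating utilities
at the noisy share: a 50:50 offer presented at s = 45 is genuinely
(mildly) disadvantageous and carries the corresponding bound.

**Similarity RL (7).** Q-values over every integer offer 1–100. Initial
rejection values follow a V-shape max(α/50·(50−s), β/50·(s−50)); initial
acceptance values are 0.5 (unspecified by the V-shape; chosen for
consistency with models 3–5, configurable via the class attribute). One
feedback trial updates the taken action's value at every offer with
effective rate η·exp(−Δ²/2σ²), Δ the distance to the experienced offer.

**Numerics.** The softmax is evaluated in the numerically stable logistic
form with max-subtraction semantics, and all choice probabilities are
floored to [10⁻¹², 1 − 10⁻¹²] so the log-likelihood stays finite when a
near-deterministic parameter corner mispredicts an observed choice; away
from such corners the floor is inert.

## Fitting

Per subject, per model: NLL = −Σ_t ln P(action_t | state_t) over the
ordered Learning-phase trials, state advanced only on feedback trials.
Optimization is L-BFGS-B within the parameter boxes from uniform random
starts (log-uniform for τ), 100 starts by default, convergence tolerance
10⁻⁹ on the objective; the best converged start wins and ties go to the
first found. Two likelihood routes exist: compiled per-model kernels
(numba) and a literal per-trial loop over the model objects; the loop is
the reference and the suite holds the two to 10⁻¹⁰ agreement. Model
comparison reports summed AIC, mean AIC and per-subject best-fit counts;
the winner is the minimal summed AIC. In the Experiment-2 design the
candidate set drops the two per-type RL variants (models 3 and 4).
Choices on feedback-free trials are included in the likelihood by default
(their predictions are well defined even though states freeze); a flag
excludes them.

## Synthetic cohorts

A generative agent owns Fehr–Schmidt preferences (α_own, β_own, τ_own)
driving Baseline choices, a learning model driving Learning-phase choices,
and a contagion weight ω ∈ [0, 1]. Transfer choices use the blended
preferences α_eff = (1 − ω)·α_own + ω·α_learned (likewise β). The blend is
a generator-side operationalization of preference contagion — the
behavioural phenomenon it emulates is a Baseline-to-Transfer shift toward
the Teacher — and ω = 0 is an exact no-contagion null. For learners
without explicit envy/guilt parameters, learned (α, β) are obtained by
least-squares inversion of the final rejection-probability profile through
the Fehr–Schmidt + softmax map at the five nominal offers; this inversion
is well conditioned only where the probed probabilities are interior
(small τ), which is acceptable for its decorative generator-side role.

Prior boxes default to the fitting boxes, drawn plain-uniform. The
`REALISTIC_PRIORS` preset narrows them to a population resembling typical
Western samples — envious (α_own ∈ [1, 5]) but hardly guilty
(β_own ∈ [0, 1]), decisive (τ ∈ [0.05, 0.5] own, [0.05, 0.3] learning),
effective learners (η ∈ [0.5, 2], α₀, β₀ ∈ [0, 2]) with substantial
contagion (ω ∈ [0.5, 1]). Synthetic fairness ratings are an affine map of
inequity onto 1–7 with Gaussian noise (sd 0.5), rounded and clipped; they
complete the record schema and never enter any likelihood.

What the generator does **not** emulate: reaction times and deadlines,
attention lapses, dropout, disbelief in the cover story, any dependence of
the Teacher on the participant's behaviour, and any participant whose
Learning-phase policy is outside the seven-model family. Passing tests
therefore demonstrate internal consistency of the pipeline (the estimator
recovers what the generator produced), not that human learners obey these
models.

## Validation

**Parameter recovery** draws truths uniformly in each box, simulates the
Experiment-1 learning schedule (subjects split evenly across the two
Teacher conditions), refits with the standard pipeline, and reports
Spearman and Pearson correlations, bias and RMSE per parameter. Rank
correlation is the headline statistic because uniform-box truths pile
recovered values against the bounds. The suite's gate is ρ ≥ 0.5 per
parameter at 200 subjects and 25 starts.

A structural caveat applies to τ: on a 0–100 utility scale, choice
probabilities saturate once τ exceeds roughly 0.3, so all larger values
produce identical likelihoods for a typical trial sequence. Under
uniform-box truths ~98% of subjects lie in that saturated regime, where no
estimator can order them; measured ρ for τ is accordingly near zero while
η, α₀ and β₀ recover well (ρ ≈ 0.96 / 0.76 / 0.84 at the gate's problem
size). This is an identifiability ceiling of the design, not an optimizer
failure — raising the start count does not change it, and restricting
truths to the sub-saturation range would make τ recoverable but would test
a different population than the box defines. The corresponding suite
check is expected to flag τ.

**Model recovery** generates replicate cohorts from one model and scores
which candidate wins the summed AIC per cohort. The gate pits the
preference-inference generator against the static-preference (no
learning) and free-initial-value RL (learning, no structure) candidates:
20 cohorts of 20 subjects, 15 starts, ≥ 60% diagonal. Measured: 20/20.

**Posterior prediction** replays each fitted subject against their
condition's Teacher on fresh randomized schedules (default 100
simulations per subject; the curve SE shrinks as 1/√n_sims), averaging
within subject before across subjects (between-subject SEs, matching the
error-bar convention of the descriptive summaries). For the inference
model the mean envy/guilt trajectories are recorded per trial.

**Directional phenomena** (checked on `REALISTIC_PRIORS` cohorts of 100
per condition): learning-phase rejection trends and Baseline→Transfer
deltas on advantageous offers are larger under the Adv-Dis-I-Averse
Teacher than the Dis-I-Averse Teacher (beyond 2 SE); in the Experiment-2
design, rejection of the feedback-free 10:90 offers rises only in the
Adv-Dis-I-Averse condition (generalization through the inferred guilt
parameter); static-preference cohorts show no trend anywhere (negative
control).

## Descriptive statistics

Rejection rates are per subject × offer type; cells a subject never saw
are missing, not zero, and are excluded from condition means. Contagion is
the per-cell Transfer-minus-Baseline rate; learning trends are per-cell
least-squares slopes of binary rejection on the within-type trial index.
These are deliberately descriptive stand-ins for inferential mixed-effects
regressions, which are out of scope here; the tidy CSV schema is kept
stable so such models can be run externally.

## Problem sizes

Default study conditions mirror the task designs: 100 subjects per
condition for phenomenon checks, 200 subjects for parameter recovery.
The fitting default is 100 random starts; the validation suite and the
acceptance script use 12–25 starts, which the multi-start monotonicity
property and spot checks against 100-start fits show to be sufficient for
these likelihood surfaces. The acceptance script's model-recovery stage
uses 12 cohorts of 15 subjects.

## Known limitations

* τ's magnitude is unidentifiable above likelihood saturation (above).
* The inference model's bound-update rule is deterministic given the
  Teacher's choice; it cannot represent graded confidence, and a single
  anomalous rejection can move an estimate far toward a large bound
  (visible if Teacher profiles are configured with residual rejection
  noise on non-averse types).
* The contagion weight ω is an artifact-level construct: the generator
  needs *some* mechanism linking Learning to Transfer, and a convex blend
  is the simplest; nothing here validates it against human transfer data.
* Fairness ratings are generated but never modelled.
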