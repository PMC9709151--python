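# Methods

## The repeat paradigm, as modelled here

A subject is trained to perform a small repertoire of arbitrary behaviors
on command, plus a *repeat* command meaning "perform your most recent
action again". A session is an ordered list of trials of these kinds:

- **control** — an action command followed by a *different* action
  command (no repeat), preventing a blanket always-repeat strategy;
- **single repeat** — an action command followed by one repeat command;
- **double repeat** — an action command followed by two consecutive
  repeat commands, both scored against the *original* action;
- **delayed repeat** — a single repeat presented after an adaptive delay;
- **novel probes** — a newly trained, never-repeated behavior followed by
  a repeat command, once at the session start and once after 2–4 control
  trials (the *critical* trial).

The package builds these plans, simulates subjects on them, and fits the
analysis models. Session compositions are fixed: repeat-test sessions
have 26 trials (4 single repeats, 8 double repeats, 14 controls — the
stated per-condition counts of 4/8/10 sum to 22, so the session is padded
with 4 additional control trials to reach the stated length of 26;
repeat-trial analyses are unaffected by the padding), criterion sessions
have 20 trials (12 ending in a repeat command, 8 controls), and the
delayed block has 6 sessions of 16 single-repeat trials.

### Counterbalancing

Within a session, behaviors are assigned to trial slots in balanced
blocks: each behavior appears `floor(n/k)` times per condition, any
remainder is drawn without replacement, and the trial order is then
shuffled. All randomization flows from one integer seed per session, so a
plan is a pure function of its inputs and seed. No constraint is imposed
against the same behavior on consecutive trials.

### The delay staircase

The delay between action and repeat command starts at 3 s, increases 3 s
after a correct response and decreases 3 s after an error, clamped at a
3 s floor (keeping log-delay defined and all delays on the 3 s grid);
there is no ceiling by default. The staircase state carries across
sessions of a delayed block. Note that the resulting delay sequence is a
strongly autocorrelated random walk around the point where the subject's
success probability is 1/2: per-run mean delays fluctuate by several
seconds over a few hundred trials, which matters when choosing run
lengths for stationarity checks (the test suite uses 2000-trial runs).

## Synthetic agents

An agent's repeat success follows the same structure the analysis models
assume: `logit(p) = α + γ_behavior (+ β·log t)` with `α` the individual
baseline (log-odds), `γ` per-behavior offsets, and `β` the retention
slope per unit log-delay. Failed repeats respond uniformly over the
remaining trained behaviors — the minimal error model consistent with the
uniform 1/4 chance level; a `chance`-mode agent responds uniformly over
all trained behaviors, reproducing the 1/4 and 1/16 reference rates. The
second repeat of a double is scored against the original command (not the
possibly wrong first response), which is what makes 1/16 the analytic
both-correct chance rate. Control trials are simulated as compliant by
default (`control_correct_prob=1`), since only repeat trials are
analyzed. Novel behaviors reuse the same model with per-behavior offsets
drawn once per agent from `normal(0, 0.45)` unless set explicitly —
0.45 being the scale of the behavior-offset spread the repeat analyses
typically estimate.

The reference cohort (`default_config()`) is three subjects with
`α = 1.1` (≈75% undelayed success, the performance level the paradigm's
published studies report for well-trained subjects) and slope `−0.6`,
running the full design: one criterion session, eight 26-trial repeat
sessions, six 16-trial delayed sessions and three novel probes each.

### What the generator does and does not emulate

It reproduces the trial structure, counterbalancing, staircase dynamics
and the binomial outcome model, so recovery tests exercise exactly the
inference path real data would take. It does **not** emulate learning or
fatigue within/across sessions, serial dependence of errors, biased error
responses (e.g. a preferred behavior), or experimenter mistakes. Passing
recovery tests therefore shows the estimators are consistent under the
models' own assumptions, not that those assumptions hold for any given
animal.

## Models and sampler

The two hierarchical binomial models (see README for the full
specifications, including every prior) are fitted on the unconstrained
scale with a non-centred parameterization (`α = ᾱ + σ_α z`, `z ~ N(0,1)`,
scales sampled as logs with the exponential-prior Jacobian included).
Bernoulli rows are aggregated to binomial cells per individual × behavior
(× delay), which leaves the likelihood unchanged and makes evaluations
cheap.

Sampling uses emcee's affine-invariant ensemble sampler behind a fit
contract that any backend satisfying the quadrature-oracle and recovery
suites could implement. Choices that matter:

- **Moves**: an 80/20 mixture of differential-evolution and DE-snooker
  moves; these mix ~2.5× faster than the default stretch move on these
  mildly heavy-tailed posteriors (integrated autocorrelation ~40 vs ~100
  steps on the prior-only target).
- **Initialization**: walkers start in a 0.1-sd Gaussian ball around the
  posterior mode (Nelder–Mead then L-BFGS refinement), so short warmups
  suffice.
- **Chain structure**: `n_chains` independent ensembles are run;
  each advances every walker `n_iterations` steps, discards `n_warmup`,
  and the pooled walker trajectories are thinned to
  `n_iterations − n_warmup` draws per chain — matching the per-chain draw
  count a single-trajectory sampler with the same settings would report.
  Defaults are 4 chains × 8000 iterations, 500 warmup.
- **Diagnostics**: split-Rhat (arviz) across the independent ensembles; a
  `ConvergenceWarning` is raised above 1.05. Ensemble moves have no
  divergence concept, so the reported divergence count is structurally 0.
- **Accuracy**: on a collapsed one-individual, one-behavior dataset the
  posterior mean and 89% interval of the success probability agree with
  an independent numeric-quadrature oracle to < 0.01 at 4000 iterations
  (the lower tail is the slowest quantity; at 1500 iterations its error
  can reach ~0.013).

Summaries are central percentile intervals (not HPD), reported at 89% by
convention. Average performance is `logit⁻¹(ᾱ)` pushed through the draws
— the average individual on an average behavior; per-individual and
per-behavior predictions index the group-level draws instead. For
population-level delay predictions the slope term uses the across-group
means of the ζ and ι draws.

### Degenerate inputs and edge rules

- An empty trial table is accepted and returns the prior (used by the
  prior-recovery tests).
- Non-binary outcomes and non-positive delays raise errors before
  sampling.
- The criterion rule is exact at 12 repeat trials (pass ⇔ ≥ 7 correct);
  other counts trigger a warning and a `ceil(7/12·n)` generalization,
  which is an extension beyond the published design and flagged as such.
- The staircase clamps at its floor rather than erroring on an error at
  the floor.

## Problem sizes used by the test and acceptance suites

Quadrature cross-checks use 40 trials (30 correct) in one cell; interval
coverage uses 20 replicate studies of 3 individuals × 4 behaviors × 96
single-repeat rows with true average performance 0.75 (the fitted 89%
interval must cover the truth in ≥ 16 of 20); slope recovery uses ~500
delayed trials per individual generated by the staircase from agents with
slope −1 and true p(10 s) = 0.4. Model fits in these suites run at 1500–
5000 iterations rather than the 8000-iteration default; the quantities
checked (posterior means, 89% quantiles) are stable at these sizes as the
quadrature comparison shows.

## Known limitations

- With three individuals the population mean ᾱ is prior-influenced:
  population-average predictions shrink toward the prior centre, so
  recovery checks at this scale are interval-coverage checks, not
  point-accuracy checks.
- The delay model has no global mean-slope parameter (slopes are centred
  at zero only through the ζ and ι priors), so a shared nonzero slope is
  absorbed jointly by both component groups; per-individual slope
  summaries should combine them, as `repeatlab` does.
- The generator's independence assumptions (see above) make synthetic
  data cleaner than real sessions; Rhat and the convergence warning are
  the only safeguards carried over to messy real tables.
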