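# repeatlab

Tools for designing, simulating and analyzing **action-repeat ("repeat
paradigm") experiments** — studies in which an animal is trained to
re-perform its own most recent commanded action, probing memory for
self-performed behavior. The package targets the workflow used with small
cohorts of individually tested subjects (the reference design is three
macaws trained on four behaviors): counterbalanced session plans mixing
single-repeat, double-repeat and control trials, an adaptive ±3 s delay
staircase for memory retention, a novel-behavior generalization probe, and
Bayesian multilevel analysis of the resulting binary outcomes.

It is aimed at comparative-cognition researchers who want to plan such an
experiment, pilot its statistical power on synthetic subjects, or analyze
trial tables from a completed study.

## The models

Repeat performance is analyzed with a multilevel binomial model with
partial pooling over individuals and behaviors,

```
response_i ~ binomial(1, p_i)
logit(p_i) = α_individual[i] + γ_behaviour[i]
α ~ normal(ᾱ, σ_α)        ᾱ ~ normal(-0.5, 1)
γ ~ normal(0, σ_γ)
σ_α ~ exponential(1)       σ_γ ~ exponential(2)
```

with the ᾱ prior recentred at −1 for the double-repeat variant, so that
prior mass concentrates near the respective chance levels (1/4 for a
single repeat, 1/16 for both repeats of a double, with four behaviors).
Retention over delay *t* is modelled by adding a multilevel slope on log
delay:

```
logit(p_i) = α_individual[i] + γ_behaviour[i] + β_i · log(t_i)
β_i = ζ_individual[i] + ι_behaviour[i]
ζ ~ normal(0, σ_ζ)         ι ~ normal(0, σ_ι)
σ_α, σ_γ, σ_ζ, σ_ι ~ exponential(2)
```

Models are fitted by ensemble MCMC (emcee, 4 chains, 8000 iterations with
a 500-iteration warmup by default), summarized with posterior means and
central 89% percentile intervals, and monitored with split-Rhat.
See `docs/methods.md` for sampler details and design choices.

## Worked example

Simulate a full study for three synthetic birds with ~75% repeat ability
and a decaying retention slope, then analyze and fit:

```bash
repeatlab simulate --seed 1 --out trials.csv
repeatlab analyze --data trials.csv --report report.txt
repeatlab fit --model single --data trials.csv --config quick.yaml --out posterior/
```

where `quick.yaml` reduces the sampler settings for a fast fit (any
`RunConfig` field can be set this way; omitted fields keep their
defaults):

```yaml
seed: 1
mcmc: {n_chains: 4, n_iterations: 2000, n_warmup: 500}
```

which prints (seed 1):

```
single repeats: 225/288 correct (78.1%; chance 25.0%)
double repeats: 118/192 both-correct (61.5%; chance 6.25%)
criterion Bird1/Bird1_criterion: 10/12 correct -> PASS (threshold 7)
...
novel behaviors Bird1: 2 of 3 successful
single: average performance 0.744 (89% PI 0.634-0.816), max Rhat 1.047
```

Reading: pooled over 288 single-repeat observations (the first repeat of
each double-repeat trial counts as a single-repeat observation), the
cohort repeated correctly 78.1% of the time against a 25% guessing
baseline; all three birds cleared the 7-of-12 pre-test criterion; and the
fitted model puts the average individual's success probability at 0.744
with an 89% interval of 0.63–0.82, consistent with the generating value
of 0.75. The same library surface is available in Python
(`repeatlab.generate_study`, `repeatlab.fit_repeat_model`, …), and
`repeatlab run` executes the whole pipeline into a report bundle with a
reproducible run log.

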