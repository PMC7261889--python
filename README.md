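# dyadte

Directed information flow in dyadic rhythmic coordination.

When two people jointly control one object — here, a virtual ball that
both players steer by rhythmically tilting one axis each of a shared
tablet — coordination emerges without words. `dyadte` quantifies that
coordination with **transfer entropy** (TE): for each 1-minute trial it
estimates, in both directions, how much one player's movement history
improves prediction of the partner's next movement beyond the
partner's own history,

```
TE(X→Y) = Σ p(y_{t+1}, y_t^n, x_t^m) · log₂ [ p(y_{t+1} | y_t^n, x_t^m) / p(y_{t+1} | y_t^n) ],
```

estimated with the Kraskov–Stögbauer–Grassberger k-nearest-neighbour
conditional-MI method on the raw 60 Hz gyroscope signals (and, as an
exact oracle for validation, with a discrete plug-in estimator). On top
of the per-trial estimates the package provides

* **surrogate significance testing** — the observed TE against a null
  built from 1,000 random cross-dyad re-pairings of the source channel,
  with per-trial Wilcoxon tests against 0.05 and Bonferroni–Holm
  correction;
* **leader–follower inference** — TE(A→B) − TE(B→A) asymmetry, exact
  sign tests, seat-exchange-aware person indexing, and sign-reduced
  correlation with post-experiment questionnaires;
* **task performance** — mean absolute tracking error against the
  circular or rotating elliptic target, and the error-vs-asymmetry
  ("bell shape") table;
* a **simulator** of the whole paradigm (asymmetrically coupled phase
  oscillators driving a spring-anchored ball, trial/seat-exchange
  schedules, learning ramps) providing ground truth for validation.

It is aimed at researchers in joint action, interpersonal coordination
and behavioural neuroscience who want a self-contained, validated TE
pipeline for continuous dyadic control signals.

## Worked example

```python
from dyadte import DyadCoordinationModel, ExperimentSchedule, simulate_experiment

trials, truth = simulate_experiment(ExperimentSchedule.design_A(4, seed=11))
results = DyadCoordinationModel(trials).fit()
print(results.summary())
```

```
Dyadic coordination transfer-entropy analysis
======================================================
pairs:    4    trials/pair:  15    samples/trial: 3099
estimator: KSG k=4, histories m=1, n=1, delay=1, units=bits, discard=500
------------------------------------------------------
mean total TE          1.7094 bits (SD 0.0393)
mean |TE asymmetry|    0.0317 bits
learning: trial 1 total 1.6338 -> final trial 1.7454 bits
------------------------------------------------------
pair     verdict     mean diff    sign p
pair01   A_leads        0.0306    0.0010
pair02   B_leads       -0.0380    0.0010
pair03   A_leads        0.0319    0.0001
pair04   B_leads       -0.0238    0.0001
```

Each trial keeps 3,100 of its 3,600 samples after the 500-sample
initialization discard (3,099 embedded rows at m = n = 1). *Mean total
TE* is TE(A→B) + TE(B→A) averaged over all trials — the overall
coupling strength — and rises across trials (1.63 → 1.75 bits) because
the simulated cohort couples more tightly as it "learns". The verdicts
come from an exact sign test on the per-trial TE differences; all four
match the simulator's ground truth (`truth` lists which player has the
larger outgoing coupling: A, B, A, B). Surrogate p-values, learning
curves, per-condition contrasts, tracking errors and questionnaire
correlations hang off the same results object
(`results.significance()`, `results.learning_curve()`,
`results.error_vs_te()`, `results.sign_correlations()`).

The same pipeline is scriptable from the shell:

```
dyadte simulate --design A --pairs 10 --seed 1 --out cohort/
dyadte te --in cohort/ --out results.tsv
dyadte surrogate --in cohort/ --n 1000 --seed 2 --out surro.tsv
dyadte roles --te results.tsv --out roles.tsv
dyadte error --in cohort/ --out perf.tsv
dyadte report --te results.tsv --roles roles.tsv --perf perf.tsv --out report/
```

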