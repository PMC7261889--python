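# Methods

`dyadte` analyses directed information flow between the two control
signals of a dyad performing a joint rhythmic task. This note documents
the models, estimators and statistical procedures it implements, the
defaults and why they were chosen, and what the bundled simulator does
and does not emulate.

## The task and its signals

Two players jointly steer a virtual ball on a tablet screen: each
player rhythmically tilts one tablet axis (transversal for seat A,
longitudinal for seat B), the combined tilt accelerates a ball that is
tied to the screen centre by a weak spring, and the goal is to keep the
ball on a target line — a circle of radius 4.475 cm, or an ellipse with
semi-axes 5.47 and 4.235 cm rotating at 2.5 rev/min. Because the two
axes are orthogonal, accurate tracking requires the two players to
oscillate with a 90° phase difference. The recorded signals are the two
gyroscope channels (tilt angular velocity, rad/s) and the ball path
(cm), all at 60 Hz, in 1-minute trials. The first 500 samples (8.3 s)
of every trial are discarded as initialization transient, leaving 3,100
samples per trial.

## Transfer entropy

For source X and target Y with history lengths (Markov orders) m and n,
transfer entropy is the conditional mutual information

    TE(X→Y) = I(y_{t+1}; x_t^m | y_t^n)
            = Σ p(y_{t+1}, y_t^n, x_t^m)
              log[ p(y_{t+1} | y_t^n, x_t^m) / p(y_{t+1} | y_t^n) ],

where x_t^m = (x_t, …, x_{t−m+1}) and analogously for y. It is
asymmetric and model-free: it measures how much the source's past
reduces uncertainty about the target's next sample beyond the target's
own past. All results are in bits by default (nats via the config).

Two estimators:

* **Plug-in** (`te_plugin`, `plugin_te_from_joint`): direct evaluation
  of the defining sum on empirical or enumerated joint frequencies over
  a finite alphabet (capped at 64 symbols to catch continuous data
  passed by mistake). 0·log(·) terms contribute 0; the estimate is
  non-negative up to rounding. This is the oracle the continuous
  estimator is validated against.
* **KSG k-NN** (`te_ksg`): the Kraskov–Stögbauer–Grassberger-style
  conditional-MI estimator (Frenzel–Pompe form). For each embedded row
  the max-norm distance ε to its k-th nearest neighbour in the joint
  space (y_{t+1}, y^n, x^m) is found; neighbours with distance
  strictly below ε are counted in the subspaces (y^n), (y^n, y_{t+1})
  and (y^n, x^m); the estimate is
  ψ(k) + ⟨ψ(c_yn+1) − ψ(c_yn,yf+1) − ψ(c_yn,xm+1)⟩ / ln 2.

### Numerical choices

* **Histories m = n = 1, delay 1, k = 4** by default. k = 4 is standard
  KSG practice; first-order histories suit the smooth, strongly
  autocorrelated 60 Hz gyro signals. Every output table records the
  (m, n, k) used.
* **Tie-breaking jitter.** k-NN counting breaks down on exactly
  repeated values (quantised inputs). A seeded uniform jitter of
  1e-8 × the series range is added. The jitter stream is keyed by the
  *series content*, not by the embedded column: lagged copies of the
  same series (and a series embedded against itself) receive one
  coherent jitter realisation. This keeps the strict-inequality counts
  consistent — independent per-column jitter produces a spurious
  ≈ −0.08 bit offset on the self-prediction null TE(x→x) — and makes
  relabelling symmetries exact: swapping the two channels of a trial
  exchanges TE(A→B) and TE(B→A) bit for bit.
* **Small samples.** Estimates on fewer than 1,000 rows trigger a
  warning (estimates on this task typically stabilise around 1,000
  samples). A constant channel yields 0 bits with a warning rather than
  an error.
* **Sign of estimates.** The plug-in estimate is ≥ 0 by construction;
  the KSG estimate is nearly unbiased and may be slightly negative for
  weakly coupled data (magnitudes beyond −0.1 bits on default settings
  indicate a misuse, not noise).

Person-indexing: channels map to persons through the seat metadata
(`resolve_channels`), so TE(A→B) always means *person* A to *person* B
even across seat exchanges.

## Surrogate significance

The null hypothesis is "no directed coupling". The primary surrogate
scheme (**cross pairing**) replaces the source channel with the
same-role channel of a uniformly drawn different dyad (same trial index
when available), recomputing TE with identical settings — this destroys
the coupling while preserving both marginal dynamics; 1,000 pairings
per TE value by default. A secondary **block shuffle** (cyclic rotation
of the source by ≥ 10 s) covers single-dyad use. The empirical p-value
uses the add-one rule p = (1 + #{null ≥ observed}) / (n_surrogates + 1)
so p = 0 cannot occur.

Cohort-level inference follows the per-trial recipe: for each trial
index, the per-pair surrogate p-values are tested with a one-sample
Wilcoxon signed-rank test against the constant 0.05, one-sided (values
below the conventional level). Zeros are dropped, ties mid-ranked; the
null distribution is exact for n ≤ 25 (characteristic-polynomial
convolution over the observed signed ranks, valid with ties) and a
continuity-corrected normal approximation with tie-corrected variance
Σr²/4 above. The per-trial p-values are Bonferroni–Holm corrected
across trials.

A finite donor pool correlates the null draws (surrogates share
donors), which inflates the nominal rejection rate by roughly +1/D for
D distinct donors. Calibration studies in the test suite therefore use
~100 donor dyads; with few available dyads the surrogate test should be
read as slightly anti-conservative.

## Roles and subjective reports

The per-trial difference TE(A→B) − TE(B→A) is the leader–follower
asymmetry. A pair's verdict (`classify_roles`) is a two-sided exact
sign test on the per-trial signs of that difference (zeros dropped):
A_leads/B_leads when the test rejects at α = 0.05 with the matching
majority sign, no_leader otherwise. For seat-exchanging designs the
series is split by seating arrangement and "seat invariance" reports
whether the person-indexed sign agrees across both seatings.

Subjective reports are reduced to signs: open leadership answers coded
{1, 0, −1} = {I was leader, no leader, partner was leader}, and both
the codes and the 7-point Likert ratings (Q1: help given, Q2: help
received) are differenced between players and sign-reduced. Objective
and subjective signs are correlated with a plain Pearson coefficient
(ties retained; two-sided p via the t transform; 95% CI via Fisher z),
the objective sign being the mean TE difference over the final ⌈T/3⌉
trials — the questionnaire is answered once at the end, so the last
third is taken as representative. For the 30-trial design the last 10
trials are used regardless of seating (the per-seating breakdown is
also available).

## Performance

Tracking error is the mean absolute distance between the ball and the
target centreline over the trial (after the standard discard): radial
offset for the circle; orthogonal distance for the ellipse, computed by
a Brent root solve on the nearest-point condition
(ap/(t+a²))² + (bq/(t+b²))² = 1 (accurate to ~1e-9 cm against dense
parametric brute force; equal axes reduce exactly to the circle case).
The ellipse's orientation at time t is 2π·(2.5/60)·t with phase 0 at
t = 0 (configurable); absolute trial time is preserved through the
discard so the rotation phase stays aligned. The **normalised error**
divides by the target's mean radius (circle: radius; ellipse: average
of the semi-axes) — the quantity itself does not define a
normalisation, so this package states its own in every output header.
Line width is reported but not subtracted. The error-vs-coordination
table pairs each trial's TE difference with its normalised error and
summarises the error spread in |ΔTE| bins (the characteristic pattern
is a bell: near-symmetric dyads span the whole error range, strongly
asymmetric dyads cluster at low error).

## The simulator

There is no generative model of human players to import, so the
generator encodes the standard dynamical-systems reading of rhythmic
interpersonal coordination: Kuramoto-type phase oscillators with
directional coupling,

    dφ_i/dt = ω_i + K_i sin(φ_j − φ_i − Δ_i) + σ_i ξ_i(t),

integrated by Euler–Maruyama at the sample step (1/60 s). K_i
(`coupling_in`) is how strongly player i adjusts to the partner;
leader–follower is *pure coupling asymmetry* (the follower has the
larger K; equal K is the no-leader ground truth). The offsets Δ_i put
the locked state at the task's 90° lag. Tilt is θ_i = a sin φ_i; the
emitted gyro is the drift-based tilt velocity a cos(φ_i)·(dφ_i/dt)|drift
plus white measurement noise (0.01 rad/s SD). The phase diffusion
perturbs the movement itself but is not re-injected into the
observation at 1/dt scale — a gyroscope reading of smooth finger
movement does not contain white velocity noise of that magnitude, and
doing so buries the coupling signal. The ball is a damped driven
spring, r̈ = −k r − c ṙ + g·(θ_x, θ_y), integrated by semi-implicit
Euler.

Defaults (one set, chosen once): natural frequency 1 Hz (a comfortable
finger-oscillation rate), tilt amplitude 0.1 rad, follower coupling
2.0 s⁻¹ with a 4:1 leader asymmetry, phase noise 0.15 rad/√s (locked
relative-phase SD ≈ 4°, the skill level of a practised dyad), spring
9 s⁻², damping 4 s⁻¹, tilt gain 1767.8 cm s⁻²/rad so that the forced
response at 1 Hz and 0.1 rad amplitude has the circular target's
radius. Frequencies are jittered ±0.15 rad/s SD across players. The
experiment scheduler reproduces the two designs (A: 15 trials; B: 30
trials with seats exchanged every 5) and a monotone learning ramp
scales coupling from 0.4× (trial 1) to 1× (final trial); seat exchange
is a pure channel re-routing with no re-learning penalty.

What the simulator does *not* emulate: amplitude and frequency
adaptation, intermittent or turn-taking coordination strategies,
tremor/measurement artefacts beyond white noise, fatigue, or any
dependence of subjective reports on behaviour (reports are supplied
externally). Passing tests therefore demonstrate that the estimators
and statistics behave correctly on signals with the assumed
phase-coupling structure — not that human data will show the same
effect sizes. In particular the simulator's absolute TE levels
(~1.7 bits total at defaults) are higher than typically reported for
human dyads, whose movements carry far more unmodelled variability;
directionality, calibration and trend properties, not absolute
magnitudes, are the validated contracts.

## Problem sizes in the validation suite

The test suite and acceptance script scale the Monte-Carlo studies to
what the conclusions need: null calibration uses 200 replicates with
99 surrogates over a 101-dyad pool of 25 s trials; Holm-correction
calibration uses 10 cohorts of 4 independent pairs × 5 trials; the
Gaussian closed-form check uses 10 runs of N = 5,000; direction
recovery uses 20 full-length (60 s) trials plus 5 cohorts of 4 pairs ×
15 trials; the geometry oracle compares against 2×10⁶-point dense
boundary sampling.

## Known limitations

* The KSG estimator's small negative excursions and its finite-donor
  anti-conservatism (above) are inherent to the estimator family, not
  bugs; both are quantified in the test suite.
* Only bivariate TE is computed — no conditional/multivariate variants,
  no spectral or symbolic TE, and no Granger causality.
* The Wilcoxon-vs-0.05 construction needs the per-pair p-value grid to
  be finer than the threshold (n_surrogates ≥ 20, in practice ≥ 49) —
  with the add-one rule and very few surrogates every p-value can tie
  at exactly 0.05, which is rejected as undefined.
* `sign_correlation` requires ≥ 5 pairs and non-degenerate sign
  variance; cohorts where every pair agrees have no defined
  correlation.
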