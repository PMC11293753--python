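# Methods

`edmcontrol` couples three components: an empirical dynamic modeling
(EDM) forecasting core, an agent-based model (ABM) of civil disobedience
that generates nonlinear multivariate dynamics, and a logistic feedback
controller that closes the loop between the two. This note records the
models, the parameters that matter, the numerical choices, and the
limits of what the bundled experiments demonstrate.

## State-space forecasting

Forecasts are made in a reconstructed state space. A *generalized
embedding* maps the observed series into state vectors of lagged
coordinates; the default forecast embedding is six-dimensional —
Quiet and Jailed at lags 0, 2 and 4 — with the Active count at horizon
`Tp = 5` as the target. Only non-negative lags are admitted, so a state
vector at time *t* contains nothing observed after *t*; the library's
"future" for a row at *t* is the single value `target(t + Tp)` used as
the regression/projection response.

**Simplex projection** predicts the target future of a query state as
the weighted mean of the futures of its `k = E + 1` nearest library
states (Euclidean metric), with weights `u_i = exp(-d_i / d_1)`. When
the nearest distance `d_1` is zero it is floored at machine epsilon, so
an exact match receives all the weight. Predictions are therefore always
inside the range of the neighbor futures.

**S-map** (sequential locally weighted global linear map) regresses the
futures of *all* usable library rows on their state vectors, weighting
row *i* by `w_i = exp(-theta * d_i / D)` where `D` is the mean
query-to-row distance. `theta = 0` is a global linear model; larger
`theta` localizes the fit and captures state dependence. The system is
solved by SVD-based minimum-norm least squares with a relative
singular-value cutoff of `1e-10`; rank-deficient designs (e.g. a
constant coordinate collinear with the intercept) therefore return the
minimum-norm solution rather than an error, and the affected coordinate
is flagged unreliable in coefficient extraction. If all rows coincide
(`D = 0`) weights fall back to uniform. The slope coefficients of each
local solve estimate the time-varying partial derivatives (interaction
Jacobians) of the target with respect to the coordinates; the
coefficient attached to a Propaganda(lag 0) coordinate is the
dActive/dPropaganda interaction strength.

**Skill** is the sample Pearson correlation between observations and
predictions over aligned pairs; pairs with a missing member are dropped,
and fewer than three pairs or zero variance yield a NaN sentinel rather
than an exception, so scans survive degenerate cells.

**Protocol conventions.** Out-of-sample evaluation builds the library
from a training row range only; a library row may also only carry a
target future observed inside that range. For in-sample (leave-one-out
style) queries, library rows within `|dt| <= Tp` of the query time are
excluded to suppress trivial self-matching under serial correlation.
Distance ties break by ascending time stamp, making every result
reproducible bit-for-bit under a fixed seed. The kernel width is chosen
from the standard grid {0, 0.01, 0.1, 0.3, 0.5, 0.75, 1, 1.5, 2, 3, 4,
5, 6, 7, 8, 9} by maximizing out-of-sample skill on a chronological
70/30 split of the training library, ties to the smallest theta. On
effectively linear data the skill profile over theta is flat, so the
argmax is reported jointly with the full profile
(`theta_skill_profile`) rather than trusted as a sharp optimum.

**Embedding-dimension scans** use univariate delay embeddings with
1-step lags (`0..E-1`) and simplex projection, and report per horizon
the smallest E whose skill reaches 95% of that horizon's maximum — an
operationalization of the visual "skill has saturated" judgment. On a
single train/test split this statistic inherits substantial run-to-run
noise; the scan therefore optionally averages skills over rolling-origin
folds (each block predicted from all earlier blocks). The bundled
reproduction uses a 6000-step nominal run with 3 folds. Even so, the
saturation dimension of the Active series at `Tp = 5` varies between
about 2 and 7 across simulator realizations; the scan's qualitative
shape (high skill at `Tp = 1, 2` from serial correlation, skill rising
then flattening in E) is stable, the integer is not.

## The rebellion agent-based model

1200 citizens and 64 cops (4% of cells) occupy a 40x40 toroidal lattice,
at most one mobile agent per cell. Citizens carry fixed lifetime draws
`risk_aversion, perceived_hardship ~ U[0,1]`. Each tick, every mobile
agent (uniformly shuffled order) moves to a uniformly chosen empty cell
within its Chebyshev vision radius (7), then acts:

* a citizen computes grievance `g = hardship * (1 - legitimacy)` and
  estimated arrest probability `p = 1 - exp(-k * floor(C / (A + 1)))`,
  with C cops and A other active citizens within vision (itself counted
  as active), and rebels iff `g - risk_aversion * p > propaganda` —
  re-evaluated both directions every tick;
* a cop jails one uniformly chosen Active citizen in vision, if any and
  if the jailed population is below capacity; the term is drawn from
  `U{1..30}` and the citizen leaves the grid until release (to a random
  empty cell, Quiet).

`k = ln 10` so that one cop facing one active citizen arrests with
probability 0.90. The *floor* in the cop-to-active ratio is essential:
arrest risk collapses only once actives locally match cops, which is
the nucleation mechanism for rebellion cascades. With a continuous
ratio the same parameters produce an almost permanently quiet
population (maximum Active ≈ 9 over thousands of steps) and none of the
punctuated-equilibrium phenomenology; the floor restores the canonical
bursty dynamics (episodes of several hundred Active, exponentially
distributed waiting times).

Legitimacy is the exogenous forcing: constant 0.82 in the nominal
scenario, or a piecewise-constant schedule of 20 random change points
with values in (0.6, 0.85]. Propaganda is the rebellion threshold —
constant 0.1 unless the controller sets it.

**Jail capacity and trapped states.** Capacity defaults to unlimited,
under which rebellion is always eventually suppressed (cops arrest up to
64 per tick and the jailed pool equilibrates near 960, leaving too few
active citizens to sustain the detector's threshold). The
variable-legitimacy experiments instead bound capacity at 300 (25% of
the population): once the jail saturates under low legitimacy, arrests
stop, local arrest risk collapses to zero and sustained rebellion
becomes self-maintaining — an absorbing trapped state. A trapped state
is declared when the Active fraction exceeds 0.25 for at least 200
consecutive steps (both thresholds exposed). Nominal runs keep
unlimited capacity because a 300 bound also truncates ordinary episode
peaks and destroys punctuated equilibrium.

**Determinism.** A run is a pure function of (parameters, schedule,
seed). Initial placement and per-citizen draws come from one substream
of the root seed; each tick reseeds the compiled kernel's RNG from a
per-step stream, so trajectories are reproducible even when several
worlds are stepped in interleaved order, and an uncontrolled/controlled
pair sharing a seed is a matched twin (identical world and schedule).

## The control loop

The controller converts the forecast Active count into a propaganda
level through the logistic law

    P = (P_max - P_min) / (1 + exp(-m (A_hat - A_0))) + P_min

with `P_min = 0.06`, `P_max = 0.6`, `m = 0.05`, `A_0 = 50`. The response
is strictly increasing and bounded; its slope never exceeds
`(P_max - P_min) m / 4`, so forecast jitter cannot produce unbounded
propaganda swings. The forecast is used as-is (not rounded); output is
clamped to `[P_min, P_max]` against floating-point saturation overshoot.

During a warm-up of `warmup_obs` observations (default 3000 in the
library API; the bundled experiments use 600 to keep desk-scale runs
short) propaganda stays at its nominal constant while the library
accumulates. At the first engaged step theta is grid-selected on the
warm-up library and then held fixed (re-selection interval
configurable); each subsequent tick embeds the latest observations,
s-map-predicts Active at `t + Tp`, applies the logistic law, and steps
the simulator under that propaganda. The library grows online with no
forgetting window and never contains future data; if the library is
still too thin the previous propaganda level is held and a warning
logged.

## Bundled experiments and their conditions

* **Forecast benchmark** — a 3100-step uncontrolled run whose schedule
  holds legitimacy at 0.82 for 600 steps and then varies it over
  (0.6, 0.85] (capacity 300), so the observed window shows punctuated
  equilibrium first and the transition to sustained rebellion later,
  both regimes inside the training rows. Library: rows 1–1500; test:
  rows 1601–3100; 6-D embedding; `Tp = 5`; theta grid-selected on the
  training split. Letting the schedule vary from step 0 makes the
  measured correlation an artifact of where the trap transition happens
  to fall relative to the fixed split.
* **Embedding-dimension scan** — 6000-step nominal run, simplex,
  E ∈ 1..10, `Tp = 5`, 3 rolling-origin folds.
* **Control robustness** — pairs of matched twins (1500 steps, warm-up
  600, capacity 300) under an adversarial schedule drawing legitimacy
  from (0.6, 0.65] after warm-up. The uncontrolled twin traps shortly
  after the drop; the claim under test is that the controlled twin
  never does.
* **Jacobian variance by regime** — a controlled run under a mixed
  post-warm-up schedule; s-map coefficients of the 7-coordinate
  embedding (forecast coordinates plus Propaganda at lag 0, theta = 2
  for a meaningfully local map), rolling 100-step windows with stride
  10, windows labeled by mean legitimacy against 0.7 (ties to the high
  regime). The directional claim — dActive/dPropaganda variance is
  stochastically larger under low legitimacy — is tested with a
  one-sided Mann-Whitney U at alpha 0.05; the kernel density estimates
  (Gaussian, Scott bandwidth) are presentation only.

## What the synthetic experiments do and do not show

All data are generated by the bundled ABM; nothing here touches
empirical social data. Passing tests show that the forecasting core is
numerically correct against closed-form and brute-force oracles, that
the simulator reproduces the qualitative regimes it was designed for
(punctuated equilibrium, absorbing sustained rebellion, regime-dependent
interaction variance), and that the closed loop steers the system away
from the trapped state under the stated adversarial conditions. They do
not show that this controller or these thresholds transfer to any real
social system, nor that the specific saturation dimension of the scan
generalizes beyond this implementation's cascade timescales: that
integer is sensitive to micro-rules (vision, cop density, the floor in
the arrest ratio) in a way the other results are not.

## Known limitations

* The trapped state under capacity 300 is absorbing; the controller
  prevents entry but is not designed to (and generally cannot) recover
  a system already trapped, because at saturated jails arrest risk is
  zero and only the propaganda bound `P_max = 0.6 > max grievance 0.4`
  keeps new rebellion suppressed — recovery happens only through jail
  attrition.
* S-map solves are per-query dense least squares; coefficient series
  over long runs cost `O(n^2 E)` and are the slowest analysis step.
* The s-map neighbor set is all library rows (the "global map"
  localized by weights); no truncated-neighborhood variant is provided.
* Waiting-time exponentiality is tested with a KS test against an
  exponential with the fitted mean, ignoring the parameter-estimation
  correction; with the episode counts involved the test is conservative
  at alpha 0.01.
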