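# Methods

## Scope and data model

`haekit` analyses head acceleration events (HAEs) recorded by
instrumented mouthguards (iMGs) during collision-sport matches. The unit
records are: a 50 ms triggered 6-DOF kinematic window per event; a coded
table of tackle involvements (player, fixture, timestamp, role as
ball-carrier or tackler, tackle-sequence label); wear periods from the
proximity sensor; and per-player-match playing times. The two estimands
are *incidence* (HAEs above a magnitude threshold per exposure time) and
*exceedance probability* (chance a tackle involvement produces an HAE
above a threshold).

## Signal processing

**Triggering.** A window opens when any linear-acceleration axis at the
sensor first exceeds the per-axis threshold (8 g); it spans 10 ms before
to 40 ms after the trigger sample (160 samples at 3200 Hz, trigger at
index 32). While a window is open no new trigger fires; triggering
re-arms at the first sample after the window. Windows that would start
before the record are zero-padded at the head and flagged.

**Filtering.** All six channels pass a zero-phase low-pass Butterworth
realised as a forward–backward pass of a 2-pole design — net four poles
with −6 dB at the cutoff. Every event gets the 200 Hz primary pass;
events labelled noise class 1 (moderate) are re-filtered at 100 Hz and
class 2 (severe) at 50 Hz. The vendor's noise classifier itself is out
of scope; class labels are inputs. Edge transients are handled by
reflective padding spanning at least three filter time constants
(clipped to the window length).

**CoG transform.** Filtered linear acceleration is transferred from the
sensor location to the head centre of gravity with the rigid-body
relative-acceleration equation, using one fixed lever arm
r_mh = [−0.082, 0.009, −0.065] m for all players. Angular acceleration
is obtained from the filtered gyro signal by central differences
(forward/backward at the ends); linear channels are stored in g and
converted to m/s² only inside the transform. The transform is applied
after the noise-class re-filter — a single pipeline ordering chosen
because the alternative (re-filter after transform) mixes filtered and
unfiltered terms; the difference is confined to the re-filtered 8% of
events.

**Metrics.** PLA and PAA are the maxima of the resultant (Euclidean
norm) curves. RVCI is computed from angular-velocity differences
directly — since ∫α dt = Δω, the defining double-time-point search
reduces to the maximum weighted norm of ω(t₂) − ω(t₁) over all sample
pairs with 0 < t₂ − t₁ ≤ 10 ms (32 sample lags; weights 1.00, 1.00,
1.17). This is analytically identical to integrating differentiated
angular acceleration and numerically more stable. Ties across pairs are
irrelevant to the reported maximum. Note one asymmetry: because α is odd
under time reversal, the α × r_mh term makes CoG PLA sensitive to trace
orientation in time; PAA and RVCI are reversal-invariant.

## Inclusion rules and linkage

* Wear compliance is strict: a player-match is included when the in-wear
  fraction of its involvements **exceeds** 0.90 ("over 90%"); exactly
  9 of 10 is excluded. Player-matches with no involvements are included
  vacuously and flagged.
* Tackler involvements labelled *sequential* are removed as assists;
  ball-carrier rows are never removed.
* HAE↔involvement linkage replaces manual video synchronisation with a
  deterministic rule: nearest same-player same-fixture involvement
  within ±5 s, earlier involvement on ties, at most one involvement per
  HAE. Unlinked HAEs stay in the incidence counts (count models use all
  recorded events in included player-matches) but contribute to no
  involvement maximum; the probability models use only involvements
  inside wear periods. The ±5 s window is a declared convention,
  configurable in one place.
* Individual probabilities require strictly more than 15 involvements in
  both roles.

## Incidence model

Per-player-match counts of HAEs above threshold T follow

log μ = β₀ + position + β_t · log(minutes) + u_player + v_fixture,

with u ~ N(0, σ_p²), v ~ N(0, σ_f²) crossed. log playing time enters as
a free coefficient (β_t ≈ 1 recovers proportional exposure); an offset
switch pins it at 1 for sensitivity analyses. One model is fitted per
metric–threshold pair. The marginal likelihood integrates the random
effects by a Laplace approximation: an inner damped Newton solve for the
joint random-effect mode (dense Cholesky of the joint precision, which
is small — players + fixtures) inside an outer L-BFGS-B maximisation
over (β, log σ_p, log σ_f) with log-σ bounded in [−5, 2]. On tiny
crossed instances the Laplace log-likelihood agrees with adaptive tensor
Gauss–Hermite quadrature to better than 10⁻⁴ relative; with both σ
fixed at zero the fit reproduces a plain Poisson regression.

Estimates: group incidence is exp of the linear predictor with random
effects at zero, at either 80 min (full-match equivalent) or the
position's median playing time; intervals are Wald on the link scale
(95%) from a central-difference Hessian of the Laplace objective
(variance parameters estimated at their boundary are profiled out of the
covariance rather than differenced one-sidedly). Individual incidence
adds the player's random-intercept mode and combines fixed-effect
variance with the mode's conditional variance; the covariance between
the two is neglected, a standard and slightly conservative choice.
All-zero counts return an explicit zero-rate estimate instead of a
diverging intercept.

## Probability model

Each in-wear, non-sequential involvement contributes one ordered
outcome per metric: `no recorded HAEs` (lowest, assumed not to have
exceeded the trigger), a sub-lowest recorded band below the first grid
threshold (the 8 g sensor trigger can yield CoG maxima under 10 g),
the grid bands (upper-inclusive), and an open top band. Globally empty
categories are merged upward with a warning; a threshold whose boundary
is merged away has maximum-likelihood exceedance degenerate at zero and
is reported as zero with a `boundary_observed = False` flag.

The proportional-odds cumulative logit model has a ball-carrier role
effect and random intercepts for fixture, player-within-fixture and
tackle event (the nested reading of the design; a crossed player/fixture
switch exists for sensitivity). Fitting is again Laplace ML: the inner
Newton works on the sparse joint precision (sparse LU for solves and
log-determinant), the outer optimiser runs over the first cutpoint,
log-increments between cutpoints (preserving order), the role effect and
three log-σ. With all σ fixed at zero the fit matches an ordinary
proportional-odds regression to optimiser precision. Tackle-event
intercepts are weakly identified when most observed events contain a
single instrumented player — the likelihood then trades σ_te against the
latent scale — and the estimate may sit at its lower bound; this mirrors
the sparsely instrumented design rather than a numerical failure.

Group exceedance uses a parametric bootstrap (default 2000 draws): the
parameter vector is drawn from the asymptotic normal of the fit in the
transformed (order-preserving) space, random effects are marginalised by
Monte-Carlo integration (default 500 draws of the summed intercept,
N(0, σ_f² + σ_pf² + σ_te²)), and P(max > T | role) is summarised by its
mean and 2.5/97.5 percentiles. Results are deterministic given the seed;
doubling the draw count moves point estimates by well under 0.1
percentage points.

Comparisons between estimates use the interval-overlap rule: two
estimates differ significantly only when their 95% intervals do not
overlap, with a shared endpoint counting as overlap (closed intervals).

## Synthetic-data generator

The generator emulates a league-wide iMG study: 12 teams fielding one
player per position (96 players), a 27-round season with ~31%
participation per fixture (~8.3 recorded matches per player, ~800
player-matches), and the position structure of professional rugby league
— median playing times of 41 min (prop), 54 (hooker), 52 (loose
forward) and 80 elsewhere, with tackle-heavy forwards and carry-heavy
backs.

* **Playing time** is drawn uniform-by-halves: with probability ½
  uniform on [lo, median], else on [median, hi], where lo/hi are
  back-solved from the position's quartiles. This reproduces the
  configured median and IQR exactly (which the recovery targets
  require), discretised to whole minutes in [1, 80].
* **Involvements.** Carries and non-sequential tackles per player-match
  are independent Poisson draws with mean rate·(minutes/median)·
  exp(u + v); sequential assists are drawn at rate·s/(1−s), giving the
  configured long-run sequential fraction (default 34.2%). Every carry
  opens a tackle event; tackler involvements attach to a uniformly
  chosen opposing carry event. Observed events therefore group whichever
  participants were instrumented — possibly a lone tackler — as in a
  partially instrumented league. (An earlier per-event tackler-selection
  design was abandoned: with few instrumented opponents it flattened
  per-position tackle rates and broke the closed-form targets.)
* **HAEs.** Each non-sequential involvement yields at most one recorded
  HAE (Bernoulli, role-specific probability); by Poisson thinning the
  per-player-match HAE count is exactly Poisson with mean
  rate_per_min · minutes · exp(u + v). CoG PLA is lognormal per role
  (σ_log = 0.55; carrier median 12.4 g, tackler 11.4 g; occurrence
  probabilities 0.616/0.560), calibrated once so the closed-form
  per-involvement exceedance at 10 g and 25 g equals 40.31%/6.29%
  (carrier) and 33.19%/4.26% (tackler). PAA and RVCI are proportional
  scalings of PLA (80 rad/s² per g; 0.55 rad/s per g) with
  multiplicative lognormal noise, keeping every threshold analytic.
  Player and fixture log-rate intercepts default to sd 0.45 and 0.15.
* **Traces.** Each HAE becomes a half-sine CoG linear pulse along +x
  plus a smoothstep angular-velocity ramp on z whose total change
  realises the RVCI target (the ramp fits inside the 10 ms window) and
  whose duration is set from the PAA target. The sensor trace is the
  exact inversion of the CoG transform, embedded in a 0.25 s carrier
  with class-dependent white sensor noise (0.2/0.5/1.2 g), clipped at
  ±200 g / ±35 rad/s. Pulse durations are drawn per noise class — 10–20,
  15–20 and 25 ms — because shorter pulses lose unacceptably much peak
  through the 100/50 Hz re-filters: the chain then recovers drawn PLA
  within 2% for minimal-noise events and within 10% for severe-noise
  events. Draws whose sensor trace never crosses the 8 g per-axis
  trigger emit no trace (sub-trigger censoring); by construction every
  draw above 10 g at the CoG triggers, so grid-threshold quantities are
  unaffected. The trace-free fast path flags a draw as recorded when its
  CoG PLA exceeds 8 g, a cheap stand-in for the trace-level trigger that
  is exact above 10 g.

**What the generator does not emulate.** Raw-signal morphology is a
stand-in (half-sine/smoothstep), not an inference about real impacts;
there is no impact-location modelling, no vendor true/false-positive
classification (all generated events are true positives), at most one
HAE per involvement (real involvements can produce several, so the
generator cannot simultaneously match a real study's total event count
and its per-involvement exceedances — the exceedance calibration was
kept), and the two-part occurrence/magnitude model satisfies
proportional odds only approximately. Passing recovery tests therefore
demonstrate correctness of the estimation machinery under the stated
generative model, not robustness to real-data artefacts.

## Recovery experiments and problem sizes

The test suite fits the Poisson model on 50 simulated seasons (~96
players, ~700 player-matches after participation thinning) with wear
misses switched off — the compliance rule is exercised by its own
boundary tests, and leaving misses on changes the estimand itself
through count-correlated selection, which is a property of the design,
not an estimation error. Closed-form per-position incidence falls inside
the fitted 95% interval in ≥90% of position×replicate checks (measured
~95%). The ordinal model is checked against model-based simulation: the
role effect is recovered within three Monte-Carlo standard errors at
zero random-effect sds, and across 10 replicates with random effects the
bootstrap interval covers a generator-set carrier exceedance of 0.063 in
at least 9. The end-to-end structural run uses a 4-team, 10-round season
with full trace generation; the acceptance script uses the same scale.
These sizes keep the full suite and script comfortably reproducible on a
single CPU while leaving the statistical conclusions unchanged at larger
scale.

## Known limitations

* Wald intervals ignore uncertainty in the variance components; the
  bootstrap propagates it only through the asymptotic normal of the
  transformed parameters.
* σ_tackle-event is near-unidentified with singleton observed events
  (see above).
* The Laplace approximation is biased for very sparse counts (many
  zero-count player-matches at the highest thresholds); the degenerate
  all-zero case is handled explicitly, but top-threshold estimates at
  desk scale carry wide intervals.
* The linkage window and the trace-morphology choices are conventions;
  both are configurable and documented rather than inferred.
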