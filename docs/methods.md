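# Methods

## The model

`telemark` implements a Bayesian multistate (Arnason–Schwarz) mark–recapture
model for acoustic-telemetry data from a sound connected to an open gulf
through monitored entrance passages, as a discrete hidden Markov model on a
weekly grid.

**States.** Each tagged fish occupies one of eight latent states per
detection occasion: expired (1, absorbing), at a spawning-ground array (2),
at an interior array (3), inside the sound away from receivers (4), at one
of three entrance arrays (5 Hinchinbrook, 6 Strait, 7 Passages), or in the
gulf (8). Observation codes 1–6 are a deterministic function of state:
detection is assumed certain within an array, so states 1, 4 and 8 all emit
"no detection" and each array state emits its own code.

**Transitions.** Weekly transition probabilities factor as φ^{rs} = S^r ψ^{rs},
where S^r is survival in state r and ψ^{rs} movement conditional on survival.
Mortality is possible only from states 4 and 8 (a live fish within reception
range cannot silently vanish; tag shedding and permanent emigration are
confounded with death in state 8). The allowed moves encode the geography:
spawning grounds and interior arrays exchange fish only with the open sound;
each entrance exchanges fish with the sound and the gulf; the gulf exchanges
fish with the entrances. All ψ and S are binned by season (default: two
April–August "spring/summer" and two September–March "fall/winter" bins
over a 24-month study) and, optionally, by a binary fish class obtained by
a median split on one covariate (length, weight, condition = weight·length⁻³,
sex, or tag burden = tag weight / body weight).

**Likelihood.** For fish i released at occasion c_i with transmitter life
l_i occasions, the observation window is {c_i+1, …, min(c_i+l_i, f)} with f
the final study occasion. The initial state is the spawning grounds with
probability one. The marginal likelihood sums over latent paths by the HMM
forward algorithm; because emission is deterministic the recursion simply
restricts support to the states feasible for each week's code. The
recursion is normalized step by step with log accumulation; agreement with
exhaustive path enumeration is maintained to ≤1e-10 relative error on small
instances (tested).

## Data preparation

* **Occasions** are half-open 7-day intervals; a date belongs to exactly one
  occasion. Transmitter life in occasions uses the floor of days/7 — a
  partly covered week cannot guarantee an active transmitter.
* **Presence** at an array in a week requires a detection belonging to a
  qualifying cluster: ≥2 detections at that array with consecutive gaps
  ≤24 h. Clusters spanning a week boundary mark presence in every week they
  touch. Presence is monotone in the data.
* **Multi-array weeks** are resolved "latest wins": the array whose last
  qualifying detection is latest supplies the code, preserving the
  direction of travel into the next week. The underlying rule is a package
  choice; conflicts are logged.
* **Validation** flags consecutive observed pairs impossible under the move
  graph (e.g. spawning grounds followed immediately by an entrance). The
  default is a hard error; an optional repair mode recodes the earlier
  member to "undetected" and logs it — silent mangling is never performed.

## Directional priors

Each entrance carries an inner (sound-side) and outer (gulf-side) receiver
line. A fish's detections at one entrance are segmented into visits —
maximal runs with gaps ≤24 h (a gap of exactly 24 h stays inside the visit;
only a strict exceedance closes it). A visit is oriented sound→gulf when
its first detections lie exclusively on the inner line and its last
exclusively on the outer line, gulf→sound for the reverse, and is left
unassigned when first or last detections coincide across lines (same
second by default; the tolerance is configurable), when the visit touches
an inner receiver with no complementary outer line, or when first and last
lines agree.

Assigned passages are counted per entrance r, class y and season k as
d^{r4} (gulf→sound) and d^{r8} (sound→gulf). The stay/leave ratio
q_r — fish-weeks present at r in two consecutive occasions divided by
fish-weeks present then absent — is pooled over classes and seasons, and
the stay pseudo-count is d^{rr} = q_r (d^{r4} + d^{r8}), kept fractional.
The entrance movement prior is then

    (ψ^{r4}, ψ^{rr}, ψ^{r8}) ~ Dirichlet(d^{r4}+1, d^{rr}+1, d^{r8}+1),

an empirical-Bayes plug-in; with no passages in a cell it reduces to the
flat Dirichlet(1,1,1). Remaining blocks get weakly-informative defaults:
Dirichlet(2,…,2) on each movement simplex (origins 2, 3, 4, 8) and
Beta(2,2) on S⁴ and S⁸, identical across classes and seasons. The joint
prior is the product of the blocks.

The passage season is the season of the occasion containing the visit's
exit time (the consequence of a passage — being in the gulf or the sound —
starts at exit). A passage event is one visit, not one fish: a fish
crossing twice contributes two counts, matching the per-occasion character
of the transition probabilities being informed.

## Posterior computation

The Dirichlet/Beta priors are conjugate to the complete-data likelihood, so
the sampler is FFBS-within-Gibbs:

1. forward-filtering backward-sampling draws each fish's latent path
   exactly from its conditional distribution given data and parameters;
2. movement blocks update as Dirichlet(α + movement counts among
   survivors) and survival as Beta(a + survivors, b + deaths), with the
   transition from occasion j to j+1 binned to the season of occasion j.

Chains are seeded independently from one root seed via `SeedSequence`
spawning; identical configuration and data reproduce draws bit-for-bit.
Default production settings mirror common practice for this model class
(4 chains × 200,000 iterations, 10,000 burn-in, thinning 25); tests and
the acceptance script use reduced counts (4 × 5,000 for the full closure
study, smaller for toy checks) chosen to keep runs in the minutes range —
the conjugate sampler mixes quickly, and R-hat is monitored throughout.

**Diagnostics.** R-hat is the classic (non-rank-normalized) Gelman–Rubin
potential scale reduction factor computed from between- and within-chain
variances; constant chains report 1 with a warning. DIC uses the marginal
(latent-states-integrated) deviance: DIC = D̄ + pD with pD = D̄ − D(θ̄),
where θ̄ is the posterior mean with simplex blocks mean-then-renormalized
(DIC variants differ; this plug-in form is the package's documented
choice). Summaries report posterior medians and equal-tailed 90% intervals
(linear-interpolated percentiles of pooled post-burn-in draws).

**Covariate effects.** With two classes, the logit-link slope for any
movement or survival probability is recovered draw-by-draw as
β₁ = logit(p_{y=1}) − logit(p_{y=0}), flagged significant when the 90%
interval excludes zero. β is a derived contrast of class-specific simplex
parameters rather than a raw likelihood term: an unnormalized per-component
logit link on a simplex is not a valid probability model, while the
contrast reproduces the inferential use (sign and interval exclusion of
zero).

## The synthetic-data generator

The generator emulates the study design end to end: two spring release
cohorts (124 and 202 fish released one year apart), a mix of 246-day and
755-day transmitters (60 short-lived tags split pro rata), morphometrics
(weight ~ N(120, 20²) g, standard length ~ N(195, 12²) mm, transmitter
weight by model), weekly latent movement under known class- and
season-specific parameters, and a fine-scale detection stream whose
entrance geometry encodes true passage directions (inner line first when
leaving the sound, outer first when returning; ≥2 detections per dwell
week so the presence rule always fires). Optional corruption reproduces
the two direction-failure modes at configurable rates: coincident
first/last timestamps across lines, and routing past an inner receiver
with no complementary outer line.

The default generating parameters describe a seasonally coherent partial
migration with heavy, geographically balanced entrance use: in
spring/summer fish leave the sound through the entrances
(ψ^{r8} ≫ ψ^{r4}, strongest at Hinchinbrook) and in fall/winter they
return (ψ^{r4} ≫ ψ^{r8}); entrance dwells last about two weeks
(ψ^{rr} ≈ 0.5); weekly mortality is higher in spring/summer (1−S⁴ = 0.03)
than in fall/winter (0.015). Two deliberate generator choices deserve
note:

* *Coherent flow.* The empirical entrance prior reads passage counts as a
  multinomial sample of the movement simplex. That reading is exact only
  when crossings sample the exit distribution — i.e. when within-season
  counterflow is weak or entries from the two sides are balanced, because
  visits that enter and exit on the same side are, by construction,
  direction-unassigned and dropped. The generator's defaults operate in
  this coherent-migration regime, which is the regime the model itself
  assumes. Under strong within-season counterflow the plug-in prior is
  biased for the minority direction; this is a property of the method, not
  of the implementation, and it is visible in experiments if counterflow
  is dialed up.
* *Moderate mortality.* Weekly mortality is kept moderate so that all four
  seasonal bins retain informative sample sizes; field point estimates as
  high as 0.16/week would leave later seasons of a 326-fish study almost
  prior-dominated, which is a statement about study power rather than
  about the estimator.

What the generator does **not** emulate: receiver outages and imperfect
detection (the model's certain-detection assumption is built in), tag
shedding as a separate process, within-array spatial structure, tides or
environmental covariates, and non-Markovian movement (e.g. memory of a
previous wintering site). Passing recovery tests therefore validates the
estimation machinery under the model's own assumptions, not robustness to
their violation in field data.

## Numerical choices and degenerate inputs

* Forward recursion in normalized space with log accumulation; zero
  support raises (strict) or returns −∞, by configuration.
* Dirichlet concentrations may be fractional (the stay pseudo-count is
  q·(d4+d8)); all concentrations must be strictly positive.
* Empty cells: a class/season cell with no passages gets the flat
  Dirichlet(1,1,1) — the formula's own limit; no pooling across cells.
* q_r with zero observed departures raises with instructions to configure
  a fallback value.
* Percentiles use linear interpolation; burn-in and thinning are applied
  per chain before pooling.
* An empty fish set is valid: the sampler then draws from the joint prior,
  which is used as an end-to-end check of the prior plumbing.

## Known limitations

* The empirical prior double-counts the data (counts inform both prior
  and likelihood); this is inherent to the plug-in design.
* Gulf mortality is confounded with permanent emigration; sound mortality
  with tag shedding.
* Direction assignment ignores detection-range overlap between lines;
  the coincidence tolerance is a blunt instrument for it.
* The sampler is exact but serial in chains; very long production runs
  are CPU-bound.
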