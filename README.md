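# telemark

Bayesian multistate mark–recapture for acoustic telemetry arrays, with
direction-of-travel information from paired receiver lines folded into the
model through empirical-Bayes priors.

## The problem

Acoustic-tagged fish moving through a geographically complex region — a
sound connected to an open gulf through a few monitored entrance passages —
are detected only when they pass a receiver array. The Arnason–Schwarz (AS)
multistate mark–recapture model describes such data as a hidden Markov
model: each week a fish occupies a latent state (spawning grounds, interior
array, open sound, one of three entrances, gulf, or expired) and weekly
transition probabilities factor into survival and movement, φ^{rs} = S^r ψ^{rs}.
Plain AS models cannot tell whether a fish leaving an entrance went into the
gulf or back into the sound — both are undetectable — which inflates state
uncertainty exactly where the migration question lives.

When entrance arrays carry two parallel receiver lines (inner on the sound
side, outer on the gulf side), the order of first and last detections in a
visit reveals the direction of passage. `telemark` turns those oriented
passages into informative Dirichlet priors on the entrance movement
simplexes,

    (ψ^{r4}, ψ^{rr}, ψ^{r8}) ~ Dirichlet(d^{r4}+1, d^{rr}+1, d^{r8}+1),

where d^{r4} and d^{r8} count gulf→sound and sound→gulf passages per fish
class and season, and d^{rr} = q_r (d^{r4} + d^{r8}) is a stay pseudo-count
built from the weekly stay/leave ratio q_r. All remaining movement blocks
get Dirichlet(2,…,2) and survival in the sound and gulf Beta(2,2). The
posterior is computed exactly by forward-filtering backward-sampling within
a Gibbs sampler (the priors are conjugate to the complete-data counts),
with Gelman–Rubin R-hat diagnostics, DIC model comparison, posterior
medians with equal-tailed 90% intervals, and logit-scale covariate
contrasts β₁ for median-split fish classes (length, weight, condition,
sex, tag burden).

Intended users: movement ecologists and quantitative fisheries scientists
analyzing stationary acoustic telemetry from sounds, fjords and estuaries.
See `docs/methods.md` for the model's assumptions and design choices.

## Worked example

The package ships a generator that emulates a full study — release
cohorts, transmitter battery lives, weekly movement under known seasonal
parameters, and the fine-scale two-line detection geometry — so the whole
pipeline can be exercised without field data:

```python
from telemark import build_grid, simulate_dataset, fit_pipeline
from telemark.simulate import SimulationScenario

grid = build_grid(end="2018-03-31",
                  season_starts=[("spring/summer", "2017-04-01"),
                                 ("fall/winter",   "2017-09-01")])
scen = SimulationScenario(cohort_sizes=(124,), release_occasions=(1,),
                          short_tag_counts=(23,))
data = simulate_dataset(scen, grid, seed=7)

result = fit_pipeline(
    data.detections, data.registry, data.deployments, grid,
    covariate="none",
    n_chains=4, n_iterations=2000, burn_in=500, thin=5, seed=1,
)
print(result.counts.q)                      # stay/leave ratios per entrance
print(result.estimator.summary_.table)      # medians, 90% CIs, R-hat
print(result.estimator.dic_)
```

Output (abridged):

```
stay/leave ratios q_r: {5: 0.75, 6: 0.88, 7: 0.89}
                 median    lo5   hi95   rhat
parameter
psi[5->4|y0,k0]   0.027  0.009  0.060  1.000
psi[5->4|y0,k1]   0.495  0.429  0.559  1.001
psi[5->8|y0,k0]   0.531  0.466  0.592  0.999
psi[5->8|y0,k1]   0.080  0.040  0.132  0.999
S[4|y0,k0]        0.987  0.974  0.995  0.999
S[4|y0,k1]        0.979  0.963  0.991  1.000
max R-hat: 1.003
DIC: {'dic': 6827.4, 'pd': 27.2, 'mean_deviance': 6800.2}
```

`psi[5->4|y0,k]` and `psi[5->8|y0,k]` are the weekly probabilities of
moving from the Hinchinbrook entrance back into the sound and out into the
gulf in season k. The fitted medians reproduce the seasonal migration the
data were generated with: in spring/summer (k0) fish at the entrance
overwhelmingly continue into the gulf (0.53 vs 0.03), and in fall/winter
(k1) the ordering reverses (0.08 vs 0.50) as fish return. `S[4|…]` is
weekly survival inside the sound; R-hat ≈ 1 indicates converged chains, and
`pd` is the effective parameter count behind the DIC.

The same pipeline runs from the shell on CSV inputs:

```bash
telemark simulate --config sim.yaml --outdir data/ --seed 3
telemark fit --config fit.yaml            # writes posterior.csv, summary.json, ...
telemark diagnose fit-out/posterior.csv   # R-hat table + deviance report
```

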