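# popassign

Assignment errors between distributed neural population codes: analytic
theory, Monte-Carlo simulation, receptive-field code performance, and
feedforward networks that learn the integration.

## The problem

When several stimuli are represented simultaneously in two brain regions —
say, the vocalizations of a dog and a cat in auditory cortex and their
visual features in visual cortex — behavior requires the *assignment
problem* to be solved: which auditory representation goes with which visual
one? Picking the wrong map produces a barking cat. The only way to solve it
better than chance (error probability `1 − 1/N!` for `N` stimuli) is
redundancy: `C` stimulus features represented in *both* regions, each
decoded with variance `D_X` and `D_Y`.

For two stimuli at distance `δ` in that common space, the estimates swap
order in one region (but not in a way that cancels) with probability

    F(δ) = Q(−δ/√(2D_X)) + Q(−δ/√(2D_Y)) − Q(−δ/√(2D_X))·Q(−δ/√(2D_Y))

with `Q` the standard normal CDF. Weighting by the distance density
`p_C(δ)` of uniform stimuli and the number of pairs gives the overall rate

    AE_C ≤ (N choose 2) ∫ p_C(δ) F(δ) dδ,
    AE_1 ≈ (N choose 2) · 2√(D_X+D_Y) / (s√π)          (C = 1, s² ≫ D)

and the redundancy this costs, in nats,

    R = (C/2) · log(s² / (D_X + D_Y)).

The package instantiates this tradeoff in random Gaussian receptive-field
codes (width `w`, peak `P`, noise `σ_N`), whose local precision is set by
the Fisher information `FI ≈ SNR²/(2w²)` and which additionally make rare
catastrophic *threshold* errors with probability `p_thr`; the per-feature
error is

    Err ≈ (1 − p_thr)/FI + p_thr/6.

On top of that it compares one-, two- and three-region codes for
8-dimensional stimuli under a shared neuron/power budget, and trains small
feedforward networks to perform the integration directly from noisy
population activity.

## Worked example

```python
from popassign.theory import (AssignmentProblem, CommonSpaceSpec, NoiseSpec,
                              assignment_error_closed_form,
                              assignment_error_bound, redundancy)
from popassign.simulate import simulate_error_rate

noise = NoiseSpec(D_X=5e-4, D_Y=5e-4)       # decoder variances per region
space = CommonSpaceSpec(C=1, s=1.0)          # one shared feature on [0, 1]
problem = AssignmentProblem(N=2, space=space, noise=noise)

print(f"closed-form error rate : {assignment_error_closed_form(2, 1.0, noise):.4f}")
print(f"union upper bound      : {assignment_error_bound(problem):.4f}")
sim = simulate_error_rate(problem, n_trials=100_000, seed=0)
print(f"simulated rate         : {sim.rate:.4f}  (95% CI {sim.ci_low:.4f}-{sim.ci_high:.4f})")
print(f"redundancy             : {redundancy(space, noise):.2f} nats")
```

prints

```
closed-form error rate : 0.0357
union upper bound      : 0.0422
simulated rate         : 0.0362  (95% CI 0.0351-0.0374)
redundancy             : 3.45 nats
```

The Monte-Carlo rate (sampling stimuli, corrupting each region's estimates,
and solving the matching exactly) agrees with the closed form to within its
binomial error and stays below the union bound; sharing that one feature at
this precision costs 3.45 nats of redundant information between the regions.

## Command line

The `popassign` CLI exposes the experiments as subcommands writing CSV
tables (`theory`, `simulate-assignment`, `rf-sweep`, `multiregion`,
`train-integrator`) plus `figures` to render them:

```
popassign simulate-assignment --seed 1 --out out/
popassign figures --out out/figs --table assignment=out/assignment_sim.csv
```

Each subcommand accepts `--config <yaml>` for its parameter grid; every
stochastic step derives its seed from the global `--seed`.

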