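# Methods

This note documents the models implemented in `popassign`, the assumptions
they make, the numerical choices behind them, and what the synthetic data
do and do not capture.

## Stimuli and representations

A stimulus set is `N` independent draws from the uniform distribution on
`[0, s]^K`; each of the `K` dimensions is a feature (position, pitch,
orientation, ...). Two regions, X and Y, each encode a subset of the
features; the `C` features encoded by both span the *common space* through
which assignment is solved. Decoded feature estimates are modeled as
unbiased Gaussians with variances `D_X`, `D_Y` per region — the maximum-
entropy (worst-case) distribution for a given variance. Estimates are not
clipped to `[0, s]`: clipping would bias edge behavior and break the
Gaussian assumption the analytic theory rests on.

The most probable one-to-one map between the two regions' representations
maximizes `log p(M | X̂, Ŷ) ∝ −Σᵢⱼ (x̂ᵢⱼ − ŷ_{M(i)j})²` under a uniform
prior over maps, i.e. it is the minimum-cost matching of squared Euclidean
distances in the common space (`theory.map_log_posterior`,
`simulate.solve_assignment`). The solver enumerates all `N!` permutations
for `N ≤ 4` (exact, lexicographic tie-break) and uses the Jonker–Volgenant
algorithm (`scipy.optimize.linear_sum_assignment`) for larger `N`; the
enumeration is retained as an oracle up to `N = 7`.

## Crossing probability and error rates

A pairwise assignment error corresponds to the two stimuli's common-space
estimates crossing in one region's ordering. The implemented form

`F(δ) = Q_X + Q_Y − Q_X·Q_Y`, `Q_i = Φ(−δ/√(2D_i))`

is the probability of a cross in *at least* one region; it equals 0.75 at
`δ = 0` for any symmetric noise. Two caveats, both verified numerically and
reflected in the tests:

- For `N = 2`, `C = 1` the exact error event is a cross in *exactly* one
  region (`Q_X + Q_Y − 2 Q_X Q_Y`), so the integral of the implemented `F`
  against the distance density is a strict upper bound, while the one-term
  closed form `AE₁ ≈ (N choose 2)·2√(D_X+D_Y)/(s√π)` happens to track the
  exact rate to ~1% at low rates (the dropped product and boundary terms
  nearly cancel).
- For `C > 1` the crossing picture is itself an approximation: noise
  components orthogonal to the separation also flip the dot-product sign,
  so the true pairwise rate slightly exceeds `F(δ)` and the "bound" is no
  longer strict. Bound-direction assertions are therefore made at `C = 1`.

The closed form multiplies the per-pair probability by `(N choose 2)`
(union bound). Its own validity requires the expected pair-error count to
be small; at large `N·√D` the union bound visibly overestimates the
simulated rate, which is expected behavior of the first-order theory, not
a discrepancy of the implementation.

Pairwise distances of uniform stimuli follow the triangular density
`2(s−δ)/s²` for `C = 1`. For `C > 1` the density of the squared distance
is built by convolving the per-dimension squared-difference distribution on
a 4096-cell grid — cell masses are taken from the analytic CDF
`(2s√u − u)/s²` so the `1/√u` singularity costs no accuracy, atoms sit at
their conditional means, and the convolved CDF is interpolated with a
monotone (PCHIP) spline whose derivative is the density. The tabulated
means agree with the known constants (0.5214 for the unit square, 0.6617
for the cube) to ~1e-5 and the density integrates to 1 within 1e-6. The
error-bound integral uses adaptive quadrature with breakpoints at the
`√(D_X+D_Y)` scale, where the integrand concentrates.

The chance-level control replaces region Y's stimuli with an independent
fresh draw. (Merely permuting Y's rows does not produce chance: the matcher
recovers a row permutation through the common-feature values themselves.)
With independent representations the cost matrix is exchangeable, the
matching is uniform over permutations, and the error rate is `1 − 1/N!`.

## Redundancy

`R = (C/2)·log(s²/(D_X+D_Y))` nats (natural logs throughout). This is the
mutual information of the Gaussian channel `X̂ = S + n_X`, `Ŷ = S + n_Y`
with a Gaussian source of variance `s²` in the `s² ≫ D` limit, which is the
channel used for the discretized mutual-information cross-check in the
tests (a uniform source adds a `(1/2)log 2πe` entropy mismatch per
dimension and is not what the formula describes). Asymmetric representation
uses `D_X = 2D_S/(1+ΔD)`, `D_Y = 2D_S/(1−ΔD)`, so `D_X+D_Y = 4D_S/(1−ΔD²)`
and `R = (C/2)·log[s²(1−ΔD²)/(4D_S)]` — consistent with the symmetric form
at `ΔD = 0` and monotone decreasing in `|ΔD|`. The parametrization lives
behind the single function `theory.asymmetric_noise` so it can be swapped.

## Receptive-field codes

`n` units with Gaussian tuning of common width `w`, peak `P`, centers
i.i.d. uniform on `[0,1]^K` (no edge correction — the analytic integrals
embed the same convention via the triangular density of `|x−μ|`), and
additive Gaussian noise `σ_N` added once per unit regardless of how many
stimuli are present (multi-stimulus responses superpose linearly).

With `A(w) = √π·w·erf(1/w) − w²(1−e^{−1/w²})` and
`B(w) = (√π w³/2)·erf(1/w) − w⁴(1−e^{−1/w²})`:

- power `V = n P² A^K` (the `[√π w − w²]^K` small-`w` form agrees within 1%
  for `w < 0.3`); `P` is solved from the target `SNR = √V/σ_N`;
- Fisher information per dimension `FI = (nP²/σ_N²w⁴) A^{K−1} B`, whose
  small-`w` limit is `SNR²/(2w²)`. These expressions were re-derived from
  the response model and are validated against Monte-Carlo integration
  (power, 2%) and a score-function estimator (FI, 3%) in the tests. The
  local MSE is reported as `1/E[FI(x)]`, accurate while `FI(x)` varies
  little across stimuli.

Threshold (catastrophic) errors: the manifold is discretized into
`1/S(w,K)` subpopulations (`S` the volume of a `K`-sphere of radius `2w`);
a switch requires noise beyond half the typical representation distance
`√(2V)`, giving `p_switch = erfc(√V_λ/(2σ_N))/2` and
`p_thr = p_switch/S(w,K)`, clipped to `[0,1]`. `V_λ = max(V − λσ_V, 0)`
(default `λ = 2`) discounts the mean power by the across-stimulus standard
deviation `σ_V`, estimated empirically from 4000 uniform stimuli (cached
per population geometry and rescaled by `P²`; the closed form for `σ_V` is
not implemented). Two robustness choices: the estimator's stimulus stream
is decorrelated from the center draw (an identical integer seed would
replay the centers as "stimuli"), and the analytic `V` entering `V_λ` is
capped at the Monte-Carlo mean of `V(x)` — for very sparse coverage the
sample misses the rare enormous peaks, and without the cap an essentially
uncovered code would look error-free. `p_thr` is an order-of-magnitude
construct: it reproduces when threshold errors matter, not their exact
rate (at narrow widths it typically overestimates).

Total per-feature error: `Err = (1−p_thr)/FI + p_thr·(1/6)`, where `1/6 =
E[(U−U′)²]` is the mean squared size of an error landing uniformly in the
space; the small-`w` variant `2w²σ_N²/V + p_thr/6` is also exposed. The
optimal width minimizes this over a 200-point log grid on `[0.01, 0.5]`
with golden-section refinement; the objective is deterministic given the
seed. Narrowing fields raises `FI` but fragments coverage, so the total is
U-shaped with an interior optimum.

Maximum-likelihood decoding is least-squares template matching on a grid
(512 points/dimension for `K ≤ 2`, 64 for `K = 3`, guarded for `K ≥ 4`),
refined by per-dimension parabolic interpolation in batch mode and by
Nelder-Mead (1e-8 tolerance) for single decodes; ties take the smaller
coordinate. Decoding errors are classified as threshold errors above a
cutoff of `6/√FI` clipped to `[0.1, 0.3]`; the empirical error histogram
is strongly bimodal, with the threshold tail following the uniform-landing
triangular law `P(err > c) ∝ (1−c)²` rather than being flat in `c`.

Ramp codes (auditory-like position tuning) replace the Gaussian factor on
designated dimensions by `2P(x_R − ½)·u_R`, with per-unit random unit
vectors `u_R`; the linear factor contributes `E[(2(x_R−½)·u_R)²] = 1/3` to
the power normalization, and the Monte-Carlo estimator is used wherever no
closed form is printed.

## Multi-region architectures

For `K = 8` features: one region with all 8; two regions with 4 + 5
features sharing one; three regions in a chain 3 + 4 + 3 sharing one per
adjacent pair (10 slots). Units and power split equally (only the totals
are constrained); each region's width is optimized for its own
dimensionality and budget; regions whose own total MSE exceeds 0.5 — half
the feature range — mark the architecture excluded. The architecture's
local MSE is the slot-average of `1/FI`, and the total error is

`total = (1 − p_ae)·local + p_ae·(1/6)`

— an assignment error swaps unique features between two uniform stimuli,
so its per-feature cost has the same 1/6 expectation as a threshold error.
For three regions, assignment is solved pairwise along the chain and the
pairwise rates combine by union bound.

The assignment term `p_ae` supports three modes. The default,
`typical_distance`, evaluates `F(δ)` at the mean pairwise distance of the
shared space (times the number of stimulus pairs, `N_stimuli = 2` by
default). The alternatives integrate the bound over the full distance
density (`bound`) or simulate (`simulation`). The default matters: the
integrated bound scales as `√D` because it is dominated by the rare
nearly-coincident stimulus pairs, while every local-MSE quantity scales as
`D` — under that worst-case accounting the assignment cost always
outweighs the efficiency gain of lower-dimensional codes and a single
region wins at *every* budget. Evaluated at the typical configuration, the
assignment rate instead decays exponentially with SNR, and the expected
regime structure appears: at small unit/SNR budgets the single region wins
(split budgets cannot cover even the lower-dimensional spaces, and
assignment is unreliable), while at large budgets two- and three-region
codes win because a K=8 code's width is pinned high by coverage (roughly
`n·A(w)^K` active units per stimulus must stay above ~λ²) while the
lower-dimensional codes can shrink theirs. The differences between viable
architectures at large budgets remain modest compared to the regime gaps.

## Integration networks

Two stimuli with `K = 3` features (common `c`, unique `u_x`, `u_y`);
region X encodes `(c, u_x)` and region Y `(c, u_y)` as RF codes at SNR 20
with widths set by the total-MSE optimum. The network maps the
concatenated noisy activities to the noiseless response of an output RF
code representing the bound pairs `(u_x, u_y)` — the common feature is
marginalized out, and producing the correct binding requires solving
assignment. The integration-learning variants add a mid-network layer
trained (as an equally weighted second MSE objective) to reproduce a
noiseless `K = 3` RF representation of both stimuli; end-to-end variants
train only on the output. Targets are noiseless mean responses — a
well-defined regression target; a noisy-target mode exists behind the
`noisy_inputs` flag of the generator. Hidden layers are ReLU, the output
head is affine, weights are He-initialized, and training is Adam
(lr 1e-3) with batch 200, fresh input noise every epoch, a 10% validation
split, and early stopping at patience 2 with best-weight restoration.

Evaluation: a trial errs when the output is closer in squared distance to
the swapped target (unique features exchanged — the prototypical
assignment error) than to the correct one; by the exchange symmetry of the
generative process an untrained network scores exactly 1/2. Rates are
binned by the true common-feature distance (10 equal bins on `[0,1]`,
minimum 200 trials per bin, sparse bins reported missing) and compared to
`F(δ)` computed from the input codes' common-feature local MSE (`1/FI`;
for ramp inputs `FI = 12·SNR²` from the linear term). The default sizes
here are scaled down — 128-unit input/output populations, 256-unit
integration layer, 10⁴ training samples, ≤30 epochs — which keeps training
to tens of seconds per network; at these sizes trained networks reach
overall error rates around 0.17 (affine baseline ≈ 0.5) with rates
decreasing in δ but plateauing well above the theory curve, which at SNR 20
is essentially zero beyond the smallest bin. Closing that remaining gap
requires the larger printed sizes; the qualitative ordering of variants is
already stable at the scaled sizes.

## Problem sizes used by the test suite and acceptance script

Monte-Carlo assignment rates use 10⁵ trials (binomial SE ≲ 0.2%);
power/FI oracles use 10⁵/8·10⁴ samples; decoding comparisons use 10⁴–10⁵
trials; the architecture comparison evaluates the budget corners
(500 units, SNR 3) and (10⁴ units, SNR 30) with a 32-point width grid and
800-stimulus power-variance estimates; network experiments train three
seeds at the scaled sizes above. Everything runs on one CPU; all
randomness derives from explicit seeds.

## Limitations

- The analytic theory assumes unbiased Gaussian decoders and uniform
  stimuli; real decoders are biased near feature-space edges.
- `F(δ)` is approximate for `C > 1` (see above) and the union bound is
  loose at high error rates.
- `p_thr` is an order-of-magnitude theory; the λ-correction is calibrated
  only in the sense that λ = 2 gives reasonable agreement.
- Multi-stimulus decoding from a single population, Poisson or correlated
  noise, heterogeneous widths, unbalanced assignment (unequal stimulus
  counts across regions), and nonlinear feature mappings between regions
  are out of scope.
- The synthetic generator captures none of the structure of real neural
  data (tuning heterogeneity, noise correlations, non-uniform stimulus
  statistics); passing tests certify the internal consistency of theory,
  simulation, and learning under the model's own assumptions.
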