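"""Monte-Carlo simulation of the assignment process.

The generative process: sample ``N`` stimuli uniformly in ``[0, s]^K``,
corrupt the features represented in each region with additive Gaussian noise
(variance ``D_X`` / ``D_Y`` per feature, including the common ones), build
the matrix of squared Euclidean distances between the two regions' estimates
in the common feature space, and solve the balanced assignment problem. A
trial counts as an error if at least one stimulus is assigned to the wrong
partner.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import beta as beta_dist

from .theory import AssignmentProblem

__all__ = [
    "StimulusSet",
    "RegionObservation",
    "AssignmentOutcome",
    "SimulationResult",
    "sample_stimuli",
    "observe",
    "cost_matrix",
    "solve_assignment",
    "brute_force_assignment",
    "simulate_error_rate",
]

# brute-force enumeration is exact and tie-deterministic; use it by default
# for tiny problems and as an oracle up to this size
_BRUTE_FORCE_DEFAULT_N = 4
_BRUTE_FORCE_MAX_N = 7


@dataclass(frozen=True)
class StimulusSet:
    """N stimuli with K feature values drawn i.i.d. uniform on [0, s]."""

    values: np.ndarray
    s: float
    seed: int | None = None

    @property
    def N(self) -> int:
        return self.values.shape[0]

    @property
    def K(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class RegionObservation:
    """One region's noisy estimates of a subset of the stimulus features.

    ``feature_indices[j]`` records which global feature column ``j`` of
    ``estimates`` refers to; common features must be listed in the same
    order in both regions.
    """

    estimates: np.ndarray
    feature_indices: tuple[int, ...]
    variance: float


@dataclass(frozen=True)
class AssignmentOutcome:
    permutation: np.ndarray
    is_error: bool
    n_misassigned: int


@dataclass(frozen=True)
class SimulationResult:
    rate: float
    ci_low: float
    ci_high: float
    mean_n_misassigned: float
    n_trials: int
    n_errors: int


def sample_stimuli(N: int, K: int, s: float = 1.0, seed: int | np.random.Generator | None = None) -> StimulusSet:
    """Draw N i.i.d. uniform stimuli in [0, s]^K."""
    if N < 1 or K < 1:
        raise ValueError(f"need N >= 1 and K >= 1, got N={N}, K={K}")
    if s <= 0:
        raise ValueError("s must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = rng.uniform(0.0, s, size=(N, K))
    return StimulusSet(values=values, s=s, seed=seed if isinstance(seed, int) else None)


def observe(
    stimuli: StimulusSet,
    feature_indices: tuple[int, ...] | list[int],
    variance: float,
    seed: int | np.random.Generator | None = None,
) -> RegionObservation:
    """Noisy per-region estimates: truth + N(0, sqrt(variance)) per entry.

    Estimates are deliberately not clipped to [0, s]: the Gaussian-estimator
    assumption is unbounded, and clipping would bias behavior near the
    feature-space edges.
    """
    if variance < 0:
        raise ValueError("variance must be >= 0")
    idx = tuple(int(i) for i in feature_indices)
    if any(i < 0 or i >= stimuli.K for i in idx):
        raise ValueError(f"feature indices {idx} out of range for K={stimuli.K}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    truth = stimuli.values[:, idx]
    noise = rng.normal(0.0, math.sqrt(variance), size=truth.shape) if variance > 0 else 0.0
    return RegionObservation(estimates=truth + noise, feature_indices=idx, variance=variance)


def cost_matrix(obs_x: RegionObservation, obs_y: RegionObservation) -> np.ndarray:
    """Squared Euclidean distances in the common feature space.

    Entry (i, j) is the squared distance between stimulus i's estimates in
    region X and stimulus j's estimates in region Y, restricted to the
    features represented in both regions. Minimizing the matching cost of
    this matrix is equivalent to maximizing the map log-posterior.
    """
    common = [f for f in obs_x.feature_indices if f in obs_y.feature_indices]
    if not common:
        raise ValueError("no common features: the assignment problem is unsolvable")
    xi = [obs_x.feature_indices.index(f) for f in common]
    yi = [obs_y.feature_indices.index(f) for f in common]
    x = obs_x.estimates[:, xi]
    y = obs_y.estimates[:, yi]
    diff = x[:, None, :] - y[None, :, :]
    return np.einsum("ijk,ijk->ij", diff, diff)


def brute_force_assignment(cost: np.ndarray) -> np.ndarray:
    """Exact minimum-cost matching by enumeration (oracle, N <= 7).

    Ties are broken toward the lexicographically smallest permutation, which
    itertools.permutations enumerates first.
    """
    n = cost.shape[0]
    if n > _BRUTE_FORCE_MAX_N:
        raise ValueError(f"brute force limited to N <= {_BRUTE_FORCE_MAX_N}")
    best_perm, best_cost = None, np.inf
    rows = np.arange(n)
    for perm in itertools.permutations(range(n)):
        c = cost[rows, perm].sum()
        if c < best_cost:  # strict: keeps the first (lexicographic) tie
            best_cost, best_perm = c, perm
    return np.array(best_perm)


def solve_assignment(cost: np.ndarray) -> np.ndarray:
    """Permutation pi minimizing sum_i cost[i, pi[i]].

    Brute-force enumeration for N <= 4 (exact, deterministic ties); the
    Jonker-Volgenant solver otherwise.
    """
    cost = np.asarray(cost, dtype=float)
    if cost.ndim != 2 or cost.shape[0] != cost.shape[1]:
        raise ValueError(f"cost matrix must be square, got shape {cost.shape}")
    if not np.all(np.isfinite(cost)):
        raise ValueError("cost matrix contains non-finite entries")
    if cost.shape[0] <= _BRUTE_FORCE_DEFAULT_N:
        return brute_force_assignment(cost)
    _, cols = linear_sum_assignment(cost)
    return cols


def _outcome(perm: np.ndarray) -> AssignmentOutcome:
    wrong = int(np.sum(perm != np.arange(perm.size)))
    return AssignmentOutcome(permutation=perm, is_error=wrong > 0, n_misassigned=wrong)


def _binomial_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson interval."""
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(beta_dist.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(beta_dist.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def simulate_error_rate(
    problem: AssignmentProblem,
    K: int | None = None,
    n_trials: int = 100_000,
    seed: int | None = None,
    *,
    independence_control: bool = False,
) -> SimulationResult:
    """Monte-Carlo assignment error rate.

    Each trial samples ``N`` stimuli, corrupts the common features with the
    per-region variances, and solves the matching. With
    ``independence_control=True`` region Y observes an independent,
    freshly drawn stimulus set, so its representations carry no information
    about region X's and the error rate approaches the chance level
    ``1 - 1/N!``. (Merely permuting Y's rows would not do: the matcher
    recovers a row permutation through the common-feature values.)

    Trials are vectorized: for ``N <= 4`` all permutation costs are
    evaluated in a single batch; larger problems call the matching solver
    per trial.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    N, C, s = problem.N, problem.space.C, problem.space.s
    K = C if K is None else K
    if K < C:
        raise ValueError("K must be at least C")
    rng = np.random.default_rng(seed)
    sx = math.sqrt(problem.noise.D_X)
    sy = math.sqrt(problem.noise.D_Y)

    n_err = 0
    n_wrong_total = 0
    batch = max(1, min(n_trials, 2_000_000 // max(1, N * C)))
    perms = None
    if N <= _BRUTE_FORCE_DEFAULT_N:
        perms = np.array(list(itertools.permutations(range(N))))
    done = 0
    while done < n_trials:
        b = min(batch, n_trials - done)
        truth = rng.uniform(0.0, s, size=(b, N, C))
        xh = truth + rng.normal(0.0, 1.0, size=truth.shape) * sx
        truth_y = rng.uniform(0.0, s, size=(b, N, C)) if independence_control else truth
        yh = truth_y + rng.normal(0.0, 1.0, size=truth.shape) * sy
        correct = np.broadcast_to(np.arange(N), (b, N))
        if perms is not None:
            # costs: (b, n_perms); cost of perm p = sum_i |xh_i - yh_p(i)|^2
            costs = np.stack(
                [np.sum((xh - yh[:, p, :]) ** 2, axis=(1, 2)) for p in perms], axis=1
            )
            chosen = perms[np.argmin(costs, axis=1)]
        else:
            chosen = np.empty((b, N), dtype=int)
            for t in range(b):
                diff = xh[t][:, None, :] - yh[t][None, :, :]
                cm = np.einsum("ijk,ijk->ij", diff, diff)
                chosen[t] = solve_assignment(cm)
        wrong = np.sum(chosen != correct, axis=1)
        n_err += int(np.count_nonzero(wrong))
        n_wrong_total += int(wrong.sum())
        done += b

    rate = n_err / n_trials
    lo, hi = _binomial_ci(n_err, n_trials)
    return SimulationResult(
        rate=rate,
        ci_low=lo,
        ci_high=hi,
        mean_n_misassigned=n_wrong_total / n_trials,
        n_trials=n_trials,
        n_errors=n_err,
    )
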