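"""Analytic theory of assignment errors between distributed representations.

Two brain regions hold noisy estimates of ``N`` stimuli. When ``C`` stimulus
features are represented in both regions (the *common feature space*), the
most probable one-to-one map between the two sets of representations is the
minimum-cost matching in that space, and an assignment error occurs when the
estimates of two stimuli cross over in one region but not the other. This
module collects the closed-form and quadrature-based predictions for that
process: the pairwise crossing probability ``F(delta)``, the density of
pairwise distances between uniform stimuli, the resulting assignment-error
rate (a union bound over pairs and a ``C = 1`` closed form), the chance
error level ``1 - 1/N!``, the map log-posterior, and the information-theoretic
redundancy the common features impose between the regions.

All feature values live in ``[0, s]`` per dimension; decoder variances
``D_X, D_Y`` are the variances of optimal unbiased (Gaussian) estimators of a
common feature from each region's activity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.special import ndtr  # standard normal CDF, vectorized

__all__ = [
    "CommonSpaceSpec",
    "NoiseSpec",
    "AsymmetryParams",
    "AssignmentProblem",
    "crossing_probability",
    "pairwise_distance_density",
    "assignment_error_bound",
    "assignment_error_closed_form",
    "chance_error_rate",
    "map_log_posterior",
    "redundancy",
    "redundancy_asymmetric",
    "asymmetric_noise",
]


@dataclass(frozen=True)
class CommonSpaceSpec:
    """The common feature space shared by two regions.

    Parameters
    ----------
    C : int
        Number of commonly represented features (dimensionality of the
        common space).
    s : float
        Linear extent of each feature dimension, in feature units.
    """

    C: int
    s: float = 1.0

    def __post_init__(self) -> None:
        if self.C < 0:
            raise ValueError(f"C must be >= 0, got {self.C}")
        if self.s <= 0:
            raise ValueError(f"s must be > 0, got {self.s}")


@dataclass(frozen=True)
class NoiseSpec:
    """Decoder variances of the common features in the two regions."""

    D_X: float
    D_Y: float

    def __post_init__(self) -> None:
        if self.D_X < 0 or self.D_Y < 0:
            raise ValueError("decoder variances must be non-negative")

    @property
    def total(self) -> float:
        return self.D_X + self.D_Y


@dataclass(frozen=True)
class AsymmetryParams:
    """Symmetric/asymmetric split of the decoder variances.

    ``D_S`` sets the overall variance scale and ``delta_D`` in (-1, 1) tilts
    it between the regions: ``D_X = 2 D_S / (1 + delta_D)`` and
    ``D_Y = 2 D_S / (1 - delta_D)``, so that
    ``D_X + D_Y = 4 D_S / (1 - delta_D**2)``.
    """

    D_S: float
    delta_D: float = 0.0

    def __post_init__(self) -> None:
        if self.D_S <= 0:
            raise ValueError("D_S must be > 0")
        if abs(self.delta_D) >= 1:
            raise ValueError(f"|delta_D| must be < 1, got {self.delta_D}")


@dataclass(frozen=True)
class AssignmentProblem:
    """N stimuli whose common features are estimated in two noisy regions."""

    N: int
    space: CommonSpaceSpec
    noise: NoiseSpec

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError(f"N must be >= 1, got {self.N}")


def asymmetric_noise(asym: AsymmetryParams) -> NoiseSpec:
    """Map (D_S, delta_D) to per-region variances.

    Kept as a single swappable function: only this parametrization ties the
    asymmetric redundancy expression to per-region variances.
    """
    return NoiseSpec(
        D_X=2.0 * asym.D_S / (1.0 + asym.delta_D),
        D_Y=2.0 * asym.D_S / (1.0 - asym.delta_D),
    )


def crossing_probability(
    delta: float | np.ndarray,
    noise: NoiseSpec,
    *,
    drop_product_term: bool = False,
) -> float | np.ndarray:
    """Probability F(delta) that two stimuli at common-space distance delta swap.

    The full form is ``F = Q_X + Q_Y - Q_X * Q_Y`` with
    ``Q_i = Phi(-delta / sqrt(2 D_i))`` (``Phi`` the standard normal CDF):
    the probability that the estimates cross over in at least one region.
    With ``drop_product_term=True`` the product is omitted (the two-term
    approximation), which is accurate when both ``Q_i`` are small.

    At ``delta = 0`` the full form evaluates to 0.75 for any positive noise.
    """
    delta = np.asarray(delta, dtype=float)
    if np.any(delta < 0):
        raise ValueError("delta must be non-negative")
    if noise.D_X == 0 and noise.D_Y == 0 and np.any(delta == 0):
        raise ValueError("delta = 0 with zero noise in both regions is undefined")

    with np.errstate(divide="ignore"):
        qx = ndtr(-delta / np.sqrt(2.0 * noise.D_X)) if noise.D_X > 0 else np.where(delta > 0, 0.0, 0.5)
        qy = ndtr(-delta / np.sqrt(2.0 * noise.D_Y)) if noise.D_Y > 0 else np.where(delta > 0, 0.0, 0.5)
    out = qx + qy if drop_product_term else qx + qy - qx * qy
    out = np.clip(out, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def _triangular_density(delta: np.ndarray, s: float) -> np.ndarray:
    """C = 1 closed form: p(delta) = 2 (s - delta) / s**2 on [0, s]."""
    inside = (delta >= 0) & (delta <= s)
    return np.where(inside, 2.0 * (s - delta) / s**2, 0.0)


class PairwiseDistanceDensity:
    """Density of the Euclidean distance between two uniform points in [0, s]^C.

    For ``C = 1`` this is the triangular density ``2 (s - delta) / s**2``.
    For ``C > 1`` it is tabulated numerically: the squared distance is a sum
    of ``C`` i.i.d. per-dimension squared differences, whose density is
    obtained from the triangular density of ``|x - y|`` and convolved
    ``C - 1`` times on a uniform grid (FFT convolution), then transformed
    back to the distance scale.
    """

    def __init__(self, space: CommonSpaceSpec, n_grid: int = 4096):
        if space.C < 1:
            raise ValueError("pairwise distances need C >= 1 common features")
        self.space = space
        self.n_grid = n_grid
        self.max_distance = space.s * math.sqrt(space.C)
        if space.C > 1:
            self._tabulate()

    def _tabulate(self) -> None:
        s, C, n = self.space.s, self.space.C, self.n_grid
        # per-dimension squared difference u = (x - y)^2, u in [0, s^2]:
        # |x - y| ~ Tri(0, s) gives CDF F(u) = (2 s sqrt(u) - u) / s^2, so the
        # cell masses are exact despite the 1/sqrt(u) density singularity
        du = s**2 / n
        edges = np.arange(n + 1) * du
        cdf = (2.0 * s * np.sqrt(edges) - edges) / s**2
        pmf = np.diff(cdf)
        # place each cell's atom at its conditional mean,
        # E[u | cell] from int u p(u) du = (2 s u^{3/2} / 3 - u^2 / 2) / s^2
        m1 = (2.0 * s * edges**1.5 / 3.0 - edges**2 / 2.0) / s**2
        cell_mean = np.diff(m1) / pmf
        # convolve C times on the sum-of-squares axis (atoms stay on the
        # uniform index grid; positions tracked via the summed cell means)
        total = pmf.copy()
        for _ in range(C - 1):
            total = np.convolve(total, pmf)
        mean_offset = C * (cell_mean - (np.arange(n) + 0.5) * du).mean()
        # transform q = delta^2: p_delta(d) = p_q(d^2) * 2 d, with p_q taken
        # as the derivative of a monotone spline through the convolved CDF
        # (much more accurate near q = 0 than interpolating the density)
        from scipy.interpolate import PchipInterpolator

        q_edges = (np.arange(total.size + 1) + 0.5 * (C - 1)) * du + mean_offset
        q_edges = np.clip(q_edges, 0.0, None)
        cdf_q = np.concatenate([[0.0], np.cumsum(total)])
        cdf_q /= cdf_q[-1]
        self._q_max = q_edges[-1]
        self._q_cdf = PchipInterpolator(q_edges, cdf_q, extrapolate=False)
        self._q_pdf = self._q_cdf.derivative()

    def __call__(self, delta: float | np.ndarray) -> float | np.ndarray:
        delta = np.asarray(delta, dtype=float)
        if self.space.C == 1:
            out = _triangular_density(delta, self.space.s)
        else:
            d2 = np.clip(delta**2, 0.0, self._q_max)
            p_q = np.nan_to_num(self._q_pdf(d2), nan=0.0)
            out = np.maximum(p_q, 0.0) * 2.0 * delta
        return float(out) if out.ndim == 0 else out

    def mean(self) -> float:
        """Mean pairwise distance, by quadrature on the tabulated density."""
        grid = np.linspace(0.0, self.max_distance, 20001)
        return float(np.trapezoid(grid * self(grid), grid))


def pairwise_distance_density(space: CommonSpaceSpec, n_grid: int = 4096) -> PairwiseDistanceDensity:
    """Return an evaluator for the pairwise-distance density p_C(delta)."""
    return PairwiseDistanceDensity(space, n_grid=n_grid)


def assignment_error_bound(
    problem: AssignmentProblem,
    *,
    drop_product_term: bool = False,
    density: PairwiseDistanceDensity | None = None,
) -> float:
    """Union (upper) bound on the assignment error rate.

    ``AE_C <= (N choose 2) * integral p_C(delta) F(delta) d delta``,
    evaluated by adaptive quadrature over ``[0, s * sqrt(C)]``. The result is
    clipped to [0, 1].
    """
    N = problem.N
    if N < 2:
        return 0.0
    if problem.space.C < 1:
        raise ValueError("assignment error bound needs C >= 1")
    p_C = density if density is not None else pairwise_distance_density(problem.space)

    def integrand(d: float) -> float:
        return float(p_C(d)) * float(
            crossing_probability(d, problem.noise, drop_product_term=drop_product_term)
        )

    # F decays on the sqrt(D) scale; give quad the interior breakpoints
    scale = math.sqrt(max(problem.noise.total, 1e-300))
    upper = p_C.max_distance
    points = [p for p in (scale, 10 * scale, 100 * scale) if 0 < p < upper]
    val, abserr = integrate.quad(integrand, 0.0, upper, points=points, limit=200, epsabs=1e-10)
    if not np.isfinite(val):
        raise ArithmeticError(f"quadrature failed (value={val}, abserr={abserr})")
    pairs = N * (N - 1) / 2
    return float(min(1.0, pairs * val))


def assignment_error_closed_form(
    N: int,
    s: float,
    noise: NoiseSpec,
    *,
    two_term: bool = False,
) -> float:
    """C = 1 closed-form assignment error rate for uniform stimuli.

    One-term form: ``(N choose 2) * 2 sqrt(D_X + D_Y) / (s sqrt(pi))``.
    With ``two_term=True`` the finer form
    ``(N choose 2) * [2 sqrt(D_X+D_Y)/(s sqrt(pi)) - 4 (D_X+D_Y)/s**2]``
    is returned. Both assume ``s**2 >> D_X, D_Y``.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if s <= 0:
        raise ValueError("s must be > 0")
    D = noise.total
    if D > 0 and s**2 < 100.0 * D:
        warnings.warn(
            f"closed form assumes s^2 >> D (s^2={s**2:.3g}, D_X+D_Y={D:.3g}); "
            "the approximation may be poor",
            stacklevel=2,
        )
    pairs = N * (N - 1) / 2
    value = 2.0 * math.sqrt(D) / (s * math.sqrt(math.pi))
    if two_term:
        value -= 4.0 * D / s**2
    return float(min(1.0, max(0.0, pairs * value)))


def chance_error_rate(N: int) -> float:
    """Error rate with independent representations: ``1 - 1/N!``."""
    if N < 1:
        raise ValueError("N must be >= 1")
    return 1.0 - 1.0 / math.factorial(N)


def map_log_posterior(
    xhat: np.ndarray,
    yhat: np.ndarray,
    perm: np.ndarray,
    noise: NoiseSpec | None = None,
) -> float:
    """Log-posterior (up to constants) of the map pairing row i with row perm[i].

    ``log p(M | xhat, yhat)`` is proportional to
    ``- sum_i sum_j (xhat[i, j] - yhat[perm[i], j])**2``; the permutation
    maximizing it is the minimum-cost matching in the common feature space.
    The noise spec only scales the posterior and is accepted for interface
    symmetry; constants are dropped.
    """
    xhat = np.asarray(xhat, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if xhat.shape != yhat.shape:
        raise ValueError(f"shape mismatch: {xhat.shape} vs {yhat.shape}")
    perm = np.asarray(perm)
    n = xhat.shape[0]
    if sorted(perm.tolist()) != list(range(n)):
        raise ValueError("perm must be a permutation of 0..N-1")
    return float(-np.sum((xhat - yhat[perm]) ** 2))


def redundancy(space: CommonSpaceSpec, noise: NoiseSpec) -> float:
    """Redundancy (mutual information, nats) between the two regions.

    ``R = (C / 2) * log(s**2 / (D_X + D_Y))``.
    """
    if noise.total == 0:
        raise ValueError("infinite redundancy: D_X + D_Y must be > 0")
    return 0.5 * space.C * math.log(space.s**2 / noise.total)


def redundancy_asymmetric(space: CommonSpaceSpec, asym: AsymmetryParams) -> float:
    """Redundancy under asymmetric per-region variances.

    ``R = (C / 2) * log(s**2 (1 - delta_D**2) / (4 D_S))``; with the
    parametrization of :func:`asymmetric_noise` this is exactly
    :func:`redundancy` evaluated at ``D_X + D_Y = 4 D_S / (1 - delta_D**2)``,
    and reduces to the symmetric form at ``delta_D = 0``.
    """
    return redundancy(space, asymmetric_noise(asym))
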