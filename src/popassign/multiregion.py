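"""Single- versus multi-region coding strategies under shared budgets.

A ``K = 8``-dimensional stimulus can be encoded by one population, or split
across two or three populations that each encode a lower-dimensional slice.
Multi-region architectures must represent at least one feature redundantly
per integrated region pair (otherwise assignment is at chance), so they pay
twice: redundant feature slots, and a nonzero assignment-error rate. In
exchange, their lower-dimensional receptive-field codes are more efficient.
This module evaluates the three architectures under a common total budget
of units and population power, combining each region's local MSE (from the
code's Fisher information at its optimal width) with the analytic
assignment-error bound into a total error::

    total = (1 - p_ae) * local_mse + p_ae * 1/6

mirroring the threshold-error bookkeeping: an assignment error exchanges
unique features between two uniform stimuli, so its per-feature squared
error has expectation ``E[(U - U')^2] = 1/6``.

The assignment term ``p_ae`` can be computed three ways (``ae_mode``):

- ``"typical_distance"`` (default): the pairwise crossing probability
  ``F(delta)`` evaluated at the mean pairwise distance in the shared
  feature space, times the number of stimulus pairs. This decays
  exponentially with SNR, which is what lets large budgets amortize the
  redundancy cost and favor multi-region codes; it treats the typical
  stimulus configuration rather than the worst case.
- ``"bound"``: the union upper bound integrated over the distance density.
  This scales as ``sqrt(D)`` and is dominated by the rare close stimulus
  pairs; because ``sqrt(D)`` shrinks slower than any local-MSE advantage
  (which scales as ``D``), under this pessimistic accounting a single
  region is preferred at *every* budget.
- ``"simulation"``: the Monte-Carlo assignment error rate (same scaling as
  the bound).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import rf_code
from .simulate import simulate_error_rate
from .theory import (
    AssignmentProblem,
    CommonSpaceSpec,
    NoiseSpec,
    assignment_error_bound,
    crossing_probability,
    pairwise_distance_density,
)

__all__ = [
    "ArchitectureSpec",
    "ArchitectureResult",
    "SweepResult",
    "make_architectures",
    "evaluate_architecture",
    "sweep",
]

# architectures with total error above half the stimulus-space size are
# dominated by catastrophic errors and are excluded from comparisons
EXCLUSION_MSE = 0.5


@dataclass(frozen=True)
class ArchitectureSpec:
    """How K global features are laid out across regions.

    ``feature_partition[r]`` lists the global feature indices represented in
    region ``r``; a feature present in two partitions is a redundant (shared)
    copy. Every consecutive region pair in the chain shares at least one
    feature so that pairwise assignment is solvable.
    """

    n_regions: int
    feature_partition: tuple[tuple[int, ...], ...]
    K: int

    def __post_init__(self) -> None:
        covered = set()
        for part in self.feature_partition:
            covered.update(part)
        if covered != set(range(self.K)):
            raise ValueError(
                f"partition covers {sorted(covered)}, expected all of 0..{self.K - 1}"
            )
        for a, b in self.integration_pairs():
            pass  # raises if a pair to integrate shares nothing

    @property
    def n_slots(self) -> int:
        """Total represented feature slots, redundant copies included."""
        return sum(len(p) for p in self.feature_partition)

    def shared_features(self, a: int, b: int) -> tuple[int, ...]:
        return tuple(
            sorted(set(self.feature_partition[a]) & set(self.feature_partition[b]))
        )

    def integration_pairs(self) -> list[tuple[int, int]]:
        """Consecutive region pairs along the sharing chain."""
        pairs = []
        for r in range(self.n_regions - 1):
            if not self.shared_features(r, r + 1):
                raise ValueError(
                    f"regions {r} and {r + 1} share no feature; assignment "
                    "between them is unsolvable"
                )
            pairs.append((r, r + 1))
        return pairs


@dataclass(frozen=True)
class ArchitectureResult:
    arch: ArchitectureSpec
    local_mse: float
    ae_rate: float
    total_error: float
    excluded: bool
    region_widths: tuple[float, ...]
    region_units: tuple[int, ...]
    region_snr: tuple[float, ...]
    region_total_mse: tuple[float, ...]


def make_architectures(K: int = 8) -> list[ArchitectureSpec]:
    """The one-, two- and three-region layouts for a K-feature stimulus.

    One region holds all features with no redundancy. Two regions split
    them 4 + 5 with one shared feature. Three regions form a chain
    3 + 4 + 3 with one shared feature per adjacent pair (K + 2 slots).
    Only ``K >= 5`` admits the fixed two/three-region layouts used here.
    """
    if K < 5:
        raise ValueError("the fixed multi-region layouts require K >= 5")
    h = K // 2
    one = ArchitectureSpec(1, (tuple(range(K)),), K)
    two = ArchitectureSpec(
        2,
        (tuple(range(h)), tuple(range(h - 1, K))),  # h and K-h+1 features, share h-1
        K,
    )
    t = K // 3 + 1
    three = ArchitectureSpec(
        3,
        (
            tuple(range(t)),
            tuple(range(t - 1, 2 * t)),
            tuple(range(2 * t - 1, K)),
        ),
        K,
    )
    return [one, two, three]


def _split_budget(total: int, n: int) -> tuple[int, ...]:
    """Integer split conserving the total exactly."""
    base = total // n
    rem = total - base * n
    return tuple(base + (1 if r < rem else 0) for r in range(n))


_MEAN_DISTANCE_CACHE: dict[int, float] = {}


def _pair_error_rate(
    N: int, C: int, noise: NoiseSpec, mode: str, seed: int = 0
) -> float:
    problem = AssignmentProblem(N=N, space=CommonSpaceSpec(C=C, s=1.0), noise=noise)
    if mode == "bound":
        return assignment_error_bound(problem)
    if mode == "simulation":
        return simulate_error_rate(problem, n_trials=20_000, seed=seed).rate
    if mode == "typical_distance":
        if C not in _MEAN_DISTANCE_CACHE:
            _MEAN_DISTANCE_CACHE[C] = pairwise_distance_density(
                CommonSpaceSpec(C=C, s=1.0)
            ).mean()
        pairs = N * (N - 1) / 2
        return min(1.0, pairs * float(crossing_probability(_MEAN_DISTANCE_CACHE[C], noise)))
    raise ValueError(f"unknown ae_mode {mode!r}")


def evaluate_architecture(
    arch: ArchitectureSpec,
    total_units: int,
    total_snr: float,
    N_stimuli: int = 2,
    seed: int = 0,
    lam: float = 2.0,
    width_grid: int = 32,
    sigma_v_mc: int = 800,
    ae_mode: str = "typical_distance",
) -> ArchitectureResult:
    """Evaluate one architecture at a total unit/power budget.

    Units and power are split equally across regions (the totals are the
    only stated constraint), each region's width is chosen to minimize its
    own predicted total MSE, the local MSE is the slot-average of ``1/FI``,
    and the assignment term is the analytic error bound along the sharing
    chain (union over chain pairs), using each region's local MSE as the
    common-feature decoder variance.
    """
    if total_units < arch.n_regions or total_snr <= 0:
        raise ValueError("budgets must be positive and at least one unit per region")
    sigma_N = 1.0
    units = _split_budget(total_units, arch.n_regions)
    V_total = (total_snr * sigma_N) ** 2
    V_r = V_total / arch.n_regions
    snr_r = math.sqrt(V_r) / sigma_N

    widths, local, region_mse, snrs = [], [], [], []
    for r in range(arch.n_regions):
        K_r = len(arch.feature_partition[r])
        w = rf_code.optimal_width(
            units[r],
            K_r,
            snr_r,
            sigma_N,
            lam=lam,
            n_grid=width_grid,
            seed=seed + r,
            sigma_v_mc=sigma_v_mc,
        )
        pop = rf_code.build_population(units[r], K_r, w, snr_r, sigma_N, seed=seed + r)
        fi, _ = rf_code.fisher_information(pop)
        mse = rf_code.total_mse(pop, lam=lam, n_mc=sigma_v_mc, seed=seed + r)
        widths.append(w)
        local.append(1.0 / fi)
        region_mse.append(mse.weighted)
        snrs.append(snr_r)

    # slot-weighted average local MSE over represented features
    slots = [len(p) for p in arch.feature_partition]
    local_mse = float(
        sum(d * k for d, k in zip(local, slots)) / sum(slots)
    )

    ae = 0.0
    for a, b in arch.integration_pairs():
        C_pair = len(arch.shared_features(a, b))
        ae += _pair_error_rate(
            N_stimuli,
            C_pair,
            NoiseSpec(D_X=local[a], D_Y=local[b]),
            ae_mode,
            seed=seed,
        )
    ae = min(1.0, ae)

    total_error = (1.0 - ae) * local_mse + ae * rf_code.THRESHOLD_ERROR_MSE
    excluded = any(m > EXCLUSION_MSE for m in region_mse) or total_error >= EXCLUSION_MSE
    return ArchitectureResult(
        arch=arch,
        local_mse=local_mse,
        ae_rate=ae,
        total_error=total_error,
        excluded=excluded,
        region_widths=tuple(widths),
        region_units=units,
        region_snr=tuple(snrs),
        region_total_mse=tuple(region_mse),
    )


@dataclass
class SweepResult:
    table: pd.DataFrame  # long form: one row per (units, snr, n_regions)
    argmin_map: pd.DataFrame  # rows=units, cols=snr; best region count or 0=excluded

    def best_regions(self, units: int, snr: float) -> int:
        return int(self.argmin_map.loc[units, snr])


def sweep(
    unit_grid,
    snr_grid,
    K: int = 8,
    N_stimuli: int = 2,
    seed: int = 0,
    lam: float = 2.0,
    width_grid: int = 32,
    sigma_v_mc: int = 800,
    ae_mode: str = "typical_distance",
) -> SweepResult:
    """Evaluate all architectures over a (units, SNR) budget grid.

    Cells where every architecture is excluded (no total error below 0.5)
    get an argmin entry of 0.
    """
    unit_grid = list(unit_grid)
    snr_grid = list(snr_grid)
    if not unit_grid or not snr_grid:
        raise ValueError("grids must be non-empty")
    archs = make_architectures(K)
    rows = []
    amap = pd.DataFrame(index=unit_grid, columns=snr_grid, dtype=int)
    for units in unit_grid:
        for snr in snr_grid:
            results = [
                evaluate_architecture(
                    a,
                    units,
                    snr,
                    N_stimuli=N_stimuli,
                    seed=seed,
                    lam=lam,
                    width_grid=width_grid,
                    sigma_v_mc=sigma_v_mc,
                    ae_mode=ae_mode,
                )
                for a in archs
            ]
            for res in results:
                rows.append(
                    {
                        "total_units": units,
                        "total_snr": snr,
                        "n_regions": res.arch.n_regions,
                        "n_slots": res.arch.n_slots,
                        "local_mse": res.local_mse,
                        "ae_rate": res.ae_rate,
                        "total_error": res.total_error,
                        "excluded": res.excluded,
                    }
                )
            viable = [r for r in results if not r.excluded]
            if viable:
                best = min(viable, key=lambda r: r.total_error)
                amap.loc[units, snr] = best.arch.n_regions
            else:
                amap.loc[units, snr] = 0
    return SweepResult(table=pd.DataFrame(rows), argmin_map=amap)
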