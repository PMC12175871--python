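"""Simulation-based power and sample-size analysis for multi-rater
agreement studies.

The design question: how many subjects (videos) must R raters each rate on
a K-category ordinal scale so that a z-test of the mean pairwise weighted
kappa rejects a null agreement level kappa0 with the desired power, when
the true agreement is kappa_true?

Raters are simulated with a latent *copy model*: each subject has a true
category T drawn from a marginal distribution pi, and each rater
independently reports T with probability theta, otherwise an independent
draw from pi.  Under this model the population weighted kappa between any
two raters has the closed form theta^2 (for any weight scheme whose
diagonal is 1), so theta can be calibrated to any target kappa; the
calibration here solves the general joint-distribution expression by
bisection rather than relying on that identity.

Power is estimated by Monte Carlo: each replicate simulates a full
subjects x raters matrix, computes the mean pairwise weighted kappa with
its delete-one-subject jackknife standard error (mirroring the reliability
analysis), and applies the two-sided kappa z-test.  The minimum sample
size is the smallest n on a grid whose isotonically smoothed power curve
reaches the target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.isotonic import IsotonicRegression

from ._fastkappa import (mean_kappa_independent_batch,
                         mean_kappa_jackknife_batch)
from .agreement import WeightScheme, weight_matrix

__all__ = [
    "CategoryDistribution",
    "RaterModel",
    "SimConfig",
    "PowerResult",
    "SampleSizeResult",
    "expected_kappa",
    "calibrate_theta",
    "simulate_ratings",
    "estimate_power",
    "find_min_n",
]

_EPS = 1e-12


@dataclass(frozen=True)
class CategoryDistribution:
    """Probability vector over K ordered categories."""

    probs: tuple

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 1 or len(p) < 2:
            raise ValueError("need a 1-D vector over >= 2 categories")
        if (p < 0).any() or not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("probabilities must be nonnegative and sum to 1")
        object.__setattr__(self, "probs", tuple(float(v) for v in p))

    @property
    def k(self) -> int:
        return len(self.probs)

    @property
    def degenerate(self) -> bool:
        return any(p >= 1.0 - _EPS for p in self.probs)

    @classmethod
    def uniform(cls, k: int = 5) -> "CategoryDistribution":
        return cls(tuple(1.0 / k for _ in range(k)))


@dataclass(frozen=True)
class RaterModel:
    """Copy-model rater: reports the latent true category with probability
    ``theta``, otherwise an independent draw from ``marginal``."""

    theta: float
    marginal: CategoryDistribution

    def __post_init__(self):
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one power experiment.

    Defaults follow the agreement-study design this package targets:
    6 raters, expected kappa 0.61 against a null of 0.53, two-sided
    alpha = 0.10, quadratic weights, and a 5-category marginal (uniform
    unless a pilot distribution is supplied).
    """

    n_videos: int = 55
    n_raters: int = 6
    kappa_true: float = 0.61
    kappa_null: float = 0.53
    alpha: float = 0.10
    scheme: WeightScheme = WeightScheme.QUADRATIC
    n_reps: int = 10_000
    seed: int = 0
    marginal: CategoryDistribution = field(
        default_factory=lambda: CategoryDistribution.uniform(5))
    max_degenerate_frac: float = 0.05
    se_method: str = "jackknife"  # or "independent" (pairs pooled as if independent)

    def __post_init__(self):
        if self.n_videos < 2 or self.n_raters < 2:
            raise ValueError("need at least 2 videos and 2 raters")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie strictly between 0 and 1")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        object.__setattr__(self, "scheme", WeightScheme(self.scheme))


@dataclass(frozen=True)
class PowerResult:
    power: float
    mc_se: float
    n_rejections: int
    n_valid_reps: int
    n_redrawn: int = 0


@dataclass(frozen=True)
class SampleSizeResult:
    n_min: Optional[int]
    power_curve: tuple  # ((n, PowerResult), ...)
    smoothed_power: tuple
    target_power: float
    achieved_max: float


def expected_kappa(model: RaterModel,
                   scheme: WeightScheme | str = WeightScheme.QUADRATIC) -> float:
    """Population weighted kappa between two copy-model raters.

    Computed exactly from the pairwise joint distribution

        P(X=a, Y=b) = sum_t pi_t [theta 1(a=t) + (1-theta) pi_a]
                               * [theta 1(b=t) + (1-theta) pi_b],

    whose marginals are both pi, giving p_o = sum w_ab P_ab and
    p_e = sum w_ab pi_a pi_b.  Strictly increasing in theta.
    """
    pi = np.asarray(model.marginal.probs)
    if model.marginal.degenerate:
        raise ValueError("degenerate marginal (one category has probability 1): "
                         "kappa is undefined")
    k = len(pi)
    w = weight_matrix(k, WeightScheme(scheme))
    th = model.theta
    # joint = th^2 diag(pi) + th(1-th)(pi pi^T)*2 + (1-th)^2 pi pi^T
    outer = np.outer(pi, pi)
    joint = th ** 2 * np.diag(pi) + (2 * th * (1 - th) + (1 - th) ** 2) * outer
    p_o = float((w * joint).sum())
    p_e = float((w * outer).sum())
    return (p_o - p_e) / (1.0 - p_e)


def calibrate_theta(kappa_target: float, marginal: CategoryDistribution,
                    scheme: WeightScheme | str = WeightScheme.QUADRATIC,
                    tol: float = 1e-6) -> float:
    """Solve ``expected_kappa(theta) = kappa_target`` by bisection.

    The attainable range is [0, 1] (theta = 0 gives independent raters,
    theta = 1 perfect copies); targets outside it are rejected.
    Terminates when the bracket maps to within ``tol`` of the target
    kappa.
    """
    if not 0.0 <= kappa_target <= 1.0:
        raise ValueError(f"target kappa {kappa_target} outside attainable [0, 1]")
    if marginal.degenerate:
        raise ValueError("degenerate marginal: kappa undefined for any theta")
    if kappa_target == 0.0:
        return 0.0
    if kappa_target == 1.0:
        return 1.0
    lo, hi = 0.0, 1.0
    f = lambda th: expected_kappa(RaterModel(th, marginal), scheme) - kappa_target
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if abs(fm) <= tol:
            return mid
        if fm < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_ratings(config: SimConfig, model: RaterModel,
                     rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """One subjects x raters matrix of ordinal ratings (categories 0..K-1).

    Per video, a latent truth is drawn from the marginal; each rater
    independently copies it with probability theta, otherwise draws
    independently from the marginal.  Reproducible given ``config.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    x = _simulate_batch(rng, 1, config.n_videos, config.n_raters, model)
    return x[0]


def _simulate_batch(rng: np.random.Generator, b: int, n: int, r: int,
                    model: RaterModel) -> np.ndarray:
    """(b, n, r) matrices of copy-model ratings."""
    pi = np.asarray(model.marginal.probs)
    truth = rng.choice(len(pi), size=(b, n), p=pi)
    copy = rng.random((b, n, r)) < model.theta
    indep = rng.choice(len(pi), size=(b, n, r), p=pi)
    return np.where(copy, truth[:, :, None], indep)


def estimate_power(config: SimConfig,
                   model: Optional[RaterModel] = None,
                   chunk_size: int = 500) -> PowerResult:
    """Monte-Carlo power of the mean-pairwise-kappa z-test.

    Each replicate simulates ``n_videos x n_raters`` copy-model ratings at
    the calibrated theta, computes the mean pairwise weighted kappa and
    its jackknife SE, and tests H0: kappa = kappa_null two-sided at
    ``alpha``.  Degenerate replicates (any rater pair with chance
    agreement 1) are redrawn; if redraws exceed
    ``max_degenerate_frac * n_reps`` the run aborts with a diagnostic.
    """
    if model is None:
        theta = calibrate_theta(config.kappa_true, config.marginal, config.scheme)
        model = RaterModel(theta, config.marginal)
    if config.se_method == "jackknife":
        batch_stats = mean_kappa_jackknife_batch
    elif config.se_method == "independent":
        batch_stats = mean_kappa_independent_batch
    else:
        raise ValueError(f"unknown se_method {config.se_method!r}")
    w = weight_matrix(model.marginal.k, config.scheme)
    rng = np.random.default_rng(config.seed)

    n_valid = 0
    n_reject = 0
    n_redrawn = 0
    max_redraw = max(1, int(config.max_degenerate_frac * config.n_reps))
    while n_valid < config.n_reps:
        b = min(chunk_size, config.n_reps - n_valid + 16)
        x = _simulate_batch(rng, b, config.n_videos, config.n_raters, model)
        mean_k, se, degen = batch_stats(x, w)
        ok = ~degen
        n_redrawn += int(degen.sum())
        if n_redrawn > max_redraw:
            raise RuntimeError(
                f"more than {config.max_degenerate_frac:.0%} of replicates "
                f"produced degenerate rater pairs ({n_redrawn} redraws); the "
                "marginal is too concentrated for this design")
        mean_k, se = mean_k[ok], se[ok]
        take = min(len(mean_k), config.n_reps - n_valid)
        mean_k, se = mean_k[:take], se[:take]
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (mean_k - config.kappa_null) / se
        # se == 0 with kappa_hat != kappa0 is an (infinitely) extreme result
        z = np.where(se > 0, z, np.where(mean_k == config.kappa_null, 0.0, np.inf))
        pvals = 2.0 * stats.norm.sf(np.abs(z))
        n_reject += int((pvals < config.alpha).sum())
        n_valid += take
    power = n_reject / n_valid
    mc_se = math.sqrt(power * (1.0 - power) / n_valid)
    return PowerResult(power=power, mc_se=mc_se, n_rejections=n_reject,
                       n_valid_reps=n_valid, n_redrawn=n_redrawn)


def find_min_n(target_power: float, grid: Sequence[int],
               config: SimConfig) -> SampleSizeResult:
    """Smallest grid n whose isotonically smoothed power reaches the target.

    Runs :func:`estimate_power` at each grid point (independent seed
    streams derived from ``config.seed``), smooths the raw power curve
    with isotonic regression (power is nondecreasing in n up to Monte
    Carlo noise), and returns the first grid value at or above
    ``target_power``.  If no grid point reaches the target, ``n_min`` is
    None and the achieved maximum is reported.
    """
    grid = list(grid)
    if not grid or any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("grid must be a nonempty strictly increasing sequence")
    seeds = np.random.SeedSequence(config.seed).generate_state(len(grid)) % (2 ** 31)
    curve = []
    for n, s in zip(grid, seeds):
        cfg = replace(config, n_videos=int(n), seed=int(s))
        curve.append((int(n), estimate_power(cfg)))
    raw = np.array([pr.power for _, pr in curve])
    smoothed = IsotonicRegression(increasing=True).fit_transform(
        np.asarray(grid, dtype=float), raw)
    n_min = None
    for n, sm in zip(grid, smoothed):
        if sm >= target_power:
            n_min = int(n)
            break
    return SampleSizeResult(
        n_min=n_min,
        power_curve=tuple(curve),
        smoothed_power=tuple(float(v) for v in smoothed),
        target_power=target_power,
        achieved_max=float(smoothed.max()),
    )
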