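"""Model complexity, the modified Schwarz criterion, and tuning search.

Model complexity of a fitted profile counts the free parameters left
after sparsity and fusion: df = n - #{beta_i = 0} - #{nonzero ties}.
Fits are compared by a modified Schwarz information criterion (SIC)

    log( sum_i |y_i - beta_i| / n ) + q * 0.5 * df * log(n) / n

whose factor ``q >= 1`` scales the complexity penalty; larger ``q``
selects more parsimonious models.  The two tuning parameters are chosen
by a two-step grid search: first lambda2 (smoothness) at a small fixed
lambda1, then lambda1 (sparsity) at the selected lambda2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import FitResult, PenaltyWeights, TuningParams, fit_lad_afl
from .profile import CGHProfile

# Step factors well above 1: with autocorrelated noise the LAD loss
# keeps dropping as segments multiply, and the plain Schwarz penalty
# (q = 1) has no interior minimum on profiles like these.
DEFAULT_Q1 = 3.0
DEFAULT_Q2 = 2.0


def _default_lambda2_grid() -> np.ndarray:
    return np.linspace(0.05, 6.05, 31)


def _default_lambda1_grid() -> np.ndarray:
    return np.linspace(0.001, 1.501, 31)


@dataclass(frozen=True)
class ModelComplexity:
    """Index sets and degrees of freedom of a (thresholded) fit.

    ``a1`` holds 1-based markers with ``beta_i = 0``; ``a2`` holds
    1-based markers ``i >= 2`` fused to a nonzero predecessor.
    """

    a1: np.ndarray
    a2: np.ndarray
    n: int

    @property
    def m1(self) -> int:
        return self.a1.size

    @property
    def m2(self) -> int:
        return self.a2.size

    @property
    def df(self) -> int:
        return self.n - self.m1 - self.m2


def model_df(beta_hat: np.ndarray) -> ModelComplexity:
    """Complexity of an exactly thresholded fit (exact zeros and ties)."""
    beta = np.asarray(beta_hat, dtype=float)
    n = beta.size
    a1 = np.flatnonzero(beta == 0) + 1
    cur, prev = beta[1:], beta[:-1]
    fused = (cur == prev) & (np.maximum(np.abs(cur), np.abs(prev)) > 0)
    a2 = np.flatnonzero(fused) + 2
    return ModelComplexity(a1=a1, a2=a2, n=n)


def sic(profile: CGHProfile, fit: FitResult, q: float) -> float:
    """Modified SIC of a fit; ``-inf`` (with a warning) on a perfect fit."""
    if q < 1:
        raise ValueError("SIC factor q must be >= 1")
    n = profile.n
    mean_abs_resid = float(np.abs(fit.residuals).sum()) / n
    if mean_abs_resid <= 0:
        warnings.warn("zero residual sum: SIC undefined, returning -inf")
        return -np.inf
    df = model_df(fit.beta_hat).df
    return float(np.log(mean_abs_resid) + q * 0.5 * df * np.log(n) / n)


@dataclass(frozen=True)
class SICConfig:
    """Configuration of the two-step tuning search.

    q1/q2 are the SIC factors of the lambda2 and lambda1 steps; the
    lambda grids are uniform by default.  A single-point lambda1 grid
    fixes lambda1 (used for profiles with very large aberrations, where
    the level sparsity assumption does not hold).
    """

    q1: float = DEFAULT_Q1
    q2: float = DEFAULT_Q2
    lambda1_init: float = 0.001
    lambda2_grid: np.ndarray = field(default_factory=_default_lambda2_grid)
    lambda1_grid: np.ndarray = field(default_factory=_default_lambda1_grid)

    def __post_init__(self) -> None:
        if self.q1 < 1 or self.q2 < 1:
            raise ValueError("SIC factors must be >= 1")
        for name in ("lambda2_grid", "lambda1_grid"):
            grid = np.asarray(getattr(self, name), dtype=float)
            if grid.size == 0:
                raise ValueError(f"{name} is empty")
            if np.any(grid < 0) or np.any(np.diff(grid) <= 0) and grid.size > 1:
                raise ValueError(f"{name} must be nonnegative and increasing")
            object.__setattr__(self, name, grid)


@dataclass(frozen=True)
class TracePoint:
    lambda1: float
    lambda2: float
    df: int
    sic: float


@dataclass(frozen=True)
class SearchResult:
    """Chosen tuning parameters, the final fit, and per-grid-point traces."""

    tuning: TuningParams
    fit: FitResult
    step1_trace: list[TracePoint]
    step2_trace: list[TracePoint]


def _sweep(
    profile: CGHProfile,
    weights: PenaltyWeights | None,
    pairs: list[tuple[float, float]],
    q: float,
) -> tuple[list[TracePoint], TuningParams, FitResult]:
    trace: list[TracePoint] = []
    best: tuple[float, TuningParams, FitResult] | None = None
    for lam1, lam2 in pairs:
        tuning = TuningParams(lambda1=lam1, lambda2=lam2)
        fit = fit_lad_afl(profile, tuning, weights=weights)
        value = sic(profile, fit, q)
        trace.append(
            TracePoint(lam1, lam2, model_df(fit.beta_hat).df, value)
        )
        if not np.isfinite(value):
            # a saturated interpolant (zero residuals) carries no
            # information; it must not win the minimization
            continue
        if best is None or value <= best[0]:  # ties -> larger lambda
            best = (value, tuning, fit)
    if best is None:
        raise RuntimeError("all grid points gave degenerate (perfect) fits")
    return trace, best[1], best[2]


def two_step_search(
    profile: CGHProfile,
    config: SICConfig | None = None,
    weights: PenaltyWeights | None = None,
) -> SearchResult:
    """Select (lambda1, lambda2) by the two-step SIC search and refit.

    Step 1 fixes ``lambda1 = lambda1_init`` and picks the lambda2 grid
    point minimizing SIC with factor ``q1``; step 2 fixes that lambda2
    and picks lambda1 with factor ``q2``.  SIC ties resolve to the
    larger (more parsimonious) parameter.  ``weights=None`` means
    adaptive weights; pass unit weights for the non-adaptive variant.
    """
    config = config or SICConfig()
    step1_pairs = [(config.lambda1_init, l2) for l2 in config.lambda2_grid]
    trace1, chosen1, _ = _sweep(profile, weights, step1_pairs, config.q1)
    step2_pairs = [(l1, chosen1.lambda2) for l1 in config.lambda1_grid]
    trace2, chosen2, fit = _sweep(profile, weights, step2_pairs, config.q2)
    return SearchResult(
        tuning=chosen2, fit=fit, step1_trace=trace1, step2_trace=trace2
    )
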