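"""Segment construction, median tests, FDR estimation and breakpoint calls.

The nonzero jumps of a fitted profile divide the chromosome into K
segments.  Each segment's fitted median is tested against zero with

    z_k = 2 * f(0) * sqrt(n_k) * median(beta_hat in segment k)

which is asymptotically standard normal under the null (the sampling
variance of a median of n_k values is 1 / (4 f(0)^2 n_k)).  The error
density at zero, f(0), is estimated from an order-statistic spacing of
the residuals.  Detection proceeds in two steps: candidate breakpoints
are jumps whose flanking fitted levels exceed an amplitude threshold
b0, and the significant ones are the candidates bounding the maximal
runs of segments declared aberrant (p <= cutoff and amplitude > b0) --
so internal splits of one aberrant region are not separate calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .core import FitResult


@dataclass(frozen=True)
class Segment:
    """One constant piece of the fit; start/end are 1-based inclusive."""

    index: int
    start: int
    end: int
    y_median: float
    beta_median: float

    @property
    def n_k(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DensityAtZero:
    """Spacing estimate of the error density at zero.

    ``s`` and ``t`` are the 1-based order-statistic indices used,
    symmetric about the median index; ``f0 = (t-s) / (n (e_(t)-e_(s)))``.
    """

    f0: float
    s: int
    t: int

    @property
    def offset(self) -> float:
        return (self.t - self.s) / 2


@dataclass(frozen=True)
class SegmentTest:
    index: int
    z: float
    p: float


@dataclass(frozen=True)
class DetectionConfig:
    """Amplitude threshold b0 and p-value cutoff of the detection rule."""

    b0: float = 0.1
    p_cutoff: float = 0.002

    def __post_init__(self) -> None:
        if self.b0 < 0:
            raise ValueError("b0 must be nonnegative")
        if not 0 < self.p_cutoff < 1:
            raise ValueError("p_cutoff must be in (0, 1)")


@dataclass(frozen=True)
class FDRReport:
    """Detection output: FDR estimate, picked segments, breakpoints.

    ``picked`` are segment indices with p <= cutoff (the denominator of
    the FDR estimator); ``aberrant`` additionally pass the amplitude
    threshold and define the called aberration regions.  ``fdr_hat`` is
    None when no segment is picked.  Breakpoint positions are 1-based
    indices of the first marker of the new segment.
    """

    p_cutoff: float
    fdr_hat: float | None
    picked: tuple[int, ...]
    aberrant: tuple[int, ...] = ()
    candidates: tuple[int, ...] = ()
    significant: tuple[int, ...] = ()


def segments_from_fit(fit: FitResult) -> list[Segment]:
    """Split the profile at each nonzero jump ``u_i`` (i >= 2)."""
    beta = fit.beta_hat
    y = beta + fit.residuals
    n = beta.size
    cuts = np.flatnonzero(fit.u_hat[1:] != 0) + 1  # 0-based segment starts
    bounds = np.concatenate([[0], cuts, [n]])
    segments = []
    for k in range(bounds.size - 1):
        lo, hi = int(bounds[k]), int(bounds[k + 1])
        segments.append(
            Segment(
                index=k + 1,
                start=lo + 1,
                end=hi,
                y_median=float(np.median(y[lo:hi])),
                beta_median=float(np.median(beta[lo:hi])),
            )
        )
    return segments


def estimate_f0(residuals: np.ndarray, h: int | None = None) -> DensityAtZero:
    """Order-statistic spacing estimate of the residual density at zero.

    Sorted residuals ``e_(1) <= ... <= e_(n)`` are windowed around the
    median index m at ``s = m - h`` and ``t = m + h`` (clamped), with
    ``h = ceil(sqrt(n))`` by default; ``f0 = (t-s)/(n (e_(t)-e_(s)))``.
    A degenerate window (equal order statistics, e.g. many exact-zero
    LAD residuals) is widened once by doubling h.
    """
    e = np.sort(np.asarray(residuals, dtype=float))
    n = e.size
    if n < 5:
        raise ValueError("need at least 5 residuals to estimate f(0)")
    m = (n + 1) // 2
    if h is None:
        h = int(np.ceil(np.sqrt(n)))
    if h < 1:
        raise ValueError("window offset h must be >= 1")
    for attempt in range(2):
        s = max(1, m - h)
        t = min(n, m + h)
        spread = e[t - 1] - e[s - 1]
        if spread > 0:
            return DensityAtZero(f0=float((t - s) / (n * spread)), s=s, t=t)
        h *= 2
    raise ValueError("residuals constant across the (widened) window")


def test_segments(segments: list[Segment], f0: DensityAtZero | float) -> list[SegmentTest]:
    """Median-zero test per segment: z = 2 f0 sqrt(n_k) beta_median."""
    density = f0.f0 if isinstance(f0, DensityAtZero) else float(f0)
    if density <= 0:
        raise ValueError("f(0) must be positive")
    out = []
    for seg in segments:
        if seg.n_k < 1:
            raise ValueError(f"empty segment {seg.index}")
        z = 2.0 * density * np.sqrt(seg.n_k) * seg.beta_median
        out.append(SegmentTest(index=seg.index, z=float(z), p=float(norm.sf(abs(z)))))
    return out


def estimate_fdr(
    segments: list[Segment],
    tests: list[SegmentTest],
    p_cutoff: float = 0.002,
) -> FDRReport:
    """Conservative FDR estimate ``n * p / sum of picked segment sizes``."""
    if not 0 < p_cutoff < 1:
        raise ValueError("p_cutoff must be in (0, 1)")
    n = sum(seg.n_k for seg in segments)
    by_index = {t.index: t for t in tests}
    picked = tuple(s.index for s in segments if by_index[s.index].p <= p_cutoff)
    picked_markers = sum(s.n_k for s in segments if s.index in set(picked))
    fdr_hat = n * p_cutoff / picked_markers if picked_markers else None
    return FDRReport(p_cutoff=p_cutoff, fdr_hat=fdr_hat, picked=picked)


def detect_breakpoints(
    fit: FitResult,
    config: DetectionConfig | None = None,
) -> FDRReport:
    """Two-step breakpoint detection on a thresholded fit.

    Candidates (step 1) are jump positions whose flanking fitted levels
    reach ``max(|beta_i|, |beta_{i-1}|) > b0`` -- amplitude is taken on
    both sides so gains and losses are treated alike.  Step 2 declares a
    segment aberrant when its median test has ``p <= p_cutoff`` and its
    fitted median exceeds ``b0`` in magnitude; the significant
    breakpoints are the candidates separating aberrant from non-aberrant
    segments (boundaries of the merged aberrant regions).
    """
    config = config or DetectionConfig()
    segments = segments_from_fit(fit)
    f0 = estimate_f0(fit.residuals)
    tests = test_segments(segments, f0)
    base = estimate_fdr(segments, tests, config.p_cutoff)

    beta = fit.beta_hat
    jump_pos = np.flatnonzero(fit.u_hat[1:] != 0) + 1  # 0-based new-segment starts
    candidates = tuple(
        int(i) + 1
        for i in jump_pos
        if max(abs(beta[i]), abs(beta[i - 1])) > config.b0
    )

    aberrant_flags = [
        t.p <= config.p_cutoff and abs(s.beta_median) > config.b0
        for s, t in zip(segments, tests)
    ]
    aberrant = tuple(
        s.index for s, flag in zip(segments, aberrant_flags) if flag
    )
    region_edges = {
        segments[k].start
        for k in range(1, len(segments))
        if aberrant_flags[k] != aberrant_flags[k - 1]
    }
    significant = tuple(sorted(region_edges.intersection(candidates)))

    return FDRReport(
        p_cutoff=config.p_cutoff,
        fdr_hat=base.fdr_hat,
        picked=base.picked,
        aberrant=aberrant,
        candidates=candidates,
        significant=significant,
    )
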