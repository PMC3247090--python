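"""Synthetic aCGH designs: step profiles, autoregressive noise, studies.

The simulated designs follow the benchmark used to validate the
estimator: a piecewise-constant true log2-ratio profile (two
amplifications and one deletion over 1000 markers, or one very large
aberration over 10000 markers) observed under independent, AR(1) or
AR(2) noise with either normal or double-exponential (Laplace)
innovations.  The double-exponential scale b gives variance 2 b^2; the
AR scales are chosen so the stationary noise standard deviation is 0.1
in the heavy-tailed designs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .core import PenaltyWeights
from .inference import DetectionConfig, detect_breakpoints, segments_from_fit
from .profile import CGHProfile
from .selection import SICConfig, two_step_search

#: innovation scales of the normal designs, chosen so the stationary
#: noise sd is ~0.1 for every dependence structure
NORMAL_SCALES = {"independent": 0.1, "ar1": 0.082, "ar2": 0.065}
#: innovation scales of the double-exponential designs
LAPLACE_SCALES = {"independent": 0.0707, "ar1": 0.0566, "ar2": 0.0460}
AR_COEFFICIENTS = {"independent": (), "ar1": (0.60,), "ar2": (0.60, 0.20)}


@dataclass(frozen=True)
class StepProfile:
    """Piecewise-constant ground truth: block lengths and levels."""

    lengths: tuple[int, ...]
    levels: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.lengths) != len(self.levels) or not self.lengths:
            raise ValueError("lengths and levels must be nonempty and matched")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("block lengths must be positive")

    @property
    def n(self) -> int:
        return sum(self.lengths)

    def values(self) -> np.ndarray:
        return np.repeat(self.levels, self.lengths).astype(float)

    @property
    def true_breakpoints(self) -> frozenset[int]:
        """1-based first markers of blocks whose level changes."""
        starts = np.cumsum(self.lengths)[:-1] + 1
        changes = np.diff(self.levels) != 0
        return frozenset(int(s) for s, c in zip(starts, changes) if c)


def table1_profile(n: int = 1000) -> StepProfile:
    """The sparse benchmark profile: blocks 0/1/0/0.59/0/-1.

    At the tabulated length n=1000 the blocks are 100/10/340/10/520/20
    markers and the 5 true breakpoints sit at markers 101, 111, 451,
    461 and 981.  Other lengths scale the blocks proportionally.
    """
    base = (100, 10, 340, 10, 520, 20)
    levels = (0.0, 1.0, 0.0, 0.59, 0.0, -1.0)
    if n == 1000:
        return StepProfile(lengths=base, levels=levels)
    if n < 100:
        raise ValueError("profile too short to scale the benchmark blocks")
    scaled = [max(1, round(b * n / 1000)) for b in base]
    scaled[-1] += n - sum(scaled)
    return StepProfile(lengths=tuple(scaled), levels=levels)


def example3_profile(case: str, n: int = 10000) -> StepProfile:
    """Large-aberration profiles covering 99.8%, 80% or 50% of markers.

    Case I:  10 null, n-20 at -0.59, 10 null   (2 breakpoints)
    Case II: 0.2n null, 0.8n at -0.59          (1 breakpoint)
    Case III: 0.5n null, 0.5n at +0.59         (1 breakpoint)

    Case I keeps its defining 10-marker null flanks at any ``n``; the
    other cases scale proportionally.
    """
    key = case.upper().replace("CASE", "").strip()
    if key == "I":
        if n <= 20:
            raise ValueError("Case I needs n > 20")
        return StepProfile(lengths=(10, n - 20, 10), levels=(0.0, -0.59, 0.0))
    fractions = {
        "II": ((0.2, 0.8), (0.0, -0.59)),
        "III": ((0.5, 0.5), (0.0, 0.59)),
    }
    if key not in fractions:
        raise ValueError(f"unknown case {case!r}; expected I, II or III")
    fracs, levels = fractions[key]
    lengths = [max(1, round(f * n)) for f in fracs]
    lengths[-1] += n - sum(lengths)
    return StepProfile(lengths=tuple(lengths), levels=levels)


@dataclass(frozen=True)
class NoiseModel:
    """Stationary AR(p) noise with iid normal or Laplace innovations.

    ``scale`` is the normal standard deviation or the Laplace scale b
    (variance 2 b^2).  The AR recursion runs from a zero state through
    ``burn_in`` extra steps so the returned series is effectively
    stationary.
    """

    kind: str = "independent"
    family: str = "laplace"
    scale: float = 0.0707
    coefficients: tuple[float, ...] | None = None
    burn_in: int = 500

    def __post_init__(self) -> None:
        if self.kind not in AR_COEFFICIENTS:
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.family not in ("normal", "laplace"):
            raise ValueError(f"unknown innovation family {self.family!r}")
        if self.coefficients is None:
            object.__setattr__(self, "coefficients", AR_COEFFICIENTS[self.kind])

    @classmethod
    def example1(cls, kind: str) -> "NoiseModel":
        """Normal innovations with the tabulated scales."""
        return cls(kind=kind, family="normal", scale=NORMAL_SCALES[kind])

    @classmethod
    def example2(cls, kind: str) -> "NoiseModel":
        """Double-exponential innovations; stationary sd 0.1 throughout."""
        return cls(kind=kind, family="laplace", scale=LAPLACE_SCALES[kind])

    @property
    def stationary_sd(self) -> float:
        """Analytic stationary standard deviation of the noise."""
        var_innov = (
            self.scale**2 if self.family == "normal" else 2.0 * self.scale**2
        )
        phi = self.coefficients
        if not phi:
            return float(np.sqrt(var_innov))
        if len(phi) == 1:
            return float(np.sqrt(var_innov / (1 - phi[0] ** 2)))
        if len(phi) == 2:
            p1, p2 = phi
            var = var_innov * (1 - p2) / ((1 + p2) * ((1 - p2) ** 2 - p1**2))
            return float(np.sqrt(var))
        raise NotImplementedError("stationary sd for AR(p>2)")


def generate_noise(
    model: NoiseModel, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw one noise series of length n, deterministic given the seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    total = n + model.burn_in
    if model.family == "normal":
        innovations = rng.normal(0.0, model.scale, total)
    else:
        innovations = rng.laplace(0.0, model.scale, total)
    phi = model.coefficients
    if phi:
        series = lfilter([1.0], np.concatenate([[1.0], -np.asarray(phi)]), innovations)
    else:
        series = innovations
    return series[model.burn_in :]


def simulate_profile(
    profile: StepProfile, model: NoiseModel, seed: int | np.random.Generator
) -> CGHProfile:
    """Observed log2 ratios: true step profile plus one noise draw."""
    truth = profile.values()
    eps = generate_noise(model, truth.size, seed)
    return CGHProfile(values=truth + eps)


def evaluate_detection(
    true_breakpoints: set[int] | frozenset[int],
    detected: set[int] | tuple[int, ...] | list[int],
    window: int = 0,
) -> tuple[int, int]:
    """Count correctly and falsely detected breakpoints.

    A detection is correct when it lies within ``window`` markers of an
    unmatched true breakpoint; matching is greedy, nearest pair first,
    one-to-one.  ``window=0`` requires exact positions.
    """
    truth = sorted(true_breakpoints)
    det = sorted(set(detected))
    pairs = sorted(
        (abs(d - t), d, t) for d in det for t in truth if abs(d - t) <= window
    )
    used_d: set[int] = set()
    used_t: set[int] = set()
    correct = 0
    for _, d, t in pairs:
        if d in used_d or t in used_t:
            continue
        used_d.add(d)
        used_t.add(t)
        correct += 1
    return correct, len(det) - correct


@dataclass(frozen=True)
class StudyResult:
    """Per-replicate detection counts and their summaries."""

    detected: np.ndarray
    correct: np.ndarray
    false: np.ndarray
    seeds: tuple[int, ...]

    @property
    def n_reps(self) -> int:
        return self.detected.size

    @property
    def mean_detected(self) -> float:
        return float(self.detected.mean())

    @property
    def sd_detected(self) -> float:
        return float(self.detected.std(ddof=1)) if self.n_reps > 1 else 0.0

    @property
    def mean_correct(self) -> float:
        return float(self.correct.mean())

    @property
    def mean_false(self) -> float:
        return float(self.false.mean())


def _replicate_seeds(base_seed: int, n_reps: int) -> list[np.random.Generator]:
    seq = np.random.SeedSequence(base_seed)
    return [np.random.default_rng(child) for child in seq.spawn(n_reps)]


def run_study(
    profile: StepProfile,
    model: NoiseModel,
    method: str = "lad_afl",
    n_reps: int = 40,
    base_seed: int = 0,
    detection: DetectionConfig | None = None,
    sic_config: SICConfig | None = None,
    window: int = 0,
) -> StudyResult:
    """Replicate study: simulate, tune, detect, score against the truth."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if method not in ("lad_afl", "lad_fl"):
        raise ValueError(f"unknown method {method!r}")
    truth = profile.true_breakpoints
    rngs = _replicate_seeds(base_seed, n_reps)
    detected = np.zeros(n_reps, dtype=int)
    correct = np.zeros(n_reps, dtype=int)
    for rep, rng in enumerate(rngs):
        observed = simulate_profile(profile, model, rng)
        weights = PenaltyWeights.unit(observed.n) if method == "lad_fl" else None
        result = two_step_search(observed, config=sic_config, weights=weights)
        try:
            report = detect_breakpoints(result.fit, detection)
            significant = report.significant
        except ValueError:
            # degenerate residual spacing (e.g. an interpolating fit):
            # no density estimate, hence no significance calls
            significant = ()
        detected[rep] = len(significant)
        correct[rep], _ = evaluate_detection(truth, significant, window)
    return StudyResult(
        detected=detected,
        correct=correct,
        false=detected - correct,
        seeds=tuple(range(n_reps)),
    )


@dataclass(frozen=True)
class RocPoint:
    cutoff: float
    tpr: float
    fpr: float


def roc_curve(
    profile: StepProfile,
    beta_hat: np.ndarray,
    cutoffs: np.ndarray | None = None,
) -> list[RocPoint]:
    """Probe-level ROC over an amplitude-cutoff sweep.

    At each cutoff the detected aberration region is the set of probes
    with ``|beta_hat| > cutoff``; TPR (FPR) is the fraction of that
    region with truly nonzero (zero) log2 ratio.  Cutoffs with an empty
    region are skipped.  TPR + FPR = 1 by construction.
    """
    truth_nonzero = profile.values() != 0
    beta_hat = np.asarray(beta_hat, dtype=float)
    if cutoffs is None:
        cutoffs = np.linspace(0.0, float(np.abs(beta_hat).max()), 51)
    points = []
    for cutoff in cutoffs:
        region = np.abs(beta_hat) > cutoff
        total = int(region.sum())
        if total == 0:
            continue
        tp = int((region & truth_nonzero).sum())
        points.append(
            RocPoint(cutoff=float(cutoff), tpr=tp / total, fpr=(total - tp) / total)
        )
    return points


def realized_fdr_study(
    profile: StepProfile,
    model: NoiseModel,
    n_reps: int = 100,
    p_cutoff: float = 0.002,
    base_seed: int = 0,
    detection: DetectionConfig | None = None,
    sic_config: SICConfig | None = None,
) -> tuple[float, np.ndarray]:
    """Fraction of replicates whose realized marker-level FDR < cutoff.

    Per replicate, the picked markers are those inside segments called
    aberrant by the full pipeline; the realized FDR is the fraction of
    them that are truly copy-neutral (0 when nothing is picked).
    """
    detection = detection or DetectionConfig(p_cutoff=p_cutoff)
    truth_null = profile.values() == 0
    rngs = _replicate_seeds(base_seed, n_reps)
    fdrs = np.zeros(n_reps)
    for rep, rng in enumerate(rngs):
        observed = simulate_profile(profile, model, rng)
        result = two_step_search(observed, config=sic_config)
        try:
            report = detect_breakpoints(result.fit, detection)
        except ValueError:
            fdrs[rep] = 0.0
            continue
        segments = segments_from_fit(result.fit)
        aberrant = set(report.aberrant)
        picked = false = 0
        for seg in segments:
            if seg.index in aberrant:
                picked += seg.n_k
                false += int(truth_null[seg.start - 1 : seg.end].sum())
        fdrs[rep] = false / picked if picked else 0.0
    return float(np.mean(fdrs < p_cutoff)), fdrs
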