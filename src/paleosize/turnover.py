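"""Clade-level turnover test: bootstrap size distributions and the
50% confidence-window decision rule.

A clade's pre-extinction species sizes define a "non-selective turnover"
null: resampling N_m species' log sizes (with replacement, B times) from the
pre-extinction pool describes the clade means one would see if extinction
and origination were unbiased with respect to body size.  The modern fauna
is classified LARGER / SMALLER / NO_CHANGE according to whether the mean of
the modern resampled distribution falls above, below, or inside the central
coverage window (default: central 50%, the 25th–75th percentiles) of that
null distribution.  No p-value is attached: the rule is a descriptor whose
null flag rate is roughly 1 - coverage, not a calibrated test (see the
methods note for its operating characteristics).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .measurements import FaunaTable

__all__ = [
    "Decision",
    "ResamplePlan",
    "ResampleResult",
    "log_sizes",
    "bootstrap_means",
    "central_window",
    "classify_turnover",
]


class Decision(str, enum.Enum):
    LARGER = "larger"
    SMALLER = "smaller"
    NO_CHANGE = "no_change"


#: numeric encoding used in tabular output: LARGER=+1, SMALLER=-1, NO_CHANGE=0
DECISION_CODE = {Decision.LARGER: 1, Decision.NO_CHANGE: 0, Decision.SMALLER: -1}


@dataclass(frozen=True)
class ResamplePlan:
    """Parameters of the bootstrap comparison.

    n_boot
        Number of bootstrap draws B per distribution (default 1000).
    coverage
        Central coverage of the decision window in (0, 1); 0.5 gives the
        25th–75th percentile window.
    seed
        Root seed; the three distributions use independent substreams
        spawned from it.
    log_base
        Base of the size logarithm; ``None`` means natural log.  The
        decision is invariant to this choice.
    """

    n_boot: int = 1000
    coverage: float = 0.5
    seed: int = 0
    log_base: float | None = None

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if not 0 < self.coverage < 1:
            raise ValueError("coverage must lie in (0, 1)")
        if self.log_base is not None and (self.log_base <= 0 or self.log_base == 1):
            raise ValueError("log_base must be positive and != 1")


@dataclass(frozen=True)
class ResampleResult:
    """The three bootstrap distributions and the window decision.

    fossil_resampled: B means of N_f log sizes drawn from the fossil pool.
    test_dist: B means of N_m log sizes drawn from the fossil pool — the
        non-selective turnover null.
    modern_resampled: B means of N_m log sizes drawn from the modern pool.
    window_lo/window_hi bound the central `coverage` of test_dist;
    modern_center is the mean of modern_resampled.  All log-scale values are
    in the plan's log units.
    """

    clade: str
    metric: str
    n_f: int
    n_m: int
    plan: ResamplePlan
    fossil_resampled: np.ndarray
    test_dist: np.ndarray
    modern_resampled: np.ndarray
    window_lo: float
    window_hi: float
    modern_center: float
    decision: Decision

    @property
    def window_lo_mm(self) -> float:
        return float(_unlog(self.window_lo, self.plan.log_base))

    @property
    def window_hi_mm(self) -> float:
        return float(_unlog(self.window_hi, self.plan.log_base))

    @property
    def modern_center_mm(self) -> float:
        return float(_unlog(self.modern_center, self.plan.log_base))


def log_sizes(sizes, log_base: float | None = None) -> np.ndarray:
    """Element-wise log of positive sizes (natural log unless a base is given)."""
    arr = np.asarray(sizes, dtype=float)
    bad = np.flatnonzero(~(arr > 0))
    if bad.size:
        raise ValueError(f"non-positive size at index {int(bad[0])}")
    out = np.log(arr)
    if log_base is not None:
        out = out / np.log(log_base)
    return out


def _unlog(value: float, log_base: float | None) -> float:
    return float(np.exp(value)) if log_base is None else float(log_base**value)


def bootstrap_means(
    values, n_draw: int, n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    """B means of ``n_draw`` values resampled uniformly with replacement."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot bootstrap an empty value vector")
    if n_draw < 1 or n_boot < 1:
        raise ValueError("n_draw and n_boot must be >= 1")
    idx = rng.integers(0, arr.size, size=(int(n_boot), int(n_draw)))
    return arr[idx].mean(axis=1)


def central_window(dist, coverage: float) -> tuple[float, float]:
    """Central-coverage bounds of a sample, linear-interpolation quantiles.

    Returns (lo, hi) = the (1-coverage)/2 and 1-(1-coverage)/2 quantiles.
    """
    arr = np.asarray(dist, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot take quantiles of an empty distribution")
    if not 0 < coverage < 1:
        raise ValueError("coverage must lie in (0, 1)")
    tail = (1.0 - coverage) / 2.0
    lo, hi = np.quantile(arr, [tail, 1.0 - tail])
    return float(lo), float(hi)


def classify_turnover(fauna: FaunaTable, plan: ResamplePlan) -> ResampleResult:
    """Run the three-distribution bootstrap comparison on a fauna.

    Builds, on log sizes: the fossil pool resampled at its own size N_f,
    the non-selective turnover null (fossil pool resampled at N_m), and the
    modern pool resampled at N_m.  The modern center (mean of the modern
    resampled distribution) is compared with the central coverage window of
    the null; ties on a window bound count as NO_CHANGE ("fell within").
    """
    if fauna.n_f == 0:
        raise ValueError(f"{fauna.clade}: pre-extinction bin is empty")
    if fauna.n_m == 0:
        raise ValueError(f"{fauna.clade}: modern bin is empty")
    pre_log = log_sizes(fauna.pre_sizes, plan.log_base)
    mod_log = log_sizes(fauna.modern_sizes, plan.log_base)
    streams = [
        np.random.default_rng(s) for s in np.random.SeedSequence(plan.seed).spawn(3)
    ]
    fossil_resampled = bootstrap_means(pre_log, fauna.n_f, plan.n_boot, streams[0])
    test_dist = bootstrap_means(pre_log, fauna.n_m, plan.n_boot, streams[1])
    modern_resampled = bootstrap_means(mod_log, fauna.n_m, plan.n_boot, streams[2])
    window_lo, window_hi = central_window(test_dist, plan.coverage)
    modern_center = float(modern_resampled.mean())
    if modern_center > window_hi:
        decision = Decision.LARGER
    elif modern_center < window_lo:
        decision = Decision.SMALLER
    else:
        decision = Decision.NO_CHANGE
    return ResampleResult(
        clade=fauna.clade,
        metric=fauna.metric.value,
        n_f=fauna.n_f,
        n_m=fauna.n_m,
        plan=plan,
        fossil_resampled=fossil_resampled,
        test_dist=test_dist,
        modern_resampled=modern_resampled,
        window_lo=window_lo,
        window_hi=window_hi,
        modern_center=modern_center,
        decision=decision,
    )
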