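"""The statistical core: from overlap counts to a genome-size estimate.

Model
-----
Place a query read q of length lq uniformly on a genome of size GS
(GS - lq possible start positions, ignoring edge effects).  A fixed
target read t of length lt is overlapped by at least OT bases exactly
when q's start falls in an interval of size lq + lt - 2*OT + 1, so

    P(overlap) = (lq + lt - 2*OT + 1) / (GS - lq).

Summing over the target set T \\ {q} gives the expected overlap count;
inverting that expectation at the *observed* count yields a per-read
genome-size estimate

    GS_q = lq + |T \\ {q}| * (lq + mean_lt - 2*OT + 1) / count(q).

A read with no overlaps has an undefined estimate (the count sits in the
denominator); the overall estimate is the median of the defined per-read
estimates, which is robust to such dropouts and to outliers.  The
reported range is a percentile interval of the per-read estimates
(15th-65th by default, a width-50 band calibrated so the true size falls
inside for most samples).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .read_io import EstimationImpossibleError, ReadSetPair, Strategy
from .overlaps import OverlapCounts

__all__ = [
    "PerReadEstimate",
    "EstimateResult",
    "overlap_probability",
    "per_read_estimate",
    "per_read_estimates",
    "aggregate",
    "relative_error",
    "calibrate_confidence_range",
]

DEFAULT_CI_LOWER_PCT = 15.0
DEFAULT_CI_WIDTH_PCT = 50.0


@dataclass(frozen=True, slots=True)
class PerReadEstimate:
    """Genome size implied by one query read's overlap count.

    ``estimate`` is None (the undefined sentinel) when the read had no
    overlaps — never infinity, so aggregation cannot silently propagate
    non-finite values.
    """

    query_id: str
    query_len: int
    n_targets: int
    mean_target_len: float
    overlap_count: float
    estimate: Optional[float]


@dataclass(slots=True)
class EstimateResult:
    """Median genome-size estimate with its percentile range and diagnostics."""

    genome_size: float
    ci_low: float
    ci_high: float
    per_read: list[PerReadEstimate]
    n_zero_overlap: int
    n_used: int
    strategy: Optional[Strategy] = None
    seed: Optional[int] = None
    ot: Optional[int] = None
    ci_lower_pct: float = DEFAULT_CI_LOWER_PCT
    ci_width_pct: float = DEFAULT_CI_WIDTH_PCT

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.genome_size <= self.ci_high):
            raise ValueError(
                "median estimate must lie within the percentile range: "
                f"{self.ci_low} <= {self.genome_size} <= {self.ci_high} fails"
            )


def overlap_probability(
    len_q: int, len_t: int, ot: int, genome_size: float
) -> float:
    """Probability that a fixed read t overlaps a uniformly placed read q
    by at least ``ot`` bases, ignoring genome-end edge effects.
    """
    if ot < 1:
        raise ValueError("ot must be >= 1")
    if genome_size <= len_q:
        raise ValueError(
            f"genome_size ({genome_size}) must exceed query length ({len_q})"
        )
    interval = max(0, len_q + len_t - 2 * ot + 1)
    return min(1.0, interval / (genome_size - len_q))


def per_read_estimate(
    len_q: int,
    n_targets: int,
    mean_target_len: float,
    ot: int,
    overlap_count: Union[int, float],
    query_id: str = "",
) -> PerReadEstimate:
    """Invert the expected-overlap-count formula at the observed count.

    With zero overlaps the estimate is undefined (None).  The count may
    be real-valued so analytic expectations can be substituted directly.
    """
    if len_q <= 0 or n_targets < 1 or mean_target_len <= 0:
        raise ValueError("len_q, n_targets and mean_target_len must be positive")
    if ot < 1:
        raise ValueError("ot must be >= 1")
    if overlap_count < 0:
        raise ValueError("overlap_count must be >= 0")
    if len_q < ot:
        raise ValueError(
            f"query length {len_q} is below the minimum overlap threshold {ot}"
        )
    interval = len_q + mean_target_len - 2 * ot + 1
    if interval <= 0:
        raise ValueError(
            "overlap interval is non-positive; reads are too short for this OT"
        )
    if overlap_count == 0:
        est = None
    else:
        est = len_q + n_targets * interval / overlap_count
    return PerReadEstimate(
        query_id=query_id,
        query_len=len_q,
        n_targets=n_targets,
        mean_target_len=mean_target_len,
        overlap_count=overlap_count,
        estimate=est,
    )


def per_read_estimates(
    pair: ReadSetPair, counts: OverlapCounts, ot: int
) -> list[PerReadEstimate]:
    """Per-read estimates for every query in the pair, from tallied counts."""
    out = []
    for q in pair.queries:
        out.append(
            per_read_estimate(
                len_q=q.length,
                n_targets=counts.n_targets_effective[q.id],
                mean_target_len=counts.mean_target_len_effective[q.id],
                ot=ot,
                overlap_count=counts.counts[q.id],
                query_id=q.id,
            )
        )
    return out


def aggregate(
    per_read: Sequence[PerReadEstimate],
    ci_lower_pct: float = DEFAULT_CI_LOWER_PCT,
    ci_width_pct: float = DEFAULT_CI_WIDTH_PCT,
    strategy: Optional[Strategy] = None,
    seed: Optional[int] = None,
    ot: Optional[int] = None,
) -> EstimateResult:
    """Median of the defined per-read estimates, with a percentile range.

    Zero-overlap (undefined) entries are counted in ``n_zero_overlap``
    and excluded from the median and from both percentiles.  Percentiles
    use linear interpolation between the closest order statistics.
    """
    if not (0 <= ci_lower_pct <= 50 <= ci_lower_pct + ci_width_pct <= 100):
        raise ValueError(
            "percentile range must satisfy 0 <= lower <= 50 <= lower+width <= 100 "
            "so the median lies inside it"
        )
    defined = [e.estimate for e in per_read if e.estimate is not None]
    n_zero = len(per_read) - len(defined)
    if not defined:
        raise EstimationImpossibleError(
            "no query read had any overlap; cannot estimate genome size "
            "(try more reads or a lower minimum overlap threshold)"
        )
    arr = np.asarray(defined, dtype=float)
    median = float(np.median(arr))
    lo, hi = np.percentile(
        arr, [ci_lower_pct, ci_lower_pct + ci_width_pct], method="linear"
    )
    return EstimateResult(
        genome_size=median,
        ci_low=float(lo),
        ci_high=float(hi),
        per_read=list(per_read),
        n_zero_overlap=n_zero,
        n_used=len(defined),
        strategy=strategy,
        seed=seed,
        ot=ot,
        ci_lower_pct=ci_lower_pct,
        ci_width_pct=ci_width_pct,
    )


def relative_error(estimate: float, true_size: float) -> float:
    """Signed percentage error: positive means overestimate."""
    if true_size <= 0:
        raise ValueError("true_size must be > 0")
    return (estimate / true_size - 1.0) * 100.0


def calibrate_confidence_range(
    samples: Sequence[tuple[Sequence[float], float]],
    width_pct: float = DEFAULT_CI_WIDTH_PCT,
    step_pct: float = 1.0,
) -> tuple[float, float]:
    """Scan all width-``width_pct`` percentile ranges containing the median
    and return the lower bound maximizing true-size coverage.

    Each sample is (defined per-read estimates, true genome size).  A
    candidate lower bound L (0 <= L <= 100 - width, stepped by
    ``step_pct``) is admissible when L <= 50 <= L + width, i.e. the
    overall median estimate lies inside the range.  Coverage of L is the
    fraction of samples whose true size falls within the [L, L+width]
    percentile interval of that sample's estimates.  Ties prefer the
    range most nearly centered on the median, then the smaller L.

    Returns (best_lower_pct, coverage).
    """
    if not samples:
        raise ValueError("at least one sample is required")
    if not (0 <= width_pct <= 100):
        raise ValueError("width_pct must be in [0, 100]")
    if step_pct <= 0:
        raise ValueError("step_pct must be > 0")

    n_steps = int(round((100.0 - width_pct) / step_pct))
    grid = [min(i * step_pct, 100.0 - width_pct) for i in range(n_steps + 1)]
    candidates = [L for L in grid if L <= 50.0 <= L + width_pct]
    if not candidates:
        raise ValueError(
            f"no percentile range of width {width_pct} on the scanned grid "
            "contains the median (50th percentile)"
        )

    arrays = [
        (np.asarray([e for e in ests if e is not None], dtype=float), truth)
        for ests, truth in samples
    ]
    for arr, _ in arrays:
        if arr.size == 0:
            raise ValueError("a sample has no defined per-read estimates")

    centered = 50.0 - width_pct / 2.0
    best: Optional[tuple[float, float]] = None
    for L in candidates:
        hits = 0
        for arr, truth in arrays:
            lo, hi = np.percentile(arr, [L, L + width_pct], method="linear")
            if lo <= truth <= hi:
                hits += 1
        cov = hits / len(arrays)
        if (
            best is None
            or cov > best[1] + 1e-12
            or (
                abs(cov - best[1]) <= 1e-12
                and (
                    abs(L - centered) < abs(best[0] - centered) - 1e-12
                    or (
                        abs(abs(L - centered) - abs(best[0] - centered)) <= 1e-12
                        and L < best[0]
                    )
                )
            )
        ):
            best = (L, cov)
    assert best is not None
    return best
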