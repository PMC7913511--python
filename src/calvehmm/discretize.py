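"""Discretization of posture-change counts into ordinal activity levels.

Counts are mapped to three levels — Low, Medium, High — relative to the
sample mean mu and sample standard deviation sigma of the series itself:

* hourly tier: L if n < mu, M if mu <= n < mu + sigma, H if n >= mu + sigma;
* windowed tier (non-overlapping window sums, typically 3 h): L if
  s < mu_w + sigma_w, M if mu_w + sigma_w <= s < mu_w + 2 sigma_w,
  H if s >= mu_w + 2 sigma_w, with mu_w, sigma_w computed on the sums.

Bands are half-open so that counts exactly on a threshold are assigned
deterministically (to the upper band). Sigma uses the n-1 denominator.
The windowed thresholds sit one band higher than the hourly ones because
window sums concentrate around w*mu, which already exceeds mu; the shifted
pair (mu_w + sigma_w, mu_w + 2 sigma_w) keeps Low the majority label in
the pre-calving baseline at both resolutions. See docs/methods.md for a
discussion of this convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import AlignmentError, InsufficientDataError
from .io import ActivitySeries

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SummaryStats:
    """Sample mean and standard deviation of a count series."""

    mu: float
    sigma: float
    n_obs: int


@dataclass(frozen=True)
class LevelSequence:
    """Ordinal L/M/H activity labels plus the statistics that produced them.

    ``tier`` records whether labels were assigned per hour or per window
    sum; ``window`` is the window length in hours (1 for hourly).
    """

    symbols: tuple[str, ...]
    stats: SummaryStats
    tier: Literal["hourly", "windowed"]
    window: int = 1

    def __post_init__(self) -> None:
        bad = set(self.symbols) - {"L", "M", "H"}
        if bad:
            raise ValueError(f"symbols outside alphabet: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.symbols)


def summary_stats(counts: Sequence[int] | Iterable[int]) -> SummaryStats:
    """Sample mean and sample standard deviation (n-1 denominator).

    Raises :class:`InsufficientDataError` for fewer than two observations.
    """
    arr = np.asarray(list(counts), dtype=float)
    if arr.size < 2:
        raise InsufficientDataError(
            f"need at least 2 observations for a standard deviation, got {arr.size}"
        )
    return SummaryStats(
        mu=float(arr.mean()), sigma=float(arr.std(ddof=1)), n_obs=int(arr.size)
    )


def _classify(values: np.ndarray, low_thr: float, high_thr: float) -> tuple[str, ...]:
    # Half-open bands: [.., low_thr) -> L, [low_thr, high_thr) -> M, [high_thr, ..) -> H
    return tuple(
        "L" if v < low_thr else ("M" if v < high_thr else "H") for v in values
    )


def hourly_levels(series: ActivitySeries, stats: SummaryStats | None = None) -> LevelSequence:
    """Map each hourly count to L/M/H using thresholds mu and mu + sigma.

    If ``stats`` is omitted they are computed from the series itself.
    """
    if stats is None:
        stats = summary_stats(series.counts)
    symbols = _classify(
        np.asarray(series.counts, dtype=float), stats.mu, stats.mu + stats.sigma
    )
    return LevelSequence(symbols=symbols, stats=stats, tier="hourly", window=1)


def aggregate_window(series: ActivitySeries, window: int) -> np.ndarray:
    """Non-overlapping consecutive window sums, earliest hours first.

    Raises :class:`AlignmentError` if the series length is not divisible
    by ``window``.
    """
    if window < 1:
        raise ValueError(f"window must be a positive integer, got {window}")
    n = len(series)
    if n % window:
        raise AlignmentError(
            f"series length {n} is not divisible by window {window}"
        )
    return np.asarray(series.counts, dtype=int).reshape(n // window, window).sum(axis=1)


def windowed_levels(sums: Sequence[int] | np.ndarray, window: int = 3) -> LevelSequence:
    """Map window sums to L/M/H using thresholds mu_w+sigma_w and mu_w+2*sigma_w.

    The statistics are computed on the sums themselves with the same
    estimator as :func:`summary_stats`.
    """
    arr = np.asarray(sums, dtype=float)
    stats = summary_stats(arr)
    logger.info(
        "windowed discretization: mu_w=%.4f sigma_w=%.4f thresholds=(%.4f, %.4f) "
        "(package convention: band edges at mu_w+sigma_w and mu_w+2*sigma_w on window sums)",
        stats.mu, stats.sigma, stats.mu + stats.sigma, stats.mu + 2 * stats.sigma,
    )
    symbols = _classify(arr, stats.mu + stats.sigma, stats.mu + 2 * stats.sigma)
    return LevelSequence(symbols=symbols, stats=stats, tier="windowed", window=window)


def discretize(series: ActivitySeries, window: int = 3) -> LevelSequence:
    """Convenience pipeline: aggregate into windows (if window > 1) and label."""
    if window == 1:
        return hourly_levels(series)
    return windowed_levels(aggregate_window(series, window), window=window)
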