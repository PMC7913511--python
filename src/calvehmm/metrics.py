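"""Performance metrics for interval-level calving detection.

Sensitivity and precision are computed per interval with the calving
state C as the positive class. Ratios with an empty denominator are
reported as NaN with an explicit flag rather than silently as zero, so
that averages across animals are not corrupted.

:func:`threshold_accuracy` implements a summary accuracy that scores how
close the fitted activity threshold mu + sigma lands to a fixed
pre-calving horizon (default 3 h): the relative error is squared and
converted to a percentage accuracy. It is a descriptive figure of merit
for the worked example, not a proper scoring rule; see docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .discretize import SummaryStats
from .errors import ValidationError


@dataclass(frozen=True)
class Metrics:
    """Per-interval confusion counts and the derived percentages."""

    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float  # percent, NaN when tp + fn == 0
    precision: float  # percent, NaN when tp + fp == 0
    sensitivity_defined: bool
    precision_defined: bool


def confusion_metrics(truth: Sequence[str], predicted: Sequence[str]) -> Metrics:
    """Score a predicted NC/C sequence against the true one, per interval."""
    if len(truth) != len(predicted):
        raise ValidationError(
            f"length mismatch: truth {len(truth)} vs predicted {len(predicted)}"
        )
    valid = {"NC", "C"}
    bad = (set(truth) | set(predicted)) - valid
    if bad:
        raise ValidationError(f"labels outside {{NC, C}}: {sorted(bad)}")
    tp = sum(t == "C" and p == "C" for t, p in zip(truth, predicted))
    fp = sum(t == "NC" and p == "C" for t, p in zip(truth, predicted))
    fn = sum(t == "C" and p == "NC" for t, p in zip(truth, predicted))
    tn = sum(t == "NC" and p == "NC" for t, p in zip(truth, predicted))
    sens_def = (tp + fn) > 0
    prec_def = (tp + fp) > 0
    return Metrics(
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        sensitivity=100.0 * tp / (tp + fn) if sens_def else math.nan,
        precision=100.0 * tp / (tp + fp) if prec_def else math.nan,
        sensitivity_defined=sens_def,
        precision_defined=prec_def,
    )


def threshold_accuracy(
    stats: SummaryStats,
    horizon: float = 3.0,
    *,
    decimals: int | None = 3,
) -> float:
    """Accuracy percentage from the squared relative error of mu + sigma.

    ``err = |horizon - (mu + sigma)|``; the returned value is
    ``(1 - (err / horizon)^2) * 100``. By default mu + sigma is taken at
    3-decimal reporting precision, the precision at which the summary
    statistics of a fit are quoted; pass ``decimals=None`` to use the full
    floating-point value.
    """
    if horizon <= 0:
        raise ValidationError(f"horizon must be positive, got {horizon}")
    mu_sigma = stats.mu + stats.sigma
    if decimals is not None:
        mu_sigma = round(mu_sigma, decimals)
    pct = abs(horizon - mu_sigma) / horizon
    return (1.0 - pct**2) * 100.0
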