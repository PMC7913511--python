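"""Moment-style estimation of the two-state calving HMM.

The estimator is not Baum-Welch. Each labelled segment of the training
series (an assumed non-calving prefix and calving suffix of known
durations) yields a 3x3 co-occurrence matrix of consecutive L/M/H pairs.
Row-normalizing gives a first-order level-transition chain per hidden
state; the stationary distribution of that chain is taken as the state's
emission distribution. The 2x2 hidden-state transition matrix comes from
the segment durations alone: a regime expected to last d hours gets a
self-transition probability d/(d+1).

With several training animals, co-occurrence counts are pooled across
animals per segment before normalizing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.sparse.csgraph import connected_components

from .discretize import LevelSequence
from .errors import DegeneracyError, InsufficientDataError, ValidationError
from .io import HMMParams, SYMBOLS

logger = logging.getLogger(__name__)

_SYM_INDEX = {s: i for i, s in enumerate(SYMBOLS)}


@dataclass(frozen=True)
class SegmentSpec:
    """Durations of the assumed non-calving prefix and calving suffix."""

    nc_hours: int = 60
    c_hours: int = 12

    def __post_init__(self) -> None:
        if self.nc_hours < 1 or self.c_hours < 1:
            raise ValidationError(
                f"segment durations must be >= 1, got ({self.nc_hours}, {self.c_hours})"
            )


def cooccurrence(symbols: Sequence[str]) -> np.ndarray:
    """3x3 counts of consecutive level pairs within one segment.

    ``counts[i, j]`` is the number of positions t with symbol_t = i and
    symbol_{t+1} = j, both inside the segment; pairs crossing a segment
    boundary are never counted. Total count is ``len(symbols) - 1``.
    """
    if len(symbols) < 2:
        raise InsufficientDataError(
            f"need at least 2 symbols for co-occurrence counts, got {len(symbols)}"
        )
    counts = np.zeros((3, 3), dtype=int)
    idx = [_SYM_INDEX[s] for s in symbols]
    for a, b in zip(idx, idx[1:]):
        counts[a, b] += 1
    return counts


def row_normalize(counts: np.ndarray) -> np.ndarray:
    """Divide each row by its sum; an all-zero row becomes uniform.

    The uniform imputation keeps the pipeline total on sparse segments
    where a level never occurs as a pair origin; it is logged so the
    imputation is visible.
    """
    counts = np.asarray(counts, dtype=float)
    sums = counts.sum(axis=1, keepdims=True)
    zero = (sums == 0).ravel()
    if zero.any():
        logger.warning(
            "row_normalize: zero rows %s imputed as uniform", np.flatnonzero(zero).tolist()
        )
    out = np.where(sums > 0, counts / np.where(sums > 0, sums, 1.0), 1.0 / counts.shape[1])
    return out


def stationary(matrix: np.ndarray) -> np.ndarray:
    """Left stationary distribution pi of a row-stochastic matrix.

    Solves the linear system pi M = pi with the normalization sum(pi) = 1
    replacing one redundant equation, at full floating precision. The
    chain must be irreducible (one communicating class): a reducible
    chain either has a non-unique stationary distribution or puts exactly
    zero mass on its transient states, which would make an emission
    distribution degenerate, so a :class:`DegeneracyError` naming the
    communicating classes is raised.
    """
    M = np.asarray(matrix, dtype=float)
    k = M.shape[0]
    if M.shape != (k, k) or np.any(np.abs(M.sum(axis=1) - 1.0) > 1e-9):
        raise ValidationError("stationary() requires a square row-stochastic matrix")

    n_comp, labels = connected_components(M > 0, directed=True, connection="strong")
    if n_comp != 1:
        classes = [np.flatnonzero(labels == c).tolist() for c in range(n_comp)]
        raise DegeneracyError(
            "chain is reducible; no fully-supported stationary distribution: "
            f"communicating classes {classes}"
        )

    A = np.vstack([M.T - np.eye(k), np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def duration_transition(nc_hours: int, c_hours: int) -> np.ndarray:
    """2x2 hidden-state transition matrix from expected regime durations.

    A state expected to persist d hours transitions to itself with
    probability d/(d+1) and leaves with probability 1/(d+1):
    ``A = [[d1/(d1+1), 1/(d1+1)], [1/(d2+1), d2/(d2+1)]]``.
    """
    if nc_hours < 1 or c_hours < 1:
        raise ValidationError(
            f"durations must be >= 1, got ({nc_hours}, {c_hours})"
        )
    d1, d2 = float(nc_hours), float(c_hours)
    return np.array(
        [[d1 / (d1 + 1), 1 / (d1 + 1)], [1 / (d2 + 1), d2 / (d2 + 1)]]
    )


def segment_counts(levels: LevelSequence, seg: SegmentSpec) -> tuple[np.ndarray, np.ndarray]:
    """Co-occurrence counts for the NC prefix and C suffix of one series."""
    if seg.nc_hours + seg.c_hours != len(levels):
        raise ValidationError(
            f"segment spec ({seg.nc_hours}+{seg.c_hours}) does not match "
            f"sequence length {len(levels)}"
        )
    sym = levels.symbols
    return cooccurrence(sym[: seg.nc_hours]), cooccurrence(sym[seg.nc_hours :])


def build_hmm(
    levels: LevelSequence | Sequence[LevelSequence],
    seg: SegmentSpec = SegmentSpec(),
    pi: Sequence[float] | None = None,
) -> HMMParams:
    """Assemble lambda = (A, B, Pi) from labelled level sequences.

    Emission row for each hidden state is the stationary distribution of
    the row-normalized pooled co-occurrence matrix of its segment; A comes
    from the segment durations; Pi defaults to the uninformative [0.5, 0.5].
    """
    if isinstance(levels, LevelSequence):
        levels = [levels]
    if not levels:
        raise InsufficientDataError("no level sequences supplied")
    nc_total = np.zeros((3, 3), dtype=int)
    c_total = np.zeros((3, 3), dtype=int)
    for lev in levels:
        nc, c = segment_counts(lev, seg)
        nc_total += nc
        c_total += c
    P = row_normalize(nc_total)
    Q = row_normalize(c_total)
    B = np.vstack([stationary(P), stationary(Q)])
    A = duration_transition(seg.nc_hours, seg.c_hours)
    Pi = np.array([0.5, 0.5]) if pi is None else np.asarray(pi, dtype=float)
    logger.info("fitted emission matrix B=%s from pooled counts over %d series",
                np.round(B, 3).tolist(), len(levels))
    return HMMParams(A=A, B=B, Pi=Pi)
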