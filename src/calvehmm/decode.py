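"""Hidden-state decoding and calving-time prediction.

Two decoders are provided. :func:`viterbi` returns the single most
probable NC/C path (log-space dynamic program, ties broken toward NC so a
calving call always requires positive evidence). :func:`forward_backward`
returns the smoothed per-interval posterior probability of the calving
state given the whole observation record, computed with per-step scaling.

:func:`predict_calving_time` turns either decoder into a point prediction
of the calving interval under one of three explicit strategies:

``viterbi_onset``
    first interval whose Viterbi state is C (None if the path has no C);
``max_posterior``
    interval maximizing the smoothed posterior gamma_t(C) — the default,
    appropriate when transitions strongly favour staying in NC so the
    joint-mode path is conservative;
``posterior_threshold``
    first interval with gamma_t(C) >= tau (None if never reached).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .discretize import LevelSequence
from .io import HMMParams

STRATEGIES = ("viterbi_onset", "max_posterior", "posterior_threshold")


@dataclass(frozen=True)
class DecodingResult:
    """Decoded path, its log-likelihood, posteriors and the predicted interval.

    ``predicted_interval`` is a 0-based index into the observation
    sequence, or None when the strategy makes no calving call.
    ``log_likelihood`` is the natural-log joint probability of the Viterbi
    path and the observations (-inf when no feasible path exists).
    """

    path: tuple[str, ...]
    log_likelihood: float
    posteriors: np.ndarray
    predicted_interval: int | None
    strategy: str


def _encode(params: HMMParams, obs: LevelSequence | Sequence[str]) -> np.ndarray:
    symbols = obs.symbols if isinstance(obs, LevelSequence) else tuple(obs)
    index = {s: i for i, s in enumerate(params.symbols)}
    try:
        return np.array([index[s] for s in symbols], dtype=int)
    except KeyError as exc:
        raise ValueError(f"symbol {exc.args[0]!r} outside alphabet {params.symbols}") from None


def _log(x: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(x)


def viterbi(params: HMMParams, obs: LevelSequence | Sequence[str]) -> tuple[tuple[str, ...], float]:
    """Most probable hidden-state path and its joint log-likelihood.

    Log-space DP with -inf as the zero-probability sentinel; on ties the
    lower-index state (NC) wins, so the decoder never claims calving
    without strictly stronger evidence.
    """
    o = _encode(params, obs)
    logA, logB, logPi = _log(params.A), _log(params.B), _log(params.Pi)
    T, k = len(o), len(params.states)
    delta = logPi + logB[:, o[0]]
    back = np.zeros((T, k), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + logA  # cand[i, j]: best arriving in j from i
        back[t] = cand.argmax(axis=0)
        delta = cand.max(axis=0) + logB[:, o[t]]
    last = int(delta.argmax())  # argmax takes the first maximum -> NC on ties
    path = [last]
    for t in range(T - 1, 0, -1):
        path.append(int(back[t, path[-1]]))
    path.reverse()
    return tuple(params.states[s] for s in path), float(delta[last])


def forward_backward(params: HMMParams, obs: LevelSequence | Sequence[str]) -> np.ndarray:
    """Smoothed posterior P(state_t = C | all observations), one value per t.

    Uses scaled forward/backward recursions, so sequences of arbitrary
    length decode without underflow. Returns an array in [0, 1]; the NC
    posterior is its complement.
    """
    o = _encode(params, obs)
    A, B, Pi = params.A, params.B, params.Pi
    T, k = len(o), len(params.states)
    alpha = np.zeros((T, k))
    scale = np.zeros(T)
    alpha[0] = Pi * B[:, o[0]]
    scale[0] = alpha[0].sum()
    if scale[0] == 0:
        raise ValueError("observation sequence has zero probability under the model")
    alpha[0] /= scale[0]
    for t in range(1, T):
        alpha[t] = (alpha[t - 1] @ A) * B[:, o[t]]
        scale[t] = alpha[t].sum()
        if scale[t] == 0:
            raise ValueError("observation sequence has zero probability under the model")
        alpha[t] /= scale[t]
    beta = np.ones((T, k))
    for t in range(T - 2, -1, -1):
        beta[t] = A @ (B[:, o[t + 1]] * beta[t + 1]) / scale[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    return gamma[:, 1]


def sequence_log_likelihood(params: HMMParams, obs: LevelSequence | Sequence[str]) -> float:
    """Natural-log marginal likelihood log P(observations | lambda)."""
    o = _encode(params, obs)
    alpha = params.Pi * params.B[:, o[0]]
    ll = 0.0
    for t in range(len(o)):
        if t:
            alpha = (alpha @ params.A) * params.B[:, o[t]]
        s = alpha.sum()
        if s == 0:
            return float("-inf")
        ll += np.log(s)
        alpha = alpha / s
    return float(ll)


def predict_calving_time(
    params: HMMParams,
    obs: LevelSequence | Sequence[str],
    strategy: str = "max_posterior",
    threshold: float | None = None,
) -> DecodingResult:
    """Decode the record and predict the calving interval.

    ``threshold`` (tau) is required for the ``posterior_threshold``
    strategy and must lie strictly inside (0, 1).
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
    path, ll = viterbi(params, obs)
    gamma = forward_backward(params, obs)
    if strategy == "viterbi_onset":
        hits = [i for i, s in enumerate(path) if s == "C"]
        predicted = hits[0] if hits else None
    elif strategy == "max_posterior":
        predicted = int(np.argmax(gamma))
    else:
        if threshold is None or not 0 < threshold < 1:
            raise ValueError(
                f"posterior_threshold requires a threshold in (0, 1), got {threshold!r}"
            )
        above = np.flatnonzero(gamma >= threshold)
        predicted = int(above[0]) if above.size else None
    return DecodingResult(
        path=path,
        log_likelihood=ll,
        posteriors=gamma,
        predicted_interval=predicted,
        strategy=strategy,
    )
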