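"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's dynamic-programming code paths:
Viterbi is checked against exhaustive enumeration of all 2^T state paths,
smoothed posteriors against exact path-sum marginals, and stationary
distributions against long power iteration.
"""

from itertools import product

import numpy as np


def enumerate_best_path(A, B, Pi, obs):
    """Max-probability path by enumerating every state sequence."""
    T = len(obs)
    best_logp, best_path = -np.inf, None
    with np.errstate(divide="ignore"):
        lA, lB, lPi = np.log(A), np.log(B), np.log(Pi)
    for path in product(range(A.shape[0]), repeat=T):
        logp = lPi[path[0]] + lB[path[0], obs[0]]
        for t in range(1, T):
            logp += lA[path[t - 1], path[t]] + lB[path[t], obs[t]]
        if logp > best_logp:
            best_logp, best_path = logp, path
    return best_path, best_logp


def pathsum_posteriors(A, B, Pi, obs):
    """Exact P(state_t = s | obs) by summing joint probabilities of all paths."""
    T, k = len(obs), A.shape[0]
    joint = np.zeros((T, k))
    total = 0.0
    for path in product(range(k), repeat=T):
        p = Pi[path[0]] * B[path[0], obs[0]]
        for t in range(1, T):
            p *= A[path[t - 1], path[t]] * B[path[t], obs[t]]
        total += p
        for t, s in enumerate(path):
            joint[t, s] += p
    return joint / total


def power_iteration_stationary(M, iters=20000):
    """Stationary distribution by averaging iterates of pi @ M."""
    k = M.shape[0]
    pi = np.full(k, 1.0 / k)
    avg = np.zeros(k)
    for _ in range(iters):
        pi = pi @ M
        avg += pi
    avg /= iters
    return avg / avg.sum()
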