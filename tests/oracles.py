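"""Independent brute-force oracles used to check the fast implementations."""

import itertools

import numpy as np

from serpeak.intervals import overlaps_reciprocal


def brute_force_forward(logB, A, pi):
    """Log-likelihood by explicit summation over all K**T state paths."""
    T, K = logB.shape
    total = -np.inf
    for path in itertools.product(range(K), repeat=T):
        lp = np.log(pi[path[0]]) + logB[0, path[0]]
        for t in range(1, T):
            lp += np.log(A[path[t - 1], path[t]]) + logB[t, path[t]]
        total = np.logaddexp(total, lp)
    return total


def brute_force_viterbi(logB, A, pi):
    """Best path log-probability by explicit maximization over all paths."""
    T, K = logB.shape
    best = -np.inf
    best_path = None
    for path in itertools.product(range(K), repeat=T):
        lp = np.log(pi[path[0]]) + logB[0, path[0]]
        for t in range(1, T):
            lp += np.log(A[path[t - 1], path[t]]) + logB[t, path[t]]
        if lp > best:
            best, best_path = lp, path
    return np.array(best_path), best


def brute_force_posterior(logB, A, pi):
    """Per-position marginal state probabilities by path enumeration."""
    T, K = logB.shape
    gamma = np.zeros((T, K))
    for path in itertools.product(range(K), repeat=T):
        lp = np.log(pi[path[0]]) + logB[0, path[0]]
        for t in range(1, T):
            lp += np.log(A[path[t - 1], path[t]]) + logB[t, path[t]]
        w = np.exp(lp)
        for t, s in enumerate(path):
            gamma[t, s] += w
    return gamma / gamma.sum(axis=1, keepdims=True)


def brute_force_overlap_pairs(peaks_a, peaks_b, frac=0.3):
    """All-pairs O(n^2) reciprocal-overlap scan."""
    return sorted(
        (i, j)
        for i, a in enumerate(peaks_a)
        for j, b in enumerate(peaks_b)
        if overlaps_reciprocal(a, b, frac)
    )


def random_hmm_params(rng, K):
    A = rng.dirichlet(np.ones(K), size=K)
    pi = rng.dirichlet(np.ones(K))
    return A, pi
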