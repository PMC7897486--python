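"""Hidden Markov model core: scaled forward/backward, Viterbi and Baum-Welch.

Two emission families are provided, matching the two segmentation problems in
the pipeline:

* :class:`GaussianHMM` — univariate Gaussian emissions on transformed window
  counts; used for the 4-state signal-enrichment model.
* :class:`BernoulliHMM` — product-Bernoulli emissions over binarized
  histone-mark presence vectors; used for the 6-state chromatin-state model.

Multiple observation sequences (chromosomes, cell types) are treated as
independent chains sharing one parameter set. The E-step uses the classic
per-step scaling recursion, so sequences of hundreds of thousands of bins are
handled without underflow; inner loops are numba-compiled.

Baum-Welch is guaranteed non-decreasing in log-likelihood; the fitted models
record the per-iteration log-likelihood history in ``history_`` so callers
can assert monotonicity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from numba import njit
from scipy.stats import norm

__all__ = ["GaussianHMM", "BernoulliHMM", "forward_loglik", "viterbi_path"]

_TINY = 1e-300


@njit(cache=True)
def _forward(B, A, pi):
    """Scaled forward pass. B is the (T, K) emission likelihood matrix."""
    T, K = B.shape
    alpha = np.empty((T, K))
    c = np.empty(T)
    a = pi * B[0]
    s = a.sum()
    if s <= 0.0:
        s = _TINY
    c[0] = s
    alpha[0] = a / s
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * B[t]
        s = a.sum()
        if s <= 0.0:
            s = _TINY
        c[t] = s
        alpha[t] = a / s
    return alpha, c


@njit(cache=True)
def _backward(B, A, c):
    T, K = B.shape
    beta = np.empty((T, K))
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (B[t + 1] * beta[t + 1])) / c[t + 1]
    return beta


@njit(cache=True)
def _transition_numerator(alpha, beta, B, A, c):
    T, K = B.shape
    xi = np.zeros((K, K))
    for t in range(T - 1):
        w = B[t + 1] * beta[t + 1] / c[t + 1]
        for i in range(K):
            for j in range(K):
                xi[i, j] += alpha[t, i] * A[i, j] * w[j]
    return xi


@njit(cache=True)
def _viterbi(logB, logA, logpi):
    T, K = logB.shape
    delta = logpi + logB[0]
    back = np.zeros((T, K), dtype=np.int64)
    for t in range(1, T):
        new = np.empty(K)
        for j in range(K):
            best_i = 0
            best = delta[0] + logA[0, j]
            for i in range(1, K):
                v = delta[i] + logA[i, j]
                if v > best:
                    best = v
                    best_i = i
            new[j] = best + logB[t, j]
            back[t, j] = best_i
        delta = new
    path = np.empty(T, dtype=np.int64)
    k = int(np.argmax(delta))
    path[T - 1] = k
    for t in range(T - 2, -1, -1):
        k = back[t + 1, k]
        path[t] = k
    return path, delta.max()


def _safe_log(x: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(x)


def _likelihoods_from_log(logB: np.ndarray) -> Tuple[np.ndarray, float]:
    """exp(logB) with per-row max factored out; returns (B, summed offset)."""
    m = logB.max(axis=1)
    B = np.exp(logB - m[:, None])
    return B, float(m.sum())


def forward_loglik(logB: np.ndarray, transition: np.ndarray, startprob: np.ndarray) -> float:
    """Total log-likelihood of one observation sequence (scaled forward)."""
    B, off = _likelihoods_from_log(np.asarray(logB, dtype=np.float64))
    _, c = _forward(B, np.asarray(transition, float), np.asarray(startprob, float))
    return float(np.log(c).sum() + off)


def viterbi_path(
    logB: np.ndarray, transition: np.ndarray, startprob: np.ndarray
) -> Tuple[np.ndarray, float]:
    """Most probable state path and its joint log-probability."""
    path, logp = _viterbi(
        np.ascontiguousarray(logB, dtype=np.float64),
        _safe_log(np.asarray(transition, float)),
        _safe_log(np.asarray(startprob, float)),
    )
    return path, float(logp)


def _posteriors(logB, A, pi):
    """gamma (T, K), transition numerator (K, K) and sequence log-likelihood."""
    B, off = _likelihoods_from_log(logB)
    alpha, c = _forward(B, A, pi)
    beta = _backward(B, A, c)
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    xi = _transition_numerator(alpha, beta, B, A, c)
    return gamma, xi, float(np.log(c).sum() + off)


def _relabel(order: np.ndarray, transition, startprob, *emission_arrays):
    """Apply a state permutation to all parameter blocks."""
    out = [transition[np.ix_(order, order)], startprob[order]]
    out += [e[order] for e in emission_arrays]
    return out


class _BaseHMM:
    """Shared Baum-Welch driver; subclasses supply emission log-pdfs + M-step."""

    transition: np.ndarray
    startprob: np.ndarray
    history_: List[float]

    @property
    def n_states(self) -> int:
        return len(self.startprob)

    # -- subclass hooks ---------------------------------------------------
    def _log_emission(self, obs) -> np.ndarray:  # (T, K)
        raise NotImplementedError

    def _emission_mstep(self, seqs, gammas) -> None:
        raise NotImplementedError

    def _relabel_states(self) -> None:
        raise NotImplementedError

    # ---------------------------------------------------------------------
    def loglikelihood(self, seqs: Sequence) -> float:
        """Joint log-likelihood of independent sequences under the model."""
        return sum(
            forward_loglik(self._log_emission(obs), self.transition, self.startprob)
            for obs in seqs
        )

    def viterbi(self, obs) -> np.ndarray:
        """Most probable state path (0-based state indices)."""
        path, _ = viterbi_path(self._log_emission(obs), self.transition, self.startprob)
        return path

    def posterior(self, obs) -> np.ndarray:
        """Per-position marginal state probabilities (T, K)."""
        gamma, _, _ = _posteriors(
            self._log_emission(obs), self.transition, self.startprob
        )
        return gamma

    def fit(
        self,
        seqs: Sequence,
        max_iter: int = 200,
        tol: float = 1e-6,
        min_self_transition: float = 0.0,
    ):
        """Baum-Welch over independent sequences sharing this parameter set.

        Stops when the relative log-likelihood improvement drops below
        ``tol`` or after ``max_iter`` M-steps. An infinite tolerance accepts
        the initial model (no update). After fitting, states are relabelled
        into the family's canonical order.

        ``min_self_transition`` constrains the transition M-step: when the
        unconstrained update would push a diagonal entry below the floor, the
        diagonal is clamped there and the off-diagonal mass rescaled
        (the exact solution of the constrained M-step, so the EM monotonicity
        guarantee is preserved). This acts as segment-length regularization
        for segmentation use, where state runs should not fragment.
        """
        seqs = [s for s in seqs if len(s) > 0]
        if not seqs:
            raise ValueError("need at least one non-empty sequence")
        self.history_ = []
        if np.isinf(tol):
            return self
        for _ in range(max_iter):
            gammas, xi_sum, ll = [], np.zeros((self.n_states, self.n_states)), 0.0
            start_acc = np.zeros(self.n_states)
            for obs in seqs:
                gamma, xi, l = _posteriors(
                    self._log_emission(obs), self.transition, self.startprob
                )
                gammas.append(gamma)
                xi_sum += xi
                start_acc += gamma[0]
                ll += l
            if self.history_ and ll - self.history_[-1] < tol * abs(self.history_[-1]):
                self.history_.append(ll)
                break
            self.history_.append(ll)
            # M-step
            denom = xi_sum.sum(axis=1, keepdims=True)
            self.transition = np.where(denom > 0, xi_sum / np.maximum(denom, _TINY), self.transition)
            self.transition /= self.transition.sum(axis=1, keepdims=True)
            if min_self_transition > 0.0:
                for i in range(self.n_states):
                    if self.transition[i, i] < min_self_transition:
                        off = 1.0 - self.transition[i, i]
                        scale = (1.0 - min_self_transition) / max(off, _TINY)
                        self.transition[i] *= scale
                        self.transition[i, i] = min_self_transition
            self.startprob = start_acc / start_acc.sum()
            self._emission_mstep(seqs, gammas)
        self._relabel_states()
        return self


@dataclass
class GaussianHMM(_BaseHMM):
    """HMM with univariate Gaussian emissions, one (mean, sd) per state.

    After fitting, states are relabelled so emission means are non-decreasing
    with state index; the two highest-index states then carry the strongest
    signal by construction.
    """

    means: np.ndarray
    sds: np.ndarray
    transition: np.ndarray
    startprob: np.ndarray
    sd_floor: float = 1e-3
    history_: List[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=np.float64)
        self.sds = np.maximum(np.asarray(self.sds, dtype=np.float64), self.sd_floor)
        self.transition = np.asarray(self.transition, dtype=np.float64)
        self.startprob = np.asarray(self.startprob, dtype=np.float64)
        _check_stochastic(self.transition, self.startprob)

    @classmethod
    def from_percentile_init(
        cls,
        data: np.ndarray,
        n_states: int = 4,
        self_transition: float = 0.9,
        sd_floor: float = 1e-3,
    ) -> "GaussianHMM":
        """Deterministic rank-ordered initialization.

        Emission means sit at the 20th/50th/80th/99th percentiles of the data
        (evenly spread percentiles capped at 99 for other state counts), sds
        equal the global standard deviation, the transition matrix has
        ``self_transition`` on the diagonal, and the initial vector is
        uniform.
        """
        data = np.asarray(data, dtype=np.float64).ravel()
        if n_states == 4:
            qs = [20.0, 50.0, 80.0, 99.0]
        else:
            qs = list(np.linspace(100 / (n_states + 1), 99.0, n_states))
        means = np.percentile(data, qs)
        # nudge coincident percentiles apart so states are distinguishable
        for k in range(1, n_states):
            if means[k] <= means[k - 1]:
                means[k] = means[k - 1] + 1e-3
        sd = max(float(data.std()), sd_floor)
        off = (1.0 - self_transition) / (n_states - 1)
        transition = np.full((n_states, n_states), off)
        np.fill_diagonal(transition, self_transition)
        return cls(
            means=means,
            sds=np.full(n_states, sd),
            transition=transition,
            startprob=np.full(n_states, 1.0 / n_states),
            sd_floor=sd_floor,
        )

    def _log_emission(self, obs) -> np.ndarray:
        obs = np.asarray(obs, dtype=np.float64)
        return norm.logpdf(obs[:, None], loc=self.means[None, :], scale=self.sds[None, :])

    def _emission_mstep(self, seqs, gammas) -> None:
        K = self.n_states
        w = np.zeros(K)
        wx = np.zeros(K)
        wxx = np.zeros(K)
        for obs, gamma in zip(seqs, gammas):
            obs = np.asarray(obs, dtype=np.float64)
            w += gamma.sum(axis=0)
            wx += gamma.T @ obs
            wxx += gamma.T @ (obs * obs)
        means = wx / np.maximum(w, _TINY)
        var = wxx / np.maximum(w, _TINY) - means**2
        self.means = means
        self.sds = np.maximum(np.sqrt(np.maximum(var, 0.0)), self.sd_floor)

    def _relabel_states(self) -> None:
        order = np.argsort(self.means, kind="stable")
        self.transition, self.startprob, self.means, self.sds = _relabel(
            order, self.transition, self.startprob, self.means, self.sds
        )


@dataclass
class BernoulliHMM(_BaseHMM):
    """HMM with product-Bernoulli emissions over M binary mark tracks.

    Observations are (T, M) binary matrices. Internally each row is mapped to
    one of 2**M symbols so the emission likelihood is a (K, 2**M) lookup
    table, which keeps the E-step cheap. After fitting, states are relabelled
    by descending total emission probability (the most mark-rich state
    first), so the all-low "quiescent" state lands at the highest index.
    """

    emission: np.ndarray  # (K, M) Bernoulli success probabilities
    transition: np.ndarray
    startprob: np.ndarray
    prob_clip: float = 1e-6
    history_: List[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.emission = np.asarray(self.emission, dtype=np.float64)
        if self.emission.ndim != 2:
            raise ValueError("emission must be a (n_states, n_marks) matrix")
        if ((self.emission < 0) | (self.emission > 1)).any():
            raise ValueError("emission probabilities must lie in [0, 1]")
        self.transition = np.asarray(self.transition, dtype=np.float64)
        self.startprob = np.asarray(self.startprob, dtype=np.float64)
        _check_stochastic(self.transition, self.startprob)

    @property
    def n_marks(self) -> int:
        return self.emission.shape[1]

    @classmethod
    def random_init(
        cls,
        n_states: int,
        n_marks: int,
        rng: np.random.Generator,
        self_transition: float = 0.9,
    ) -> "BernoulliHMM":
        if n_states == 1:
            transition = np.ones((1, 1))
        else:
            off = (1.0 - self_transition) / (n_states - 1)
            transition = np.full((n_states, n_states), off)
            np.fill_diagonal(transition, self_transition)
        return cls(
            emission=rng.uniform(0.1, 0.9, size=(n_states, n_marks)),
            transition=transition,
            startprob=np.full(n_states, 1.0 / n_states),
        )

    def _bits(self) -> np.ndarray:
        M = self.n_marks
        sym = np.arange(2**M)
        return ((sym[:, None] >> np.arange(M)[None, :]) & 1).astype(np.float64)

    @staticmethod
    def _symbols(obs: np.ndarray) -> np.ndarray:
        obs = np.asarray(obs)
        weights = 1 << np.arange(obs.shape[1])
        return obs.astype(np.int64) @ weights

    def _log_table(self) -> np.ndarray:
        """(K, 2**M) log-likelihood of each mark-presence pattern per state."""
        # clip for the log only: exact 0/1 probabilities map to a very
        # negative finite penalty instead of -inf (0 * -inf would be NaN)
        p = np.clip(self.emission, 1e-300, 1.0)
        q = np.clip(1.0 - self.emission, 1e-300, 1.0)
        bits = self._bits()  # (S, M)
        return bits @ np.log(p).T + (1.0 - bits) @ np.log(q).T  # [symbol, state]

    def _log_emission(self, obs) -> np.ndarray:
        table = self._log_table()  # (S, K)
        return table[self._symbols(obs)]

    def _emission_mstep(self, seqs, gammas) -> None:
        K, M = self.emission.shape
        num = np.zeros((K, M))
        den = np.zeros(K)
        for obs, gamma in zip(seqs, gammas):
            obs = np.asarray(obs, dtype=np.float64)
            num += gamma.T @ obs
            den += gamma.sum(axis=0)
        p = num / np.maximum(den, _TINY)[:, None]
        self.emission = np.clip(p, self.prob_clip, 1.0 - self.prob_clip)

    def _relabel_states(self) -> None:
        totals = self.emission.sum(axis=1)
        # descending total emission; stable ties by original index
        order = np.argsort(-totals, kind="stable")
        relabelled = _relabel(order, self.transition, self.startprob, self.emission)
        self.transition, self.startprob, self.emission = relabelled


def _check_stochastic(transition: np.ndarray, startprob: np.ndarray) -> None:
    if transition.ndim != 2 or transition.shape[0] != transition.shape[1]:
        raise ValueError("transition must be square")
    if not np.allclose(transition.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("transition rows must sum to 1")
    if not np.isclose(startprob.sum(), 1.0, atol=1e-9):
        raise ValueError("startprob must sum to 1")
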