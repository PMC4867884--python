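"""k-segment inference on the counter-augmented HMM.

Three exact, linear-time problems conditional on an event about the segment
count c_x (or a generalized / excursion count):

- optimal decoding: the MAP path among paths satisfying the event;
- probability computation: the exact posterior p(c_x = k | y) over counts;
- path sampling: i.i.d. draws from the event-conditioned posterior.

All of them run the classical recursions on the extended state (counter,
phase, hidden state); the deterministic counter structure (increments of at
most 1 per step) keeps the cost at O((k_max + 1) M^2 N).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from . import _dp
from .counting import AugmentedChain, CountingSpec, build_augmented_transition
from .hmm_core import (
    DegenerateEvidenceError,
    HMMParams,
    InfeasibleEventError,
    InputError,
)

__all__ = [
    "SegmentEvent",
    "PosteriorSegmentDistribution",
    "KSummary",
    "ConstrainedMarginals",
    "kseg_viterbi",
    "kseg_summary",
    "kseg_forward",
    "kseg_sample",
    "constrained_marginals",
]

EXACTLY = "exactly"
AT_MOST = "at_most"
GREATER_THAN = "greater_than"
BETWEEN = "between"


@dataclass(frozen=True)
class SegmentEvent:
    """An event about the terminal counter value: {c=k}, {c<=k}, {c>k} or
    {k1<=c<=k2}."""

    comparator: str
    k: int | None = None
    k1: int | None = None
    k2: int | None = None

    def __post_init__(self):
        if self.comparator in (EXACTLY, AT_MOST, GREATER_THAN):
            if self.k is None or self.k < 0:
                raise InputError("event needs a nonnegative k")
        elif self.comparator == BETWEEN:
            if self.k1 is None or self.k2 is None or not 0 <= self.k1 < self.k2:
                raise InputError("between events need 0 <= k1 < k2")
        else:
            raise InputError(f"unknown event comparator {self.comparator!r}")

    @classmethod
    def exactly(cls, k: int) -> "SegmentEvent":
        return cls(EXACTLY, k=int(k))

    @classmethod
    def at_most(cls, k: int) -> "SegmentEvent":
        return cls(AT_MOST, k=int(k))

    @classmethod
    def greater_than(cls, k: int) -> "SegmentEvent":
        return cls(GREATER_THAN, k=int(k))

    @classmethod
    def between(cls, k1: int, k2: int) -> "SegmentEvent":
        return cls(BETWEEN, k1=int(k1), k2=int(k2))

    @classmethod
    def at_least(cls, k: int) -> "SegmentEvent":
        """{c >= k}, expressed through the greater-than comparator."""
        if k < 1:
            raise InputError("at_least needs k >= 1; {c >= 0} is vacuous")
        return cls(GREATER_THAN, k=int(k) - 1)

    def matches(self, count: int) -> bool:
        if self.comparator == EXACTLY:
            return count == self.k
        if self.comparator == AT_MOST:
            return count <= self.k
        if self.comparator == GREATER_THAN:
            return count > self.k
        return self.k1 <= count <= self.k2

    def __str__(self):
        if self.comparator == EXACTLY:
            return f"c={self.k}"
        if self.comparator == AT_MOST:
            return f"c<={self.k}"
        if self.comparator == GREATER_THAN:
            return f"c>{self.k}"
        return f"{self.k1}<=c<={self.k2}"


def _event_layout(event: SegmentEvent, spec: CountingSpec, N: int):
    """(cap, allowed terminal counter values) for an event.

    The recursion always absorbs at ``cap``; the event is imposed by
    restricting (maximizing / marginalizing / sampling over) the terminal
    counter values.
    """
    if event.comparator == BETWEEN:
        cap = event.k2 + 1
        lo, hi = event.k1, event.k2
    elif event.comparator == GREATER_THAN:
        cap = event.k + 1
        lo = hi = cap
    else:
        cap = event.k + 1
        lo = 0 if event.comparator == AT_MOST else event.k
        hi = event.k
    if not spec.counts_from_zero:
        lo = max(lo, 1)
        if hi < 1 and event.comparator != GREATER_THAN:
            raise InfeasibleEventError(
                f"event {{{event}}} is infeasible: this counting variant never yields 0"
            )
    if event.comparator != GREATER_THAN and lo > min(hi, N):
        raise InfeasibleEventError(f"event {{{event}}} allows no achievable count")
    allowed = np.zeros(cap + 1, dtype=np.bool_)
    allowed[lo : hi + 1] = True
    return cap, allowed


def _prepare(model: HMMParams, y, spec: CountingSpec, cap: int):
    chain = build_augmented_transition(model, spec, cap, absorbing=True)
    loglik = chain.emission_loglik(model, y)
    return chain, loglik


def vacuous_event(N: int) -> SegmentEvent:
    """An event satisfied by every path of length N (any counting variant)."""
    return SegmentEvent.between(0, N) if N >= 1 else SegmentEvent.at_most(0)


# ---------------------------------------------------------------------------
# optimal decoding
# ---------------------------------------------------------------------------


def kseg_viterbi(model: HMMParams, y, spec: CountingSpec, event: SegmentEvent):
    """MAP path among the paths satisfying the count event, with its log score.

    Raises InfeasibleEventError when no path satisfies the event with nonzero
    probability.  Ties break lexicographically on (counter, state).
    """
    spec = spec.bind(model.M)
    cap, allowed = _event_layout(event, spec, np.asarray(y).shape[0])
    chain, loglik = _prepare(model, y, spec, cap)
    final, bp = _dp.viterbi_dp(
        loglik, chain.logpi_u, chain.s1, chain.logA_u, chain.inc, chain.S, chain.absorbing
    )
    masked = np.where(allowed[:, None], final, -np.inf)
    flat = int(np.argmax(masked))
    score = float(masked.flat[flat])
    if not np.isfinite(score):
        raise InfeasibleEventError(
            f"no path satisfies {{{event}}} with nonzero probability"
        )
    s, u = divmod(flat, chain.U)
    path = chain.states_of(_dp.backtrack(bp, s, u))
    return path, score


@dataclass
class KSummary:
    """The k_max + 1 summary: MAP paths for c = k_min..k_max plus the
    absorbing entry (MAP under {c > k_max})."""

    k_min: int
    k_max: int
    paths: dict  # k -> path or None when infeasible
    scores: dict  # k -> log score (-inf when infeasible)
    absorbing_path: np.ndarray | None
    absorbing_score: float

    def entries(self):
        for k in range(self.k_min, self.k_max + 1):
            yield k, self.paths[k], self.scores[k]

    def all_paths(self):
        out = [p for _, p, _ in self.entries() if p is not None]
        if self.absorbing_path is not None:
            out.append(self.absorbing_path)
        return out


def kseg_summary(model: HMMParams, y, spec: CountingSpec, k_max: int) -> KSummary:
    """One O(k_max M^2 N) pass giving MAP paths for every k up to k_max plus
    the {c > k_max} entry; the set always contains the standard Viterbi path."""
    if k_max < 1:
        raise InputError("k_max must be >= 1")
    spec = spec.bind(model.M)
    cap = k_max + 1
    chain, loglik = _prepare(model, y, spec, cap)
    final, bp = _dp.viterbi_dp(
        loglik, chain.logpi_u, chain.s1, chain.logA_u, chain.inc, chain.S, chain.absorbing
    )
    paths, scores = {}, {}
    for k in range(chain.s_min, k_max + 1):
        u = int(np.argmax(final[k]))
        score = float(final[k, u])
        if np.isfinite(score):
            paths[k] = chain.states_of(_dp.backtrack(bp, k, u))
        else:
            paths[k] = None
        scores[k] = score
    u = int(np.argmax(final[cap]))
    ab_score = float(final[cap, u])
    ab_path = chain.states_of(_dp.backtrack(bp, cap, u)) if np.isfinite(ab_score) else None
    return KSummary(
        k_min=chain.s_min,
        k_max=k_max,
        paths=paths,
        scores=scores,
        absorbing_path=ab_path,
        absorbing_score=ab_score,
    )


# ---------------------------------------------------------------------------
# probability computation
# ---------------------------------------------------------------------------


@dataclass
class PosteriorSegmentDistribution:
    """Exact posterior over the count: p(c = k | y) for k = k_min..k_max plus
    the tail mass p(c > k_max | y)."""

    k_min: int
    k_max: int
    probs: np.ndarray  # index k - k_min
    log_probs: np.ndarray
    tail: float
    log_tail: float
    log_evidence: float

    @property
    def ks(self) -> np.ndarray:
        return np.arange(self.k_min, self.k_max + 1)

    def p(self, k: int) -> float:
        if not self.k_min <= k <= self.k_max:
            raise InputError(f"k={k} outside summarized range")
        return float(self.probs[k - self.k_min])

    def total(self) -> float:
        return float(self.probs.sum() + self.tail)

    def mode(self) -> int:
        return int(self.k_min + np.argmax(self.probs))


def kseg_forward(model: HMMParams, y, spec: CountingSpec, k_max: int,
                 ) -> PosteriorSegmentDistribution:
    """Exact segment-count posterior from one forward pass on the augmented
    chain; p(c = k | y) = p(s_N = k, y) / p(y), with an absorbing tail."""
    if k_max < 1:
        raise InputError("k_max must be >= 1")
    spec = spec.bind(model.M)
    chain, loglik = _prepare(model, y, spec, k_max + 1)
    final = _dp.forward_final(
        loglik, chain.logpi_u, chain.s1, chain.logA_u, chain.inc, chain.S, chain.absorbing
    )
    per_count = logsumexp(final, axis=1)  # log p(s_N = k, y)
    logz = float(logsumexp(per_count))
    if not np.isfinite(logz):
        raise DegenerateEvidenceError("log p(y) = -inf under this model")
    lp = per_count - logz
    return PosteriorSegmentDistribution(
        k_min=chain.s_min,
        k_max=k_max,
        probs=np.exp(lp[chain.s_min : k_max + 1]),
        log_probs=lp[chain.s_min : k_max + 1],
        tail=float(np.exp(lp[k_max + 1])),
        log_tail=float(lp[k_max + 1]),
        log_evidence=logz,
    )


# ---------------------------------------------------------------------------
# path sampling
# ---------------------------------------------------------------------------


def kseg_sample(model: HMMParams, y, spec: CountingSpec, event: SegmentEvent,
                n_samples: int, seed: int) -> np.ndarray:
    """i.i.d. draws from p(x | event, y) by FF-BS on the augmented chain.

    Returns (n_samples, N) 1-based paths; every draw satisfies the event.
    Sample i consumes row i of the seeded uniform stream in position order
    n = N..1.
    """
    if n_samples < 1:
        raise InputError("n_samples must be >= 1")
    spec = spec.bind(model.M)
    N = np.asarray(y).shape[0]
    cap, allowed = _event_layout(event, spec, N)
    chain, loglik = _prepare(model, y, spec, cap)
    alpha = _dp.forward_alpha(
        loglik, chain.logpi_u, chain.s1, chain.logA_u, chain.inc, chain.S, chain.absorbing
    )
    log_event = float(logsumexp(alpha[-1][allowed]))
    if not np.isfinite(log_event):
        raise InfeasibleEventError(f"event {{{event}}} has zero posterior probability")
    rng = np.random.default_rng(seed)
    uniforms = rng.random((n_samples, N))
    u_paths = _dp.sample_backward(alpha, chain.logA_u, chain.inc, chain.absorbing,
                                  allowed, uniforms)
    return u_paths % model.M + 1


# ---------------------------------------------------------------------------
# event-conditioned marginals (the constrained E-step quantities)
# ---------------------------------------------------------------------------


@dataclass
class ConstrainedMarginals:
    site: np.ndarray  # (N, M) p(x_n | event, y)
    pairwise: np.ndarray  # (N-1, M, M) p(x_{n-1}, x_n | event, y)
    log_xi: np.ndarray  # (M, M) log expected transition counts given the event
    log_event_evidence: float  # log p(event, y)
    log_evidence: float  # log p(y)

    @property
    def log_event_posterior(self) -> float:
        return self.log_event_evidence - self.log_evidence


def constrained_marginals(model: HMMParams, y, spec: CountingSpec,
                          event: SegmentEvent) -> ConstrainedMarginals:
    """Site and pairwise posteriors conditional on the count event, obtained
    by summing the auxiliary counting (and phase) variables out of the
    augmented forward-backward messages."""
    spec = spec.bind(model.M)
    N = np.asarray(y).shape[0]
    cap, allowed = _event_layout(event, spec, N)
    chain, loglik = _prepare(model, y, spec, cap)
    alpha = _dp.forward_alpha(
        loglik, chain.logpi_u, chain.s1, chain.logA_u, chain.inc, chain.S, chain.absorbing
    )
    logz = float(logsumexp(alpha[-1]))
    log_event = float(logsumexp(alpha[-1][allowed]))
    if not np.isfinite(log_event):
        raise InfeasibleEventError(f"event {{{event}}} has zero posterior probability")
    beta = _dp.backward_beta(loglik, chain.logA_u, chain.inc, chain.S,
                             chain.absorbing, allowed)
    P, M = chain.n_phases, model.M
    g = np.exp(alpha + beta - log_event).sum(axis=1)  # (N, U)
    site = g.reshape(N, P, M).sum(axis=1)
    site /= site.sum(axis=1, keepdims=True)
    logxi = _dp.pairwise_logjoint(alpha, beta, loglik, chain.logA_u, chain.inc,
                                  chain.absorbing)
    logxi_m = logsumexp(logxi.reshape(N - 1, P, M, P, M), axis=(1, 3))
    pair = np.exp(logxi_m - log_event)
    pair /= pair.sum(axis=(1, 2), keepdims=True)
    log_xi = logsumexp(logxi_m, axis=0) - log_event
    return ConstrainedMarginals(
        site=site, pairwise=pair, log_xi=log_xi,
        log_event_evidence=log_event, log_evidence=logz,
    )
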