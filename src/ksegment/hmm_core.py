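"""Standard hidden-Markov-model data model and classical recursions.

States are labelled ``1..M`` in all public inputs and outputs (positions are
``1..N``); internally everything is 0-based.  All recursions run in the log
domain with ``-inf`` for zero probability, so sequences of length ~10^6 need
no scaling constants.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from heapq import heappush, heappop

import numpy as np

from . import _dp

logger = logging.getLogger("ksegment")

__all__ = [
    "KsegmentError",
    "InputError",
    "DegenerateEvidenceError",
    "InfeasibleEventError",
    "HMMParams",
    "Segmentation",
    "ForwardBackwardMessages",
    "forward_backward",
    "viterbi",
    "ffbs_sample",
    "best_list_viterbi",
    "em_fit",
]


class KsegmentError(Exception):
    """Base class for package errors."""


class InputError(KsegmentError):
    """Malformed model, observations, or configuration."""


class DegenerateEvidenceError(KsegmentError):
    """The observations have zero likelihood under the model (log p(y) = -inf)."""


class InfeasibleEventError(KsegmentError):
    """No path satisfies the requested segment-count event with nonzero probability."""


def log_safe(p):
    """Elementwise log mapping 0 -> -inf without warnings."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, -np.inf)
    np.log(p, out=out, where=p > 0)
    return out


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------

GAUSSIAN = "gaussian"
CATEGORICAL = "categorical"


@dataclass
class HMMParams:
    """HMM parameters theta = (pi0, A, phi).

    ``emission_params`` holds per-state emission parameters:

    - gaussian: ``{"means": (M,), "variances": (M,)}``
    - categorical: ``{"probs": (M, V)}`` rows over a shared vocabulary 1..V
    """

    M: int
    pi0: np.ndarray
    A: np.ndarray
    emission_family: str
    emission_params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pi0 = np.asarray(self.pi0, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        if self.emission_family == GAUSSIAN:
            self.emission_params = {
                "means": np.asarray(self.emission_params["means"], dtype=float),
                "variances": np.asarray(self.emission_params["variances"], dtype=float),
            }
        elif self.emission_family == CATEGORICAL:
            self.emission_params = {
                "probs": np.asarray(self.emission_params["probs"], dtype=float)
            }
        self.validate()

    def validate(self, atol: float = 1e-9):
        if self.M < 1:
            raise InputError("M must be >= 1")
        if self.pi0.shape != (self.M,):
            raise InputError(f"pi0 must have length M={self.M}")
        if self.A.shape != (self.M, self.M):
            raise InputError(f"A must be {self.M}x{self.M}")
        if np.any(self.pi0 < 0) or np.any(self.A < 0):
            raise InputError("probabilities must be nonnegative")
        if abs(self.pi0.sum() - 1.0) > atol:
            raise InputError(f"pi0 sums to {self.pi0.sum()!r}, not 1")
        rowsum = self.A.sum(axis=1)
        bad = np.where(np.abs(rowsum - 1.0) > atol)[0]
        if bad.size:
            raise InputError(
                f"transition matrix row {bad[0] + 1} sums to {rowsum[bad[0]]!r}, not 1"
            )
        if self.emission_family == GAUSSIAN:
            m = self.emission_params["means"]
            v = self.emission_params["variances"]
            if m.shape != (self.M,) or v.shape != (self.M,):
                raise InputError("gaussian emissions need one mean and variance per state")
            if np.any(v <= 0):
                raise InputError("gaussian variances must be positive")
        elif self.emission_family == CATEGORICAL:
            p = self.emission_params["probs"]
            if p.ndim != 2 or p.shape[0] != self.M:
                raise InputError("categorical emissions need one probability row per state")
            if np.any(p < 0) or np.any(np.abs(p.sum(axis=1) - 1.0) > atol):
                raise InputError("categorical emission rows must be distributions")
        else:
            raise InputError(f"unknown emission family {self.emission_family!r}")
        return self

    @property
    def V(self) -> int:
        if self.emission_family != CATEGORICAL:
            raise InputError("V is defined only for categorical emissions")
        return self.emission_params["probs"].shape[1]

    def log_likelihood_matrix(self, y) -> np.ndarray:
        """Per-position emission log-likelihoods, shape (N, M)."""
        y = validate_observations(y, self)
        if self.emission_family == GAUSSIAN:
            m = self.emission_params["means"]
            v = self.emission_params["variances"]
            return (
                -0.5 * np.log(2 * np.pi * v)[None, :]
                - 0.5 * (y[:, None] - m[None, :]) ** 2 / v[None, :]
            )
        probs = self.emission_params["probs"]
        return log_safe(probs)[:, y.astype(int) - 1].T.copy()

    # JSON schema: {M, pi0, A, emission_family, emission_params}
    def to_dict(self) -> dict:
        d = {
            "M": int(self.M),
            "pi0": self.pi0.tolist(),
            "A": self.A.tolist(),
            "emission_family": self.emission_family,
            "emission_params": {k: v.tolist() for k, v in self.emission_params.items()},
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "HMMParams":
        try:
            return cls(
                M=int(d["M"]),
                pi0=d["pi0"],
                A=d["A"],
                emission_family=d["emission_family"],
                emission_params=d["emission_params"],
            )
        except KeyError as e:
            raise InputError(f"model file missing field {e}") from e

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "HMMParams":
        return cls.from_dict(json.loads(text))


def validate_observations(y, model: HMMParams) -> np.ndarray:
    y = np.asarray(y)
    if y.ndim != 1 or y.shape[0] < 1:
        raise InputError("observations must be a nonempty 1-D sequence")
    if model.emission_family == CATEGORICAL:
        yi = y.astype(int)
        if np.any(yi != y):
            raise InputError("categorical observations must be integer symbol indices")
        if yi.min() < 1 or yi.max() > model.V:
            raise InputError(f"symbols must lie in 1..V={model.V}")
        return yi
    return y.astype(float)


def validate_path(x, M: int | None = None) -> np.ndarray:
    x = np.asarray(x, dtype=int)
    if x.ndim != 1 or x.size < 1:
        raise InputError("state path must be a nonempty 1-D integer sequence")
    if x.min() < 1 or (M is not None and x.max() > M):
        raise InputError("state labels must lie in 1..M")
    return x


# ---------------------------------------------------------------------------
# run-length segmentation container
# ---------------------------------------------------------------------------


@dataclass
class Segmentation:
    """Run-length view of a path: (start, end, state), 1-based inclusive."""

    segments: list  # list of (start, end, state)
    N: int

    @classmethod
    def from_path(cls, x) -> "Segmentation":
        x = validate_path(x)
        change = np.nonzero(np.diff(x))[0]  # last index of each run (0-based)
        starts = np.concatenate(([0], change + 1))
        ends = np.concatenate((change, [x.size - 1]))
        segs = [(int(s) + 1, int(e) + 1, int(x[s])) for s, e in zip(starts, ends)]
        return cls(segments=segs, N=int(x.size))

    def to_path(self) -> np.ndarray:
        x = np.empty(self.N, dtype=int)
        for s, e, m in self.segments:
            x[s - 1 : e] = m
        return x

    def to_bed(self, seqname: str = "seq") -> list:
        """0-based half-open rows (seqname, start, end, state)."""
        return [(seqname, s - 1, e, m) for s, e, m in self.segments]

    @classmethod
    def from_bed(cls, rows) -> "Segmentation":
        segs = [(int(start) + 1, int(end), int(state)) for _, start, end, state in rows]
        return cls(segments=segs, N=segs[-1][1] if segs else 0)

    def __len__(self):
        return len(self.segments)


# ---------------------------------------------------------------------------
# the trivial (counter-free) augmentation used by the standard recursions
# ---------------------------------------------------------------------------


def _trivial_chain(model: HMMParams):
    U = model.M
    logpi = log_safe(model.pi0)
    logA = log_safe(model.A)
    s1 = np.zeros(U, dtype=np.int64)
    inc = np.zeros((U, U), dtype=np.int64)
    return logpi, s1, logA, inc


def _check_evidence(logz: float):
    if not np.isfinite(logz):
        raise DegenerateEvidenceError(
            "observations have zero likelihood under the model (log p(y) = -inf)"
        )


# ---------------------------------------------------------------------------
# classical recursions
# ---------------------------------------------------------------------------


@dataclass
class ForwardBackwardMessages:
    log_alpha: np.ndarray  # (N, M)
    log_beta: np.ndarray  # (N, M)
    log_evidence: float

    def posterior_marginals(self) -> np.ndarray:
        """p(x_n = m | y), shape (N, M); each row sums to 1."""
        g = self.log_alpha + self.log_beta - self.log_evidence
        p = np.exp(g)
        return p / p.sum(axis=1, keepdims=True)


def path_log_joint(model: HMMParams, y, x) -> float:
    """log p(y | x) p(x) for a fixed path (the score Viterbi maximizes)."""
    x = validate_path(x, model.M)
    loglik = model.log_likelihood_matrix(y)
    if x.size != loglik.shape[0]:
        raise InputError("path and observations must have equal length")
    lj = log_safe(model.pi0)[x[0] - 1] + loglik[np.arange(x.size), x - 1].sum()
    if x.size > 1:
        lj += log_safe(model.A)[x[:-1] - 1, x[1:] - 1].sum()
    return float(lj)


def forward_backward(model: HMMParams, y) -> ForwardBackwardMessages:
    """Log-domain forward-backward recursion; returns messages and log p(y)."""
    loglik = model.log_likelihood_matrix(y)
    logpi, s1, logA, inc = _trivial_chain(model)
    term_ok = np.ones(1, dtype=np.bool_)
    alpha = _dp.forward_alpha(loglik, logpi, s1, logA, inc, 1, False)
    beta = _dp.backward_beta(loglik, logA, inc, 1, False, term_ok)
    from scipy.special import logsumexp

    logz = float(logsumexp(alpha[-1, 0, :]))
    _check_evidence(logz)
    return ForwardBackwardMessages(
        log_alpha=alpha[:, 0, :], log_beta=beta[:, 0, :], log_evidence=logz
    )


def viterbi(model: HMMParams, y):
    """MAP path argmax_x p(y|x) p(x) and its log score.

    Ties are broken deterministically toward the smallest state index.
    """
    loglik = model.log_likelihood_matrix(y)
    logpi, s1, logA, inc = _trivial_chain(model)
    final, bp = _dp.viterbi_dp(loglik, logpi, s1, logA, inc, 1, False)
    u = int(np.argmax(final[0]))
    score = float(final[0, u])
    _check_evidence(score)
    path = _dp.backtrack(bp, 0, u) + 1
    return path, score


def ffbs_sample(model: HMMParams, y, n_samples: int, seed: int) -> np.ndarray:
    """i.i.d. draws from p(x | y) by forward filtering, backward sampling.

    Returns an (n_samples, N) integer array of 1-based paths.  Each draw
    consumes its own row of uniforms in position order n = N..1, so the same
    seed reproduces the same stream.
    """
    if n_samples < 1:
        raise InputError("n_samples must be >= 1")
    loglik = model.log_likelihood_matrix(y)
    logpi, s1, logA, inc = _trivial_chain(model)
    alpha = _dp.forward_alpha(loglik, logpi, s1, logA, inc, 1, False)
    from scipy.special import logsumexp

    _check_evidence(float(logsumexp(alpha[-1, 0, :])))
    rng = np.random.default_rng(seed)
    uniforms = rng.random((n_samples, loglik.shape[0]))
    term_ok = np.ones(1, dtype=np.bool_)
    paths = _dp.sample_backward(alpha, logA, inc, False, term_ok, uniforms)
    return paths + 1


# ---------------------------------------------------------------------------
# best-list (top-P) Viterbi via Lawler partitioning
# ---------------------------------------------------------------------------


def _constrained_viterbi(loglik, logpi, logA, prefix, banned):
    """Best path with x[:len(prefix)] forced and x[len(prefix)] not in banned."""
    N, M = loglik.shape
    t = len(prefix)
    delta = np.full(M, -np.inf)
    bps = np.zeros((N, M), dtype=np.int64)
    if t == 0:
        delta = logpi + loglik[0]
        delta[list(banned)] = -np.inf
        start = 1
    else:
        delta[prefix[0]] = logpi[prefix[0]] + loglik[0, prefix[0]]
        start = 1
        for n in range(1, t):
            v = delta[prefix[n - 1]] + logA[prefix[n - 1], prefix[n]] + loglik[n, prefix[n]]
            delta = np.full(M, -np.inf)
            delta[prefix[n]] = v
            start = n + 1
        if t < N:
            nxt = delta[prefix[t - 1]] + logA[prefix[t - 1]] + loglik[t]
            delta = nxt.copy()
            delta[list(banned)] = -np.inf
            start = t + 1
    for n in range(start, N):
        cand = delta[:, None] + logA  # (from, to)
        bps[n] = np.argmax(cand, axis=0)
        delta = cand[bps[n], np.arange(M)] + loglik[n]
    u = int(np.argmax(delta))
    score = float(delta[u])
    path = np.empty(N, dtype=int)
    path[N - 1] = u
    for n in range(N - 1, max(start - 1, 0), -1):
        path[n - 1] = bps[n, path[n]]
    if start > 1:
        path[: start - 1] = prefix[: start - 1] if t else path[: start - 1]
        if t:
            path[:t] = prefix
    return path, score


def best_list_viterbi(model: HMMParams, y, P: int):
    """The P distinct paths with largest posterior probability, best first.

    Exact Lawler-style partitioning on the first point of divergence from
    already-extracted paths; the first element equals the Viterbi path.
    """
    if P < 1:
        raise InputError("P must be >= 1")
    loglik = model.log_likelihood_matrix(y)
    N, M = loglik.shape
    total = M**N if N * np.log(M) < 50 else None
    if total is not None and P > total:
        warnings.warn(f"P={P} exceeds the number of paths {total}; returning all")
        P = total
    logpi = log_safe(model.pi0)
    logA = log_safe(model.A)

    path0, score0 = _constrained_viterbi(loglik, logpi, logA, [], set())
    _check_evidence(score0)
    results = []
    heap = []
    counter = 0
    heappush(heap, (-score0, counter, tuple(path0), 0, frozenset()))
    while heap and len(results) < P:
        nscore, _, path, t0, banned0 = heappop(heap)
        path = np.asarray(path)
        results.append((path + 1, -nscore))
        # children: diverge from this path at t = t0..N-1
        for t in range(t0, N):
            banned = set(banned0) | {int(path[t])} if t == t0 else {int(path[t])}
            prefix = [int(v) for v in path[:t]]
            cpath, cscore = _constrained_viterbi(loglik, logpi, logA, prefix, banned)
            if np.isfinite(cscore):
                counter += 1
                heappush(heap, (-cscore, counter, tuple(cpath), t, frozenset(banned)))
    if len(results) < P:
        warnings.warn(
            f"only {len(results)} paths with nonzero probability exist; returning those"
        )
    return results


# ---------------------------------------------------------------------------
# EM (Baum-Welch)
# ---------------------------------------------------------------------------


def m_step(
    model: HMMParams,
    y: np.ndarray,
    gamma: np.ndarray,
    log_xi: np.ndarray,
    variance_floor_frac: float = 1e-8,
    dirichlet_smoothing: float = 0.0,
    frozen_emission_states=(),
) -> HMMParams:
    """Maximization step shared by unconstrained and constrained EM.

    ``gamma`` are site marginals (N, M); ``log_xi`` holds the log of the
    expected transition counts summed over positions (M, M).  Transition rows
    are renormalized in the log domain, so states with vanishing occupancy
    still get the correct conditional row instead of an underflow artifact.
    ``frozen_emission_states`` lists 1-based states whose emission parameters
    are held fixed.
    """
    from scipy.special import logsumexp

    y = validate_observations(y, model)
    pi0 = gamma[0] + dirichlet_smoothing
    pi0 = pi0 / pi0.sum()
    Aout = model.A.copy()
    if dirichlet_smoothing > 0:
        Anew = np.exp(log_xi) + dirichlet_smoothing
        Aout = Anew / Anew.sum(axis=1, keepdims=True)
    else:
        for m in range(model.M):
            tot = logsumexp(log_xi[m])
            if np.isfinite(tot):
                Aout[m] = np.exp(log_xi[m] - tot)
    occ = gamma.sum(axis=0)
    frozen = {int(m) - 1 for m in frozen_emission_states}
    if model.emission_family == GAUSSIAN:
        means = model.emission_params["means"].copy()
        variances = model.emission_params["variances"].copy()
        floor = max(variance_floor_frac * float(np.var(y)), 1e-12)
        for m in range(model.M):
            if m in frozen or occ[m] <= 0:
                continue
            means[m] = float(gamma[:, m] @ y) / occ[m]
            v = float(gamma[:, m] @ (y - means[m]) ** 2) / occ[m]
            if v < floor:
                logger.warning("variance of state %d floored at %.3g", m + 1, floor)
                v = floor
            variances[m] = v
        params = {"means": means, "variances": variances}
    else:
        probs = model.emission_params["probs"].copy()
        V = probs.shape[1]
        for m in range(model.M):
            if m in frozen or occ[m] <= 0:
                continue
            cnt = np.bincount(y - 1, weights=gamma[:, m], minlength=V) + dirichlet_smoothing
            if cnt.sum() > 0:
                probs[m] = cnt / cnt.sum()
        params = {"probs": probs}
    return HMMParams(model.M, pi0, Aout, model.emission_family, params)


def _e_step(model: HMMParams, y):
    """Unconstrained E-step: (gamma, log expected transition counts, log evidence)."""
    loglik = model.log_likelihood_matrix(y)
    logpi, s1, logA, inc = _trivial_chain(model)
    term_ok = np.ones(1, dtype=np.bool_)
    alpha = _dp.forward_alpha(loglik, logpi, s1, logA, inc, 1, False)
    beta = _dp.backward_beta(loglik, logA, inc, 1, False, term_ok)
    from scipy.special import logsumexp

    logz = float(logsumexp(alpha[-1, 0, :]))
    _check_evidence(logz)
    gamma = np.exp(alpha[:, 0, :] + beta[:, 0, :] - logz)
    gamma /= gamma.sum(axis=1, keepdims=True)
    logxi = _dp.pairwise_logjoint(alpha, beta, loglik, logA, inc, False)
    log_xi = logsumexp(logxi, axis=0) - logz
    return gamma, log_xi, logz


def em_fit(
    init: HMMParams,
    y,
    tol: float = 1e-6,
    max_iter: int = 500,
    variance_floor_frac: float = 1e-8,
    dirichlet_smoothing: float = 0.0,
    frozen_emission_states=(),
):
    """Maximum-likelihood fit by EM (Baum-Welch).

    Stops when the relative change in log p(y) falls below ``tol`` or after
    ``max_iter`` iterations.  Returns (fitted model, log-likelihood trace);
    the trace is nondecreasing up to numerical tolerance.
    """
    model = init
    trace = []
    for _ in range(max_iter):
        gamma, log_xi, logz = _e_step(model, y)
        if trace and abs(logz - trace[-1]) < tol * max(1.0, abs(trace[-1])):
            trace.append(logz)
            break
        trace.append(logz)
        model = m_step(
            model,
            y,
            gamma,
            log_xi,
            variance_floor_frac=variance_floor_frac,
            dirichlet_smoothing=dirichlet_smoothing,
            frozen_emission_states=frozen_emission_states,
        )
    else:
        _, _, logz = _e_step(model, y)
        trace.append(logz)
    return model, np.asarray(trace)
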