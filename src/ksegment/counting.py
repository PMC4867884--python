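"""Auxiliary counting Markov chains.

A counting chain is a deterministic auxiliary process (s, and e for
excursions) unrolled alongside the hidden path that tallies the events of
interest:

- ``standard``: every segment; the counter starts at 1 and increments at each
  transition x_{n-1} != x_n.
- ``generalized``: segments selected by a binary initial-state mask ``mu`` and
  a binary transition-colouring matrix ``C`` (zero diagonal); the counter
  starts at mu(x_1) and increments when C(x_{n-1}, x_n) = 1.
- ``excursion``: completed round trips from a null-state set into abnormal
  states and back; a binary phase variable e flags an open excursion and the
  counter increments on each 1 -> 0 phase drop.
- ``restricted_excursion``: as above, but switching between distinct abnormal
  states mid-excursion is forbidden (those paths get zero probability).

Because the augmentation leaves p(y, x) unaltered, marginalizing the
auxiliary variables out of the augmented joint recovers the original HMM
exactly; ``build_augmented_transition`` produces the arrays the DP kernels
consume, including the absorbing cap used for events {c > k} and for
k_max + 1 summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hmm_core import HMMParams, InputError, log_safe, validate_path

__all__ = [
    "STANDARD",
    "GENERALIZED",
    "EXCURSION",
    "RESTRICTED_EXCURSION",
    "CountingSpec",
    "AugmentedChain",
    "count_segments",
    "generalized_count",
    "count_excursions",
    "count_for_spec",
    "build_augmented_transition",
]

STANDARD = "standard"
GENERALIZED = "generalized"
EXCURSION = "excursion"
RESTRICTED_EXCURSION = "restricted_excursion"
_VARIANTS = (STANDARD, GENERALIZED, EXCURSION, RESTRICTED_EXCURSION)


@dataclass
class CountingSpec:
    """Which segments / transitions / excursions are counted.

    ``mu`` and ``C`` apply to the generalized variant; ``null_states`` (1-based
    labels) to the excursion variants.  The standard variant is the generalized
    one with mu = 1 and C(i, j) = I(i != j).
    """

    variant: str = STANDARD
    mu: np.ndarray | None = None
    C: np.ndarray | None = None
    null_states: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.variant not in _VARIANTS:
            raise InputError(f"unknown counting variant {self.variant!r}")
        if self.mu is not None:
            self.mu = np.asarray(self.mu, dtype=np.int64)
        if self.C is not None:
            self.C = np.asarray(self.C, dtype=np.int64)
        self.null_states = frozenset(int(m) for m in self.null_states)
        if self.variant == GENERALIZED:
            if self.mu is None or self.C is None:
                raise InputError("generalized counting requires mu and C")
            if not np.isin(self.mu, (0, 1)).all() or not np.isin(self.C, (0, 1)).all():
                raise InputError("mu and C must be binary")
            if self.C.ndim != 2 or self.C.shape[0] != self.C.shape[1]:
                raise InputError("C must be square")
            if np.any(np.diag(self.C) != 0):
                raise InputError("C must have a zero diagonal")
            if self.mu.shape[0] != self.C.shape[0]:
                raise InputError("mu and C disagree on the state count")
        elif self.variant in (EXCURSION, RESTRICTED_EXCURSION):
            if self.mu is not None or self.C is not None:
                raise InputError(
                    "excursion counting with a nontrivial (mu, C) is not supported"
                )
            if not self.null_states:
                raise InputError("excursion counting requires a nonempty null-state set")

    def bind(self, M: int) -> "CountingSpec":
        """Validate against a concrete state count and fill standard mu/C."""
        if self.variant == STANDARD:
            mu = np.ones(M, dtype=np.int64)
            C = 1 - np.eye(M, dtype=np.int64)
            return CountingSpec(GENERALIZED, mu, C)
        if self.variant == GENERALIZED:
            if self.mu.shape[0] != M:
                raise InputError(f"mu has length {self.mu.shape[0]}, model has M={M}")
            return self
        bad = [m for m in self.null_states if not 1 <= m <= M]
        if bad:
            raise InputError(f"null states {bad} outside 1..M={M}")
        if len(self.null_states) >= M:
            raise InputError("null-state set must be a proper subset of the states")
        return self

    @property
    def counts_from_zero(self) -> bool:
        """True when the counter can start (and hence end) at zero."""
        if self.variant == STANDARD:
            return False
        if self.variant == GENERALIZED:
            return bool(np.any(self.mu == 0))
        return True

    def to_dict(self) -> dict:
        d = {"variant": self.variant}
        if self.mu is not None:
            d["mu"] = self.mu.tolist()
        if self.C is not None:
            d["C"] = self.C.tolist()
        if self.null_states:
            d["null_states"] = sorted(self.null_states)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CountingSpec":
        return cls(
            variant=d.get("variant", STANDARD),
            mu=d.get("mu"),
            C=d.get("C"),
            null_states=frozenset(d.get("null_states", ())),
        )


# ---------------------------------------------------------------------------
# direct (scan) count functions: the reference semantics for every variant
# ---------------------------------------------------------------------------


def count_segments(x) -> int:
    """Number of maximal constant runs: 1 + #{n : x_{n-1} != x_n}."""
    x = validate_path(x)
    return int(1 + np.count_nonzero(np.diff(x)))


def generalized_count(x, spec: CountingSpec) -> int:
    """mu(x_1) + sum_n C(x_{n-1}, x_n) under a generalized counting spec."""
    x = validate_path(x)
    spec = spec.bind(int(x.max())) if spec.variant == STANDARD else spec
    if spec.variant != GENERALIZED:
        raise InputError("generalized_count requires a standard or generalized spec")
    if x.max() > spec.mu.shape[0]:
        raise InputError("path uses states outside the spec dimension")
    c = int(spec.mu[x[0] - 1])
    if x.size > 1:
        c += int(spec.C[x[:-1] - 1, x[1:] - 1].sum())
    return c


def _unroll_e(x, spec: CountingSpec):
    """Unroll the deterministic excursion-phase chain; returns (e, feasible)."""
    null = spec.null_states
    e = np.zeros(x.size, dtype=np.int64)
    feasible = True
    for n in range(1, x.size):
        prev_null = x[n - 1] in null
        cur_null = x[n] in null
        if prev_null and not cur_null:
            e[n] = 1
        elif not prev_null and cur_null:
            e[n] = 0
        else:
            if (
                spec.variant == RESTRICTED_EXCURSION
                and e[n - 1] == 1
                and not prev_null
                and not cur_null
                and x[n - 1] != x[n]
            ):
                feasible = False  # e would leave {0, 1}
                e[n] = e[n - 1]
            else:
                e[n] = e[n - 1]
    return e, feasible


def count_excursions(x, spec: CountingSpec):
    """(number of completed excursions, feasibility flag).

    An excursion completes on each 1 -> 0 drop of the phase chain; an
    excursion still open at n = N is not counted.  For the restricted variant,
    ``feasible`` is False when the path switches between distinct abnormal
    states mid-excursion (the count is then undefined).
    """
    x = validate_path(x)
    if spec.variant not in (EXCURSION, RESTRICTED_EXCURSION):
        raise InputError("count_excursions requires an excursion spec")
    e, feasible = _unroll_e(x, spec)
    count = int(np.count_nonzero((e[:-1] == 1) & (e[1:] == 0)))
    return count, feasible


def count_for_spec(x, spec: CountingSpec, M: int | None = None):
    """Dispatch to the variant's count function; an infeasible restricted
    excursion yields None."""
    if spec.variant in (EXCURSION, RESTRICTED_EXCURSION):
        c, feasible = count_excursions(x, spec)
        return c if feasible else None
    spec = spec.bind(M if M is not None else int(np.max(x)))
    return generalized_count(x, spec)


# ---------------------------------------------------------------------------
# augmented-chain construction
# ---------------------------------------------------------------------------


@dataclass
class AugmentedChain:
    """Arrays describing the counter-augmented HMM for the DP kernels.

    Extended state u = phase * M + x0 (x0 the 0-based hidden state); counter
    values are 0..S-1 with ``absorbing`` freezing the counter at S-1.
    """

    M: int
    n_phases: int
    logpi_u: np.ndarray  # (U,)
    s1: np.ndarray  # (U,) initial counter value
    logA_u: np.ndarray  # (U, U)
    inc: np.ndarray  # (U, U) binary increments
    S: int
    absorbing: bool
    s_min: int  # smallest achievable count

    @property
    def U(self) -> int:
        return self.n_phases * self.M

    def states_of(self, u_path: np.ndarray) -> np.ndarray:
        """Map extended-state paths back to 1-based hidden states."""
        return u_path % self.M + 1

    def emission_loglik(self, model: HMMParams, y) -> np.ndarray:
        ll = model.log_likelihood_matrix(y)
        return np.tile(ll, (1, self.n_phases)) if self.n_phases > 1 else ll


def build_augmented_transition(
    model: HMMParams,
    spec: CountingSpec,
    cap: int,
    absorbing: bool = True,
) -> AugmentedChain:
    """Build the counting-augmented chain with counter values 0..cap.

    With ``absorbing`` the counter freezes at ``cap`` (events {c > k} and
    k_max + 1 summaries); otherwise ``cap`` must be at least the largest
    achievable count so no probability is truncated.  Marginalizing the
    counter (and phase) out of the augmented joint recovers p(y, x) exactly.
    """
    M = model.M
    spec = spec.bind(M)
    if cap < 0:
        raise InputError("cap must be nonnegative")
    logpi = log_safe(model.pi0)
    logA = log_safe(model.A)
    if spec.variant == GENERALIZED:
        s1 = spec.mu.astype(np.int64).copy()
        inc = spec.C.astype(np.int64).copy()
        chain = AugmentedChain(
            M=M,
            n_phases=1,
            logpi_u=logpi,
            s1=np.minimum(s1, cap),
            logA_u=logA,
            inc=inc,
            S=cap + 1,
            absorbing=absorbing,
            s_min=0 if spec.counts_from_zero else min(1, cap),
        )
        return chain
    # excursion variants: phase e in {0, 1}, u = e * M + x
    null = np.array([m + 1 in spec.null_states for m in range(M)])
    U = 2 * M
    logpi_u = np.full(U, -np.inf)
    logpi_u[:M] = logpi  # e_1 = 0
    s1 = np.zeros(U, dtype=np.int64)
    logA_u = np.full((U, U), -np.inf)
    inc = np.zeros((U, U), dtype=np.int64)
    restricted = spec.variant == RESTRICTED_EXCURSION
    for ep in range(2):
        for xp in range(M):
            for xn in range(M):
                la = logA[xp, xn]
                if la == -np.inf:
                    continue
                if null[xp] and not null[xn]:
                    en = 1
                elif not null[xp] and null[xn]:
                    en = 0
                elif restricted and ep == 1 and not null[xp] and not null[xn] and xp != xn:
                    continue  # e would leave {0, 1}: zero probability
                else:
                    en = ep
                up, un = ep * M + xp, en * M + xn
                logA_u[up, un] = la
                inc[up, un] = 1 if (ep == 1 and en == 0) else 0
    return AugmentedChain(
        M=M,
        n_phases=2,
        logpi_u=logpi_u,
        s1=s1,
        logA_u=logA_u,
        inc=inc,
        S=cap + 1,
        absorbing=absorbing,
        s_min=0,
    )


def unroll_counter(x, spec: CountingSpec, M: int, cap: int | None = None,
                   absorbing: bool = False) -> np.ndarray:
    """Unroll the counting chain along a fixed path (cross-check utility).

    Returns the counter sequence s_1..s_N; with ``absorbing`` the counter
    stops once it reaches ``cap``.
    """
    x = validate_path(x, M)
    spec = spec.bind(M)
    if spec.variant == GENERALIZED:
        s = np.empty(x.size, dtype=np.int64)
        s[0] = spec.mu[x[0] - 1]
        for n in range(1, x.size):
            step = int(spec.C[x[n - 1] - 1, x[n] - 1])
            if absorbing and s[n - 1] >= cap:
                step = 0
            s[n] = s[n - 1] + step
        return s
    e, _ = _unroll_e(x, spec)
    s = np.zeros(x.size, dtype=np.int64)
    for n in range(1, x.size):
        step = 1 if (e[n - 1] == 1 and e[n] == 0) else 0
        if absorbing and s[n - 1] >= cap:
            step = 0
        s[n] = s[n - 1] + step
    return s
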