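"""Synthetic data, the brute-force enumeration oracle, and evaluation statistics.

``SimulationDesign`` defaults to the three-state Gaussian benchmark used
throughout the package's tests: N = 1000, means (-2, -1, 1), sigma = 0.9,
uniform initial distribution and a sticky transition matrix with 0.98
diagonal.  ``enumerate_posterior`` exhaustively scores every one of the M^N
paths of a small instance and is the ground truth for all oracle-equivalence
tests.  The document utilities (overlap ratio, detection rate, add-one topic
estimator, synthetic labelled documents) support the topic-retrieval demo.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import logsumexp

from .counting import (
    CountingSpec,
    count_excursions,
    count_segments,
    generalized_count,
)
from .hmm_core import (
    HMMParams,
    InputError,
    em_fit,
    validate_path,
    viterbi,
)
from .kseg import SegmentEvent, kseg_forward

__all__ = [
    "SimulationDesign",
    "IntervalPair",
    "Document",
    "EnumeratedPosterior",
    "simulate_hmm",
    "simulate_from_model",
    "enumerate_posterior",
    "overlap_ratio",
    "detection_rate",
    "estimate_topic_emissions",
    "synth_documents",
    "document_scores",
    "roc_points",
    "roc_auc",
    "dominates_point",
    "segmental_classification_error",
]

_DEFAULT_A = np.array(
    [
        [0.98, 0.015, 0.005],
        [0.005, 0.98, 0.015],
        [0.015, 0.005, 0.98],
    ]
)


@dataclass
class SimulationDesign:
    """Gaussian-HMM simulation settings (defaults: the three-state benchmark)."""

    M: int = 3
    N: int = 1000
    means: np.ndarray = field(default_factory=lambda: np.array([-2.0, -1.0, 1.0]))
    sigma: float = 0.9
    pi0: np.ndarray | None = None
    A: np.ndarray = field(default_factory=lambda: _DEFAULT_A.copy())
    n_replicates: int = 1

    def model(self) -> HMMParams:
        pi0 = np.full(self.M, 1.0 / self.M) if self.pi0 is None else np.asarray(self.pi0)
        return HMMParams(
            M=self.M,
            pi0=pi0,
            A=self.A,
            emission_family="gaussian",
            emission_params={
                "means": np.asarray(self.means, dtype=float),
                "variances": np.full(self.M, float(self.sigma) ** 2),
            },
        )


def simulate_from_model(model: HMMParams, N: int, seed: int):
    """Draw (path, observations) from an HMM; reproducible per seed."""
    if N < 1:
        raise InputError("N must be >= 1")
    rng = np.random.default_rng(seed)
    x = np.empty(N, dtype=int)
    x[0] = rng.choice(model.M, p=model.pi0)
    for n in range(1, N):
        x[n] = rng.choice(model.M, p=model.A[x[n - 1]])
    if model.emission_family == "gaussian":
        m = model.emission_params["means"]
        v = model.emission_params["variances"]
        y = rng.normal(m[x], np.sqrt(v[x]))
    else:
        probs = model.emission_params["probs"]
        y = np.array([rng.choice(model.V, p=probs[s]) + 1 for s in x])
    return x + 1, y


def simulate_hmm(design: SimulationDesign, seed: int):
    """Draw one (path, observations) replicate from a simulation design."""
    return simulate_from_model(design.model(), design.N, seed)


def informative_init(y, M: int = 3, sticky: float = 10.0 / 12.0) -> HMMParams:
    """Default EM initialization for Gaussian fits.

    Means spread uniformly over [min(y)/2, max(y)/2], variances set large
    (the sample variance), uniform initial distribution, and a sticky
    transition matrix (diagonal ``sticky``, off-diagonal mass shared evenly).
    """
    y = np.asarray(y, dtype=float)
    A = np.full((M, M), (1.0 - sticky) / (M - 1)) if M > 1 else np.ones((1, 1))
    np.fill_diagonal(A, sticky if M > 1 else 1.0)
    return HMMParams(
        M=M,
        pi0=np.full(M, 1.0 / M),
        A=A,
        emission_family="gaussian",
        emission_params={
            "means": np.linspace(y.min() / 2, y.max() / 2, M),
            "variances": np.full(M, max(float(np.var(y)), 1e-6)),
        },
    )


# ---------------------------------------------------------------------------
# brute-force enumeration oracle
# ---------------------------------------------------------------------------


def _all_paths(M: int, N: int) -> np.ndarray:
    """All M^N paths (0-based), lexicographic order, shape (M^N, N)."""
    idx = np.arange(M**N)
    paths = np.empty((M**N, N), dtype=np.int64)
    for n in range(N - 1, -1, -1):
        paths[:, n] = idx % M
        idx //= M
    return paths


@dataclass
class EnumeratedPosterior:
    """Exhaustive path table: the ground truth for small instances."""

    paths: np.ndarray  # (P, N), 1-based
    log_joint: np.ndarray  # log p(y | x) p(x)
    log_evidence: float
    counts: np.ndarray  # count under the bound spec; -1 where undefined
    feasible: np.ndarray  # False only for infeasible restricted excursions
    M: int

    @property
    def posterior(self) -> np.ndarray:
        return np.exp(self.log_joint - self.log_evidence)

    def _mask(self, event: SegmentEvent | None) -> np.ndarray:
        ok = self.feasible.copy()
        if event is not None:
            ok &= np.array([c >= 0 and event.matches(c) for c in self.counts])
        return ok

    def event_log_evidence(self, event: SegmentEvent | None) -> float:
        m = self._mask(event)
        if not m.any():
            return -np.inf
        return float(logsumexp(self.log_joint[m]))

    def count_distribution(self, k_max: int):
        """(probs for k = 0..k_max, tail mass), conditioned on feasible paths."""
        logz = self.event_log_evidence(None)
        probs = np.zeros(k_max + 1)
        tail = 0.0
        w = np.exp(self.log_joint - logz)
        for c, fe, p in zip(self.counts, self.feasible, w):
            if not fe:
                continue
            if c <= k_max:
                probs[c] += p
            else:
                tail += p
        return probs, tail

    def map_under_event(self, event: SegmentEvent | None):
        """(best path, log joint score) among paths satisfying the event."""
        m = self._mask(event)
        if not m.any():
            return None, -np.inf
        scores = np.where(m, self.log_joint, -np.inf)
        best = int(np.argmax(scores))
        if not np.isfinite(scores[best]):
            return None, -np.inf
        return self.paths[best], float(scores[best])

    def marginals_under_event(self, event: SegmentEvent | None):
        """(site (N, M), pairwise (N-1, M, M)) posteriors given the event."""
        m = self._mask(event)
        logze = self.event_log_evidence(event)
        w = np.where(m, np.exp(self.log_joint - logze), 0.0)
        N = self.paths.shape[1]
        site = np.zeros((N, self.M))
        for s in range(self.M):
            site[:, s] = (w[:, None] * (self.paths == s + 1)).sum(axis=0)
        pair = np.zeros((N - 1, self.M, self.M))
        for n in range(1, N):
            for p, wt in zip(self.paths, w):
                if wt:
                    pair[n - 1, p[n - 1] - 1, p[n] - 1] += wt
        return site, pair

    def path_probabilities(self, event: SegmentEvent | None):
        """dict path-tuple -> conditional probability given the event."""
        m = self._mask(event)
        logze = self.event_log_evidence(event)
        return {
            tuple(p): float(np.exp(lj - logze))
            for p, lj, ok in zip(self.paths, self.log_joint, m)
            if ok
        }

    def top_paths(self, P: int):
        """The P most probable paths with scores, best first."""
        order = np.argsort(-self.log_joint, kind="stable")[:P]
        return [(self.paths[i], float(self.log_joint[i])) for i in order]


def enumerate_posterior(model: HMMParams, y, spec: CountingSpec | None = None,
                        cap: int = 60_000) -> EnumeratedPosterior:
    """Score every path of a small instance exhaustively.

    Counts use the direct scan functions, an implementation independent of
    the counting-chain DP they are used to check.  Refuses when M^N > cap.
    """
    from .hmm_core import log_safe

    N = np.asarray(y).shape[0]
    if model.M**N > cap:
        raise InputError(f"M^N = {model.M ** N} exceeds the enumeration cap {cap}")
    loglik = model.log_likelihood_matrix(y)
    logpi = log_safe(model.pi0)
    logA = log_safe(model.A)
    paths = _all_paths(model.M, N)
    lj = logpi[paths[:, 0]] + loglik[np.arange(N)[None, :], paths].sum(axis=1)
    if N > 1:
        lj += logA[paths[:, :-1], paths[:, 1:]].sum(axis=1)
    paths1 = paths + 1
    spec = (spec or CountingSpec()).bind(model.M)
    feasible = np.ones(paths.shape[0], dtype=bool)
    if spec.variant == "generalized":
        counts = spec.mu[paths[:, 0]].astype(np.int64)
        if N > 1:
            counts = counts + spec.C[paths[:, :-1], paths[:, 1:]].sum(axis=1)
    else:
        counts = np.empty(paths.shape[0], dtype=np.int64)
        for i, p in enumerate(paths1):
            c, fe = count_excursions(p, spec)
            counts[i] = c if fe else -1
            feasible[i] = fe
    return EnumeratedPosterior(
        paths=paths1,
        log_joint=lj,
        log_evidence=float(logsumexp(lj)),
        counts=counts,
        feasible=feasible,
        M=model.M,
    )


# ---------------------------------------------------------------------------
# retrieval evaluation statistics
# ---------------------------------------------------------------------------


@dataclass
class IntervalPair:
    """A predicted segment matched with a ground-truth segment, both as
    1-based inclusive (start, end) endpoints."""

    predicted: tuple
    truth: tuple

    def __post_init__(self):
        for name, (lo, hi) in (("predicted", self.predicted), ("truth", self.truth)):
            if lo > hi or lo < 1:
                raise InputError(f"{name} interval ({lo}, {hi}) is malformed")


def overlap_ratio(pair: IntervalPair) -> float:
    """|intersection| / |union| on integer positions, in [0, 1]."""
    (al, ar), (bl, br) = pair.predicted, pair.truth
    inter = max(0, min(ar, br) - max(al, bl) + 1)
    union = (ar - al + 1) + (br - bl + 1) - inter
    return inter / union


def detection_rate(pairs, k: int, threshold: float = 0.8) -> float:
    """Per-document detection rate: (1/k) sum_i I(r_i > threshold).

    ``pairs`` holds the k_p <= k predictions, as IntervalPair objects or as
    precomputed overlap ratios; the denominator is the requested list size k.
    """
    if k < 1:
        raise InputError("k must be >= 1")
    if not 0 < threshold < 1:
        raise InputError("threshold must lie in (0, 1)")
    ratios = [overlap_ratio(p) if isinstance(p, IntervalPair) else float(p) for p in pairs]
    if len(ratios) > k:
        raise InputError(f"{len(ratios)} predictions exceed the list size k={k}")
    return sum(r > threshold for r in ratios) / k


def estimate_topic_emissions(word_counts, V: int) -> np.ndarray:
    """Add-one (uniform-Dirichlet posterior mean) estimator (n_v + 1)/(n + V)."""
    counts = np.asarray(word_counts, dtype=float)
    if counts.shape != (V,):
        raise InputError(f"need exactly V={V} counts, got shape {counts.shape}")
    if np.any(counts < 0):
        raise InputError("counts must be nonnegative")
    return (counts + 1.0) / (counts.sum() + V)


# ---------------------------------------------------------------------------
# synthetic labelled documents
# ---------------------------------------------------------------------------


@dataclass
class Document:
    symbols: np.ndarray  # 1-based symbol indices
    relevant: bool  # ground-truth label
    intervals: list  # inserted relevant segments, 1-based inclusive


def synth_documents(
    relevant_emissions,
    n_docs: int = 100,
    doc_length: int = 200,
    n_segments_range: tuple = (1, 3),
    segment_length_range: tuple = (20, 40),
    irrelevant_emissions=None,
    seed: int = 0,
) -> list:
    """Generate labelled symbol sequences with inserted relevant-topic segments.

    Half the documents (rounded down) are relevant: their background text,
    drawn from a (per-document, Dirichlet-sampled unless given) irrelevant
    word distribution, has 1+ non-overlapping segments of relevant-topic
    symbols spliced in at recorded positions.  Irrelevant documents have zero
    insertions.
    """
    phi_r = np.asarray(relevant_emissions, dtype=float)
    V = phi_r.size
    rng = np.random.default_rng(seed)
    lo_n, hi_n = n_segments_range
    lo_l, hi_l = segment_length_range
    if lo_n < 1 or lo_l < 1 or hi_l > doc_length:
        raise InputError("infeasible insertion counts or lengths")
    docs = []
    for d in range(n_docs):
        relevant = d < n_docs // 2
        if irrelevant_emissions is None:
            phi_d = rng.dirichlet(np.ones(V))
        else:
            phi_d = np.asarray(irrelevant_emissions, dtype=float)
        symbols = rng.choice(V, size=doc_length, p=phi_d) + 1
        intervals = []
        if relevant:
            n_seg = int(rng.integers(lo_n, hi_n + 1))
            for _ in range(n_seg):
                for _attempt in range(100):
                    L = int(rng.integers(lo_l, min(hi_l, doc_length) + 1))
                    start = int(rng.integers(1, doc_length - L + 2))
                    span = (start, start + L - 1)
                    if all(span[1] < s - 1 or span[0] > e + 1 for s, e in intervals):
                        break
                else:
                    continue
                symbols[span[0] - 1 : span[1]] = rng.choice(V, size=L, p=phi_r) + 1
                intervals.append(span)
            intervals.sort()
        docs.append(Document(symbols=symbols, relevant=relevant, intervals=intervals))
    return docs


def document_scores(
    docs,
    relevant_emissions,
    sticky: float = 0.95,
    em_max_iter: int = 30,
) -> dict:
    """Per-document relevance scores for the classification demo.

    Fits each document's irrelevant-topic emissions (state 2) by EM with the
    relevant-topic row (state 1) held fixed, then scores the document by
    p(c > 0 | y) where the counter tallies relevant-topic segments only
    (mu = [1, 0], C = [[0, 0], [1, 0]]), and records whether the Viterbi path
    contains the relevant topic at all.
    """
    phi_r = np.asarray(relevant_emissions, dtype=float)
    V = phi_r.size
    spec = CountingSpec(
        variant="generalized", mu=np.array([1, 0]), C=np.array([[0, 0], [1, 0]])
    )
    scores, viterbi_hits, labels = [], [], []
    for doc in docs:
        init = HMMParams(
            M=2,
            pi0=np.array([0.5, 0.5]),
            A=np.array([[sticky, 1 - sticky], [1 - sticky, sticky]]),
            emission_family="categorical",
            emission_params={"probs": np.vstack([phi_r, np.full(V, 1.0 / V)])},
        )
        model, _ = em_fit(
            init, doc.symbols, max_iter=em_max_iter,
            dirichlet_smoothing=1.0, frozen_emission_states=(1,),
        )
        post = kseg_forward(model, doc.symbols, spec, k_max=1)
        scores.append(1.0 - post.p(0))
        path, _ = viterbi(model, doc.symbols)
        viterbi_hits.append(bool(np.any(path == 1)))
        labels.append(doc.relevant)
    return {
        "score": np.asarray(scores),
        "viterbi_hit": np.asarray(viterbi_hits),
        "label": np.asarray(labels),
    }


# ---------------------------------------------------------------------------
# ROC and classification-error helpers
# ---------------------------------------------------------------------------


def roc_points(scores, labels):
    """(fpr, tpr) arrays swept over all thresholds, monotone in fpr."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    order = np.argsort(-scores, kind="stable")
    tp = np.concatenate(([0], np.cumsum(labels[order])))
    fp = np.concatenate(([0], np.cumsum(~labels[order])))
    tpr = tp / max(labels.sum(), 1)
    fpr = fp / max((~labels).sum(), 1)
    return fpr, tpr


def roc_auc(scores, labels) -> float:
    fpr, tpr = roc_points(scores, labels)
    return float(np.trapezoid(tpr, fpr))


def dominates_point(scores, labels, point_fpr: float, point_tpr: float,
                    tol: float = 1e-12) -> bool:
    """True when some threshold achieves tpr >= point_tpr and fpr <= point_fpr."""
    fpr, tpr = roc_points(scores, labels)
    ok = (fpr <= point_fpr + tol) & (tpr >= point_tpr - tol)
    return bool(ok.any())


def segmental_classification_error(true_path, est_path, M: int) -> float:
    """Per-site error after optimal one-to-one state relabelling.

    Fitted state labels are arbitrary; the error is reported after matching
    estimated to true states with the assignment that maximizes agreement.
    """
    t = validate_path(true_path, M)
    e = validate_path(est_path, M)
    if t.size != e.size:
        raise InputError("paths must have equal length")
    conf = np.zeros((M, M))
    np.add.at(conf, (t - 1, e - 1), 1.0)
    rows, cols = linear_sum_assignment(-conf)
    return 1.0 - conf[rows, cols].sum() / t.size
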