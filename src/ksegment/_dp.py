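"""Log-domain dynamic-programming kernels on the counter-augmented state space.

Every recursion in the package (standard and constrained forward/backward,
Viterbi, backward sampling, pairwise posterior statistics) runs on one shared
representation: an extended hidden state ``u`` (phase * M + emission state),
a counter taking values ``0..S-1`` and a binary increment matrix ``inc`` that
says which extended-state transitions advance the counter.  When ``absorbing``
is true the counter freezes at its top value ``S-1``; otherwise ``S-1`` must
bound the largest achievable count so that no probability mass is truncated.

All kernels work in natural-log space with ``-inf`` encoding zero probability.
"""

import numpy as np
from numba import njit

NEG_INF = -np.inf


@njit(cache=True, inline="always")
def _lae(a, b):
    # logaddexp with explicit -inf handling
    if a == NEG_INF:
        return b
    if b == NEG_INF:
        return a
    if a < b:
        a, b = b, a
    return a + np.log1p(np.exp(b - a))


@njit(cache=True)
def forward_alpha(loglik, logpi, s1, logA, inc, S, absorbing):
    """Full forward pass; returns alpha[n, s, u] = log p(y_1..n, u_n=u, s_n=s)."""
    N, U = loglik.shape
    alpha = np.full((N, S, U), NEG_INF)
    for u in range(U):
        if logpi[u] > NEG_INF:
            alpha[0, s1[u], u] = logpi[u] + loglik[0, u]
    for n in range(1, N):
        for s in range(S):
            for u in range(U):
                acc = NEG_INF
                for up in range(U):
                    la = logA[up, u]
                    if la == NEG_INF:
                        continue
                    ic = inc[up, u]
                    sp = s - ic
                    if sp >= 0:
                        a = alpha[n - 1, sp, up]
                        if a > NEG_INF:
                            acc = _lae(acc, a + la)
                    if absorbing and ic == 1 and s == S - 1:
                        # counter already absorbed: increment suppressed
                        a = alpha[n - 1, S - 1, up]
                        if a > NEG_INF:
                            acc = _lae(acc, a + la)
                alpha[n, s, u] = acc + loglik[n, u]
    return alpha


@njit(cache=True)
def forward_final(loglik, logpi, s1, logA, inc, S, absorbing):
    """Memory-light forward pass returning only the final slice alpha[N-1]."""
    N, U = loglik.shape
    prev = np.full((S, U), NEG_INF)
    cur = np.full((S, U), NEG_INF)
    for u in range(U):
        if logpi[u] > NEG_INF:
            prev[s1[u], u] = logpi[u] + loglik[0, u]
    for n in range(1, N):
        for s in range(S):
            for u in range(U):
                acc = NEG_INF
                for up in range(U):
                    la = logA[up, u]
                    if la == NEG_INF:
                        continue
                    ic = inc[up, u]
                    sp = s - ic
                    if sp >= 0:
                        a = prev[sp, up]
                        if a > NEG_INF:
                            acc = _lae(acc, a + la)
                    if absorbing and ic == 1 and s == S - 1:
                        a = prev[S - 1, up]
                        if a > NEG_INF:
                            acc = _lae(acc, a + la)
                cur[s, u] = acc + loglik[n, u]
        tmp = prev
        prev = cur
        cur = tmp
    return prev.copy()


@njit(cache=True)
def backward_beta(loglik, logA, inc, S, absorbing, term_ok):
    """Backward pass conditioned on the terminal counter lying in ``term_ok``.

    beta[n, s, u] = log p(y_{n+1..N}, s_N in allowed set | u_n=u, s_n=s).
    """
    N, U = loglik.shape
    beta = np.full((N, S, U), NEG_INF)
    for s in range(S):
        if term_ok[s]:
            for u in range(U):
                beta[N - 1, s, u] = 0.0
    for n in range(N - 1, 0, -1):
        for sp in range(S):
            for up in range(U):
                acc = NEG_INF
                for u in range(U):
                    la = logA[up, u]
                    if la == NEG_INF:
                        continue
                    if absorbing and sp == S - 1:
                        t = S - 1
                    else:
                        t = sp + inc[up, u]
                        if t > S - 1:
                            continue
                    b = beta[n, t, u]
                    if b > NEG_INF:
                        acc = _lae(acc, la + loglik[n, u] + b)
                beta[n - 1, sp, up] = acc
    return beta


@njit(cache=True)
def viterbi_dp(loglik, logpi, s1, logA, inc, S, absorbing):
    """Max-product pass.  Returns (final delta slice (S,U), backpointers).

    Backpointer code at (n, s, u) packs ``ds * U + up`` where ``ds`` is the
    counter decrement (0 or 1) and ``up`` the predecessor extended state.
    Ties are broken toward the smaller predecessor counter value, then the
    smaller predecessor state index (first strict improvement wins).
    """
    N, U = loglik.shape
    prev = np.full((S, U), NEG_INF)
    cur = np.full((S, U), NEG_INF)
    bp = np.full((N, S, U), -1, np.int16)
    for u in range(U):
        if logpi[u] > NEG_INF:
            prev[s1[u], u] = logpi[u] + loglik[0, u]
    for n in range(1, N):
        for s in range(S):
            for u in range(U):
                best = NEG_INF
                code = -1
                for ds in range(1, -1, -1):
                    sp = s - ds
                    if sp < 0:
                        continue
                    for up in range(U):
                        la = logA[up, u]
                        if la == NEG_INF:
                            continue
                        ic = inc[up, u]
                        valid = ic == ds
                        if not valid and absorbing and s == S - 1 and ic == 1 and ds == 0:
                            valid = True  # absorbed self-loop of the counter
                        if not valid:
                            continue
                        v = prev[sp, up] + la
                        if v > best:
                            best = v
                            code = ds * U + up
                cur[s, u] = best + loglik[n, u]
                bp[n, s, u] = code
        tmp = prev
        prev = cur
        cur = tmp
    return prev.copy(), bp


@njit(cache=True)
def backtrack(bp, s_term, u_term):
    """Recover the extended-state sequence ending at (s_term, u_term)."""
    N = bp.shape[0]
    U = bp.shape[2]
    path = np.empty(N, np.int64)
    s = s_term
    u = u_term
    path[N - 1] = u
    for n in range(N - 1, 0, -1):
        code = bp[n, s, u]
        ds = code // U
        up = code % U
        s = s - ds
        u = up
        path[n - 1] = u
    return path


@njit(cache=True)
def sample_backward(alpha, logA, inc, absorbing, term_ok, uniforms):
    """Draw paths from the event-conditioned posterior by backward sampling.

    ``uniforms`` has shape (n_samples, N); sample i consumes its own row in
    position order n = N..1, so streams are reproducible draw by draw.
    Returns extended-state paths of shape (n_samples, N).
    """
    n_samples, N = uniforms.shape
    S, U = alpha.shape[1], alpha.shape[2]
    out = np.empty((n_samples, N), np.int64)

    # terminal distribution over (s, u) restricted to allowed counter values
    K = S * U
    w = np.full(K, NEG_INF)
    for s in range(S):
        if term_ok[s]:
            for u in range(U):
                w[s * U + u] = alpha[N - 1, s, u]
    mx = w.max()
    p = np.exp(w - mx)
    p /= p.sum()
    cdf = np.cumsum(p)

    wl = np.empty(2 * U)
    for i in range(n_samples):
        r = uniforms[i, N - 1]
        idx = 0
        while idx < K - 1 and cdf[idx] <= r:
            idx += 1
        s = idx // U
        u = idx % U
        out[i, N - 1] = u
        for n in range(N - 1, 0, -1):
            for j in range(2 * U):
                wl[j] = NEG_INF
            for ds in range(2):
                sp = s - ds
                if sp < 0:
                    continue
                for up in range(U):
                    la = logA[up, u]
                    if la == NEG_INF:
                        continue
                    ic = inc[up, u]
                    ok = ic == ds
                    if not ok and absorbing and s == S - 1 and ic == 1 and ds == 0:
                        ok = True
                    if ok:
                        v = alpha[n - 1, sp, up] + la
                        if v > wl[ds * U + up]:
                            wl[ds * U + up] = v
            mx2 = wl.max()
            tot = 0.0
            for j in range(2 * U):
                tot += np.exp(wl[j] - mx2)
            r = uniforms[i, n - 1]
            acc = 0.0
            idx2 = 2 * U - 1
            for j in range(2 * U):
                acc += np.exp(wl[j] - mx2) / tot
                if acc > r:
                    idx2 = j
                    break
            ds = idx2 // U
            up = idx2 % U
            s = s - ds
            u = up
            out[i, n - 1] = u
    return out


@njit(cache=True)
def pairwise_logjoint(alpha, beta, loglik, logA, inc, absorbing):
    """log p(u_{n-1}=up, u_n=u, event, y) for n = 2..N, shape (N-1, U, U)."""
    N, S, U = alpha.shape
    out = np.full((N - 1, U, U), NEG_INF)
    for n in range(1, N):
        for up in range(U):
            for u in range(U):
                la = logA[up, u]
                if la == NEG_INF:
                    continue
                ic = inc[up, u]
                acc = NEG_INF
                for sp in range(S):
                    if absorbing and sp == S - 1:
                        t = S - 1
                    else:
                        t = sp + ic
                        if t > S - 1:
                            continue
                    a = alpha[n - 1, sp, up]
                    if a == NEG_INF:
                        continue
                    b = beta[n, t, u]
                    if b == NEG_INF:
                        continue
                    acc = _lae(acc, a + la + loglik[n, u] + b)
                out[n - 1, up, u] = acc
    return out
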