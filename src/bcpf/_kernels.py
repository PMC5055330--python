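"""Numba kernels for the triad-revision / opinion-update inner loops.

These mirror the reference (pure-Python) dynamics exactly in semantics; they
exist so that ensemble experiments with hundreds of runs at N ~ 40-100 stay
fast.  All randomness inside the kernels comes from numba's global NumPy
legacy RNG, which the caller seeds once per run via :func:`seed_kernel`;
results are therefore bit-reproducible for a fixed seed and call sequence.

Branch codes for flip bookkeeping (shared with :mod:`bcpf.dynamics`):
0 smallest-delta, 1 largest-delta, 2 negative-to-positive, 3 random,
4 rejected-by-constraint.
"""

import numpy as np
from numba import njit

BRANCH_SMALLEST = 0
BRANCH_LARGEST = 1
BRANCH_NEG_TO_POS = 2
BRANCH_RANDOM = 3
BRANCH_REJECTED = 4


@njit(cache=True)
def seed_kernel(seed):
    np.random.seed(seed)


@njit(cache=True)
def _pair_dist(x, a, b, metric):
    # metric: 0 = chebyshev (max per-issue gap), 1 = euclidean
    if metric == 0:
        m = 0.0
        for f in range(x.shape[1]):
            d = abs(x[a, f] - x[b, f])
            if d > m:
                m = d
        return m
    s = 0.0
    for f in range(x.shape[1]):
        d = x[a, f] - x[b, f]
        s += d * d
    return np.sqrt(s)


@njit(cache=True)
def _pair_unbalanced(signs, a, b):
    n = signs.shape[0]
    u = 0
    sab = signs[a, b]
    for m in range(n):
        if m != a and m != b:
            if sab * signs[a, m] * signs[b, m] == -1:
                u += 1
    return u


@njit(cache=True)
def _apply_flip(signs, a, b, unbal):
    """Flip pair (a, b); return the updated unbalanced-triad count."""
    n = signs.shape[0]
    u = _pair_unbalanced(signs, a, b)
    signs[a, b] = -signs[a, b]
    signs[b, a] = signs[a, b]
    return unbal + (n - 2) - 2 * u


@njit(cache=True)
def _update_opinion(signs, x, a, eps, metric):
    """Bounded-confidence revision of agent a: mean over self plus friends
    within eps, issue by issue, using the current state (asynchronous)."""
    n, nf = x.shape
    acc = np.zeros(nf)
    for f in range(nf):
        acc[f] = x[a, f]
    cnt = 1
    for j in range(n):
        if j != a and signs[a, j] == 1 and _pair_dist(x, a, j, metric) <= eps:
            for f in range(nf):
                acc[f] += x[j, f]
            cnt += 1
    for f in range(nf):
        x[a, f] = acc[f] / cnt


@njit(cache=True)
def advance(signs, x, unbal, t0, n_steps, p, eps, metric, rule,
            period, stochastic, q, branch_counts):
    """Run ``n_steps`` triad-revision steps (plus scheduled opinion updates).

    Mutates ``signs``, ``x`` and ``branch_counts`` in place.  Returns
    ``(t, unbal, t_balance, flips)`` with ``t_balance`` the absolute step at
    which the unbalanced count first reached zero during this call (-1 if it
    did not).
    """
    n = signs.shape[0]
    t = t0
    t_balance = -1
    flips = 0
    ia = np.empty(3, np.int64)
    ib = np.empty(3, np.int64)
    cand = np.empty(3, np.int64)
    for _ in range(n_steps):
        t += 1
        # uniform canonical triad via three distinct draws
        i = np.random.randint(0, n)
        j = np.random.randint(0, n)
        while j == i:
            j = np.random.randint(0, n)
        k = np.random.randint(0, n)
        while k == i or k == j:
            k = np.random.randint(0, n)
        prod = signs[i, j] * signs[i, k] * signs[j, k]
        if prod == -1:
            ia[0], ib[0] = i, j
            ia[1], ib[1] = i, k
            ia[2], ib[2] = j, k
            n_neg = 0
            for q3 in range(3):
                if signs[ia[q3], ib[q3]] == -1:
                    n_neg += 1
            sel = -1
            branch = -1
            if rule == 0:  # preferential
                if n_neg == 3:
                    best = 2.0
                    m = 0
                    for q3 in range(3):
                        d = _pair_dist(x, ia[q3], ib[q3], metric)
                        if d < best:
                            best = d
                            cand[0] = q3
                            m = 1
                        elif d == best:
                            cand[m] = q3
                            m += 1
                    sel = cand[np.random.randint(0, m)] if m > 1 else cand[0]
                    branch = BRANCH_SMALLEST
                else:  # (-++)
                    if np.random.random() < p:
                        for q3 in range(3):
                            if signs[ia[q3], ib[q3]] == -1:
                                sel = q3
                        branch = BRANCH_NEG_TO_POS
                    else:
                        best = -1.0
                        m = 0
                        for q3 in range(3):
                            if signs[ia[q3], ib[q3]] == 1:
                                d = _pair_dist(x, ia[q3], ib[q3], metric)
                                if d > best:
                                    best = d
                                    cand[0] = q3
                                    m = 1
                                elif d == best:
                                    cand[m] = q3
                                    m += 1
                        sel = cand[np.random.randint(0, m)] if m > 1 else cand[0]
                        branch = BRANCH_LARGEST
            else:  # random (LTD) candidate; constrained (CTD) filters it
                if n_neg == 3:
                    sel = np.random.randint(0, 3)
                    branch = BRANCH_RANDOM
                else:
                    if np.random.random() < p:
                        for q3 in range(3):
                            if signs[ia[q3], ib[q3]] == -1:
                                sel = q3
                        branch = BRANCH_NEG_TO_POS
                    else:
                        m = 0
                        for q3 in range(3):
                            if signs[ia[q3], ib[q3]] == 1:
                                cand[m] = q3
                                m += 1
                        sel = cand[np.random.randint(0, m)]
                        branch = BRANCH_RANDOM
                if rule == 2:  # CTD admissibility
                    u = _pair_unbalanced(signs, ia[sel], ib[sel])
                    if (n - 2) - 2 * u > 0:
                        sel = -1
                        branch = BRANCH_REJECTED
            if sel >= 0:
                unbal = _apply_flip(signs, ia[sel], ib[sel], unbal)
                flips += 1
                branch_counts[branch] += 1
                if unbal == 0 and t_balance < 0:
                    t_balance = t
            else:
                branch_counts[BRANCH_REJECTED] += 1
        # scheduled opinion revision
        if stochastic == 1:
            if np.random.random() < q:
                _update_opinion(signs, x, np.random.randint(0, n), eps, metric)
        elif t % period == 0:
            _update_opinion(signs, x, np.random.randint(0, n), eps, metric)
    return t, unbal, t_balance, flips


@njit(cache=True)
def opinion_round(signs, x, eps, metric):
    """One round of opinion relaxation: N i.i.d. uniform single-agent
    revisions (the network is not touched)."""
    n = x.shape[0]
    for _ in range(n):
        _update_opinion(signs, x, np.random.randint(0, n), eps, metric)


@njit(cache=True)
def fp_residual(signs, x, eps, metric):
    """Synchronous fixed-point residual: the largest per-component change any
    single agent's revision would produce right now.  Zero exactly at the
    fixed points of the asynchronous dynamics; does not mutate the state."""
    n, nf = x.shape
    acc = np.empty(nf)
    mx = 0.0
    for a in range(n):
        for f in range(nf):
            acc[f] = x[a, f]
        cnt = 1
        for j in range(n):
            if j != a and signs[a, j] == 1 and _pair_dist(x, a, j, metric) <= eps:
                for f in range(nf):
                    acc[f] += x[j, f]
                cnt += 1
        for f in range(nf):
            r = abs(acc[f] / cnt - x[a, f])
            if r > mx:
                mx = r
    return mx
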