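"""JIT-compiled inner loops of the SLDS blocked Gibbs sampler.

Hand-rolled 2x2 linear algebra: the latent state is a 2D position, so
Kalman filtering/sampling and the HMM forward-filter backward-sample pass
reduce to scalar arithmetic.  All randomness enters through pre-drawn
normal/uniform arrays so the single numpy Generator upstream controls
determinism.  A pure-python fallback is selected automatically when numba
is unavailable.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is a hard dependency in practice
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@njit(cache=False)
def _chol2(c00, c01, c11):
    l00 = np.sqrt(c00)
    l10 = c01 / l00
    l11 = np.sqrt(max(c11 - l10 * l10, 1e-300))
    return l00, l10, l11


@njit(cache=False)
def kalman_ffbs(y, r_var, s, A, b, Q, zn):
    """Sample the latent positions z given labels and parameters.

    y: (T,2) observations; r_var: (T,) per-frame observation variance;
    s: (T-1,) state of each transition t->t+1; A,b,Q: per-state dynamics;
    zn: (T,2) standard normals.  Returns z: (T,2).
    """
    T = y.shape[0]
    m = np.empty((T, 2))
    P = np.empty((T, 3))  # packed symmetric (p00, p01, p11)
    # init: prior N(y0, r0 I) updated with y0 -> posterior N(y0, r0/2 I)
    m[0, 0] = y[0, 0]
    m[0, 1] = y[0, 1]
    P[0, 0] = r_var[0] * 0.5
    P[0, 1] = 0.0
    P[0, 2] = r_var[0] * 0.5

    for t in range(1, T):
        k = s[t - 1]
        a00, a01, a10, a11 = A[k, 0, 0], A[k, 0, 1], A[k, 1, 0], A[k, 1, 1]
        # predict mean
        mp0 = a00 * m[t - 1, 0] + a01 * m[t - 1, 1] + b[k, 0]
        mp1 = a10 * m[t - 1, 0] + a11 * m[t - 1, 1] + b[k, 1]
        # predict cov: A P A' + Q
        p00, p01, p11 = P[t - 1, 0], P[t - 1, 1], P[t - 1, 2]
        t00 = a00 * p00 + a01 * p01
        t01 = a00 * p01 + a01 * p11
        t10 = a10 * p00 + a11 * p01
        t11 = a10 * p01 + a11 * p11
        pp00 = t00 * a00 + t01 * a01 + Q[k, 0, 0]
        pp01 = t00 * a10 + t01 * a11 + Q[k, 0, 1]
        pp11 = t10 * a10 + t11 * a11 + Q[k, 1, 1]
        # update with y_t, R = r I
        r = r_var[t]
        s00 = pp00 + r
        s01 = pp01
        s11 = pp11 + r
        det = s00 * s11 - s01 * s01
        i00 = s11 / det
        i01 = -s01 / det
        i11 = s00 / det
        # K = P_pred S^-1
        k00 = pp00 * i00 + pp01 * i01
        k01 = pp00 * i01 + pp01 * i11
        k10 = pp01 * i00 + pp11 * i01
        k11 = pp01 * i01 + pp11 * i11
        inn0 = y[t, 0] - mp0
        inn1 = y[t, 1] - mp1
        m[t, 0] = mp0 + k00 * inn0 + k01 * inn1
        m[t, 1] = mp1 + k10 * inn0 + k11 * inn1
        # P = (I - K) P_pred (Joseph's simple form; symmetric enough here)
        P[t, 0] = (1.0 - k00) * pp00 - k01 * pp01
        P[t, 1] = (1.0 - k00) * pp01 - k01 * pp11
        P[t, 2] = -k10 * pp01 + (1.0 - k11) * pp11

    z = np.empty((T, 2))
    # sample z_{T-1}
    l00, l10, l11 = _chol2(max(P[T - 1, 0], 1e-300), P[T - 1, 1], P[T - 1, 2])
    z[T - 1, 0] = m[T - 1, 0] + l00 * zn[T - 1, 0]
    z[T - 1, 1] = m[T - 1, 1] + l10 * zn[T - 1, 0] + l11 * zn[T - 1, 1]
    for t in range(T - 2, -1, -1):
        k = s[t]
        a00, a01, a10, a11 = A[k, 0, 0], A[k, 0, 1], A[k, 1, 0], A[k, 1, 1]
        p00, p01, p11 = P[t, 0], P[t, 1], P[t, 2]
        # S = A P A' + Q
        t00 = a00 * p00 + a01 * p01
        t01 = a00 * p01 + a01 * p11
        t10 = a10 * p00 + a11 * p01
        t11 = a10 * p01 + a11 * p11
        s00 = t00 * a00 + t01 * a01 + Q[k, 0, 0]
        s01 = t00 * a10 + t01 * a11 + Q[k, 0, 1]
        s11 = t10 * a10 + t11 * a11 + Q[k, 1, 1]
        det = s00 * s11 - s01 * s01
        i00 = s11 / det
        i01 = -s01 / det
        i11 = s00 / det
        # G = P A' S^-1 ; note (P A')_ij = sum_l P_il A_jl
        pa00 = p00 * a00 + p01 * a01
        pa01 = p00 * a10 + p01 * a11
        pa10 = p01 * a00 + p11 * a01
        pa11 = p01 * a10 + p11 * a11
        g00 = pa00 * i00 + pa01 * i01
        g01 = pa00 * i01 + pa01 * i11
        g10 = pa10 * i00 + pa11 * i01
        g11 = pa10 * i01 + pa11 * i11
        # predicted mean of z_{t+1} given m_t
        mp0 = a00 * m[t, 0] + a01 * m[t, 1] + b[k, 0]
        mp1 = a10 * m[t, 0] + a11 * m[t, 1] + b[k, 1]
        inn0 = z[t + 1, 0] - mp0
        inn1 = z[t + 1, 1] - mp1
        mu0 = m[t, 0] + g00 * inn0 + g01 * inn1
        mu1 = m[t, 1] + g10 * inn0 + g11 * inn1
        # cov = P - G (A P) ; (A P)_ij = pa_ji
        c00 = p00 - (g00 * pa00 + g01 * pa01)
        c01 = p01 - (g00 * pa10 + g01 * pa11)
        c11 = p11 - (g10 * pa10 + g11 * pa11)
        l00, l10, l11 = _chol2(max(c00, 1e-300), c01, max(c11, 1e-300))
        z[t, 0] = mu0 + l00 * zn[t, 0]
        z[t, 1] = mu1 + l10 * zn[t, 0] + l11 * zn[t, 1]
    return z


@njit(cache=False)
def hmm_ffbs(z, A, b, Qi, Qld, log_pi, log_pi0, u):
    """Sample the per-transition state sequence given latent positions.

    z: (T,2); Qi: (L,3) packed inverse covariances; Qld: (L,) log-dets;
    log_pi: (L,L) log transition matrix; u: (T-1,) uniforms.
    Returns s: (T-1,) int64.
    """
    T = z.shape[0]
    L = log_pi.shape[0]
    n = T - 1
    # emission log-likelihoods
    ll = np.empty((n, L))
    for t in range(n):
        for k in range(L):
            e0 = z[t + 1, 0] - (A[k, 0, 0] * z[t, 0] + A[k, 0, 1] * z[t, 1] + b[k, 0])
            e1 = z[t + 1, 1] - (A[k, 1, 0] * z[t, 0] + A[k, 1, 1] * z[t, 1] + b[k, 1])
            q = e0 * e0 * Qi[k, 0] + 2.0 * e0 * e1 * Qi[k, 1] + e1 * e1 * Qi[k, 2]
            ll[t, k] = -0.5 * (q + Qld[k]) - 1.8378770664093453  # log(2*pi)
    # forward pass (log space, normalized)
    alpha = np.empty((n, L))
    for k in range(L):
        alpha[0, k] = log_pi0[k] + ll[0, k]
    mx = alpha[0].max()
    norm = 0.0
    for k in range(L):
        norm += np.exp(alpha[0, k] - mx)
    norm = mx + np.log(norm)
    for k in range(L):
        alpha[0, k] -= norm
    for t in range(1, n):
        for k in range(L):
            mx = -1e308
            for j in range(L):
                v = alpha[t - 1, j] + log_pi[j, k]
                if v > mx:
                    mx = v
            acc = 0.0
            for j in range(L):
                acc += np.exp(alpha[t - 1, j] + log_pi[j, k] - mx)
            alpha[t, k] = mx + np.log(acc) + ll[t, k]
        mx = alpha[t].max()
        acc = 0.0
        for k in range(L):
            acc += np.exp(alpha[t, k] - mx)
        nrm = mx + np.log(acc)
        for k in range(L):
            alpha[t, k] -= nrm
    # backward sampling
    s = np.empty(n, dtype=np.int64)
    p = np.empty(L)
    mx = alpha[n - 1].max()
    tot = 0.0
    for k in range(L):
        p[k] = np.exp(alpha[n - 1, k] - mx)
        tot += p[k]
    r = u[n - 1] * tot
    acc = 0.0
    s[n - 1] = L - 1
    for k in range(L):
        acc += p[k]
        if r <= acc:
            s[n - 1] = k
            break
    for t in range(n - 2, -1, -1):
        mx = -1e308
        for k in range(L):
            v = alpha[t, k] + log_pi[k, s[t + 1]]
            if v > mx:
                mx = v
        tot = 0.0
        for k in range(L):
            p[k] = np.exp(alpha[t, k] + log_pi[k, s[t + 1]] - mx)
            tot += p[k]
        r = u[t] * tot
        acc = 0.0
        s[t] = L - 1
        for k in range(L):
            acc += p[k]
            if r <= acc:
                s[t] = k
                break
    return s
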