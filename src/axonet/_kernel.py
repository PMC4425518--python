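"""Compiled inner loop for the implicit network integrator.

The time loop advances gate variables with table-interpolated steady
states and relaxation factors (rebuilt per run for the chosen dt), then
solves the tridiagonal-plus-low-rank implicit voltage system with a
Thomas factorisation and the Woodbury identity for the gap-junction
coupling.  A pure-python fallback with identical semantics lives in
:mod:`axonet.solver`; the two are cross-checked in the test suite.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if len(args) == 1 and callable(args[0]):
            return args[0]

        def deco(f):
            return f

        return deco


@njit(cache=True)
def run_active(
    V,
    X,
    v0,
    dvinv,
    xinf_tab,
    decay_tab,
    fghk_tab,
    g_na,
    g_kf,
    g_ks,
    leak,
    c_ca,
    e_na,
    e_k,
    e_lk,
    cap_dt,
    off,
    axial_diag,
    ii,
    jj,
    g_gj,
    stim_comp,
    stim_amp,
    stim_t0,
    stim_t1,
    syn_g,
    syn_e,
    soma_idx,
    probe_idx,
    dt,
    n_settle,
    n_run,
    lag_gj,
):  # pragma: no cover - exercised via integrate()
    n = V.shape[0]
    k = ii.shape[0]
    woodbury = k > 0 and not lag_gj
    n_gates = xinf_tab.shape[0]
    ntab = xinf_tab.shape[1]
    n_probe = probe_idx.shape[0]
    traces = np.empty((n_probe, n_run + 1))
    for p in range(n_probe):
        traces[p, 0] = V[probe_idx[p]]

    diag = np.empty(n)
    rhs = np.empty(n)
    dprime = np.empty(n)
    w = np.zeros(n)
    x0 = np.empty(n)
    Y = np.zeros((k, n))
    start = np.empty(k, np.int64)
    for r in range(k):
        start[r] = min(ii[r], jj[r])
    M = np.empty((k, k))
    cvec = np.empty(k)
    fail_step = -1

    for step in range(-n_settle, n_run):
        t_new = (step + 1) * dt

        # staggered gate update via tables interpolated at V^n
        for gi in range(n_gates):
            for c in range(n):
                pos = (V[c] - v0) * dvinv
                if pos < 0.0:
                    pos = 0.0
                if pos > ntab - 2:
                    pos = float(ntab - 2)
                i0 = int(pos)
                fr = pos - i0
                xinf = xinf_tab[gi, i0] + (xinf_tab[gi, i0 + 1] - xinf_tab[gi, i0]) * fr
                dec = decay_tab[gi, i0] + (decay_tab[gi, i0 + 1] - decay_tab[gi, i0]) * fr
                X[gi, c] = xinf + (X[gi, c] - xinf) * dec

        for c in range(n):
            m = X[0, c]
            gna = g_na[c] * m * m * m * X[1, c]
            nk = X[2, c] * X[2, c]
            gkf = g_kf[c] * nk * nk
            gks = g_ks[c] * X[3, c] * X[3, c]
            pos = (V[c] - v0) * dvinv
            if pos < 0.0:
                pos = 0.0
            if pos > ntab - 2:
                pos = float(ntab - 2)
            i0 = int(pos)
            fr = pos - i0
            f = fghk_tab[i0] + (fghk_tab[i0 + 1] - fghk_tab[i0]) * fr
            mca = X[4, c]
            ica = c_ca[c] * f * mca * mca
            diag[c] = cap_dt[c] + leak[c] + gna + gkf + gks + axial_diag[c]
            rhs[c] = (
                cap_dt[c] * V[c]
                + leak[c] * e_lk
                + gna * e_na
                + (gkf + gks) * e_k
                + ica
            )

        if step >= 0:
            for si in range(stim_comp.shape[0]):
                if stim_t0[si] <= t_new < stim_t1[si]:
                    rhs[stim_comp[si]] += stim_amp[si]
            if syn_g.shape[0] > 0:
                for s in range(soma_idx.shape[0]):
                    g = syn_g[step, s]
                    diag[soma_idx[s]] += g
                    rhs[soma_idx[s]] += g * syn_e

        if lag_gj and k > 0:
            # junction conductance implicit on the diagonal, partner
            # voltage lagged one step: unconditionally stable splitting
            for r in range(k):
                g = g_gj[r]
                diag[ii[r]] += g
                diag[jj[r]] += g
                rhs[ii[r]] += g * V[jj[r]]
                rhs[jj[r]] += g * V[ii[r]]

        # Thomas factorisation of the tridiagonal part
        dprime[0] = diag[0]
        for c in range(1, n):
            wv = off[c - 1] / dprime[c - 1]
            w[c] = wv
            dprime[c] = diag[c] - wv * off[c - 1]

        x0[0] = rhs[0]
        for c in range(1, n):
            x0[c] = rhs[c] - w[c] * x0[c - 1]
        x0[n - 1] = x0[n - 1] / dprime[n - 1]
        for c in range(n - 2, -1, -1):
            x0[c] = (x0[c] - off[c] * x0[c + 1]) / dprime[c]

        if woodbury:
            # Woodbury correction for the gap-junction rank-k term
            for r in range(k):
                st = start[r]
                for c in range(st):
                    Y[r, c] = 0.0
                prev = 0.0
                for c in range(st, n):
                    b = 0.0
                    if c == ii[r]:
                        b = 1.0
                    elif c == jj[r]:
                        b = -1.0
                    prev = b - w[c] * prev if c > st else b
                    Y[r, c] = prev
                Y[r, n - 1] = Y[r, n - 1] / dprime[n - 1]
                for c in range(n - 2, -1, -1):
                    Y[r, c] = (Y[r, c] - off[c] * Y[r, c + 1]) / dprime[c]
            for r in range(k):
                cvec[r] = x0[ii[r]] - x0[jj[r]]
                for s in range(k):
                    M[r, s] = Y[s, ii[r]] - Y[s, jj[r]]
                M[r, r] += 1.0 / g_gj[r]
            mvec = np.linalg.solve(M, cvec)
            for r in range(k):
                mr = mvec[r]
                for c in range(n):
                    x0[c] -= Y[r, c] * mr

        for c in range(n):
            V[c] = x0[c]

        if step % 100 == 0:
            bad = False
            for c in range(n):
                if not np.isfinite(V[c]):
                    bad = True
                    break
            if bad:
                fail_step = step
                break

        if step >= 0:
            for p in range(n_probe):
                traces[p, step + 1] = V[probe_idx[p]]

    return traces, fail_step
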