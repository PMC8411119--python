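"""Optional numba kernels for the per-step hot paths.

Pure-numpy fallbacks live next to each caller; the kernels implement the
identical arithmetic (single fused pass, no temporaries).  ``HAVE_NUMBA``
tells callers whether the fast path is available.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(fn):
            return fn
        return deco if not (args and callable(args[0])) else args[0]


@njit(cache=True, fastmath=False)
def lif_step(V, theta, ref, clamped, g_exc, g_inh, gv, drive, spiked,
             dt, tau_m, v_rest, t_ref):
    """Fused exponential-Euler membrane update with spike detection.

    ``drive`` is R*(i_ex + i_ext) in mV per neuron; ``gv`` is
    sum(g*coupling*v_rev).  Clamped and refractory neurons are held at
    rest; a neuron entering the step at or above threshold spikes.
    """
    for i in range(V.shape[0]):
        if clamped[i]:
            V[i] = v_rest
            spiked[i] = False
            continue
        if ref[i] > 0.0:
            V[i] = v_rest
            ref[i] -= dt
            spiked[i] = False
            continue
        v_old = V[i]
        a = 1.0 + g_exc[i] + g_inh[i]
        v_inf = (v_rest + gv[i] + drive[i]) / a
        v = v_inf + (v_old - v_inf) * math.exp(-a * dt / tau_m)
        if v >= theta[i] or v_old >= theta[i]:
            spiked[i] = True
            V[i] = v_rest
            ref[i] = t_ref
        else:
            spiked[i] = False
            V[i] = v


@njit(cache=True)
def deliver(W, idx, g_bar, g):
    """g += g_bar * sum of the columns of W selected by idx."""
    for k in range(idx.shape[0]):
        j = idx[k]
        for i in range(W.shape[0]):
            g[i] += g_bar * W[i, j]


@njit(cache=True)
def accumulate(g, coupling, v_rev, g_sum, gv_sum):
    """g_sum += coupling*g; gv_sum += coupling*v_rev*g."""
    cv = coupling * v_rev
    for i in range(g.shape[0]):
        g_sum[i] += coupling * g[i]
        gv_sum[i] += cv * g[i]


@njit(cache=True)
def hebb_homeo_update(W, x_post, x_pre, eta_hebb, eta_homeo, theta_homeo,
                      w_max, dt):
    """One Euler step of the Hebbian + homeostatic weight ODE with
    clipping at zero (dense mask)."""
    n_post, n_pre = W.shape
    for j in range(n_post):
        s = 0.0
        for i in range(n_pre):
            s += W[j, i]
        homeo = eta_homeo * (s - theta_homeo)
        xj = x_post[j]
        for i in range(n_pre):
            w = W[j, i] + dt * (eta_hebb * (w_max - W[j, i]) * xj * x_pre[i]
                                - homeo)
            W[j, i] = 0.0 if w < 0.0 else w


def _np_lif_step(V, theta, ref, clamped, g_exc, g_inh, gv, drive, spiked,
                 dt, tau_m, v_rest, t_ref):
    at_threshold = V >= theta
    a = 1.0 + g_exc + g_inh
    v_inf = (v_rest + gv + drive) / a
    v_new = v_inf + (V - v_inf) * np.exp(a * (-dt / tau_m))
    refractory = ref > 0.0
    inactive = refractory | clamped
    np.copyto(V, v_new)
    sp = (V >= theta) | at_threshold
    sp &= ~inactive
    V[inactive] = v_rest
    V[sp] = v_rest
    ref[sp] = t_ref
    ref[refractory] -= dt
    np.copyto(spiked, sp)


def _np_deliver(W, idx, g_bar, g):
    g += g_bar * W[:, idx].sum(axis=1)


def _np_accumulate(g, coupling, v_rev, g_sum, gv_sum):
    g_sum += coupling * g
    gv_sum += (coupling * v_rev) * g


def _np_hebb_homeo_update(W, x_post, x_pre, eta_hebb, eta_homeo,
                          theta_homeo, w_max, dt):
    hebb = eta_hebb * (w_max - W) * np.outer(x_post, x_pre)
    homeo = eta_homeo * (W.sum(axis=1) - theta_homeo)
    W += dt * (hebb - homeo[:, None])
    np.clip(W, 0.0, None, out=W)


if not HAVE_NUMBA:  # pragma: no cover
    lif_step = _np_lif_step
    deliver = _np_deliver
    accumulate = _np_accumulate
    hebb_homeo_update = _np_hebb_homeo_update
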