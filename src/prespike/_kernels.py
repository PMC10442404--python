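"""Numba inner loops for the per-timestep recursions.

These kernels are the hot paths; their semantics are pinned by the pure-numpy
step functions in :mod:`prespike.plasticity` and :mod:`prespike.neuron`, and
the test suite asserts the two routes agree to machine precision.

Update order within a timestep (mode > 0):
  1. prediction error  eps_t = x_t - v_{t-1} w_{t-1}  and global signal
     E_t = eps_t . w_{t-1}
  2. loss accumulation L_t = 0.5 ||eps_t||^2
  3. weight update (online: w += eta*(eps*v + E*p); scaled: bracket
     premultiplied elementwise by w_{t-1})
  4. influence update p_t = alpha*p_{t-1} + x_t (no reset at spikes)
  5. membrane update with the NEW weights, spike emission.
"""

import numpy as np
from numba import njit

#: divergence guard: |v| or |w| beyond this aborts the epoch
GUARD = 1.0e6

MODE_FROZEN = 0


@njit(cache=True)
def exp_filter_inplace(counts, beta):
    """Causal first-order exponential filter along axis 0, in place."""
    T, N = counts.shape
    for t in range(1, T):
        for i in range(N):
            counts[t, i] += beta * counts[t - 1, i]
    return counts


MODE_ONLINE = 1
MODE_SCALED = 2
MODE_EPOCH = 3   # accumulate the online bracket, apply once at epoch end


@njit(cache=True)
def epoch_loop(x, w, p, alpha, v_th, eta, mode):
    """Run one epoch; mutates and returns ``w`` and ``p``.

    Returns (v_series, s_series, loss_series, w, p, ok_flag).
    """
    T, N = x.shape
    v_series = np.empty(T)
    s_series = np.zeros(T, dtype=np.uint8)
    loss_series = np.empty(T)
    eps = np.empty(N)
    v_prev = 0.0
    s_prev = 0.0
    ok = True
    for t in range(T):
        glob = 0.0
        loss = 0.0
        for i in range(N):
            e = x[t, i] - v_prev * w[i]
            eps[i] = e
            glob += e * w[i]
            loss += 0.5 * e * e
        loss_series[t] = loss
        if mode == MODE_ONLINE:
            for i in range(N):
                w[i] += eta * (eps[i] * v_prev + glob * p[i])
        elif mode == MODE_SCALED:
            for i in range(N):
                w[i] += eta * w[i] * (eps[i] * v_prev + glob * p[i])
        drive = 0.0
        for i in range(N):
            p[i] = alpha * p[i] + x[t, i]
            drive += w[i] * x[t, i]
        v = alpha * v_prev - v_th * s_prev + drive
        s = 1.0 if v >= v_th else 0.0
        v_series[t] = v
        s_series[t] = np.uint8(s)
        if not np.isfinite(v) or abs(v) > GUARD:
            ok = False
            break
        v_prev = v
        s_prev = s
    return v_series, s_series, loss_series, w, p, ok


@njit(cache=True)
def epoch_gradient_loop(x, w, alpha, v_th):
    """Exact epoch gradient of the cumulative prediction loss at fixed w.

    Forward accumulation through the influence vector p (gamma = 0, so the
    voltage Jacobian is alpha at every step, spikes included).
    Returns (gradient, loss).
    """
    T, N = x.shape
    grad = np.zeros(N)
    p = np.zeros(N)
    v_prev = 0.0
    s_prev = 0.0
    loss = 0.0
    for t in range(T):
        glob = 0.0
        for i in range(N):
            e = x[t, i] - v_prev * w[i]
            glob += e * w[i]
            loss += 0.5 * e * e
            grad[i] -= e * v_prev
        drive = 0.0
        for i in range(N):
            e = x[t, i] - v_prev * w[i]
            grad[i] -= glob * p[i]
            p[i] = alpha * p[i] + x[t, i]
            drive += w[i] * x[t, i]
        v = alpha * v_prev - v_th * s_prev + drive
        s_prev = 1.0 if v >= v_th else 0.0
        v_prev = v
    return grad, loss


@njit(cache=True)
def network_epoch_loop(
    x, aff_idx, adj, w_aff, p_aff, w_lat, p_lat,
    alpha, beta_x, v_th, eta, mode, lateral_gain,
):
    """One epoch of the recurrent network; mutates the weight/influence arrays.

    x : (T, n_afferent_channels) filtered afferent drive
    aff_idx : (M, K) channel indices assigned to each neuron
    adj : (M, M) 0/1 adjacency, adj[j, i] = 1 when j projects to i (no self)
    w_lat, p_lat : (M, M), entry [j, i] is the weight / influence of the
        lateral channel j -> i (only where adj[j, i] = 1)

    A spike of neuron j at step t-1 enters the lateral traces at step t as a
    unit event filtered with the same exponential kernel as the afferents
    (decay beta_x per step).  Plasticity treats lateral channels identically
    to afferents; no gradient flows through the recurrence (each neuron's
    influence vector covers only its own input channels).

    Returns (s_out (T, M) uint8, v_out (T, M), loss_total, ok_flag).
    """
    T = x.shape[0]
    M, K = aff_idx.shape
    s_out = np.zeros((T, M), dtype=np.uint8)
    v_out = np.empty((T, M))
    y = np.zeros(M)        # filtered lateral traces (one per source neuron)
    v_prev = np.zeros(M)
    s_prev = np.zeros(M)
    eps_a = np.empty(K)
    eps_l = np.empty(M)
    acc_aff = np.zeros((M, K))
    acc_lat = np.zeros((M, M))
    loss_total = 0.0
    ok = True
    for t in range(T):
        for j in range(M):
            y[j] = beta_x * y[j] + lateral_gain * s_prev[j]
        for i in range(M):
            vp = v_prev[i]
            glob = 0.0
            for k in range(K):
                e = x[t, aff_idx[i, k]] - vp * w_aff[i, k]
                eps_a[k] = e
                glob += e * w_aff[i, k]
                loss_total += 0.5 * e * e
            for j in range(M):
                if adj[j, i]:
                    e = y[j] - vp * w_lat[j, i]
                    eps_l[j] = e
                    glob += e * w_lat[j, i]
                    loss_total += 0.5 * e * e
            if mode == MODE_ONLINE:
                for k in range(K):
                    w_aff[i, k] += eta * (eps_a[k] * vp + glob * p_aff[i, k])
                for j in range(M):
                    if adj[j, i]:
                        w_lat[j, i] += eta * (eps_l[j] * vp + glob * p_lat[j, i])
            elif mode == MODE_SCALED:
                for k in range(K):
                    w_aff[i, k] += eta * w_aff[i, k] * (
                        eps_a[k] * vp + glob * p_aff[i, k]
                    )
                for j in range(M):
                    if adj[j, i]:
                        w_lat[j, i] += eta * w_lat[j, i] * (
                            eps_l[j] * vp + glob * p_lat[j, i]
                        )
            elif mode == MODE_EPOCH:
                for k in range(K):
                    acc_aff[i, k] += eps_a[k] * vp + glob * p_aff[i, k]
                for j in range(M):
                    if adj[j, i]:
                        acc_lat[j, i] += eps_l[j] * vp + glob * p_lat[j, i]
            drive = 0.0
            for k in range(K):
                p_aff[i, k] = alpha * p_aff[i, k] + x[t, aff_idx[i, k]]
                drive += w_aff[i, k] * x[t, aff_idx[i, k]]
            for j in range(M):
                if adj[j, i]:
                    p_lat[j, i] = alpha * p_lat[j, i] + y[j]
                    drive += w_lat[j, i] * y[j]
            v = alpha * vp - v_th * s_prev[i] + drive
            v_out[t, i] = v
            if not np.isfinite(v) or abs(v) > GUARD:
                ok = False
            v_prev[i] = v
        if not ok:
            break
        for i in range(M):
            s_new = 1.0 if v_prev[i] >= v_th else 0.0
            s_prev[i] = s_new
            s_out[t, i] = np.uint8(s_new)
    return s_out, v_out, loss_total, acc_aff, acc_lat, ok
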