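"""Fixed-step (forward-Euler) integrators, numba-compiled.

Drift is deterministic; stochastic input enters through the pre-sampled
stimulus traces (Euler–Maruyama handled at trace generation).  Units:
mV, ms, nA, nF, µS.

Spike events are detected online by upward threshold crossing with a
refractory period; each event instantaneously increments the conductance
of the cell's outgoing spike-triggered synapses, which then decay
exponentially.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["integrate_single", "integrate_network"]


@njit(cache=True)
def integrate_single(stim, dt, v0, w0, c_abs, g_leak, e_leak,
                     g_fast, e_fast, g_slow, e_slow,
                     v1, v2, v3, v4, phi, spiking):  # pragma: no cover - jit
    n_steps = stim.shape[0]
    out = np.empty(n_steps, dtype=np.float64)
    v = v0
    w = w0
    for k in range(n_steps):
        i_ion = -g_leak * (v - e_leak)
        if spiking:
            minf = 0.5 * (1.0 + np.tanh((v - v1) / v2))
            i_ion -= g_fast * minf * (v - e_fast)
            i_ion -= g_slow * w * (v - e_slow)
            winf = 0.5 * (1.0 + np.tanh((v - v3) / v4))
            lam = phi * np.cosh((v - v3) / (2.0 * v4))
            w = w + dt * lam * (winf - w)
            if w < 0.0:  # open fraction is physical: clamp
                w = 0.0
            elif w > 1.0:
                w = 1.0
        v = v + dt * (i_ion + stim[k]) / c_abs
        out[k] = v
    return out


@njit(cache=True)
def integrate_network(
    stim, dt,
    c_abs, g_leak, e_leak, spiking,
    g_fast, e_fast, g_slow, e_slow, v1, v2, v3, v4, phi,
    e_pre, e_post, e_g,
    c_pre, c_post, c_w, c_decay, c_erev,
    out_ptr, out_idx,
    gr_pre, gr_post, gr_imax, gr_theta, gr_slope,
    v_init, w_init,
    threshold, refractory,
    rec_stride, max_spikes,
):  # pragma: no cover - jit
    """Advance the coupled network; returns (v_rec, spike_times, counts, status).

    status = (-1., -1.) on success, else (cell index, time of blow-up).
    """
    n_steps = stim.shape[0]
    n = stim.shape[1]
    n_elec = e_pre.shape[0]
    n_chem = c_pre.shape[0]
    n_grad = gr_pre.shape[0]

    v = v_init.copy()
    w = w_init.copy()
    g_syn = np.zeros(n_chem, dtype=np.float64)
    i_tot = np.empty(n, dtype=np.float64)

    n_rec = n_steps // rec_stride if rec_stride > 0 else 0
    v_rec = np.empty((n_rec, n), dtype=np.float64)
    spike_times = np.full((n, max_spikes), np.nan, dtype=np.float64)
    counts = np.zeros(n, dtype=np.int64)
    last_spike = np.full(n, -1e12, dtype=np.float64)
    status = (-1.0, -1.0)

    for k in range(n_steps):
        t = k * dt
        for i in range(n):
            i_tot[i] = stim[k, i]
        # electrical couplings: ohmic, conserving
        for s in range(n_elec):
            a = e_pre[s]
            b = e_post[s]
            d = e_g[s] * (v[b] - v[a])
            i_tot[a] += d
            i_tot[b] -= d
        # spike-triggered conductance synapses
        for s in range(n_chem):
            g_syn[s] *= c_decay[s]
            i_tot[c_post[s]] += g_syn[s] * (c_erev[s] - v[c_post[s]])
        # graded-potential synapses
        for s in range(n_grad):
            x = (v[gr_pre[s]] - gr_theta[s]) / gr_slope[s]
            if x > 35.0:
                sig = 1.0
            elif x < -35.0:
                sig = 0.0
            else:
                sig = 1.0 / (1.0 + np.exp(-x))
            i_tot[gr_post[s]] += gr_imax[s] * sig
        # membrane update
        for i in range(n):
            vi = v[i]
            i_ion = -g_leak[i] * (vi - e_leak[i])
            if spiking[i]:
                minf = 0.5 * (1.0 + np.tanh((vi - v1[i]) / v2[i]))
                i_ion -= g_fast[i] * minf * (vi - e_fast[i])
                i_ion -= g_slow[i] * w[i] * (vi - e_slow[i])
                winf = 0.5 * (1.0 + np.tanh((vi - v3[i]) / v4[i]))
                lam = phi[i] * np.cosh((vi - v3[i]) / (2.0 * v4[i]))
                wi = w[i] + dt * lam * (winf - w[i])
                if wi < 0.0:  # open fraction is physical: clamp
                    wi = 0.0
                elif wi > 1.0:
                    wi = 1.0
                w[i] = wi
            v_new = vi + dt * (i_ion + i_tot[i]) / c_abs[i]
            if not np.isfinite(v_new):
                status = (float(i), t)
                return v_rec, spike_times, counts, status
            # upward threshold crossing with refractory period
            if spiking[i] and vi < threshold and v_new >= threshold:
                if t - last_spike[i] >= refractory:
                    last_spike[i] = t
                    if counts[i] < max_spikes:
                        spike_times[i, counts[i]] = t
                    counts[i] += 1
                    for p in range(out_ptr[i], out_ptr[i + 1]):
                        g_syn[out_idx[p]] += c_w[out_idx[p]]
            v[i] = v_new
        if rec_stride > 0 and (k + 1) % rec_stride == 0:
            r = (k + 1) // rec_stride - 1
            if r < n_rec:
                for i in range(n):
                    v_rec[r, i] = v[i]
    return v_rec, spike_times, counts, status
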