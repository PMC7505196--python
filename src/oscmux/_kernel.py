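"""Forward-Euler simulation kernel (numba-compiled).

One kernel serves every network in the package: conductance-based synapses
routed by presynaptic E/I identity (Dale's law), per-presynaptic-neuron
axonal delays handled by a ring buffer, an optional bank of signed
"current" synapses (used for the projections between oscillator networks
and the reservoir, which inject current rather than conductance), an
optional low-rank external drive I_ext = M_drive @ S[t], and an optional
burst-gated plasticity rule on selected rows of M_drive (place cells).

The kernel mutates the state arrays in place and appends spikes to
pre-allocated output buffers, so a single compiled function supports both
single-step and whole-run execution.
"""

from __future__ import annotations

import numba
import numpy as np

# status codes returned by the kernel
OK = 0
NONFINITE = 1


@numba.njit(cache=True)
def _simulate(  # noqa: C901 - deliberately monolithic hot loop
    n_steps, dt, step0,
    # per-neuron parameters
    C, R_gohm, E_L, V_theta, V_reset, I_tonic,
    tau_ex, tau_in, E_ex, E_in, G_ex_ns, G_in_ns,
    is_ex, delay_steps, refr_steps,
    # conductance synapses, CSC by presynaptic neuron
    w_indptr, w_indices, w_data,
    # signed current synapses, CSC by presynaptic neuron
    c_indptr, c_indices, c_data, tau_cur,
    # low-rank drive: (N, K) @ (n_steps, K) rows
    M_drive, S,
    # dense per-step drive (n_steps, N) or (0, 0)
    I_dense,
    # plasticity on rows of M_drive (place cells); n_bank = number of
    # leading S columns that are plastic inputs
    plastic_rows, n_bank, alpha, w_lo, w_hi, burst_win_steps,
    plast_refr_steps, plast_last_update,
    plast_prev1, plast_prev2,
    # mutable state
    V, g_ex, g_in, I_cur, refr_left, clamped, buf, buf_pos_arr,
    # outputs
    spike_neuron, spike_step, n_spikes_arr,
    rate_counts,
    rec_every, recV, recGex, recGin, recIext,
    burst_row, burst_step, n_bursts_arr,
):
    N = V.shape[0]
    D = buf.shape[0]
    K = M_drive.shape[1]
    n_plastic = plastic_rows.shape[0]
    use_dense = I_dense.shape[0] > 0
    n_sp = n_spikes_arr[0]
    n_bu = n_bursts_arr[0]
    buf_pos = buf_pos_arr[0]
    cap = spike_neuron.shape[0]

    for n in range(n_steps):
        gstep = step0 + n  # global step index (spike/burst timestamps only)

        # --- deliver spikes whose delay elapses at this step -------------
        for j in range(N):
            if buf[buf_pos, j]:
                buf[buf_pos, j] = 0
                lo = w_indptr[j]
                hi = w_indptr[j + 1]
                if is_ex[j]:
                    for a in range(lo, hi):
                        i = w_indices[a]
                        g_ex[i] += G_ex_ns[i] * w_data[a]
                else:
                    for a in range(lo, hi):
                        i = w_indices[a]
                        g_in[i] += G_in_ns[i] * w_data[a]
                lo = c_indptr[j]
                hi = c_indptr[j + 1]
                for a in range(lo, hi):
                    I_cur[c_indices[a]] += c_data[a]

        rec_now = rec_every > 0 and n % rec_every == 0
        m = n // rec_every if rec_every > 0 else 0

        # --- integrate membrane, detect threshold crossings --------------
        nsp_step = 0
        for i in range(N):
            drive_i = I_cur[i]
            for k in range(K):
                drive_i += M_drive[i, k] * S[n, k]
            if use_dense:
                drive_i += I_dense[n, i]

            if rec_now:
                recV[m, i] = V[i]
                recGex[m, i] = g_ex[i]
                recGin[m, i] = g_in[i]
                recIext[m, i] = drive_i

            if clamped[i]:
                V[i] = E_L[i]
            elif refr_left[i] > 0:
                refr_left[i] -= 1
                V[i] = V_reset[i]
            else:
                dV = (dt / C[i]) * (
                    (E_L[i] - V[i]) / R_gohm[i]
                    + g_ex[i] * (E_ex[i] - V[i])
                    + g_in[i] * (E_in[i] - V[i])
                    + I_tonic[i]
                    + drive_i
                )
                V[i] += dV
                if not np.isfinite(V[i]):
                    n_spikes_arr[0] = n_sp
                    n_bursts_arr[0] = n_bu
                    buf_pos_arr[0] = buf_pos
                    return NONFINITE, i, gstep
                if V[i] >= V_theta[i]:
                    # spike: reset, refractory, schedule delayed delivery
                    V[i] = V_reset[i]
                    refr_left[i] = refr_steps[i]
                    buf[(buf_pos + delay_steps[i]) % D, i] = 1
                    if n_sp < cap:
                        spike_neuron[n_sp] = i
                        spike_step[n_sp] = gstep
                    n_sp += 1
                    nsp_step += 1
        rate_counts[n] = nsp_step

        # --- burst-gated plasticity on place-cell rows --------------------
        if n_plastic > 0 and nsp_step > 0:
            for p in range(n_plastic):
                i = plastic_rows[p]
                if refr_left[i] == refr_steps[i] and not clamped[i]:
                    # neuron i spiked this step; plasticity re-arms only
                    # after the plateau refractory period
                    if (
                        plast_last_update[p] >= 0
                        and n - plast_last_update[p] < plast_refr_steps
                    ):
                        pass
                    elif (
                        plast_prev2[p] >= 0
                        and n - plast_prev2[p] <= burst_win_steps
                    ):
                        b = plast_prev2[p]  # first spike of the triplet
                        for k in range(n_bank):
                            w = M_drive[i, k] + alpha * S[b, k]
                            if w < w_lo:
                                w = w_lo
                            elif w > w_hi:
                                w = w_hi
                            M_drive[i, k] = w
                        if n_bu < burst_row.shape[0]:
                            burst_row[n_bu] = p
                            burst_step[n_bu] = step0 + b
                        n_bu += 1
                        plast_prev1[p] = -1
                        plast_prev2[p] = -1
                        plast_last_update[p] = n
                    else:
                        plast_prev2[p] = plast_prev1[p]
                        plast_prev1[p] = n

        # --- decay conductances and current synapses ----------------------
        for i in range(N):
            g_ex[i] -= dt * g_ex[i] / tau_ex[i]
            g_in[i] -= dt * g_in[i] / tau_in[i]
            I_cur[i] -= dt * I_cur[i] / tau_cur

        buf_pos = (buf_pos + 1) % D

    n_spikes_arr[0] = n_sp
    n_bursts_arr[0] = n_bu
    buf_pos_arr[0] = buf_pos
    return OK, -1, -1


@numba.njit(cache=True)
def filter_spike_grid(spike_t, spike_n, neuron_map, n_keep,
                      grid, tau_r, tau_d):
    """Double-exponential filter sampled exactly on ``grid`` (ms).

    Impulse response (unit area):
        r(t) = [exp(-t/tau_d) - exp(-t/tau_r)] / (tau_d - tau_r)
    realized as r' = -r/tau_d + h, h' = -h/tau_r + delta/(tau_r*tau_d),
    integrated exactly between events.

    ``spike_t`` must be sorted ascending; ``neuron_map[j]`` gives the output
    row of global neuron j, or -1 to drop it.
    """
    n_grid = grid.shape[0]
    out = np.zeros((n_grid, n_keep))
    r = np.zeros(n_keep)
    h = np.zeros(n_keep)
    t_now = 0.0
    s = 0
    n_spk = spike_t.shape[0]
    c = tau_r * tau_d / (tau_d - tau_r)
    for gi in range(n_grid):
        tg = grid[gi]
        # process spikes with t <= tg in order
        while s < n_spk and spike_t[s] <= tg:
            ts = spike_t[s]
            dt_ = ts - t_now
            if dt_ > 0:
                ed = np.exp(-dt_ / tau_d)
                er = np.exp(-dt_ / tau_r)
                for q in range(n_keep):
                    r[q] = r[q] * ed + h[q] * c * (ed - er)
                    h[q] = h[q] * er
                t_now = ts
            q = neuron_map[spike_n[s]]
            if q >= 0:
                h[q] += 1.0 / (tau_r * tau_d)
            s += 1
        dt_ = tg - t_now
        if dt_ > 0:
            ed = np.exp(-dt_ / tau_d)
            er = np.exp(-dt_ / tau_r)
            for q in range(n_keep):
                r[q] = r[q] * ed + h[q] * c * (ed - er)
                h[q] = h[q] * er
            t_now = tg
        for q in range(n_keep):
            out[gi, q] = r[q]
    return out
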