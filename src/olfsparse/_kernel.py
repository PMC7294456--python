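"""Forward-Euler integration kernel for the three-population network.

Compiled with numba for speed; the pure-Python reference integrator used in
the test suite mirrors the same update order, which is, per step k
(covering [t_k, t_k + dt)):

1. synaptic conductances decay exponentially over dt, then jump by the
   synaptic weight for every presynaptic spike assigned to the boundary
   t_k (pooled ORN drive counts of step k, and network spikes detected at
   the end of step k-1);
2. adaptation currents of SFA-enabled populations decay (Euler) and
   receive an Ornstein-Uhlenbeck noise increment; the increment is applied
   every ``noise_every`` steps with variance scaled accordingly
   (sqrt(2 sigma^2 * noise_every * dt / tau_A)), which leaves the
   stationary statistics of the noise unchanged and is an excellent
   approximation on the default 1 ms noise grid because the OU correlation
   time tau_A = 389 ms is orders of magnitude longer; populations with SFA
   disabled use the static compensation current (PN/LN) or zero (KC);
3. membrane voltages take one Euler step; refractory neurons stay clamped
   at the reset potential;
4. spikes are detected at the step end (v >= V_T outside refractoriness):
   the voltage is reset, the refractory countdown starts, the adaptation
   current jumps by delta_I_A, and the spike is delivered to postsynaptic
   conductances at the next step boundary.

The LN->PN inhibitory conductance is a single shared scalar: every LN
spike increments it and it is applied identically to every PN (global,
unspecific lateral inhibition).
"""

import numpy as np
from numba import njit

__all__ = ["integrate"]


@njit(cache=False)
def integrate(
    drive,              # (n_glu, n_steps) int64 pooled ORN counts per step
    W,                  # (n_kc, n_glu) float64 binary PN->KC connectivity
    dt,                 # ms
    record_from,        # first recorded step (prerun length in steps)
    # synaptic weights (nS) and parameters
    w_op, w_ol, w_lp, w_pk,
    ee, ei, tau_e, tau_i,
    # cell parameters
    cm, gl, el, vr, vt, ref_steps,
    # adaptation
    delta_ia, tau_a, sigma2,
    sfa_pn, sfa_ln, sfa_kc,
    i0_pn, i0_ln,       # static compensation currents (pA) when SFA off
    noise_seed,
    ia_every,           # KC adaptation sampling interval in steps; 0 = off
    noise_every,        # OU noise increment interval in steps (>= 1)
    probe,              # record per-step state of neuron 0 of each population
):
    np.random.seed(noise_seed)
    n_glu, n_steps = drive.shape
    n_kc = W.shape[0]

    v_pn = np.full(n_glu, el)
    v_ln = np.full(n_glu, el)
    v_kc = np.full(n_kc, el)
    g_op = np.zeros(n_glu)
    g_ol = np.zeros(n_glu)
    g_pk = np.zeros(n_kc)
    g_lp = 0.0
    ia_pn = np.zeros(n_glu)
    ia_ln = np.zeros(n_glu)
    ia_kc = np.zeros(n_kc)
    ref_pn = np.zeros(n_glu, dtype=np.int64)
    ref_ln = np.zeros(n_glu, dtype=np.int64)
    ref_kc = np.zeros(n_kc, dtype=np.int64)
    spiked_pn = np.zeros(n_glu, dtype=np.bool_)
    spiked_ln_count = 0

    de = np.exp(-dt / tau_e)
    di = np.exp(-dt / tau_i)
    namp = np.sqrt(2.0 * sigma2 * noise_every * dt / tau_a)

    rec_steps = n_steps - record_from
    # refractoriness caps the spike count per neuron at one per ref window
    cap = int(np.ceil(rec_steps / max(ref_steps, 1))) + 2
    pn_id = np.empty(n_glu * cap, dtype=np.int32)
    pn_t = np.empty(n_glu * cap)
    ln_id = np.empty(n_glu * cap, dtype=np.int32)
    ln_t = np.empty(n_glu * cap)
    kc_id = np.empty(n_kc * cap, dtype=np.int32)
    kc_t = np.empty(n_kc * cap)
    n_pn = 0
    n_ln = 0
    n_kc_sp = 0

    if ia_every > 0:
        n_samples = rec_steps // ia_every
        ia_trace = np.empty((n_samples, n_kc), dtype=np.float32)
    else:
        n_samples = 0
        ia_trace = np.empty((0, n_kc), dtype=np.float32)
    sample_row = 0

    # probe columns: v_pn0, g_op0, g_lp, ia_pn0, v_ln0, g_ol0, v_kc0, g_pk0
    probe_trace = np.empty((n_steps if probe else 0, 8))

    status = 0  # 1 = non-finite state detected (sentinel check), run aborted

    inc = np.zeros(n_kc)
    decay_a = dt / tau_a

    for k in range(n_steps):
        # --- 1. conductances: decay, then boundary spike increments
        new_spiked_pn = np.zeros(n_glu, dtype=np.bool_)
        for i in range(n_glu):
            g_op[i] = g_op[i] * de + w_op * drive[i, k]
            g_ol[i] = g_ol[i] * de + w_ol * drive[i, k]
        g_lp = g_lp * di + w_lp * spiked_ln_count
        any_pn = False
        for j in range(n_glu):
            if spiked_pn[j]:
                any_pn = True
                break
        if any_pn:
            for i in range(n_kc):
                inc[i] = 0.0
            for j in range(n_glu):
                if spiked_pn[j]:
                    for i in range(n_kc):
                        inc[i] += w_pk * W[i, j]
        spiked_ln_count = 0

        t_spike = (k + 1) * dt
        recording = k >= record_from
        noise_now = (k % noise_every) == 0

        # --- PN population
        for i in range(n_glu):
            if sfa_pn:
                ia_pn[i] -= ia_pn[i] * decay_a
                if noise_now:
                    ia_pn[i] += namp * np.random.normal(0.0, 1.0)
                ia = ia_pn[i]
            else:
                ia = i0_pn
            if ref_pn[i] > 0:
                v_pn[i] = vr
                ref_pn[i] -= 1
            else:
                v = v_pn[i]
                v += dt / cm * (
                    gl * (el - v) + g_op[i] * (ee - v) + g_lp * (ei - v) - ia
                )
                if v >= vt:
                    v_pn[i] = vr
                    ref_pn[i] = ref_steps
                    new_spiked_pn[i] = True
                    if sfa_pn:
                        ia_pn[i] += delta_ia
                    if recording:
                        pn_id[n_pn] = i
                        pn_t[n_pn] = t_spike
                        n_pn += 1
                else:
                    v_pn[i] = v

        # --- LN population
        for i in range(n_glu):
            if sfa_ln:
                ia_ln[i] -= ia_ln[i] * decay_a
                if noise_now:
                    ia_ln[i] += namp * np.random.normal(0.0, 1.0)
                ia = ia_ln[i]
            else:
                ia = i0_ln
            if ref_ln[i] > 0:
                v_ln[i] = vr
                ref_ln[i] -= 1
            else:
                v = v_ln[i]
                v += dt / cm * (gl * (el - v) + g_ol[i] * (ee - v) - ia)
                if v >= vt:
                    v_ln[i] = vr
                    ref_ln[i] = ref_steps
                    spiked_ln_count += 1
                    if sfa_ln:
                        ia_ln[i] += delta_ia
                    if recording:
                        ln_id[n_ln] = i
                        ln_t[n_ln] = t_spike
                        n_ln += 1
                else:
                    v_ln[i] = v

        # --- KC population (synaptic decay fused into the neuron loop)
        for i in range(n_kc):
            g = g_pk[i] * de
            if any_pn:
                g += inc[i]
            g_pk[i] = g
            if sfa_kc:
                ia_kc[i] -= ia_kc[i] * decay_a
                if noise_now:
                    ia_kc[i] += namp * np.random.normal(0.0, 1.0)
                ia = ia_kc[i]
            else:
                ia = 0.0
            if ref_kc[i] > 0:
                v_kc[i] = vr
                ref_kc[i] -= 1
            else:
                v = v_kc[i]
                v += dt / cm * (gl * (el - v) + g * (ee - v) - ia)
                if v >= vt:
                    v_kc[i] = vr
                    ref_kc[i] = ref_steps
                    if sfa_kc:
                        ia_kc[i] += delta_ia
                    if recording:
                        kc_id[n_kc_sp] = i
                        kc_t[n_kc_sp] = t_spike
                        n_kc_sp += 1
                else:
                    v_kc[i] = v

        spiked_pn = new_spiked_pn

        if ia_every > 0 and recording:
            if (k - record_from + 1) % ia_every == 0 and sample_row < n_samples:
                for i in range(n_kc):
                    ia_trace[sample_row, i] = ia_kc[i]
                sample_row += 1

        if k % 5000 == 0:
            if not (np.isfinite(v_pn[0]) and np.isfinite(v_ln[0])
                    and np.isfinite(v_kc[0]) and np.isfinite(g_lp)):
                status = 1
                break

        if probe:
            probe_trace[k, 0] = v_pn[0]
            probe_trace[k, 1] = g_op[0]
            probe_trace[k, 2] = g_lp
            probe_trace[k, 3] = ia_pn[0]
            probe_trace[k, 4] = v_ln[0]
            probe_trace[k, 5] = g_ol[0]
            probe_trace[k, 6] = v_kc[0]
            probe_trace[k, 7] = g_pk[0]

    return (
        pn_id[:n_pn], pn_t[:n_pn],
        ln_id[:n_ln], ln_t[:n_ln],
        kc_id[:n_kc_sp], kc_t[:n_kc_sp],
        ia_trace, probe_trace, status,
    )
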