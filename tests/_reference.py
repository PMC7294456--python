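"""Independently written scalar per-neuron reference integrator.

Implements the same three-population dynamics as the production kernel —
leaky integrate-and-fire with conductance-based synapses, shared global
inhibitory conductance, spike-triggered adaptation, fire-and-reset with a
clamped refractory period — in plain Python, one neuron at a time, with no
vectorization and no numba.  Used as the oracle for integrator-equivalence
tests on miniature networks with the channel noise switched off.
"""

import math


def integrate_reference(drive, W, dt, record_from, cond):
    """Return spikes and probe traces for the given drive and condition.

    ``drive`` is an (n_glu, n_steps) integer array of pooled ORN counts,
    ``W`` the binary PN->KC matrix, ``cond`` a ConditionSpec whose
    adaptation noise variance must be zero (the reference is
    deterministic).
    """
    assert cond.adaptation.sigma2_I == 0.0, "reference is noise-free"
    n = cond.neuron
    s = cond.synapse
    a = cond.adaptation
    n_glu, n_steps = drive.shape
    n_kc = W.shape[0]
    ref_steps = int(round(n.tau_ref / dt))
    de = math.exp(-dt / s.tau_E)
    di = math.exp(-dt / s.tau_I)

    v = {p: [n.E_L] * m for p, m in (("pn", n_glu), ("ln", n_glu), ("kc", n_kc))}
    ia = {p: [0.0] * m for p, m in (("pn", n_glu), ("ln", n_glu), ("kc", n_kc))}
    refrac = {p: [0] * m for p, m in (("pn", n_glu), ("ln", n_glu), ("kc", n_kc))}
    g_op = [0.0] * n_glu
    g_ol = [0.0] * n_glu
    g_pk = [0.0] * n_kc
    g_lp = 0.0
    prev_pn_spikes = []
    prev_ln_count = 0

    spikes = {"pn": [], "ln": [], "kc": []}
    probe = []

    for k in range(n_steps):
        for i in range(n_glu):
            g_op[i] = g_op[i] * de + cond.w_OP * drive[i][k]
            g_ol[i] = g_ol[i] * de + cond.w_OL * drive[i][k]
        g_lp = g_lp * di + cond.w_LP * prev_ln_count
        inc = [0.0] * n_kc
        for j in prev_pn_spikes:
            for i in range(n_kc):
                inc[i] += cond.w_PK * W[i][j]
        for i in range(n_kc):
            g_pk[i] = g_pk[i] * de + inc[i]
        prev_pn_spikes = []
        prev_ln_count = 0
        t_spike = (k + 1) * dt
        recording = k >= record_from

        for pop, m, sfa, g_exc, i0 in (
            ("pn", n_glu, cond.sfa_pn, g_op, cond.i0),
            ("ln", n_glu, cond.sfa_ln, g_ol, cond.i0),
            ("kc", n_kc, cond.sfa_kc, g_pk, 0.0),
        ):
            for i in range(m):
                if sfa:
                    ia[pop][i] -= ia[pop][i] * dt / a.tau_A
                    cur = ia[pop][i]
                else:
                    cur = i0
                if refrac[pop][i] > 0:
                    v[pop][i] = n.V_R
                    refrac[pop][i] -= 1
                    continue
                vi = v[pop][i]
                drive_i = n.g_L * (n.E_L - vi) + g_exc[i] * (s.E_E - vi) - cur
                if pop == "pn":
                    drive_i += g_lp * (s.E_I - vi)
                vi += dt / n.c_m * drive_i
                if vi >= n.V_T:
                    v[pop][i] = n.V_R
                    refrac[pop][i] = ref_steps
                    if sfa:
                        ia[pop][i] += a.delta_I_A
                    if pop == "pn":
                        prev_pn_spikes.append(i)
                    elif pop == "ln":
                        prev_ln_count += 1
                    if recording:
                        spikes[pop].append((i, t_spike))
                else:
                    v[pop][i] = vi

        probe.append((v["pn"][0], g_op[0], g_lp, ia["pn"][0],
                      v["ln"][0], g_ol[0], v["kc"][0], g_pk[0]))

    return spikes, probe
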