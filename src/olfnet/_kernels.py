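"""Compiled inner loop of the circuit simulation.

The per-step dynamics (synaptic kernel states, drive summation, Euler
integration, probabilistic spiking) are pure element-wise and mat-vec
arithmetic on small arrays; at n = 100 units per group the Python/NumPy
call overhead dominates, so the loop is JIT-compiled with numba.  The
semantics are exactly those of the reference operations in
:mod:`olfnet.core` composed in anatomical update order; the test suite
cross-checks the two paths.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["step_kernel", "plasticity_kernel"]


@njit(cache=True)
def step_kernel(
    # --- connection data, one row per projection -------------------------
    idx,          # (C, N, Kmax) int64: presynaptic indices per target
    kcount,       # (C,) int64: number of inputs per target row
    g_eff,        # (C,) effective peak conductance this step
    e_n,          # (C,) reversal potentials
    dec_d,        # (C,) per-step decay factor of the slow exponential
    dec_r,        # (C,) per-step decay factor of the fast exponential
    tau_d,        # (C,) decay time constants (graded filter)
    tau_r,        # (C,) rise time constants (graded filter)
    graded,       # (C,) bool: continuous-rate source
    plastic,      # (C,) bool: weights from the plastic matrix
    identity,     # (C,) bool: one-to-one wiring
    lesioned,     # (C,) bool: projection disabled
    src,          # (C,) source population index
    tgt,          # (C,) target population index
    z_decay,      # (C, N) kernel state (slow exponential / filter stage 2)
    z_rise,       # (C, N) kernel state (fast exponential / filter stage 1)
    w,            # (N, N) plastic weight matrix
    rec_div,      # float: recurrent drive divisor
    # --- population data, one row per group ------------------------------
    v,            # (P, N) membrane potentials
    refrac,       # (P, N) remaining refractory time
    fired,        # (P, N) firing state of the previous step (updated here)
    outputs,      # (P, N) transmitted output of the previous step (updated)
    tau_m,        # (P,) membrane time constants
    beta,         # (P,) output exponents
    tmin,         # (P,) effective output thresholds this step
    tmax,         # (P,) effective saturation potentials this step
    v_hyper,      # (P,) reset potentials
    t_refrac,     # (P,) refractory periods
    spiking,      # (P,) bool
    randoms,      # (P, N) uniform draws for this step (unused rows ignored)
    # --- adaptation (pyramidal cells) -------------------------------------
    i_pyr,        # int: pyramidal population index
    i_mi_apical,  # int: apical compartment index
    i_mi_soma,    # int: somatic compartment index
    ahc,          # (N,) adaptation variable
    ahc_amp,      # float: effective adaptation increment this step
    ahc_tau,      # float
    ahc_e,        # float
    # --- input -----------------------------------------------------------
    osn_drive,    # (N,) sensory input voltage (zeros when no odor)
    i_osn,        # int: OSN population index
    dt,           # float
    p_scale,      # float: dt / 0.5 -- F(v) is a per-0.5-ms firing probability
    pyr_drive,    # (N,) out: total pyramidal drive this step
):
    C = idx.shape[0]
    P = v.shape[0]
    N = v.shape[1]

    # 1. fold the previous step's outputs into the kernel states
    for c in range(C):
        s = src[c]
        if graded[c]:
            for j in range(N):
                z_rise[c, j] += (dt / tau_r[c]) * (outputs[s, j] - z_rise[c, j])
                z_decay[c, j] += (dt / tau_d[c]) * (z_rise[c, j] - z_decay[c, j])
        else:
            for j in range(N):
                z_decay[c, j] = (z_decay[c, j] + outputs[s, j]) * dec_d[c]
                z_rise[c, j] = (z_rise[c, j] + outputs[s, j]) * dec_r[c]

    # 2. synaptic drives (driving force from current membrane potential)
    v_ext = np.zeros((P, N))
    for c in range(C):
        if lesioned[c]:
            continue
        t = tgt[c]
        g = g_eff[c]
        if graded[c]:
            zc = z_decay[c]
        else:
            zc = z_decay[c] - z_rise[c]
        if plastic[c]:
            for i in range(N):
                acc = 0.0
                for j in range(N):
                    acc += w[i, j] * zc[j]
                v_ext[t, i] += g * (acc / rec_div) * (e_n[c] - v[t, i])
        elif identity[c]:
            for i in range(N):
                v_ext[t, i] += g * zc[i] * (e_n[c] - v[t, i])
        else:
            kc = kcount[c]
            for i in range(N):
                acc = 0.0
                for q in range(kc):
                    acc += zc[idx[c, i, q]]
                v_ext[t, i] += g * acc * (e_n[c] - v[t, i])

    # sensory input
    for j in range(N):
        v_ext[i_osn, j] += osn_drive[j]

    # adaptation: integrates last step's spikes, conductance-like drive
    for j in range(N):
        ahc[j] += (dt / ahc_tau) * (ahc_amp * fired[i_pyr, j] - ahc[j])
        v_ext[i_pyr, j] += ahc[j] * (ahc_e - v[i_pyr, j])
    for j in range(N):
        pyr_drive[j] = v_ext[i_pyr, j]

    # 3. integrate and fire, in population order; the somatic compartment
    #    receives the freshly integrated apical potential within this step
    for p in range(P):
        if p == i_mi_soma:
            for j in range(N):
                v_ext[p, j] += v[i_mi_apical, j]
        inv_range = 1.0 / (tmax[p] - tmin[p])
        for j in range(N):
            if refrac[p, j] > 0.0:
                v[p, j] = v_hyper[p]
            else:
                v[p, j] += (dt / tau_m[p]) * (v_ext[p, j] - v[p, j])
        if spiking[p]:
            for j in range(N):
                x = (v[p, j] - tmin[p]) * inv_range
                if x <= 0.0:
                    prob = 0.0
                elif x >= 1.0:
                    prob = 1.0
                elif beta[p] == 2.0:
                    prob = x * x
                elif beta[p] == 3.0:
                    prob = x * x * x
                elif beta[p] == 1.0:
                    prob = x
                else:
                    prob = x ** beta[p]
                prob *= p_scale
                if prob > 1.0:
                    prob = 1.0
                if refrac[p, j] <= 0.0:
                    if randoms[p, j] < prob:
                        fired[p, j] = 1.0
                        v[p, j] = v_hyper[p]
                        refrac[p, j] = t_refrac[p]
                    else:
                        fired[p, j] = 0.0
                else:
                    fired[p, j] = 0.0
                    refrac[p, j] -= dt
                    if refrac[p, j] < 0.0:
                        refrac[p, j] = 0.0
                outputs[p, j] = fired[p, j]
        else:
            for j in range(N):
                fired[p, j] = 0.0
                x = (v[p, j] - tmin[p]) * inv_range
                if x <= 0.0:
                    out = 0.0
                elif x >= 1.0:
                    out = 1.0
                elif beta[p] == 2.0:
                    out = x * x
                elif beta[p] == 3.0:
                    out = x * x * x
                elif beta[p] == 1.0:
                    out = x
                else:
                    out = x ** beta[p]
                outputs[p, j] = out


@njit(cache=True)
def plasticity_kernel(w, w_max, rate, i_post, pre_vals):
    """Gated Hebbian update in place: dw = rate * i_post x pre * (1 - w/w_max),
    clipped to [0, w_max], zero diagonal."""
    n = w.shape[0]
    for i in range(n):
        ip = i_post[i]
        if ip <= 0.0:
            continue
        for j in range(n):
            b = pre_vals[j]
            if b <= 1e-6 or i == j:
                continue
            nw = w[i, j] + rate * ip * b * (1.0 - w[i, j] / w_max)
            if nw < 0.0:
                nw = 0.0
            elif nw > w_max:
                nw = w_max
            w[i, j] = nw
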