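"""Low-level cable-equation integrator (numba-compiled).

Method of lines on the compartment tree: membrane voltage advances by a
theta-method solve of the Hines-ordered tree system each step (theta = 0.55
by default: Crank-Nicolson with mild damping against spike-edge ringing),
gating variables advance by exact exponential integration against their
voltage-frozen steady states (NEURON-style staggering), and submembrane
calcium follows its linear ODE in closed form per step.  All channel
voltage dependence enters through precomputed lookup tables.

Units inside the kernel: mV, ms, nA, uS, nF, mM.
"""

import numpy as np
from numba import njit


@njit(cache=True, fastmath=False)
def run_kernel(v, gates, ca0,
               nstep, dt,
               parent, c_nF, gpas, epas, ga,
               istim, stim_comp,
               vg_state, vg_chan, vg_power, vg_inf, vg_tau, vmin, inv_dv,
               chan_g, chan_e, chan_carev, chan_cacur,
               chan_sk, sk_state, sk_cahalf, sk_hill, sk_tau,
               cafac, catau, carest, eca_fac, ca_ext, ca_floor,
               clamp, vcmd, gclamp,
               rec_every, vout, iclamp_out,
               per_chan, ichan_out,
               gate_lo, gate_hi, dv_last, theta):
    ncomp = v.shape[0]
    nchan = chan_g.shape[0]
    nvg = vg_state.shape[0]
    nv = vg_inf.shape[1]

    d = np.empty(ncomp)
    rhs = np.empty(ncomp)
    gk = np.empty(nchan)
    ax = np.empty(ncomp)
    cdt = c_nF / dt
    omt = 1.0 - theta
    gat = theta * ga  # axial couplings weighted for the theta-method solve

    # static part of the diagonal: capacitive + leak + axial couplings
    diag0 = np.empty(ncomp)
    for i in range(ncomp):
        diag0[i] = cdt[i] + theta * gpas[i]
    for i in range(1, ncomp):
        diag0[i] += gat[i]
        diag0[parent[i]] += gat[i]

    ca = ca0
    eca = eca_fac * np.log(ca_ext / ca)
    irec = 0
    vold = np.empty(ncomp)

    for step in range(nstep):
        vs = v[0]
        if step == nstep - 1:
            for i in range(ncomp):
                vold[i] = v[i]
        # --- gate update (exponential Euler at frozen voltage) ---
        pos = (vs - vmin) * inv_dv
        if pos < 0.0:
            pos = 0.0
        elif pos > nv - 1.001:
            pos = nv - 1.001
        j = int(pos)
        w = pos - j
        for g in range(nvg):
            inf = vg_inf[g, j] * (1.0 - w) + vg_inf[g, j + 1] * w
            tau = vg_tau[g, j] * (1.0 - w) + vg_tau[g, j + 1] * w
            s = vg_state[g]
            x = gates[s] + (inf - gates[s]) * (1.0 - np.exp(-dt / tau))
            gates[s] = x
            if x < gate_lo[s]:
                gate_lo[s] = x
            if x > gate_hi[s]:
                gate_hi[s] = x
        for k in range(nchan):
            if chan_sk[k] == 1:
                s = sk_state[k]
                zinf = 1.0 / (1.0 + (sk_cahalf[k] / ca) ** sk_hill[k])
                x = gates[s] + (zinf - gates[s]) * (1.0 - np.exp(-dt / sk_tau[k]))
                gates[s] = x
                if x < gate_lo[s]:
                    gate_lo[s] = x
                if x > gate_hi[s]:
                    gate_hi[s] = x

        # --- channel conductances (soma) ---
        gsum = 0.0
        gesum = 0.0
        for k in range(nchan):
            gk[k] = chan_g[k]
        for g in range(nvg):
            x = gates[vg_state[g]]
            p = vg_power[g]
            xp = x
            for _ in range(p - 1):
                xp *= x
            gk[vg_chan[g]] *= xp
        for k in range(nchan):
            if chan_sk[k] == 1:
                gk[k] *= gates[sk_state[k]]
            e = eca if chan_carev[k] == 1 else chan_e[k]
            gsum += gk[k]
            gesum += gk[k] * e

        # --- theta-method voltage solve on the tree (0.5 = CN) ---
        for i in range(ncomp):
            ax[i] = 0.0
        for i in range(1, ncomp):
            p = parent[i]
            flux = ga[i] * (v[i] - v[p])
            ax[i] += flux
            ax[p] -= flux
        for i in range(ncomp):
            d[i] = diag0[i]
            rhs[i] = cdt[i] * v[i] + gpas[i] * (epas[i] - omt * v[i]) \
                - omt * ax[i]
        d[0] += theta * gsum
        rhs[0] += gesum - omt * gsum * v[0]
        rhs[stim_comp] += istim[step]
        if clamp == 1:
            d[0] += gclamp
            rhs[0] += gclamp * vcmd[step]
        for i in range(ncomp - 1, 0, -1):
            f = gat[i] / d[i]
            p = parent[i]
            d[p] -= f * gat[i]
            rhs[p] += f * rhs[i]
        vnew0 = rhs[0] / d[0]
        v[0] = vnew0
        for i in range(1, ncomp):
            v[i] = (rhs[i] + gat[i] * v[parent[i]]) / d[i]

        # --- calcium shell update (exact for the linear ODE) ---
        vmid0 = 0.5 * (vs + vnew0)
        ica = 0.0
        for k in range(nchan):
            if chan_cacur[k] == 1:
                ica += gk[k] * (vmid0 - eca)
        ca_inf = carest - ica * cafac * catau
        ca = ca_inf + (ca - ca_inf) * np.exp(-dt / catau)
        if ca < ca_floor:
            ca = ca_floor
        eca = eca_fac * np.log(ca_ext / ca)

        # --- recording ---
        if step % rec_every == 0:
            vout[irec] = vnew0
            if clamp == 1:
                iclamp_out[irec] = gclamp * (vcmd[step] - vnew0)
            if per_chan == 1:
                for k in range(nchan):
                    e = eca if chan_carev[k] == 1 else chan_e[k]
                    ichan_out[k, irec] = gk[k] * (vnew0 - e)
            irec += 1
        if step == nstep - 1:
            m = 0.0
            for i in range(ncomp):
                dvi = abs(v[i] - vold[i]) / dt
                if dvi > m:
                    m = dvi
            dv_last[0] = m

    return ca
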