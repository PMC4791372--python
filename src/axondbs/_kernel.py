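"""Numba kernel: implicit integration of the double-cable axon.

Unknowns per compartment are the intracellular potential Vi and the
periaxonal potential W (both referenced to distant ground); the axolemma
transmembrane potential is Vm = Vi - W. Backward Euler couples the two
longitudinal cables into a block-tridiagonal system with 2x2 blocks whose
off-diagonal blocks are diagonal, solved each step by block Thomas
elimination (no pivoting; the system is diagonally dominant). Nodal gating
is advanced staggered with the voltage solve: deterministically with
exact-exponential (Rush-Larsen) updates, or stochastically with
competing-risk binomial Markov transitions and automatic sub-stepping.

All quantities use the package unit system: mV, ms, uS, nF, nA.
"""

import numpy as np
from numba import njit

# Q10-corrected rate constants at 36 C (mirrors fiber.gating_rates).
Q10_MP = 2.2 ** 1.6
Q10_H = 2.9 ** 1.6
Q10_S = 1.0


@njit(cache=True, fastmath=True, inline="always")
def _clamp_v(v):
    """Clamp the potential used for rate evaluation. Beyond +-(150, 250) mV
    every gate is saturated; the clamp only prevents exp over/underflow when
    extreme stimulus artifacts drive the local potential to volts."""
    if v > 150.0:
        return 150.0
    if v < -250.0:
        return -250.0
    return v


@njit(cache=True, fastmath=True, inline="always")
def _vtrap(a, x, s):
    if abs(x) < 1e-7:
        return a * s
    return a * x / (1.0 - np.exp(-x / s))


@njit(cache=True, fastmath=True, inline="always")
def _rates_m(v):
    v = _clamp_v(v)
    am = Q10_MP * _vtrap(6.57, v + 20.4, 10.3)
    bm = Q10_MP * _vtrap(0.304, -(v + 25.7), 9.16)
    return am, bm


@njit(cache=True, fastmath=True, inline="always")
def _rates_h(v):
    v = _clamp_v(v)
    ah = Q10_H * _vtrap(0.34, -(v + 114.0), 11.0)
    bh = Q10_H * 12.6 / (1.0 + np.exp(-(v + 31.8) / 13.4))
    return ah, bh


@njit(cache=True, fastmath=True, inline="always")
def _rates_p(v):
    v = _clamp_v(v)
    ap = Q10_MP * _vtrap(0.0353, v + 27.0, 10.2)
    bp = Q10_MP * _vtrap(0.000883, -(v + 34.0), 10.0)
    return ap, bp


@njit(cache=True, fastmath=True, inline="always")
def _rates_s(v):
    v = _clamp_v(v)
    as_ = Q10_S * 0.3 / (1.0 + np.exp((v + 53.0) / -5.0))
    bs = Q10_S * 0.03 / (1.0 + np.exp((v + 90.0) / -1.0))
    return as_, bs


@njit(cache=True, fastmath=True, inline="always")
def _rl_update(x, a, b, dt):
    """Exact exponential relaxation of a gate over dt at fixed rates."""
    tau = 1.0 / (a + b)
    xinf = a * tau
    return xinf + (x - xinf) * np.exp(-dt / tau)


@njit(cache=True)
def _binom(n, p):
    if n <= 0:
        return 0
    if p >= 1.0:
        return n
    if p <= 0.0:
        return 0
    mean = n * p
    var = mean * (1.0 - p)
    if var > 100.0:
        # Gaussian approximation for large-count draws (tau-leaping style);
        # relative error O(1/sqrt(var)) is negligible at these counts
        k = int(round(mean + np.sqrt(var) * np.random.standard_normal()))
        if k < 0:
            k = 0
        elif k > n:
            k = n
        return k
    return np.random.binomial(n, p)


@njit(cache=True)
def _na_markov_node(states, v, dt, max_substeps):
    """Advance one node's 8-state Na population by dt. states: int64[8]."""
    am, bm = _rates_m(v)
    ah, bh = _rates_h(v)
    # substep count from the largest total exit rate among OCCUPIED states
    max_rate = 0.0
    for idx in range(8):
        if states[idx] > 0:
            hi = idx // 4
            mi = idx - 4 * hi
            r = (3 - mi) * am + mi * bm + (ah if hi == 0 else bh)
            if r > max_rate:
                max_rate = r
    n_sub = int(np.ceil(max_rate * dt / 0.5))
    if n_sub < 1:
        n_sub = 1
    if n_sub > max_substeps:
        raise ValueError("dt too large for stochastic Na gating")
    h = dt / n_sub
    moved = np.zeros(8, dtype=np.int64)
    for _ in range(n_sub):
        for i in range(8):
            moved[i] = 0
        for idx in range(8):
            hi = idx // 4
            mi = idx - 4 * hi
            n_here = states[idx]
            if n_here == 0:
                continue
            r_up = (3 - mi) * am if mi < 3 else 0.0
            r_dn = mi * bm
            r_h = ah if hi == 0 else bh
            total = r_up + r_dn + r_h
            if total <= 0.0:
                continue
            p_leave = -np.expm1(-total * h)
            n_leave = _binom(n_here, p_leave)
            if n_leave == 0:
                continue
            # split leavers among destinations by competing rates
            n_up = _binom(n_leave, r_up / total) if r_up > 0.0 else 0
            rest = n_leave - n_up
            rem = total - r_up
            n_dn = _binom(rest, r_dn / rem) if (rest > 0 and r_dn > 0.0) else 0
            n_hf = rest - n_dn
            if n_up > 0:
                moved[4 * hi + mi + 1] += n_up
            if n_dn > 0:
                moved[4 * hi + mi - 1] += n_dn
            if n_hf > 0:
                moved[4 * (1 - hi) + mi] += n_hf
            moved[idx] -= n_leave
        for i in range(8):
            states[i] += moved[i]


@njit(cache=True)
def _k_markov_node(states, v, dt, max_substeps):
    as_, bs = _rates_s(v)
    max_rate = max(as_, bs)
    n_sub = int(np.ceil(max_rate * dt / 0.5))
    if n_sub < 1:
        n_sub = 1
    if n_sub > max_substeps:
        raise ValueError("dt too large for stochastic K gating")
    h = dt / n_sub
    for _ in range(n_sub):
        opened = _binom(states[0], -np.expm1(-as_ * h))
        closed = _binom(states[1], -np.expm1(-bs * h))
        states[0] += closed - opened
        states[1] += opened - closed


@njit(cache=True, fastmath=True)
def integrate(
    # per-compartment coefficients (n_comp)
    a_cax_dt,      # A_ax * c_ax / dt                [uS]
    g_pas_abs,     # passive axolemma conductance    [uS] (0 at nodes)
    b_pas_abs,     # g_pas_abs * e_pas               [nA]
    amy_cmy_dt,    # A_my * c_my / dt                [uS] (0 at nodes)
    g_my_abs,      # myelin conductance              [uS] (clamp at nodes)
    ga,            # intracellular axial cond i<->i+1 [uS] (n_comp-1)
    gp,            # periaxonal axial cond i<->i+1   [uS] (n_comp-1)
    node_comp,     # compartment index of each node  (n_nodes)
    # nodal channel parameters (absolute, uS)
    gnaf_abs, gnap_abs, gks_abs, glk_abs,
    e_na, e_k, e_lk,
    # state (modified in place)
    vi, w, gm, gh, gp_gate, gs,
    # stochastic machinery
    stochastic,           # 0 deterministic, 1 stochastic Na/K
    na_states, k_states,  # int64 (n_nodes, 8), (n_nodes, 2)
    gamma_na, gamma_k,    # single-channel conductance [uS]
    seed,
    # drive
    phi_unit,      # extracellular mV per mA at each compartment
    stim_ma,       # per-step stimulus current (n_steps)
    inj_na,        # per-step intracellular current (n_steps)
    inj_comp,
    dt,
    rec_comp,      # compartments whose Vm is recorded (n_rec)
    v_rec,         # output (n_rec, n_steps + 1)
):
    n_comp = vi.shape[0]
    n_nodes = node_comp.shape[0]
    n_steps = stim_ma.shape[0]
    max_substeps = 100000

    if stochastic == 1:
        np.random.seed(seed)

    # work arrays for block Thomas
    d11 = np.empty(n_comp)
    d12 = np.empty(n_comp)
    d21 = np.empty(n_comp)
    d22 = np.empty(n_comp)
    r1 = np.empty(n_comp)
    r2 = np.empty(n_comp)
    g_ion = np.empty(n_comp)
    b_ion = np.empty(n_comp)

    for j in range(rec_comp.shape[0]):
        v_rec[j, 0] = vi[rec_comp[j]] - w[rec_comp[j]]

    stim_prev = 0.0
    for step in range(n_steps):
        stim_now = stim_ma[step]

        # --- gating update at Vm from the previous step (staggered) ---
        for i in range(n_comp):
            g_ion[i] = g_pas_abs[i]
            b_ion[i] = b_pas_abs[i]
        for nidx in range(n_nodes):
            c = node_comp[nidx]
            vm = vi[c] - w[c]
            ap, bp = _rates_p(vm)
            gp_gate[nidx] = _rl_update(gp_gate[nidx], ap, bp, dt)
            if stochastic == 0:
                am, bm = _rates_m(vm)
                ah, bh = _rates_h(vm)
                as_, bs = _rates_s(vm)
                gm[nidx] = _rl_update(gm[nidx], am, bm, dt)
                gh[nidx] = _rl_update(gh[nidx], ah, bh, dt)
                gs[nidx] = _rl_update(gs[nidx], as_, bs, dt)
                gna = gnaf_abs * gm[nidx] ** 3 * gh[nidx]
                gk = gks_abs * gs[nidx]
            else:
                _na_markov_node(na_states[nidx], vm, dt, max_substeps)
                _k_markov_node(k_states[nidx], vm, dt, max_substeps)
                gna = gamma_na * na_states[nidx, 7]
                gk = gamma_k * k_states[nidx, 1]
            gnap = gnap_abs * gp_gate[nidx] ** 3
            g_ion[c] = gna + gnap + gk + glk_abs
            b_ion[c] = (gna + gnap) * e_na + gk * e_k + glk_abs * e_lk

        # --- assemble and solve the 2x2 block tridiagonal system ---
        for i in range(n_comp):
            alpha = a_cax_dt[i] + g_ion[i]
            beta = amy_cmy_dt[i] + g_my_abs[i]
            sga = 0.0
            sgp = 0.0
            if i > 0:
                sga += ga[i - 1]
                sgp += gp[i - 1]
            if i < n_comp - 1:
                sga += ga[i]
                sgp += gp[i]
            vm_old = vi[i] - w[i]
            ve_new = phi_unit[i] * stim_now
            ve_old = phi_unit[i] * stim_prev
            rhs1 = a_cax_dt[i] * vm_old + b_ion[i]
            rhs2 = (-(a_cax_dt[i] * vm_old + b_ion[i])
                    + amy_cmy_dt[i] * (w[i] + ve_new - ve_old)
                    + g_my_abs[i] * ve_new)
            d11[i] = alpha + sga
            d12[i] = -alpha
            d21[i] = -alpha
            d22[i] = alpha + sgp + beta
            r1[i] = rhs1
            r2[i] = rhs2
        r1[inj_comp] += inj_na[step]

        # forward elimination: D_i -= A_i D_{i-1}^{-1} C_{i-1}
        for i in range(1, n_comp):
            det = d11[i - 1] * d22[i - 1] - d12[i - 1] * d21[i - 1]
            inv11 = d22[i - 1] / det
            inv12 = -d12[i - 1] / det
            inv21 = -d21[i - 1] / det
            inv22 = d11[i - 1] / det
            ai1 = -ga[i - 1]   # row 1 coupling (Vi)
            ai2 = -gp[i - 1]   # row 2 coupling (W)
            # F = A_i * inv(D_{i-1}) ; A_i = diag(ai1, ai2)
            f11 = ai1 * inv11
            f12 = ai1 * inv12
            f21 = ai2 * inv21
            f22 = ai2 * inv22
            # C_{i-1} = diag(-ga[i-1], -gp[i-1])
            d11[i] -= f11 * ai1
            d12[i] -= f12 * ai2
            d21[i] -= f21 * ai1
            d22[i] -= f22 * ai2
            r1[i] -= f11 * r1[i - 1] + f12 * r2[i - 1]
            r2[i] -= f21 * r1[i - 1] + f22 * r2[i - 1]

        # back substitution
        i = n_comp - 1
        det = d11[i] * d22[i] - d12[i] * d21[i]
        vi[i] = (d22[i] * r1[i] - d12[i] * r2[i]) / det
        w[i] = (d11[i] * r2[i] - d21[i] * r1[i]) / det
        for i in range(n_comp - 2, -1, -1):
            rr1 = r1[i] + ga[i] * vi[i + 1]
            rr2 = r2[i] + gp[i] * w[i + 1]
            det = d11[i] * d22[i] - d12[i] * d21[i]
            vi[i] = (d22[i] * rr1 - d12[i] * rr2) / det
            w[i] = (d11[i] * rr2 - d21[i] * rr1) / det

        if not (-1.0e7 < vi[0] < 1.0e7):
            raise ValueError("integration diverged (non-finite state)")

        for j in range(rec_comp.shape[0]):
            v_rec[j, step + 1] = vi[rec_comp[j]] - w[rec_comp[j]]
        stim_prev = stim_now
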