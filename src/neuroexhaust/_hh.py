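"""Fixed-step RK4 integrator for the single-compartment conductance model.

Membrane equation (units: mV, ms, pA, pF, nS):

    C_m dV/dt = -rho*g_Na*m^3*h*s*(V-E_Na) - g_K*n^4*(V-E_K)
                - g_L*(V-E_L) + I_inj + noise

Fast gates m, h, n follow the classic squid-axon rate functions evaluated
at ``v = V - v_shift`` (v_shift default -60 mV places rest near -65 mV).
The slow sodium-availability gate s has a sigmoidal steady state
``s_inf(V) = 1/(1+exp((V-V_s)/k_s))`` and a voltage-dependent time
constant ``tau(V) = tau_entry + (tau_rec - tau_entry) * s_inf(V)``:
entry into unavailability is fast at depolarised potentials (tau_entry),
recovery at rest is slow (tau_rec). Cumulative loss of s during a 2-s
spike train is what produces action-potential attenuation.

Everything here is numba-compiled; the public wrappers live in
:mod:`neuroexhaust.synth`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# params vector layout (float64[:]):
# 0 C_m, 1 g_Na, 2 rho, 3 g_K, 4 g_L, 5 E_Na, 6 E_K, 7 E_L,
# 8 v_shift, 9 V_s, 10 k_s, 11 tau_s (recovery), 12 tau_s_entry,
# 13 noise_sigma (pA), 14 rate_scale (temperature-like factor on m,h,n rates)
N_PARAMS = 15


@njit(cache=False)
def _vtrap(x: float, y: float) -> float:
    # x / (exp(x/y) - 1) with the removable singularity at x = 0
    if abs(x / y) < 1e-6:
        return y * (1.0 - x / (2.0 * y))
    return x / (np.exp(x / y) - 1.0)


@njit(cache=False)
def _rates(V: float, v_shift: float, phi: float):
    # Classic squid-axon rate forms with per-gate voltage offsets (fast
    # spiking variant): h is shifted +2 mV and n +16 mV relative to m; the
    # temperature-like factor phi speeds all three gates. With
    # v_shift = -60 this is the standard fast-spiking parameterisation
    # whose rest sits near -65 mV and which fires repetitively from a low
    # rheobase (class 1 excitability).
    v = V - v_shift
    a_m = phi * 0.1 * _vtrap(25.0 - v, 10.0)
    b_m = phi * 4.0 * np.exp(-v / 18.0)
    vh = v - 2.0
    a_h = phi * 0.07 * np.exp(-vh / 20.0)
    b_h = phi / (np.exp((30.0 - vh) / 10.0) + 1.0)
    vn = v - 16.0
    a_n = phi * 0.01 * _vtrap(10.0 - vn, 10.0)
    b_n = phi * 0.125 * np.exp(-vn / 80.0)
    return a_m, b_m, a_h, b_h, a_n, b_n


@njit(cache=False)
def _s_inf(V: float, V_s: float, k_s: float) -> float:
    return 1.0 / (1.0 + np.exp((V - V_s) / k_s))


@njit(cache=False)
def _deriv(V, m, h, n, s, I_inj, p):
    a_m, b_m, a_h, b_h, a_n, b_n = _rates(V, p[8], p[14])
    si = _s_inf(V, p[9], p[10])
    tau_s = p[12] + (p[11] - p[12]) * si
    i_na = p[2] * p[1] * m * m * m * h * s * (V - p[5])
    i_k = p[3] * n * n * n * n * (V - p[6])
    i_l = p[4] * (V - p[7])
    dV = (-i_na - i_k - i_l + I_inj) / p[0]
    dm = a_m * (1.0 - m) - b_m * m
    dh = a_h * (1.0 - h) - b_h * h
    dn = a_n * (1.0 - n) - b_n * n
    ds = (si - s) / tau_s
    return dV, dm, dh, dn, ds


@njit(cache=False)
def _rk4_step(V, m, h, n, s, I_inj, dt, p):
    k1 = _deriv(V, m, h, n, s, I_inj, p)
    k2 = _deriv(V + 0.5 * dt * k1[0], m + 0.5 * dt * k1[1], h + 0.5 * dt * k1[2],
                n + 0.5 * dt * k1[3], s + 0.5 * dt * k1[4], I_inj, p)
    k3 = _deriv(V + 0.5 * dt * k2[0], m + 0.5 * dt * k2[1], h + 0.5 * dt * k2[2],
                n + 0.5 * dt * k2[3], s + 0.5 * dt * k2[4], I_inj, p)
    k4 = _deriv(V + dt * k3[0], m + dt * k3[1], h + dt * k3[2],
                n + dt * k3[3], s + dt * k3[4], I_inj, p)
    V += dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
    m += dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
    h += dt / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
    n += dt / 6.0 * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])
    s += dt / 6.0 * (k1[4] + 2 * k2[4] + 2 * k3[4] + k4[4])
    return V, m, h, n, s


@njit(cache=False)
def _steady_gates(V: float, p):
    a_m, b_m, a_h, b_h, a_n, b_n = _rates(V, p[8], p[14])
    m = a_m / (a_m + b_m)
    h = a_h / (a_h + b_h)
    n = a_n / (a_n + b_n)
    s = _s_inf(V, p[9], p[10])
    return m, h, n, s


@njit(cache=False)
def integrate_cc_sweep(p, I_hold, I_step, n_pre, n_step, n_post, n_settle,
                       dt, record_every, seed):
    """Integrate one current-clamp sweep; returns (V_rec, n_spikes, ok).

    The model is settled at I_hold for ``n_settle`` steps before recording.
    Spike truth log: upward crossings of V through -10 mV separated by at
    least 2 ms, counted at integration resolution during the step.
    ``ok`` is False if the state left the stable range (reduce dt).
    """
    np.random.seed(seed)
    V = -65.0
    m, h, n, s = _steady_gates(V, p)
    # settle to the model's resting state (no noise during settling)
    for _ in range(n_settle):
        V, m, h, n, s = _rk4_step(V, m, h, n, s, I_hold, dt, p)
    s = _s_inf(V, p[9], p[10])  # fully rested: slow gate at steady state
    total = n_pre + n_step + n_post
    n_rec = total // record_every
    out = np.empty(n_rec, dtype=np.float64)
    sigma = p[13]
    refractory_steps = int(2.0 / dt)
    n_spikes = 0
    last_cross = -refractory_steps - 1
    prev_V = V
    ok = True
    irec = 0
    for i in range(total):
        if i < n_pre:
            I = I_hold
        elif i < n_pre + n_step:
            I = I_step
        else:
            I = I_hold
        if sigma > 0.0:
            I += sigma * np.random.randn()
        if i % record_every == 0 and irec < n_rec:
            out[irec] = V
            irec += 1
        V, m, h, n, s = _rk4_step(V, m, h, n, s, I, dt, p)
        if not np.isfinite(V) or abs(V) > 250.0:
            ok = False
            break
        if prev_V < -10.0 <= V and (i - last_cross) > refractory_steps:
            n_spikes += 1
            last_cross = i
        prev_V = V
    return out, n_spikes, ok


@njit(cache=False)
def integrate_vc_sweep(p, V_hold, V_step, n_pre, n_step, n_post,
                       dt, record_every):
    """Integrate gating at the clamped command; returns (I_rec, peak_inward, ok).

    Recorded current is ionic + leak in pA. ``peak_inward`` is the most
    negative baseline-subtracted current during the step at integration
    resolution (baseline = holding-state current), embedded as ground truth.
    """
    m, h, n, s = _steady_gates(V_hold, p)  # fully rested at holding
    total = n_pre + n_step + n_post
    n_rec = total // record_every
    out = np.empty(n_rec, dtype=np.float64)
    ok = True
    irec = 0
    peak_inward = 0.0
    baseline = (p[2] * p[1] * m ** 3 * h * s * (V_hold - p[5])
                + p[3] * n ** 4 * (V_hold - p[6]) + p[4] * (V_hold - p[7]))
    for i in range(total):
        if n_pre <= i < n_pre + n_step:
            V = V_step
        else:
            V = V_hold
        I = (p[2] * p[1] * m ** 3 * h * s * (V - p[5])
             + p[3] * n ** 4 * (V - p[6]) + p[4] * (V - p[7]))
        if i % record_every == 0 and irec < n_rec:
            out[irec] = I
            irec += 1
        if n_pre <= i < n_pre + n_step and (I - baseline) < peak_inward:
            peak_inward = I - baseline
        # gate kinetics at the clamped potential (dV/dt = 0)
        a_m, b_m, a_h, b_h, a_n, b_n = _rates(V, p[8], p[14])
        si = _s_inf(V, p[9], p[10])
        tau_s = p[12] + (p[11] - p[12]) * si
        # exponential update of the linear gate ODEs at fixed V (exact)
        tm = 1.0 / (a_m + b_m)
        th = 1.0 / (a_h + b_h)
        tn = 1.0 / (a_n + b_n)
        m = a_m * tm + (m - a_m * tm) * np.exp(-dt / tm)
        h = a_h * th + (h - a_h * th) * np.exp(-dt / th)
        n = a_n * tn + (n - a_n * tn) * np.exp(-dt / tn)
        s = si + (s - si) * np.exp(-dt / tau_s)
        if not np.isfinite(I):
            ok = False
            break
    return out, peak_inward, ok
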