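"""Numba-compiled inner loops for the Monte Carlo simulators.

All kernels take plain scalars/arrays so they compile in nopython mode.
Randomness uses numba's internal NumPy-compatible generator, seeded inside
each kernel for bit-reproducibility.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, inline="always")
def _drift(x1, x2, a, b, c, f, e2s_f, e4sg, e2fg):
    d1 = x1 * (a - b * x2 - e2s_f * (f * x1 - c))
    d2 = x2 * ((-c + f * x1) * (1.0 + e4sg * x1)
               + e2fg * x1 * (b * x2 - a))
    return d1, d2


@njit(cache=True, inline="always")
def _rk4(x1, x2, h, a, b, c, f, e2s_f, e4sg, e2fg):
    k11, k12 = _drift(x1, x2, a, b, c, f, e2s_f, e4sg, e2fg)
    k21, k22 = _drift(x1 + 0.5 * h * k11, x2 + 0.5 * h * k12,
                      a, b, c, f, e2s_f, e4sg, e2fg)
    k31, k32 = _drift(x1 + 0.5 * h * k21, x2 + 0.5 * h * k22,
                      a, b, c, f, e2s_f, e4sg, e2fg)
    k41, k42 = _drift(x1 + h * k31, x2 + h * k32,
                      a, b, c, f, e2s_f, e4sg, e2fg)
    x1n = x1 + h / 6.0 * (k11 + 2.0 * k21 + 2.0 * k31 + k41)
    x2n = x2 + h / 6.0 * (k12 + 2.0 * k22 + 2.0 * k32 + k42)
    return x1n, x2n


@njit(cache=True)
def poisson_marcus(seed, t_max, dt, x1_0, x2_0,
                   a, b, c, f, e2s_f, e4sg, e2fg,
                   lam1, lam2, sig1, sig2, eps, thin, max_pulses):
    """Event-driven jump simulation: exact multiplicative pulse response.

    Between pulses the noise-free drift is advanced with fixed-step RK4;
    at a channel-i arrival the state jumps ``X_i -> X_i exp(eps Y)``.
    Returns thinned (times, x1, x2), the pulse log, and the pulse counts.
    """
    np.random.seed(seed)
    n_steps = int(t_max / dt) + 1
    n_store = n_steps // thin + 2
    ts = np.empty(n_store)
    xs1 = np.empty(n_store)
    xs2 = np.empty(n_store)
    p_t = np.empty(max_pulses)
    p_ch = np.empty(max_pulses, dtype=np.int8)
    p_amp = np.empty(max_pulses)

    x1, x2 = x1_0, x2_0
    t = 0.0
    t1 = np.random.exponential(1.0 / lam1) if lam1 > 0 else 2.0 * t_max
    t2 = np.random.exponential(1.0 / lam2) if lam2 > 0 else 2.0 * t_max
    k_store = 0
    k_pulse = 0
    step_count = 0
    ts[0] = 0.0
    xs1[0] = x1
    xs2[0] = x2
    k_store = 1

    while t < t_max:
        t_event = t1 if t1 < t2 else t2
        t_stop = t_event if t_event < t_max else t_max
        # fixed steps to t_stop (final partial step)
        while t < t_stop - 1e-12:
            h = dt if t + dt <= t_stop else t_stop - t
            x1, x2 = _rk4(x1, x2, h, a, b, c, f, e2s_f, e4sg, e2fg)
            t += h
            if not (np.isfinite(x1) and np.isfinite(x2)):
                return (ts[:k_store], xs1[:k_store], xs2[:k_store],
                        p_t[:k_pulse], p_ch[:k_pulse], p_amp[:k_pulse], -t)
            if h == dt:
                step_count += 1
                if step_count % thin == 0 and k_store < n_store:
                    ts[k_store] = t
                    xs1[k_store] = x1
                    xs2[k_store] = x2
                    k_store += 1
        if t_event >= t_max:
            break
        if t1 < t2:
            y = sig1 * np.random.standard_normal()
            x1 *= np.exp(eps * y)
            ch = 1
            t1 += np.random.exponential(1.0 / lam1)
        else:
            y = sig2 * np.random.standard_normal()
            x2 *= np.exp(eps * y)
            ch = 2
            t2 += np.random.exponential(1.0 / lam2)
        if k_pulse < max_pulses:
            p_t[k_pulse] = t
            p_ch[k_pulse] = ch
            p_amp[k_pulse] = y
            k_pulse += 1

    return (ts[:k_store], xs1[:k_store], xs2[:k_store],
            p_t[:k_pulse], p_ch[:k_pulse], p_amp[:k_pulse], t)


@njit(cache=True, inline="always")
def _tri_forcing(t, p_t, p_amp, dt, j0, n):
    """Sum of active triangular pulses (base 2*dt, unit impulse each) at t."""
    w = 0.0
    j = j0
    while j < n and p_t[j] <= t + dt:
        d = t - p_t[j]
        if -dt < d < dt:
            w += p_amp[j] * (1.0 - abs(d) / dt) / dt
        j += 1
    return w


@njit(cache=True)
def poisson_triangular(t_max, dt, x1_0, x2_0,
                       a, b, c, f, e2s_f, e4sg, e2fg,
                       p1_t, p1_amp, p2_t, p2_amp, eps, thin, floor):
    """Fixed-step RK4 with each pulse spread as a triangular impulse.

    Pulse trains are pre-drawn (sorted arrival times and amplitudes per
    channel); each pulse of amplitude Y is applied as a triangular forcing
    of base ``2 dt`` and impulse ``eps Y`` entering multiplicatively.
    States are clamped at ``floor`` with an incident counter.
    """
    n_steps = int(round(t_max / dt))
    n_store = n_steps // thin + 2
    ts = np.empty(n_store)
    xs1 = np.empty(n_store)
    xs2 = np.empty(n_store)
    x1, x2 = x1_0, x2_0
    ts[0] = 0.0
    xs1[0] = x1
    xs2[0] = x2
    k_store = 1
    j1 = 0
    j2 = 0
    n1 = p1_t.size
    n2 = p2_t.size
    clamped = 0

    for step in range(n_steps):
        t = step * dt
        while j1 < n1 and p1_t[j1] < t - dt:
            j1 += 1
        while j2 < n2 and p2_t[j2] < t - dt:
            j2 += 1
        # RK4 with time-dependent forcing X_i * eps * w_i(t)
        w1a = eps * _tri_forcing(t, p1_t, p1_amp, dt, j1, n1)
        w2a = eps * _tri_forcing(t, p2_t, p2_amp, dt, j2, n2)
        w1b = eps * _tri_forcing(t + 0.5 * dt, p1_t, p1_amp, dt, j1, n1)
        w2b = eps * _tri_forcing(t + 0.5 * dt, p2_t, p2_amp, dt, j2, n2)
        w1c = eps * _tri_forcing(t + dt, p1_t, p1_amp, dt, j1, n1)
        w2c = eps * _tri_forcing(t + dt, p2_t, p2_amp, dt, j2, n2)
        k11, k12 = _drift(x1, x2, a, b, c, f, e2s_f, e4sg, e2fg)
        k11 += x1 * w1a
        k12 += x2 * w2a
        y1 = x1 + 0.5 * dt * k11
        y2 = x2 + 0.5 * dt * k12
        k21, k22 = _drift(y1, y2, a, b, c, f, e2s_f, e4sg, e2fg)
        k21 += y1 * w1b
        k22 += y2 * w2b
        y1 = x1 + 0.5 * dt * k21
        y2 = x2 + 0.5 * dt * k22
        k31, k32 = _drift(y1, y2, a, b, c, f, e2s_f, e4sg, e2fg)
        k31 += y1 * w1b
        k32 += y2 * w2b
        y1 = x1 + dt * k31
        y2 = x2 + dt * k32
        k41, k42 = _drift(y1, y2, a, b, c, f, e2s_f, e4sg, e2fg)
        k41 += y1 * w1c
        k42 += y2 * w2c
        x1 = x1 + dt / 6.0 * (k11 + 2.0 * k21 + 2.0 * k31 + k41)
        x2 = x2 + dt / 6.0 * (k12 + 2.0 * k22 + 2.0 * k32 + k42)
        if x1 < floor:
            x1 = floor
            clamped += 1
        if x2 < floor:
            x2 = floor
            clamped += 1
        if not (np.isfinite(x1) and np.isfinite(x2)):
            return ts[:k_store], xs1[:k_store], xs2[:k_store], -(t + dt), clamped
        if (step + 1) % thin == 0 and k_store < n_store:
            ts[k_store] = t + dt
            xs1[k_store] = x1
            xs2[k_store] = x2
            k_store += 1

    return ts[:k_store], xs1[:k_store], xs2[:k_store], t_max, clamped


@njit(cache=True)
def gaussian_heun(seed, t_max, dt, x1_0, x2_0,
                  a, b, c, f, e2s_f, e4sg, e2fg,
                  D1, D2, thin):
    """Stratonovich multiplicative Gaussian noise on the log-populations.

    In log coordinates the multiplicative noise is exactly additive (the
    Stratonovich chain rule holds), so each step adds a Gaussian increment
    of variance ``D_i dt`` to ``ln X_i`` while the drift is advanced with
    the Heun predictor-corrector.
    """
    np.random.seed(seed)
    n_steps = int(round(t_max / dt))
    n_store = n_steps // thin + 2
    ts = np.empty(n_store)
    xs1 = np.empty(n_store)
    xs2 = np.empty(n_store)
    u1 = np.log(x1_0)
    u2 = np.log(x2_0)
    ts[0] = 0.0
    xs1[0] = x1_0
    xs2[0] = x2_0
    k_store = 1
    s1 = np.sqrt(D1 * dt)
    s2 = np.sqrt(D2 * dt)

    for step in range(n_steps):
        x1 = np.exp(u1)
        x2 = np.exp(u2)
        g1 = a - b * x2 - e2s_f * (f * x1 - c)
        g2 = ((-c + f * x1) * (1.0 + e4sg * x1)
              + e2fg * x1 * (b * x2 - a))
        dw1 = s1 * np.random.standard_normal()
        dw2 = s2 * np.random.standard_normal()
        v1 = u1 + dt * g1 + dw1
        v2 = u2 + dt * g2 + dw2
        y1 = np.exp(v1)
        y2 = np.exp(v2)
        h1 = a - b * y2 - e2s_f * (f * y1 - c)
        h2 = ((-c + f * y1) * (1.0 + e4sg * y1)
              + e2fg * y1 * (b * y2 - a))
        u1 = u1 + 0.5 * dt * (g1 + h1) + dw1
        u2 = u2 + 0.5 * dt * (g2 + h2) + dw2
        if not (np.isfinite(u1) and np.isfinite(u2)):
            return ts[:k_store], xs1[:k_store], xs2[:k_store], -(step * dt)
        if (step + 1) % thin == 0 and k_store < n_store:
            ts[k_store] = (step + 1) * dt
            xs1[k_store] = np.exp(u1)
            xs2[k_store] = np.exp(u2)
            k_store += 1

    return ts[:k_store], xs1[:k_store], xs2[:k_store], t_max
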