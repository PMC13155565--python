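"""Numba kernel advancing a whole pool; mirrors model.advance_state.

Gate ODEs are linear with piecewise-constant (pulse-switched) rates, so gate
values at the RK4 stage times are obtained from precomputed exponential decay
factors; only the two compartment voltages are advanced by RK4.  Per-unit
Gaussian noise is drawn inside the kernel from a single seeded stream in
fixed (step, unit) order, which makes runs bit-reproducible.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def integrate_pool(dt_ms, n_steps,
                   c_s_nF, c_d_nF, g_c, g_ls, g_ld,
                   g_na, g_kf, g_ks, g_ca,
                   e_na, e_kf, e_ks, e_ca, e_exc, e_inh,
                   g_exc_scale, g_inh_scale, v_th,
                   exc_trace, inh_trace,
                   noise_sd, tau_noise_ms, seed,
                   pulse_ms, am, bm, ah, bh, an, bn, aq, bq, bp,
                   guard_ms, max_spikes):
    """Integrate `n_units` motoneurons over `n_steps` RK4 steps.

    exc_trace / inh_trace hold the common drive sampled at step edges
    (length n_steps + 1); midpoints are linearly interpolated.  Returns
    (spike_times_ms, spike_counts, divergence_flag, divergence_unit,
    divergence_step).
    """
    n_units = c_s_nF.shape[0]
    half = dt_ms / 2.0

    # precomputed closed-form decay factors at half and full step
    em_on_h, em_on_f = np.exp(-am * half), np.exp(-am * dt_ms)
    em_off_h, em_off_f = np.exp(-bm * half), np.exp(-bm * dt_ms)
    eh_on_h, eh_on_f = np.exp(-bh * half), np.exp(-bh * dt_ms)
    eh_off_h, eh_off_f = np.exp(-ah * half), np.exp(-ah * dt_ms)
    en_on_h, en_on_f = np.exp(-an * half), np.exp(-an * dt_ms)
    en_off_h, en_off_f = np.exp(-bn * half), np.exp(-bn * dt_ms)
    eq_on_h, eq_on_f = np.exp(-aq * half), np.exp(-aq * dt_ms)
    eq_off_h, eq_off_f = np.exp(-bq * half), np.exp(-bq * dt_ms)
    ep_h, ep_f = np.exp(-bp * half), np.exp(-bp * dt_ms)

    v_s = np.zeros(n_units)
    v_d = np.zeros(n_units)
    m = np.zeros(n_units)
    h = np.ones(n_units)
    n_g = np.zeros(n_units)
    q = np.zeros(n_units)
    p = np.zeros(n_units)
    pulse_end = np.full(n_units, -1.0)
    last_spike = np.full(n_units, -1e12)

    spike_times = np.full((n_units, max_spikes), np.nan)
    spike_counts = np.zeros(n_units, dtype=np.int64)

    # Ornstein-Uhlenbeck noise per unit: exact discretisation, stationary
    # SD = noise_sd, correlation time tau_noise_ms (dt-invariant)
    eps = np.zeros(n_units)
    noise_decay = np.exp(-dt_ms / tau_noise_ms)
    noise_amp = noise_sd * np.sqrt(1.0 - noise_decay * noise_decay)

    np.random.seed(seed)
    if noise_sd > 0.0:
        for i in range(n_units):
            eps[i] = noise_sd * np.random.randn()

    for step in range(n_steps):
        t = step * dt_ms
        exc0 = exc_trace[step]
        exc1 = exc_trace[step + 1]
        exc_mid = 0.5 * (exc0 + exc1)
        inh0 = inh_trace[step]
        inh1 = inh_trace[step + 1]
        inh_mid = 0.5 * (inh0 + inh1)

        for i in range(n_units):
            if noise_sd > 0.0:
                eps[i] = eps[i] * noise_decay + noise_amp * np.random.randn()

            on = t < pulse_end[i]
            m0 = m[i]; h0 = h[i]; n0 = n_g[i]; q0 = q[i]; p0 = p[i]
            if on:
                mh = 1.0 + (m0 - 1.0) * em_on_h; mf = 1.0 + (m0 - 1.0) * em_on_f
                hh = h0 * eh_on_h;               hf = h0 * eh_on_f
                nh = 1.0 + (n0 - 1.0) * en_on_h; nf = 1.0 + (n0 - 1.0) * en_on_f
                qh = 1.0 + (q0 - 1.0) * eq_on_h; qf = 1.0 + (q0 - 1.0) * eq_on_f
            else:
                mh = m0 * em_off_h;              mf = m0 * em_off_f
                hh = 1.0 + (h0 - 1.0) * eh_off_h; hf = 1.0 + (h0 - 1.0) * eh_off_f
                nh = n0 * en_off_h;              nf = n0 * en_off_f
                qh = q0 * eq_off_h;              qf = q0 * eq_off_f
            ph = p0 * ep_h; pf = p0 * ep_f

            cs = c_s_nF[i]; cd = c_d_nF[i]
            gc = g_c[i]; gls = g_ls[i]; gld = g_ld[i]

            e0 = exc0 + eps[i]
            if e0 < 0.0:
                e0 = 0.0
            em_ = exc_mid + eps[i]
            if em_ < 0.0:
                em_ = 0.0
            e1 = exc1 + eps[i]
            if e1 < 0.0:
                e1 = 0.0
            ge0 = e0 * g_exc_scale[i]
            gem = em_ * g_exc_scale[i]
            ge1 = e1 * g_exc_scale[i]
            gi0 = inh0 * g_inh_scale[i]
            gim = inh_mid * g_inh_scale[i]
            gi1 = inh1 * g_inh_scale[i]

            gna0 = g_na[i] * m0 * m0 * m0 * h0
            gnah = g_na[i] * mh * mh * mh * hh
            gnaf = g_na[i] * mf * mf * mf * hf
            gkf0 = g_kf[i] * n0 * n0 * n0 * n0
            gkfh = g_kf[i] * nh * nh * nh * nh
            gkff = g_kf[i] * nf * nf * nf * nf
            gks0 = g_ks[i] * q0 * q0
            gksh = g_ks[i] * qh * qh
            gksf = g_ks[i] * qf * qf
            gca0 = g_ca[i] * p0
            gcah = g_ca[i] * ph
            gcaf = g_ca[i] * pf

            vs0 = v_s[i]; vd0 = v_d[i]

            # stage 1 (t, gate values at 0)
            k1s = (-gc * (vs0 - vd0) - gls * vs0
                   - gna0 * (vs0 - e_na[i]) - gkf0 * (vs0 - e_kf[i])
                   - gks0 * (vs0 - e_ks[i])) / cs
            k1d = (-gc * (vd0 - vs0) - gld * vd0
                   - gca0 * (vd0 - e_ca[i])
                   - ge0 * (vd0 - e_exc[i]) - gi0 * (vd0 - e_inh[i])) / cd
            # stage 2 (t + dt/2)
            vs = vs0 + half * k1s; vd = vd0 + half * k1d
            k2s = (-gc * (vs - vd) - gls * vs
                   - gnah * (vs - e_na[i]) - gkfh * (vs - e_kf[i])
                   - gksh * (vs - e_ks[i])) / cs
            k2d = (-gc * (vd - vs) - gld * vd
                   - gcah * (vd - e_ca[i])
                   - gem * (vd - e_exc[i]) - gim * (vd - e_inh[i])) / cd
            # stage 3 (t + dt/2)
            vs = vs0 + half * k2s; vd = vd0 + half * k2d
            k3s = (-gc * (vs - vd) - gls * vs
                   - gnah * (vs - e_na[i]) - gkfh * (vs - e_kf[i])
                   - gksh * (vs - e_ks[i])) / cs
            k3d = (-gc * (vd - vs) - gld * vd
                   - gcah * (vd - e_ca[i])
                   - gem * (vd - e_exc[i]) - gim * (vd - e_inh[i])) / cd
            # stage 4 (t + dt)
            vs = vs0 + dt_ms * k3s; vd = vd0 + dt_ms * k3d
            k4s = (-gc * (vs - vd) - gls * vs
                   - gnaf * (vs - e_na[i]) - gkff * (vs - e_kf[i])
                   - gksf * (vs - e_ks[i])) / cs
            k4d = (-gc * (vd - vs) - gld * vd
                   - gcaf * (vd - e_ca[i])
                   - ge1 * (vd - e_exc[i]) - gi1 * (vd - e_inh[i])) / cd

            vs_new = vs0 + dt_ms / 6.0 * (k1s + 2.0 * k2s + 2.0 * k3s + k4s)
            vd_new = vd0 + dt_ms / 6.0 * (k1d + 2.0 * k2d + 2.0 * k3d + k4d)

            if not (np.isfinite(vs_new) and np.isfinite(vd_new)):
                return spike_times, spike_counts, True, i, step

            t_new = t + dt_ms
            if vs0 < v_th[i] <= vs_new and t_new - last_spike[i] >= guard_ms:
                c = spike_counts[i]
                if c < max_spikes:
                    spike_times[i, c] = t_new
                spike_counts[i] = c + 1
                last_spike[i] = t_new
                pulse_end[i] = t_new + pulse_ms

            v_s[i] = vs_new
            v_d[i] = vd_new
            m[i] = min(1.0, max(0.0, mf))
            h[i] = min(1.0, max(0.0, hf))
            n_g[i] = min(1.0, max(0.0, nf))
            q[i] = min(1.0, max(0.0, qf))
            p[i] = min(1.0, max(0.0, pf))

    return spike_times, spike_counts, False, -1, -1
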