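"""Compiled (numba) inner loop for long simulations.

Semantics match one call of :func:`thetanet.core.step` followed by one call
of :func:`thetanet.plasticity.update_weights` per time step, with two
implementation shortcuts that are exercised against the reference path in
the test suite:

* the plasticity kernel ``Lambda`` is evaluated by linear interpolation in
  a precomputed table over ``[-pi, pi]`` (both provided kernels are smooth,
  so the interpolation error is far below the Euler discretisation error);
* both provided kernels are even functions of the phase difference, so each
  unordered neuron pair needs a single kernel evaluation per step.

Noise increments are supplied as a pre-drawn ``(n_steps, N)`` array of
standard normals (row = step), so the caller's ``numpy.random.Generator``
remains the single source of randomness.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: mode codes for the compiled loop
MODE_DALE = 0
MODE_UNLABELLED = 1


@njit(cache=True)
def advance(
    theta,  # (N,) phases, modified in place
    kappa,  # (N, N) weights, modified in place
    col_sign,  # (N,) +1.0 / -1.0 pre-synaptic column signs
    is_exc,  # (N,) bool, neuron is excitatory
    eta,  # (N,) excitabilities
    currents,  # (N,) external currents, constant over the call
    gate,  # (N,) bool, |I_j| > gate_threshold
    g,
    dt,
    sigma,
    eps_slow,
    eps_fast,
    eps_num,
    mode,  # MODE_DALE or MODE_UNLABELLED
    lam_table,  # (T+1,) kernel samples on [-pi, pi]
    noise,  # (n_steps, N) standard normals (unused when sigma == 0)
    step_offset,  # global step index of the first step in this call
    sample_stride,  # record phases every this many global steps (0 = never)
    phase_samples,  # (n_samples, N) output buffer
    spike_step,  # (cap,) int64 output buffer
    spike_neuron,  # (cap,) int64 output buffer
):
    """Advance ``n_steps = noise.shape[0]`` steps; returns (n_spikes, n_samples)."""
    N = theta.shape[0]
    n_steps = noise.shape[0]
    pi = np.pi
    two_pi = 2.0 * np.pi
    n_bins = lam_table.shape[0] - 1
    inv_bin = n_bins / two_pi
    sqrt_dt = np.sqrt(dt)
    cap = spike_step.shape[0]

    n_spikes = 0
    n_samples = 0
    s = np.empty(N)
    c = np.empty(N)
    drift = np.empty(N)

    for t in range(n_steps):
        for i in range(N):
            s[i] = np.sin(theta[i])
            c[i] = np.cos(theta[i])
        ks = np.dot(kappa, s)
        kc = np.dot(kappa, c)
        for i in range(N):
            coupling = (g / N) * (c[i] * ks[i] - s[i] * kc[i])
            drift[i] = (1.0 - c[i]) + (1.0 + c[i]) * (
                eta[i] + coupling + currents[i]
            )
        for i in range(N):
            old = theta[i]
            if sigma > 0.0:
                dw = noise[t, i] * sqrt_dt
                b0 = sigma * (1.0 + c[i])
                pred = old + drift[i] * dt + b0 * dw
                b1 = sigma * (1.0 + np.cos(pred))
                new = old + drift[i] * dt + 0.5 * (b0 + b1) * dw
            else:
                new = old + drift[i] * dt
            if new >= pi:
                if n_spikes < cap:
                    spike_step[n_spikes] = t
                    spike_neuron[n_spikes] = i
                n_spikes += 1
                while new >= pi:
                    new -= two_pi
            while new < -pi:
                new += two_pi
            theta[i] = new

        # weight update after the phase update, using post-update phases
        for i in range(N):
            for j in range(i + 1, N):
                d = theta[j] - theta[i]
                if d >= pi:
                    d -= two_pi
                elif d < -pi:
                    d += two_pi
                u = (d + pi) * inv_bin
                b = int(u)
                if b >= n_bins:
                    b = n_bins - 1
                frac = u - b
                lam = lam_table[b] * (1.0 - frac) + lam_table[b + 1] * frac

                if mode == MODE_DALE:
                    # dkappa/dt = eps * |kappa| (1 - |kappa|) * Lambda acts on
                    # the signed weight; clamp |kappa| into (0, 1) interior.
                    # kappa[i, j]: pre-synaptic j
                    eps = eps_slow
                    if gate[j] and is_exc[i] and is_exc[j]:
                        eps += eps_fast
                    k = kappa[i, j]
                    a = abs(k)
                    k += eps * a * (1.0 - a) * lam * dt
                    m = k * col_sign[j]
                    if m < eps_num:
                        m = eps_num
                    elif m > 1.0 - eps_num:
                        m = 1.0 - eps_num
                    kappa[i, j] = m * col_sign[j]
                    # kappa[j, i]: pre-synaptic i (kernel is even in dtheta)
                    eps = eps_slow
                    if gate[i] and is_exc[i] and is_exc[j]:
                        eps += eps_fast
                    k = kappa[j, i]
                    a = abs(k)
                    k += eps * a * (1.0 - a) * lam * dt
                    m = k * col_sign[i]
                    if m < eps_num:
                        m = eps_num
                    elif m > 1.0 - eps_num:
                        m = 1.0 - eps_num
                    kappa[j, i] = m * col_sign[i]
                else:
                    eps = eps_slow + (eps_fast if gate[j] else 0.0)
                    k = kappa[i, j]
                    k += eps * (-k + lam) * dt
                    if k < -1.0 + eps_num:
                        k = -1.0 + eps_num
                    elif k > 1.0 - eps_num:
                        k = 1.0 - eps_num
                    kappa[i, j] = k
                    eps = eps_slow + (eps_fast if gate[i] else 0.0)
                    k = kappa[j, i]
                    k += eps * (-k + lam) * dt
                    if k < -1.0 + eps_num:
                        k = -1.0 + eps_num
                    elif k > 1.0 - eps_num:
                        k = 1.0 - eps_num
                    kappa[j, i] = k

        if sample_stride > 0 and (step_offset + t + 1) % sample_stride == 0:
            if n_samples < phase_samples.shape[0]:
                for i in range(N):
                    phase_samples[n_samples, i] = theta[i]
                n_samples += 1

    return n_spikes, n_samples
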