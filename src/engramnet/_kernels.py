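"""Compiled inner loop of the full-network Euler integrator.

Fuses the rate computation, the potential updates and the plasticity updates
of one time step over many steps of constant input, operating directly on
the CSR value vector of the recurrent weight matrix.  Numerically identical
to the pure-numpy step in ``network._euler_step_inplace`` up to summation
order.
"""

import math

import numba
import numpy as np


@numba.njit(cache=True)
def step_span(u, u_inh_box, w_rec_data, indptr, indices, W_ff, c_ff,
              input_rates, eps, n_steps, dt, tau, R, alpha, beta, mu, F_T,
              kappa_rec, kappa_ff, tau_inh, R_inh, w_inh_in, w_inh_out,
              eps_inh, plastic):
    nM = u.shape[0]
    nI = input_rates.shape[0]
    F = np.empty(nM)
    # only the active inputs contribute to drive and Hebbian growth
    active = np.flatnonzero(input_rates > 0.0)
    for _ in range(n_steps):
        f_sum = 0.0
        for i in range(nM):
            x = beta * (u[i] - eps[i])
            if x > 50.0:
                F[i] = alpha
            elif x < -50.0:
                F[i] = 0.0
            else:
                F[i] = alpha / (1.0 + math.exp(-x))
            f_sum += F[i]
        xi = beta * (u_inh_box[0] - eps_inh)
        if xi > 50.0:
            F_inh = alpha
        elif xi < -50.0:
            F_inh = 0.0
        else:
            F_inh = alpha / (1.0 + math.exp(-xi))

        inh_term = w_inh_out * F_inh
        for i in range(nM):
            drive = -inh_term
            for jj in range(indptr[i], indptr[i + 1]):
                drive += w_rec_data[jj] * F[indices[jj]]
            for a in range(active.shape[0]):
                k = active[a]
                drive += W_ff[i, k] * input_rates[k]
            du = -u[i] / tau + R * drive
            if plastic:
                scale_i = (F_T - F[i])
                for jj in range(indptr[i], indptr[i + 1]):
                    w = w_rec_data[jj]
                    w += dt * mu * (F[i] * F[indices[jj]]
                                    + scale_i * w * w / kappa_rec)
                    w_rec_data[jj] = w if w > 0.0 else 0.0
                for k in range(nI):
                    if c_ff[i, k]:
                        w = W_ff[i, k]
                        w += dt * mu * (F[i] * input_rates[k]
                                        + scale_i * w * w / kappa_ff)
                        W_ff[i, k] = w if w > 0.0 else 0.0
            u[i] += dt * du
        u_inh_box[0] += dt * (-u_inh_box[0] / tau_inh
                              + R_inh * w_inh_in * f_sum)
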