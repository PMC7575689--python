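"""Dynamics of the full memory network.

Rate-coded leaky integrators: the membrane potential of memory neuron i obeys

    du_i/dt = -u_i/tau + R * ( sum_j w_rec_ij F_j - w_i,inh F_inh
                               + sum_k w_ff_ik I_k )

where F = alpha / (1 + exp(beta (epsilon - u))) converts potentials to rates.
The single inhibitory unit integrates the summed memory-area rate; its weight
onto the memory neurons is stored as a magnitude and applied with negative
sign.  Excitatory synapses evolve by Hebbian plasticity plus synaptic scaling:

    dw/dt = mu * ( F_post * F_pre + (1/kappa) (F_T - F_post) w^2 )

restricted to existing connections.  Integration is explicit Euler; weights
are clamped at zero after each plastic step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.special import expit

from .connectivity import Connectivity
from .params import ModelParams

__all__ = [
    "NetworkState",
    "transfer_rate",
    "network_derivatives",
    "plasticity_derivatives",
    "euler_step",
    "init_state",
    "simulate_span",
    "NumericalDivergenceError",
]


class NumericalDivergenceError(RuntimeError):
    """Raised when potentials or weights become non-finite."""


def transfer_rate(u, alpha=100.0, beta=0.05, epsilon=130.0):
    """Sigmoidal potential-to-rate transfer, bounded in (0, alpha).

    Implemented through the logistic ``expit`` for overflow safety at large
    |u|; strictly increasing in u, equals alpha/2 at u = epsilon.
    """
    return alpha * expit(np.multiply(beta, np.subtract(u, epsilon)))


@dataclass
class NetworkState:
    """Potentials and plastic weights of the network at time t.

    W_rec shares its sparsity pattern with the wiring (CSR, values mutate in
    place during plastic phases); W_ff is dense (nM, nI) masked by c_ff.
    """

    u: np.ndarray          # (nM,) membrane potentials
    u_inh: float           # inhibitory potential
    W_rec: sp.csr_matrix   # (nM, nM) recurrent weights on existing connections
    W_ff: np.ndarray       # (nM, nI) feed-forward weights
    t: float = 0.0

    def copy(self) -> "NetworkState":
        return NetworkState(
            u=self.u.copy(), u_inh=float(self.u_inh),
            W_rec=self.W_rec.copy(), W_ff=self.W_ff.copy(), t=self.t,
        )

    def rates(self, params: ModelParams) -> np.ndarray:
        return transfer_rate(self.u, params.alpha, params.beta, params.epsilon_vector)


def init_state(params: ModelParams, conn: Connectivity, rng: np.random.Generator) -> NetworkState:
    """Initial condition: zero potentials, recurrent weights at 0.25*w_hat_rec
    on existing connections, feed-forward weights uniform on [0, 0.7*w_hat_ff]
    on existing connections."""
    d = params.derived()
    W_rec = conn.c_rec.astype(float)
    W_rec.data[:] = 0.25 * d.w_hat_rec
    W_ff = np.where(
        conn.c_ff,
        rng.uniform(0.0, 0.7 * d.w_hat_ff, size=conn.c_ff.shape),
        0.0,
    )
    return NetworkState(
        u=np.zeros(params.nM), u_inh=0.0, W_rec=W_rec, W_ff=W_ff, t=0.0
    )


def network_derivatives(state: NetworkState, input_rates: np.ndarray,
                        params: ModelParams, conn: Connectivity):
    """Time derivatives of the membrane potentials (memory area + inhibitory
    unit) at the current state."""
    input_rates = np.asarray(input_rates, dtype=float)
    if input_rates.shape != (params.nI,):
        raise ValueError(f"input_rates must have shape ({params.nI},), got {input_rates.shape}")
    if state.W_ff.shape != (params.nM, params.nI):
        raise ValueError("feed-forward weight shape mismatch")
    F = state.rates(params)
    F_inh = transfer_rate(state.u_inh, params.alpha, params.beta, params.epsilon_inh)
    drive = state.W_rec.dot(F) - params.w_inh_out * F_inh + state.W_ff.dot(input_rates)
    du = -state.u / params.tau + params.R * drive
    du_inh = -state.u_inh / params.tau_inh + params.R_inh * params.w_inh_in * F.sum()
    return du, du_inh


def plasticity_derivatives(state: NetworkState, input_rates: np.ndarray,
                           params: ModelParams, conn: Connectivity):
    """Hebb + scaling derivatives for feed-forward and recurrent weights.

    Returns ``(dW_ff, dw_rec_data)`` where the recurrent part is the flat
    value vector aligned with the CSR data of ``state.W_rec`` (zero implicitly
    everywhere a connection does not exist).
    """
    F = state.rates(params)
    rows, cols = conn.rec_rows, conn.rec_cols
    w = state.W_rec.data
    dw_rec = params.mu * (F[rows] * F[cols]
                          + (params.F_T - F[rows]) * w * w / params.kappa_rec)
    dW_ff = params.mu * (
        F[:, None] * np.asarray(input_rates, dtype=float)[None, :]
        + ((params.F_T - F) / params.kappa_ff)[:, None] * state.W_ff**2
    )
    dW_ff *= conn.c_ff
    return dW_ff, dw_rec


def euler_step(state: NetworkState, input_rates: np.ndarray, params: ModelParams,
               conn: Connectivity, plastic: bool = True) -> NetworkState:
    """Advance one explicit-Euler step of length params.dt (out of place).

    All derivatives are evaluated at the incoming state.  Weights change only
    when ``plastic`` and are clamped at zero afterwards.
    """
    new = state.copy()
    _euler_step_inplace(new, np.asarray(input_rates, dtype=float), params, conn,
                        plastic, params.epsilon_vector)
    return new


def _euler_step_inplace(state: NetworkState, input_rates: np.ndarray,
                        params: ModelParams, conn: Connectivity, plastic: bool,
                        eps_vec: np.ndarray) -> None:
    dt = params.dt
    F = transfer_rate(state.u, params.alpha, params.beta, eps_vec)
    F_inh = transfer_rate(state.u_inh, params.alpha, params.beta, params.epsilon_inh)
    drive = state.W_rec.dot(F)
    drive -= params.w_inh_out * F_inh
    drive += state.W_ff.dot(input_rates)
    state.u += dt * (-state.u / params.tau + params.R * drive)
    state.u_inh += dt * (-state.u_inh / params.tau_inh
                         + params.R_inh * params.w_inh_in * F.sum())
    if plastic:
        rows, cols = conn.rec_rows, conn.rec_cols
        w = state.W_rec.data
        w += dt * params.mu * (F[rows] * F[cols]
                               + (params.F_T - F[rows]) * w * w / params.kappa_rec)
        np.maximum(w, 0.0, out=w)
        dW = F[:, None] * input_rates[None, :]
        dW += ((params.F_T - F) / params.kappa_ff)[:, None] * state.W_ff**2
        dW *= conn.c_ff
        state.W_ff += dt * params.mu * dW
        np.maximum(state.W_ff, 0.0, out=state.W_ff)
    state.t += dt
    if not np.isfinite(state.u).all():
        raise NumericalDivergenceError(
            f"non-finite membrane potential at t={state.t:.3f}s "
            f"(max |u| before failure may exceed float range)"
        )


try:
    from ._kernels import step_span as _fast_span
except ImportError:          # pragma: no cover - numba is an optional speedup
    _fast_span = None


def simulate_span(state: NetworkState, input_rates: np.ndarray, duration: float,
                  params: ModelParams, conn: Connectivity, plastic: bool = True,
                  callback=None, callback_every: int = 0) -> NetworkState:
    """Integrate ``duration`` seconds of constant input (in place), returning
    the advanced state.  ``callback(step_index, state)`` is invoked every
    ``callback_every`` steps if given.

    Uses a compiled fused step kernel when available; the pure-numpy step is
    the reference path and remains in use for single steps."""
    n_steps = int(round(duration / params.dt))
    input_rates = np.asarray(input_rates, dtype=float)
    eps_vec = params.epsilon_vector
    if _fast_span is not None:
        chunk = callback_every if (callback is not None and callback_every) else n_steps
        done = 0
        u_inh_box = np.array([state.u_inh], dtype=float)
        cff = conn.c_ff.astype(np.uint8)
        while done < n_steps:
            n = min(chunk, n_steps - done)
            _fast_span(
                state.u, u_inh_box, state.W_rec.data, state.W_rec.indptr,
                state.W_rec.indices, state.W_ff, cff, input_rates, eps_vec,
                n, params.dt, params.tau, params.R, params.alpha, params.beta,
                params.mu, params.F_T, params.kappa_rec, params.kappa_ff,
                params.tau_inh, params.R_inh, params.w_inh_in,
                params.w_inh_out, params.epsilon_inh, plastic,
            )
            done += n
            state.u_inh = float(u_inh_box[0])
            state.t += n * params.dt
            if not np.isfinite(state.u).all():
                raise NumericalDivergenceError(
                    f"non-finite membrane potential at t={state.t:.3f}s")
            if callback is not None and callback_every:
                callback(done - 1, state)
        return state
    for k in range(n_steps):
        _euler_step_inplace(state, input_rates, params, conn, plastic, eps_vec)
        if callback is not None and callback_every and (k + 1) % callback_every == 0:
            callback(k, state)
    return state
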