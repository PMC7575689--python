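"""Reduced population model of two competing assemblies.

Two non-overlapping populations of N neurons (candidate assemblies) and one
inhibitory unit, each population described by its mean membrane potential,
its mean recurrent weight, and its mean feed-forward weights from the two
input populations A and B — nine ODEs in total:

    du_i/dt    = -u_i/tau + R ( n_rec w_i^rec F_i - w_inh_out F_inh
                                + n_ff (w_iA I_A + w_iB I_B) )
    du_inh/dt  = -u_inh/tau_inh + R_inh w_inh_in N (F_1 + F_2)
    dw_ik/dt   = mu ( F_i I_k + (F_T - F_i) w_ik^2 / kappa_ff )
    dw_i^rec/dt= mu ( F_i^2   + (F_T - F_i) (w_i^rec)^2 / kappa_rec )

with the same sigmoidal transfer and parameter values as the full network.
The per-neuron in-degree n_rec and active-input fan-in n_ff are measured
from full-network simulations (35 and 2.3 for the reference parameters).

State vector layout (last axis): [u1, u2, u_inh, w1_rec, w2_rec,
w1A, w1B, w2A, w2B].  All dynamics functions broadcast over leading axes so
basin maps integrate thousands of initial conditions at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import root
from scipy.special import expit

from .params import ModelParams, steady_state_weight

__all__ = [
    "PopulationParams", "FixedPoint", "STATE_VARS",
    "population_derivatives", "integrate_population",
    "find_fixed_points", "bifurcation_scan", "basin_map", "ff_change_map",
]

STATE_VARS = ("u1", "u2", "u_inh", "w1_rec", "w2_rec",
              "w1A_ff", "w1B_ff", "w2A_ff", "w2B_ff")


@dataclass(frozen=True)
class PopulationParams:
    """Parameters of the reduced model (shares the network's constants)."""

    n_rec: float = 35.0    # mean within-population recurrent in-degree
    n_ff: float = 2.3      # mean fan-in from the active input population
    N: int = 120           # neurons per population (sets inhibitory drive)
    tau: float = 0.01
    R: float = 1.0 / 11.0
    alpha: float = 100.0
    beta: float = 0.05
    epsilon: float = 130.0
    mu: float = 1.0 / 15.0
    F_T: float = 0.1
    kappa_rec: float = 60.0
    kappa_ff: float = 720.0
    tau_inh: float = 0.02
    R_inh: float = 1.0
    w_inh_in: float = 0.6
    w_inh_out: float = 1200.0
    dt: float = 0.005
    input_rate: float = 130.0

    def __post_init__(self):
        if min(self.n_rec, self.n_ff, self.N) <= 0:
            raise ValueError("n_rec, n_ff and N must be positive")

    @classmethod
    def from_model_params(cls, p: ModelParams, n_rec: float = 35.0,
                          n_ff: float = 2.3, N: int = 120) -> "PopulationParams":
        eps = np.asarray(p.epsilon)
        return cls(n_rec=n_rec, n_ff=n_ff, N=N, tau=p.tau, R=p.R, alpha=p.alpha,
                   beta=p.beta, epsilon=float(eps.mean()), mu=p.mu, F_T=p.F_T,
                   kappa_rec=p.kappa_rec, kappa_ff=p.kappa_ff, tau_inh=p.tau_inh,
                   R_inh=p.R_inh, w_inh_in=p.w_inh_in, w_inh_out=p.w_inh_out,
                   dt=p.dt, input_rate=p.input_rate)

    def w_hat_rec(self) -> float:
        return float(steady_state_weight(self.alpha, self.alpha, self.kappa_rec, self.F_T))

    def w_hat_ff(self) -> float:
        return float(steady_state_weight(self.alpha, self.input_rate, self.kappa_ff, self.F_T))


def _F(u, p: PopulationParams):
    return p.alpha * expit(p.beta * (np.asarray(u) - p.epsilon))


def population_derivatives(y, inputs, p: PopulationParams) -> np.ndarray:
    """Right-hand side of the nine ODEs; broadcasts over leading axes of y."""
    y = np.asarray(y, dtype=float)
    I_A, I_B = inputs
    u1, u2, u_inh = y[..., 0], y[..., 1], y[..., 2]
    w1r, w2r = y[..., 3], y[..., 4]
    w1A, w1B, w2A, w2B = y[..., 5], y[..., 6], y[..., 7], y[..., 8]
    F1, F2, Fi = _F(u1, p), _F(u2, p), _F(u_inh, p)
    dy = np.empty_like(y)
    dy[..., 0] = -u1 / p.tau + p.R * (p.n_rec * w1r * F1 - p.w_inh_out * Fi
                                      + p.n_ff * (w1A * I_A + w1B * I_B))
    dy[..., 1] = -u2 / p.tau + p.R * (p.n_rec * w2r * F2 - p.w_inh_out * Fi
                                      + p.n_ff * (w2A * I_A + w2B * I_B))
    dy[..., 2] = -u_inh / p.tau_inh + p.R_inh * p.w_inh_in * p.N * (F1 + F2)
    dy[..., 3] = p.mu * (F1 * F1 + (p.F_T - F1) * w1r * w1r / p.kappa_rec)
    dy[..., 4] = p.mu * (F2 * F2 + (p.F_T - F2) * w2r * w2r / p.kappa_rec)
    dy[..., 5] = p.mu * (F1 * I_A + (p.F_T - F1) * w1A * w1A / p.kappa_ff)
    dy[..., 6] = p.mu * (F1 * I_B + (p.F_T - F1) * w1B * w1B / p.kappa_ff)
    dy[..., 7] = p.mu * (F2 * I_A + (p.F_T - F2) * w2A * w2A / p.kappa_ff)
    dy[..., 8] = p.mu * (F2 * I_B + (p.F_T - F2) * w2B * w2B / p.kappa_ff)
    return dy


def integrate_population(y0, inputs, p: PopulationParams, T: float = 100.0,
                         dt: float | None = None, record_every: int = 0):
    """Explicit-Euler trajectory with the same weight clamping as the full
    network.  Returns (times, trajectory) if record_every > 0, else the final
    state array."""
    dt = p.dt if dt is None else dt
    if T <= 0 or dt <= 0:
        raise ValueError("T and dt must be positive")
    y = np.array(y0, dtype=float, copy=True)
    n_steps = int(round(T / dt))
    times, traj = [], []
    for k in range(n_steps):
        y += dt * population_derivatives(y, inputs, p)
        np.maximum(y[..., 3:], 0.0, out=y[..., 3:])
        if record_every and (k + 1) % record_every == 0:
            times.append((k + 1) * dt)
            traj.append(y.copy())
    if not np.isfinite(y).all():
        raise FloatingPointError("population model diverged (non-finite state)")
    if record_every:
        return np.asarray(times), np.asarray(traj)
    return y


# ----------------------------------------------------------------------
# Fixed points
# ----------------------------------------------------------------------

@dataclass
class FixedPoint:
    state: np.ndarray           # 9-vector in STATE_VARS order
    stability: str              # "stable" | "unstable" | "saddle"
    label: str                  # "low" | "pop1" | "pop2" | "symmetric" | "both_high"
    eigenvalues: np.ndarray
    residual: float

    def rates(self, p: PopulationParams):
        return _F(self.state[:2], p)


def _steady_weights(F, p: PopulationParams, I):
    """Weight at the plasticity/scaling balance for postsynaptic rate F and
    presynaptic drive I (0 -> weight 0); denominator floored so the reduced
    map stays defined where F <= F_T (no fixed point lives there)."""
    if I == 0:
        return np.zeros_like(F)
    denom = np.maximum(F - p.F_T, 1e-12)
    return np.sqrt(np.maximum(p.kappa_ff * F * I, 0.0) / denom)


def _reduced_G(u1, u2, inputs, p: PopulationParams):
    """Potential derivatives after substituting the steady states of u_inh
    and all weights as functions of (u1, u2)."""
    I_A, I_B = inputs
    F1, F2 = _F(u1, p), _F(u2, p)
    denom1 = np.maximum(F1 - p.F_T, 1e-12)
    denom2 = np.maximum(F2 - p.F_T, 1e-12)
    w1r = np.sqrt(p.kappa_rec * F1 * F1 / denom1)
    w2r = np.sqrt(p.kappa_rec * F2 * F2 / denom2)
    w1A = _steady_weights(F1, p, I_A)
    w1B = _steady_weights(F1, p, I_B)
    w2A = _steady_weights(F2, p, I_A)
    w2B = _steady_weights(F2, p, I_B)
    u_inh = p.tau_inh * p.R_inh * p.w_inh_in * p.N * (F1 + F2)
    Fi = _F(u_inh, p)
    G1 = -u1 / p.tau + p.R * (p.n_rec * w1r * F1 - p.w_inh_out * Fi
                              + p.n_ff * (w1A * I_A + w1B * I_B))
    G2 = -u2 / p.tau + p.R * (p.n_rec * w2r * F2 - p.w_inh_out * Fi
                              + p.n_ff * (w2A * I_A + w2B * I_B))
    return G1, G2


def _full_state_from_potentials(u1, u2, inputs, p: PopulationParams):
    I_A, I_B = inputs
    F1, F2 = _F(u1, p), _F(u2, p)
    u_inh = p.tau_inh * p.R_inh * p.w_inh_in * p.N * (F1 + F2)
    denom1 = np.maximum(F1 - p.F_T, 1e-12)
    denom2 = np.maximum(F2 - p.F_T, 1e-12)
    return np.array([
        u1, u2, u_inh,
        np.sqrt(p.kappa_rec * F1 * F1 / denom1),
        np.sqrt(p.kappa_rec * F2 * F2 / denom2),
        _steady_weights(F1, p, I_A), _steady_weights(F1, p, I_B),
        _steady_weights(F2, p, I_A), _steady_weights(F2, p, I_B),
    ], dtype=float)


def _active_dims(inputs):
    """ODE dimensions that are dynamically relevant: feed-forward weights of
    a silent input sit at the neutral w=0 equilibrium (dw/dw = 0 there) and
    are excluded from the stability classification."""
    I_A, I_B = inputs
    dims = [0, 1, 2, 3, 4]
    if I_A > 0:
        dims += [5, 7]
    if I_B > 0:
        dims += [6, 8]
    return sorted(dims)


def _numeric_jacobian(y, inputs, p: PopulationParams, dims):
    n = len(dims)
    J = np.zeros((n, n))
    scale = np.maximum(np.abs(y), 1.0)
    for a, da in enumerate(dims):
        h = 1e-6 * scale[da]
        yp, ym = y.copy(), y.copy()
        yp[da] += h
        ym[da] -= h
        fp = population_derivatives(yp, inputs, p)
        fm = population_derivatives(ym, inputs, p)
        J[:, a] = (fp[dims] - fm[dims]) / (2 * h)
    return J


def _classify(eigs, tol=1e-6) -> str:
    re = eigs.real
    if np.all(re < -tol):
        return "stable"
    if np.all(re > tol):
        return "unstable"
    return "saddle"


def _label(fp_state, p: PopulationParams) -> str:
    F1, F2 = _F(fp_state[0], p), _F(fp_state[1], p)
    hi1, hi2 = F1 > p.alpha / 2, F2 > p.alpha / 2
    if hi1 and hi2:
        return "both_high"
    if hi1:
        return "pop1"
    if hi2:
        return "pop2"
    if abs(fp_state[0] - fp_state[1]) < 1e-3 * max(1.0, abs(fp_state[0])):
        return "symmetric" if F1 > 1.0 else "low"
    return "low"


def find_fixed_points(p: PopulationParams, inputs=(130.0, 0.0),
                      u_range=(-10.0, 320.0), n_grid: int = 140,
                      tol: float = 1e-9) -> list[FixedPoint]:
    """Fixed points of the reduced model at constant inputs.

    The 9-D steady-state problem is reduced to the (u1, u2) plane by
    substituting the closed-form steady states of the inhibitory potential
    and all six weights; nullcline intersections are bracketed by sign
    changes of (G1, G2) on a grid and polished with a Newton-type root
    finder, then mapped back to the full state and classified through the
    eigenvalues of the Jacobian restricted to the dynamically active
    dimensions."""
    us = np.linspace(u_range[0], u_range[1], n_grid)
    U1, U2 = np.meshgrid(us, us, indexing="ij")
    G1, G2 = _reduced_G(U1, U2, inputs, p)
    s1, s2 = np.sign(G1), np.sign(G2)

    def changes(s):
        c = np.zeros((n_grid - 1, n_grid - 1), dtype=bool)
        corner = s[:-1, :-1]
        for block in (s[1:, :-1], s[:-1, 1:], s[1:, 1:]):
            c |= corner != block
        return c

    cells = np.argwhere(changes(s1) & changes(s2))
    seeds = [((us[i] + us[i + 1]) / 2, (us[j] + us[j + 1]) / 2) for i, j in cells]

    found = []
    for u1_0, u2_0 in seeds:
        sol = root(lambda x: np.array(_reduced_G(x[0], x[1], inputs, p)),
                   x0=[u1_0, u2_0], method="hybr", tol=1e-13)
        if not sol.success:
            continue
        u1s, u2s = sol.x
        if not (u_range[0] - 1 <= u1s <= u_range[1] + 1
                and u_range[0] - 1 <= u2s <= u_range[1] + 1):
            continue
        if any(abs(u1s - f[0]) < 1e-4 and abs(u2s - f[1]) < 1e-4 for f in found):
            continue
        found.append((u1s, u2s))

    out = []
    for u1s, u2s in found:
        y = _full_state_from_potentials(u1s, u2s, inputs, p)
        dims = _active_dims(inputs)
        res = float(np.max(np.abs(population_derivatives(y, inputs, p)[dims])))
        if res > max(tol, 1e-7):
            continue
        J = _numeric_jacobian(y, inputs, p, dims)
        eigs = np.linalg.eigvals(J)
        out.append(FixedPoint(state=y, stability=_classify(eigs),
                              label=_label(y, p), eigenvalues=eigs, residual=res))
    out.sort(key=lambda f: (f.state[0], f.state[1]))
    return out


def bifurcation_scan(p: PopulationParams, I_A_values) -> dict:
    """Fixed-point structure as a function of the input amplitude.

    Two bifurcations matter for memory formation.  Stable asymmetric
    (one-population-high) fixed points exist over a wide amplitude range;
    ``threshold_existence`` is the smallest scanned amplitude with such a
    point.  But a blank network sits near the symmetric low-activity branch,
    so it only *forms* an assembly once no stable non-assembly state remains;
    ``threshold`` (= ``threshold_formation``) is the smallest scanned
    amplitude at which every remaining attractor has one population
    potentiated — below it the system stays in the low state and does not
    learn."""
    result, thr_exist, thr_form = {}, None, None
    for I in sorted(I_A_values):
        fps = find_fixed_points(p, inputs=(float(I), 0.0))
        result[float(I)] = fps
        has_ha = any(f.stability == "stable" and f.label in ("pop1", "pop2")
                     for f in fps)
        has_non_ha = any(f.stability == "stable"
                         and f.label in ("low", "symmetric") for f in fps)
        if has_ha and thr_exist is None:
            thr_exist = float(I)
        if has_ha and not has_non_ha and thr_form is None:
            thr_form = float(I)
    return {"fixed_points": result, "threshold": thr_form,
            "threshold_formation": thr_form, "threshold_existence": thr_exist}


# ----------------------------------------------------------------------
# Recruitment basins and feed-forward change map
# ----------------------------------------------------------------------

def basin_map(p: PopulationParams, ff_grid=None, rec_grid=None,
              w2A_frac: float = 0.35, w2_rec_frac: float = 0.25,
              T: float = 100.0) -> dict:
    """Which population wins as a function of population 1's initial weights.

    Initial condition per cell: u1 = u2 = u_inh = 0, w1A and w1_rec from the
    grids, w2A = w2A_frac * w_hat_ff, w2_rec = w2_rec_frac * w_hat_rec, the
    silent input's synapses at 0 (only input A is active).  After T seconds a
    population is called active if its rate exceeds alpha/2; the winner label
    is pop1/pop2/none/both."""
    w_ff_hat, w_rec_hat = p.w_hat_ff(), p.w_hat_rec()
    if ff_grid is None:
        ff_grid = np.linspace(0.0, w_ff_hat, 50)
    if rec_grid is None:
        rec_grid = np.linspace(0.0, w_rec_hat, 50)
    ff_grid = np.asarray(ff_grid, dtype=float)
    rec_grid = np.asarray(rec_grid, dtype=float)
    FF, RR = np.meshgrid(ff_grid, rec_grid, indexing="ij")
    y0 = np.zeros(FF.shape + (9,))
    y0[..., 5] = FF                      # w1A
    y0[..., 3] = RR                      # w1_rec
    y0[..., 7] = w2A_frac * w_ff_hat     # w2A
    y0[..., 4] = w2_rec_frac * w_rec_hat  # w2_rec
    yT = integrate_population(y0, (p.input_rate, 0.0), p, T=T)
    F1, F2 = _F(yT[..., 0], p), _F(yT[..., 1], p)
    hi1, hi2 = F1 > p.alpha / 2, F2 > p.alpha / 2
    winner = np.full(FF.shape, "none", dtype=object)
    winner[hi1 & ~hi2] = "pop1"
    winner[hi2 & ~hi1] = "pop2"
    winner[hi1 & hi2] = "both"
    return {"ff_grid": ff_grid, "rec_grid": rec_grid, "winner": winner,
            "final_state": yT}


def ff_change_map(I_values, F_values, w0: float, duration: float = 50.0,
                  p: PopulationParams | None = None,
                  negligible_fraction: float = 0.05) -> dict:
    """Net feed-forward weight change at clamped pre (input) and post rates.

    Integrates dw/dt = mu (F I + (F_T - F) w^2 / kappa_ff) from w0 for one
    learning phase's worth of stimulation and classifies each (I, F) cell:
    case II homosynaptic potentiation, case I heterosynaptic depression, and
    the negligible cases III (pre low) / IV (pre high) when the post rate is
    too low to drive changes beyond ``negligible_fraction`` of w_hat_ff."""
    p = PopulationParams() if p is None else p
    I_values = np.asarray(I_values, dtype=float)
    F_values = np.asarray(F_values, dtype=float)
    II, FF = np.meshgrid(I_values, F_values, indexing="ij")
    w = np.full(II.shape, float(w0))
    n_steps = int(round(duration / p.dt))
    for _ in range(n_steps):
        w += p.dt * p.mu * (FF * II + (p.F_T - FF) * w * w / p.kappa_ff)
        np.maximum(w, 0.0, out=w)
    dw = w - w0
    thresh = negligible_fraction * p.w_hat_ff()
    cases = np.full(II.shape, "III", dtype=object)
    cases[(dw >= thresh)] = "II"
    cases[(dw <= -thresh)] = "I"
    negligible = np.abs(dw) < thresh
    cases[negligible & (II >= p.input_rate / 2)] = "IV"
    cases[negligible & (II < p.input_rate / 2)] = "III"
    return {"I_values": I_values, "F_values": F_values, "delta_w": dw,
            "case": cases, "final_w": w}
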