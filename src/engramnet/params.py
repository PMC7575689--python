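"""Model parameters of the rate-coded memory network.

The network consists of an input area (``n_input`` excitatory neurons whose
rates are set externally), a memory area (``n_memory`` excitatory neurons on a
square grid with periodic boundaries) and one global inhibitory unit.  All
excitatory synapses are plastic under a combined rule of Hebbian plasticity and
synaptic scaling; connections to/from the inhibitory unit are fixed.

Units: time constants in seconds, rates in Hz, weights in model units.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

__all__ = ["ModelParams", "DerivedConstants", "steady_state_weight"]


def steady_state_weight(f_post: float, f_pre: float, kappa: float, f_target: float = 0.1):
    """Weight at which Hebbian growth and synaptic scaling cancel.

    Setting the plasticity rule ``dw/dt = mu*(F_post*F_pre + (F_T - F_post)*w^2/kappa)``
    to zero gives ``w* = sqrt(kappa * F_post * F_pre / (F_post - F_T))``.  A finite
    balance exists only for ``F_post > F_T``; for ``f_pre == 0`` the pure-depression
    rule balances only at ``w* = 0``.

    Parameters
    ----------
    f_post : postsynaptic firing rate (Hz), must exceed ``f_target``.
    f_pre : presynaptic firing rate (Hz), >= 0.
    kappa : scaling constant of the synapse class.
    f_target : homeostatic target rate (Hz).
    """
    f_post = np.asarray(f_post, dtype=float)
    if np.any(f_post <= f_target):
        raise ValueError(
            f"no finite plasticity/scaling balance: F_post={f_post} <= F_T={f_target}"
        )
    return np.sqrt(kappa * f_post * np.asarray(f_pre, dtype=float) / (f_post - f_target))


@dataclass
class ModelParams:
    """Parameters of neurons, synapses and plasticity (full network).

    Defaults are the reference parameter set used throughout: a 30x30 memory
    grid driven by 36 input neurons firing at 0 or 130 Hz.
    """

    tau: float = 0.01            # membrane time constant, memory area (s)
    R: float = 1.0 / 11.0        # membrane resistance, memory area
    nM: int = 900                # neurons in memory area
    nI: int = 36                 # neurons in input area
    input_rate: float = 130.0    # active-input firing rate (Hz)
    alpha: float = 100.0         # maximal firing rate (Hz)
    beta: float = 0.05           # sigmoid steepness
    epsilon: float | np.ndarray = 130.0   # sigmoid inflection (scalar or per-neuron)
    mu: float = 1.0 / 15.0       # plasticity time constant
    F_T: float = 0.1             # homeostatic target rate (Hz)
    kappa_rec: float = 60.0      # scaling constant, recurrent synapses
    kappa_ff: float = 720.0      # scaling constant, feed-forward synapses
    epsilon_inh: float = 130.0   # sigmoid inflection of the inhibitory unit
    tau_inh: float = 0.02        # membrane time constant, inhibitory unit (s)
    R_inh: float = 1.0           # membrane resistance, inhibitory unit
    w_inh_in: float = 0.6        # weight memory -> inhibitory unit
    w_inh_out: float = 1200.0    # magnitude of inhibitory -> memory weight
    dt: float = 0.005            # Euler step (s)
    grid_shape: tuple[int, int] = (30, 30)
    radius: float = 4.0          # recurrent neighborhood radius (grid units)
    fanin: int = 4               # feed-forward connections per memory neuron

    def __post_init__(self):
        for name in ("tau", "tau_inh", "mu", "kappa_rec", "kappa_ff", "dt",
                     "alpha", "input_rate", "R", "R_inh"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive, got {getattr(self, name)}")
        if self.alpha <= self.F_T:
            raise ValueError("alpha must exceed the target rate F_T")
        if self.nM != self.grid_shape[0] * self.grid_shape[1]:
            raise ValueError("nM must equal the product of grid_shape")
        if not (1 <= self.fanin <= self.nI):
            raise ValueError(f"fanin must lie in [1, nI], got {self.fanin}")
        eps = np.asarray(self.epsilon, dtype=float)
        if eps.ndim not in (0, 1):
            raise ValueError("epsilon must be scalar or a per-neuron vector")
        if eps.ndim == 1 and eps.size != self.nM:
            raise ValueError(f"epsilon vector length {eps.size} != nM={self.nM}")

    @property
    def epsilon_vector(self) -> np.ndarray:
        """Inflection point as an nM-vector (broadcast if scalar)."""
        return np.broadcast_to(np.asarray(self.epsilon, dtype=float), (self.nM,)).copy()

    def replace(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)

    def derived(self) -> "DerivedConstants":
        return DerivedConstants.from_params(self)

    def to_dict(self) -> dict:
        eps = np.asarray(self.epsilon)
        d = {
            "tau": self.tau, "R": self.R, "nM": self.nM, "nI": self.nI,
            "input_rate": self.input_rate, "alpha": self.alpha, "beta": self.beta,
            "epsilon": float(eps) if eps.ndim == 0 else eps.tolist(),
            "epsilon_inh": self.epsilon_inh,
            "mu": self.mu, "F_T": self.F_T,
            "kappa_rec": self.kappa_rec, "kappa_ff": self.kappa_ff,
            "tau_inh": self.tau_inh, "R_inh": self.R_inh,
            "w_inh_in": self.w_inh_in, "w_inh_out": self.w_inh_out,
            "dt": self.dt, "grid_shape": list(self.grid_shape),
            "radius": self.radius, "fanin": self.fanin,
        }
        return d

    @classmethod
    def from_dict(cls, mapping: Mapping) -> "ModelParams":
        known = {f for f in cls.__dataclass_fields__}
        bad = set(mapping) - known
        if bad:
            raise ValueError(f"unknown parameter key(s): {sorted(bad)}")
        kwargs = dict(mapping)
        if "grid_shape" in kwargs:
            kwargs["grid_shape"] = tuple(kwargs["grid_shape"])
        if "epsilon" in kwargs and isinstance(kwargs["epsilon"], (list, tuple)):
            kwargs["epsilon"] = np.asarray(kwargs["epsilon"], dtype=float)
        return cls(**kwargs)


@dataclass(frozen=True)
class DerivedConstants:
    """Balance weights of the plasticity/scaling equilibrium at saturation.

    ``w_hat_rec`` is the recurrent weight at which a synapse between two
    neurons firing at the maximal rate alpha stops changing; ``w_hat_ff`` the
    analogue for a feed-forward synapse driven by an input at ``input_rate``.
    With the reference parameters these are ~77.5 and ~306.1.
    """

    w_hat_rec: float
    w_hat_ff: float

    @classmethod
    def from_params(cls, p: ModelParams) -> "DerivedConstants":
        return cls(
            w_hat_rec=float(steady_state_weight(p.alpha, p.alpha, p.kappa_rec, p.F_T)),
            w_hat_ff=float(steady_state_weight(p.alpha, p.input_rate, p.kappa_ff, p.F_T)),
        )
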