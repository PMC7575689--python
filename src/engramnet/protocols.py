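"""Stimulation protocols and experimental manipulations.

A stimulus is a set of active input neurons firing at the stimulation rate
(all others silent).  The standard schedule alternates test phases (both
stimuli presented briefly with plasticity off) with learning phases (one
stimulus presented repeatedly with plasticity on; inputs silent during the
pauses between presentations, plasticity still on).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import Connectivity, torus_disk
from .network import NetworkState, simulate_span
from .params import ModelParams

__all__ = [
    "StimulusPattern", "Phase", "Protocol", "Manipulation", "RunRecord",
    "make_stimulus_pair", "make_stimulus", "degrade_pattern",
    "standard_protocol", "single_phase_protocol", "sequential_protocol",
    "apply_manipulation", "run_protocol",
]


@dataclass(frozen=True)
class StimulusPattern:
    """Binary input-population activity: ``active_set`` fires at ``rate`` Hz."""

    active_set: frozenset
    nI: int
    rate: float = 130.0
    name: str = ""

    def rates(self) -> np.ndarray:
        r = np.zeros(self.nI)
        r[sorted(self.active_set)] = self.rate
        return r

    def __len__(self):
        return len(self.active_set)


@dataclass(frozen=True)
class Phase:
    kind: str                      # "learn" | "test" | "pause"
    patterns: tuple                # StimulusPattern(s) presented in order
    duration: float                # duration of each presentation (s)
    plastic: bool
    pause: float = 0.0             # silent gap between presentations (s)
    repetitions: int = 1
    label: str = ""

    def total_duration(self) -> float:
        n = self.repetitions * len(self.patterns)
        return n * self.duration + max(n - 1, 0) * self.pause


@dataclass(frozen=True)
class Protocol:
    phases: tuple

    def total_duration(self) -> float:
        return sum(p.total_duration() for p in self.phases)


def make_stimulus(active, nI: int = 36, rate: float = 130.0, name: str = "") -> StimulusPattern:
    active = frozenset(int(a) for a in active)
    if active and (min(active) < 0 or max(active) >= nI):
        raise ValueError("active indices out of range")
    return StimulusPattern(active_set=active, nI=nI, rate=rate, name=name)


def make_stimulus_pair(disparity: float, nI: int = 36, pattern_size: int = 18,
                       rng: np.random.Generator | None = None,
                       rate: float = 130.0):
    """Two patterns of equal size with controlled overlap.

    Disparity d in [0, 1] fixes the shared fraction: |S1 & S2| =
    round((1-d)*pattern_size); d=1 gives disjoint patterns, d=0 identical
    ones.  Index sets are drawn uniformly given those constraints.
    """
    if not (0.0 <= disparity <= 1.0):
        raise ValueError(f"disparity must lie in [0, 1], got {disparity}")
    n_shared = int(round((1.0 - disparity) * pattern_size))
    n_total = 2 * pattern_size - n_shared
    if n_total > nI:
        raise ValueError(
            f"patterns of size {pattern_size} with disparity {disparity} "
            f"need {n_total} inputs but only {nI} exist"
        )
    rng = np.random.default_rng() if rng is None else rng
    pool = rng.permutation(nI)
    shared = pool[:n_shared]
    own1 = pool[n_shared: pattern_size]
    own2 = pool[pattern_size: n_total]
    s1 = make_stimulus(np.concatenate([shared, own1]), nI, rate, name="S1")
    s2 = make_stimulus(np.concatenate([shared, own2]), nI, rate, name="S2")
    return s1, s2


def degrade_pattern(pattern: StimulusPattern, active_fraction: float,
                    rng: np.random.Generator) -> StimulusPattern:
    """Noisy recall cue: keep a uniform random subset of the active inputs,
    of size round(active_fraction * |pattern|)."""
    if not (0.0 <= active_fraction <= 1.0):
        raise ValueError("active_fraction must lie in [0, 1]")
    members = np.array(sorted(pattern.active_set))
    k = int(round(active_fraction * len(members)))
    keep = rng.choice(members, size=k, replace=False) if k < len(members) else members
    return make_stimulus(keep, pattern.nI, pattern.rate,
                         name=f"{pattern.name}~{active_fraction:g}")


def _test_phase(s1, s2, label, duration=0.5):
    return Phase(kind="test", patterns=(s1, s2), duration=duration,
                 plastic=False, label=label)


def _learn_phase(stim, label, n_pres=10, duration=5.0, pause=1.0):
    return Phase(kind="learn", patterns=(stim,), duration=duration,
                 plastic=True, pause=pause, repetitions=n_pres, label=label)


def standard_protocol(s1: StimulusPattern, s2: StimulusPattern,
                      n_presentations: int = 10, presentation: float = 5.0,
                      pause: float = 1.0, test_duration: float = 0.5) -> Protocol:
    """Two-phase schedule: test0, learn S1 (10 x 5 s, 1 s pauses), test1,
    learn S2, test2.  Every test presents S1 then S2 for 0.5 s each with
    plasticity off."""
    return Protocol(phases=(
        _test_phase(s1, s2, "test0", test_duration),
        _learn_phase(s1, "learn1", n_presentations, presentation, pause),
        _test_phase(s1, s2, "test1", test_duration),
        _learn_phase(s2, "learn2", n_presentations, presentation, pause),
        _test_phase(s1, s2, "test2", test_duration),
    ))


def single_phase_protocol(s1: StimulusPattern, n_presentations: int = 10,
                          presentation: float = 5.0, pause: float = 1.0,
                          test_duration: float = 0.5) -> Protocol:
    """test0, learn S1, test1 — the single-session variant used for
    recruitment and pattern-completion experiments."""
    return Protocol(phases=(
        _test_phase(s1, s1, "test0", test_duration),
        _learn_phase(s1, "learn1", n_presentations, presentation, pause),
        _test_phase(s1, s1, "test1", test_duration),
    ))


def sequential_protocol(stimuli, n_presentations: int = 10, presentation: float = 5.0,
                        pause: float = 1.0, test_duration: float = 0.5) -> Protocol:
    """test0, then for each stimulus: learn it and test all stimuli seen so
    far (used by the capacity probe)."""
    phases = [Phase(kind="test", patterns=tuple(stimuli), duration=test_duration,
                    plastic=False, label="test0")]
    for i, stim in enumerate(stimuli, start=1):
        phases.append(_learn_phase(stim, f"learn{i}", n_presentations,
                                   presentation, pause))
        phases.append(Phase(kind="test", patterns=tuple(stimuli),
                            duration=test_duration, plastic=False, label=f"test{i}"))
    return Protocol(phases=tuple(phases))


@dataclass(frozen=True)
class Manipulation:
    """Local perturbation applied before learning: shift the excitability
    (sigmoid inflection) of a circular group of neurons and optionally
    pre-scale all their incoming plastic weights."""

    region: tuple                 # memory-neuron indices
    delta_epsilon: float = 0.0    # added to epsilon_i (negative = more excitable)
    weight_factor: float = 1.0    # multiplies incoming W_ff and W_rec rows

    @classmethod
    def random_disk(cls, params: ModelParams, rng: np.random.Generator,
                    delta_epsilon: float = 0.0, weight_factor: float = 1.0,
                    radius: float = 5.3) -> "Manipulation":
        center = int(rng.integers(params.nM))
        region = torus_disk(center, radius, params.grid_shape)
        return cls(region=tuple(int(i) for i in region),
                   delta_epsilon=delta_epsilon, weight_factor=weight_factor)


def apply_manipulation(params: ModelParams, state: NetworkState,
                       manipulation: Manipulation):
    """Return (params, state) with the manipulation applied.

    Epsilon of the region neurons is shifted by delta_epsilon; if
    weight_factor != 1 the incoming plastic weights (both feed-forward and
    recurrent rows) of the region are scaled.  Neurons outside the region are
    untouched."""
    region = np.asarray(manipulation.region, dtype=int)
    if region.size == 0:
        raise ValueError("manipulation region is empty")
    if region.min() < 0 or region.max() >= params.nM:
        raise ValueError("manipulation region outside the memory area")
    eps = params.epsilon_vector
    eps[region] += manipulation.delta_epsilon
    new_params = params.replace(epsilon=eps)
    new_state = state.copy()
    if manipulation.weight_factor != 1.0:
        f = manipulation.weight_factor
        new_state.W_ff[region, :] *= f
        # scale CSR data in place so the sparsity pattern stays aligned with
        # the wiring (explicit zeros must not be dropped)
        W = new_state.W_rec
        rows = np.repeat(np.arange(W.shape[0]), np.diff(W.indptr))
        W.data[np.isin(rows, region)] *= f
    return new_params, new_state


@dataclass
class RunRecord:
    """What a protocol run produced.

    test_rates[label][pattern_name] holds the memory-area rate vector at the
    final step of that pattern's test presentation; snapshots[label] the state
    copy at the end of each phase.  Full matrices are kept at phase boundaries
    only to bound memory."""

    params: ModelParams
    test_rates: dict = field(default_factory=dict)
    snapshots: dict = field(default_factory=dict)
    phase_log: list = field(default_factory=list)
    final_state: NetworkState | None = None

    def active_set(self, label: str, pattern_name: str, threshold_fraction: float = 0.5):
        from .measures import detect_active_set
        return detect_active_set(self.test_rates[label][pattern_name],
                                 self.params.alpha, threshold_fraction)


def run_protocol(state: NetworkState, protocol: Protocol, params: ModelParams,
                 conn: Connectivity, keep_snapshots: bool = False) -> RunRecord:
    """Iterate the Euler integrator over all phases of a protocol.

    Mutates ``state`` in place and returns a RunRecord with test-phase rate
    vectors and (optionally) state snapshots at phase boundaries."""
    record = RunRecord(params=params)
    silent = np.zeros(params.nI)
    for phase in protocol.phases:
        t0 = state.t
        if phase.kind == "test":
            rates_here = {}
            for j, pattern in enumerate(phase.patterns):
                # each test presentation probes the weight structure from
                # quiescence: self-sustained attractor activity left over
                # from the previous phase would otherwise mask the
                # stimulus-specific response
                state.u[:] = 0.0
                state.u_inh = 0.0
                simulate_span(state, pattern.rates(), phase.duration, params,
                              conn, plastic=phase.plastic)
                rates_here[pattern.name or f"p{j}"] = state.rates(params)
            record.test_rates[phase.label] = rates_here
        else:
            n = phase.repetitions * len(phase.patterns)
            k = 0
            for _ in range(phase.repetitions):
                for pattern in phase.patterns:
                    simulate_span(state, pattern.rates(), phase.duration,
                                  params, conn, plastic=phase.plastic)
                    k += 1
                    if k < n and phase.pause > 0:
                        simulate_span(state, silent, phase.pause, params, conn,
                                      plastic=phase.plastic)
        record.phase_log.append(
            {"label": phase.label, "kind": phase.kind, "t_start": t0,
             "t_end": state.t, "plastic": phase.plastic}
        )
        if keep_snapshots:
            record.snapshots[phase.label] = state.copy()
    record.final_state = state
    return record
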