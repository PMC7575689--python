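"""End-to-end simulation experiments.

Each experiment wires a fresh network per seed (connectivity, initial
weights and stimulus draws all derive from one integer seed), runs a
stimulation protocol, and reduces the outcome with the measures module.
Repetition counts default to modest values suited to a single CPU; the
paper-scale statistics use the same code with more repetitions.
"""

from __future__ import annotations

import numpy as np

from .connectivity import build_connectivity
from .measures import (aspl, detect_active_set, detect_assembly,
                       group_weight_summary, relative_recruitment, rvo)
from .network import init_state, simulate_span
from .params import ModelParams
from .protocols import (Manipulation, apply_manipulation, degrade_pattern,
                        make_stimulus, make_stimulus_pair, run_protocol,
                        sequential_protocol, single_phase_protocol,
                        standard_protocol)

__all__ = [
    "train_two_stimuli", "train_single_stimulus",
    "run_formation_experiment", "run_disparity_sweep",
    "run_pattern_completion", "run_recruitment_experiment",
    "run_capacity_probe",
]


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Independent child seeds (< 2**31) from one base seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def train_single_stimulus(seed: int, params: ModelParams | None = None,
                          manipulation: Manipulation | None = None,
                          keep_snapshots: bool = False):
    """Wire, initialize and train a network on one stimulus (test0, learn,
    test1).  Returns (record, conn, stimulus)."""
    params = ModelParams() if params is None else params
    rng = np.random.default_rng(seed)
    conn = build_connectivity(params, rng)
    state = init_state(params, conn, rng)
    s1, _ = make_stimulus_pair(1.0, params.nI, params.nI // 2, rng,
                               rate=params.input_rate)
    if manipulation is not None:
        params, state = apply_manipulation(params, state, manipulation)
    record = run_protocol(state, single_phase_protocol(s1), params, conn,
                          keep_snapshots=keep_snapshots)
    return record, conn, s1


def train_two_stimuli(seed: int, disparity: float = 1.0,
                      params: ModelParams | None = None,
                      keep_snapshots: bool = False):
    """Full two-phase protocol (test0, learn S1, test1, learn S2, test2).
    Returns (record, conn, s1, s2)."""
    params = ModelParams() if params is None else params
    rng = np.random.default_rng(seed)
    conn = build_connectivity(params, rng)
    state = init_state(params, conn, rng)
    s1, s2 = make_stimulus_pair(disparity, params.nI, params.nI // 2, rng,
                                rate=params.input_rate)
    record = run_protocol(state, standard_protocol(s1, s2), params, conn,
                          keep_snapshots=keep_snapshots)
    return record, conn, s1, s2


def run_formation_experiment(seed: int, params: ModelParams | None = None) -> dict:
    """Two-stimulus formation/allocation run with the standard measures:
    ASPL of each stimulus-evoked active set per test phase, group-averaged
    weights, assembly reports and the final RVO."""
    params = ModelParams() if params is None else params
    record, conn, s1, s2 = train_two_stimuli(seed, 1.0, params,
                                             keep_snapshots=True)
    out = {"seed": seed, "aspl": {}, "assemblies": {}, "group_weights": {}}
    for label in ("test0", "test1", "test2"):
        out["aspl"][label] = {}
        for stim in (s1, s2):
            # relative threshold: before learning no neuron reaches alpha/2,
            # but the wiring of the most-activated set is still meaningful
            active = detect_active_set(
                record.test_rates[label][stim.name], params.alpha,
                relative=True)
            if active.size >= 2:
                mean_len, n_disc = aspl(active, conn.c_rec)
            else:
                mean_len, n_disc = float("nan"), 0
            out["aspl"][label][stim.name] = {
                "value": mean_len, "n_active": int(active.size),
                "n_disconnected_pairs": n_disc,
            }
    ha1 = detect_assembly(record, conn, s1, "test1")
    ha2 = detect_assembly(record, conn, s2, "test2")
    out["assemblies"] = {"HA1": ha1, "HA2": ha2}
    out["rvo_final"] = rvo(record.active_set("test2", s1.name),
                           record.active_set("test2", s2.name))
    groups = {
        "HA1": ha1.members,
        "HA2": np.setdiff1d(ha2.members, ha1.members),
        "RR": np.setdiff1d(np.arange(params.nM),
                           np.union1d(ha1.members, ha2.members)),
        "I1": sorted(s1.active_set),
        "I2": sorted(s2.active_set),
    }
    for label in ("test0", "test1", "test2"):
        out["group_weights"][label] = group_weight_summary(
            record.snapshots[label], conn, groups)
    return out


def run_disparity_sweep(disparities, n_seeds: int = 10, seed: int = 0,
                        params: ModelParams | None = None) -> dict:
    """Mean final-test RVO per stimulus disparity across seeds."""
    params = ModelParams() if params is None else params
    seeds = _spawn_seeds(seed, n_seeds)
    curve, per_seed = {}, {}
    for d in disparities:
        vals = []
        for s in seeds:
            record, conn, s1, s2 = train_two_stimuli(s, float(d), params)
            vals.append(rvo(record.active_set("test2", s1.name),
                            record.active_set("test2", s2.name)))
        curve[float(d)] = float(np.mean(vals))
        per_seed[float(d)] = vals
    return {"disparities": list(map(float, disparities)), "mean_rvo": curve,
            "per_seed": per_seed, "seeds": seeds}


def run_pattern_completion(fractions, n_seeds: int = 10, seed: int = 0,
                           params: ModelParams | None = None,
                           probe_duration: float = 2.0,
                           n_draws: int = 3) -> dict:
    """Fraction of assembly members reactivated by degraded recall cues.

    Per seed the network is trained on S1 once; each degraded cue (a random
    subset of the learned inputs) is then presented for ``probe_duration``
    with plasticity off, starting from the trained state.  Near the ignition
    threshold (about half the inputs) pattern completion takes on the order
    of a second to run to completion, so recall cues are held for 2 s by
    default rather than the 0.5 s used in structural test phases.  Because
    ignition near threshold depends on which inputs the cue keeps, each
    fraction is probed with ``n_draws`` independent cue draws per seed."""
    params = ModelParams() if params is None else params
    seeds = _spawn_seeds(seed, n_seeds)
    fractions = [float(f) for f in fractions]
    per_seed = {f: [] for f in fractions}
    for s in seeds:
        record, conn, s1 = train_single_stimulus(s, params)
        ha = detect_assembly(record, conn, s1, "test1")
        if ha.empty:
            continue
        rng = np.random.default_rng(s + 1)
        base_state = record.final_state
        for f in fractions:
            for _ in range(n_draws):
                cue = degrade_pattern(s1, f, rng)
                st = base_state.copy()
                st.u[:] = 0.0      # recall probes start from quiescence
                st.u_inh = 0.0
                simulate_span(st, cue.rates(), probe_duration, params, conn,
                              plastic=False)
                active = detect_active_set(st.rates(params), params.alpha)
                per_seed[f].append(
                    len(set(active) & set(ha.members)) / ha.size)
    curve = {f: float(np.mean(v)) if v else float("nan")
             for f, v in per_seed.items()}
    return {"fractions": fractions, "mean_active_fraction": curve,
            "per_seed": per_seed, "seeds": seeds}


def run_recruitment_experiment(delta_epsilons=(-28.0, 28.0),
                               weight_factor: float = 0.1,
                               n_reps: int = 20, seed: int = 0,
                               params: ModelParams | None = None,
                               region_radius: float = 5.3) -> dict:
    """Excitability-manipulation experiment.

    Conditions: every requested excitability shift on its own, plus the
    counterbalancing condition (most negative shift combined with incoming
    weight pre-scaling by ``weight_factor``).  Per repetition a fresh wiring
    and a fresh random circular region (~10% of the grid) are drawn; the
    relative recruitment factor compares recruitment probability inside the
    region to the unmanipulated remainder.

    The default shift magnitude (28, in membrane-potential units of the
    sigmoid inflection) is calibrated so that pre-scaling the manipulated
    population's incoming weights by 0.1 restores recruitment to the control
    level, the published counterbalancing prediction."""
    params = ModelParams() if params is None else params
    seeds = _spawn_seeds(seed, n_reps)
    conditions = [(float(d), 1.0) for d in delta_epsilons]
    boost = float(min(delta_epsilons))
    conditions.append((boost, float(weight_factor)))
    factors = {}
    for d_eps, w_fac in conditions:
        memberships, regions = [], []
        for s in seeds:
            rng = np.random.default_rng(s + 10_000)
            manip = Manipulation.random_disk(params, rng, delta_epsilon=d_eps,
                                             weight_factor=w_fac,
                                             radius=region_radius)
            record, conn, s1 = train_single_stimulus(s, params, manipulation=manip)
            ha = detect_assembly(record, conn, s1, "test1")
            memberships.append(ha.members)
            regions.append(manip.region)
        factors[(d_eps, w_fac)] = relative_recruitment(memberships, regions,
                                                       params.nM)
    return {"factors": factors, "n_reps": n_reps, "seeds": seeds,
            "conditions": conditions}


def _low_overlap_patterns(n_stimuli: int, nI: int, size: int,
                          rng: np.random.Generator,
                          max_overlap: int | None = None):
    """Index sets of ``size`` inputs with minimal pairwise overlap.

    Each pattern picks the currently least-used inputs with random
    tie-breaking, so two patterns come out disjoint (for size <= nI/2) and
    larger sets approach the counting lower bound on overlap (~7 shared
    inputs for five half-size patterns on 36 inputs).  If ``max_overlap`` is
    given the construction is verified against it and an error raised when
    the requested cap is infeasible."""
    usage = np.zeros(nI, dtype=int)
    patterns = []
    for _ in range(n_stimuli):
        order = np.lexsort((rng.random(nI), usage))
        chosen = set(int(i) for i in order[:size])
        patterns.append(chosen)
        usage[list(chosen)] += 1
    if max_overlap is not None:
        worst = max((len(a & b) for i, a in enumerate(patterns)
                     for b in patterns[i + 1:]), default=0)
        if worst > max_overlap:
            raise ValueError(
                f"cannot draw {n_stimuli} patterns of size {size} from {nI} "
                f"inputs with pairwise overlap <= {max_overlap} "
                f"(best achieved: {worst})")
    return patterns


def run_capacity_probe(n_stimuli: int = 5, n_seeds: int = 1, seed: int = 0,
                       params: ModelParams | None = None,
                       max_overlap: int | None = None) -> dict:
    """Sequential learning of several low-overlap stimuli.

    Patterns are drawn by input-usage balancing (see _low_overlap_patterns):
    with half-size patterns a counting argument forces a mean pairwise
    overlap of ~7 inputs for five stimuli, so a hard low cap is infeasible
    and the probe instead uses the minimal-overlap construction, optionally
    verified against ``max_overlap``.

    After each learning phase every previously learned stimulus is probed in
    the test phase; a neuron of an earlier assembly that shows up in the
    newly formed one counts as re-assigned.  Reports the per-stimulus
    re-assignment counts and the first stimulus index at which interference
    (any re-assignment) occurs."""
    params = ModelParams() if params is None else params
    seeds = _spawn_seeds(seed, n_seeds)
    runs = []
    for s in seeds:
        rng = np.random.default_rng(s)
        conn = build_connectivity(params, rng)
        state = init_state(params, conn, rng)
        sets = _low_overlap_patterns(n_stimuli, params.nI, params.nI // 2,
                                     rng, max_overlap)
        stimuli = [make_stimulus(a, params.nI, params.input_rate, name=f"S{i+1}")
                   for i, a in enumerate(sets)]
        record = run_protocol(state, sequential_protocol(stimuli), params, conn)
        assemblies = {}
        reassigned, first_interference = [], None
        for i, stim in enumerate(stimuli, start=1):
            members = set(record.active_set(f"test{i}", stim.name).tolist())
            n_taken = sum(len(members & prev) for prev in assemblies.values())
            reassigned.append(n_taken)
            if n_taken > 0 and first_interference is None:
                first_interference = i
            # keep each earlier assembly as detected right after its own phase,
            # minus any neurons the new assembly claimed
            for k in assemblies:
                assemblies[k] -= members
            assemblies[stim.name] = members
        runs.append({"seed": s, "reassigned": reassigned,
                     "first_interference": first_interference,
                     "assembly_sizes": {k: len(v) for k, v in assemblies.items()}})
    return {"runs": runs, "n_stimuli": n_stimuli}
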