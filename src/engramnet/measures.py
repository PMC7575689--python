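"""Structural and functional readouts of the trained network.

Key quantities: the set of highly activated neurons during a test
presentation, assembly membership and its wiring statistics, the average
shortest path length (ASPL) among active neurons on the recurrent graph, the
response vector overlap (RVO) between two stimulus-evoked active sets, and
group-averaged synaptic weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra

__all__ = [
    "AssemblyReport", "detect_active_set", "detect_assembly", "aspl", "rvo",
    "group_weight_summary", "relative_recruitment",
]


def detect_active_set(rates: np.ndarray, alpha: float = 100.0,
                      threshold_fraction: float = 0.5,
                      relative: bool = False) -> np.ndarray:
    """Indices of highly activated neurons.

    Absolute mode (default): rate >= threshold_fraction * alpha.  After
    learning the rate distribution is bimodal (near 0 or near alpha), so
    membership is insensitive to the threshold over a broad band around one
    half.  Relative mode: rate >= threshold_fraction * max(rate) — needed
    before learning, when the most active neurons sit far below alpha but
    their wiring is still the quantity of interest (both modes coincide once
    an assembly saturates)."""
    rates = np.asarray(rates)
    ref = rates.max() if relative else alpha
    if relative and ref <= 0:
        return np.array([], dtype=int)
    return np.flatnonzero(rates >= threshold_fraction * ref)


@dataclass
class AssemblyReport:
    """Membership and wiring statistics of a detected Hebbian assembly."""

    members: np.ndarray          # sorted memory-neuron indices
    size: int
    mean_in_rec_degree: float    # mean # existing recurrent inputs from co-members
    mean_active_ff: float        # mean # existing ff inputs from the stimulus's active set
    empty: bool = False


def detect_assembly(record, conn, stimulus, test_label: str = "test1",
                    threshold_fraction: float = 0.5) -> AssemblyReport:
    """Assembly evoked by ``stimulus`` in the test phase after learning.

    Members are the highly activated neurons at the final step of the
    stimulus's presentation in ``test_label``.  The report adds the mean
    within-assembly recurrent in-degree and the mean count of feed-forward
    connections arriving from the stimulus's active inputs — the structural
    quantities that parameterize the reduced population model.
    An empty assembly is flagged, not raised."""
    rates = record.test_rates[test_label][stimulus.name or "p0"]
    members = detect_active_set(rates, record.params.alpha, threshold_fraction)
    if members.size == 0:
        return AssemblyReport(members=members, size=0, mean_in_rec_degree=np.nan,
                              mean_active_ff=np.nan, empty=True)
    sub = conn.c_rec[members][:, members]
    mean_deg = float(np.asarray(sub.sum(axis=1)).ravel().mean())
    active_inputs = sorted(stimulus.active_set)
    mean_ff = float(conn.c_ff[np.ix_(members, active_inputs)].sum(axis=1).mean())
    return AssemblyReport(members=members, size=int(members.size),
                          mean_in_rec_degree=mean_deg, mean_active_ff=mean_ff)


def aspl(active_set, c_rec) -> tuple[float, int]:
    """Average shortest path length among active neurons.

    Path lengths are hop counts on the undirected, unweighted recurrent
    wiring graph; paths may pass through inactive neurons.  Returns
    ``(mean_length, n_disconnected_pairs)`` over unordered pairs of distinct
    active neurons; mutually unreachable pairs are excluded from the mean and
    counted separately.
    """
    active = np.asarray(sorted(set(int(i) for i in active_set)))
    if active.size < 2:
        raise ValueError("ASPL needs at least two active neurons")
    graph = sp.csr_matrix(c_rec, dtype=float)
    dist = dijkstra(graph, directed=False, unweighted=True, indices=active)
    dist = dist[:, active]
    iu = np.triu_indices(active.size, k=1)
    pair_d = dist[iu]
    finite = np.isfinite(pair_d)
    n_disconnected = int((~finite).sum())
    if not finite.any():
        return float("nan"), n_disconnected
    return float(pair_d[finite].mean()), n_disconnected


def rvo(setA, setB) -> int:
    """Response vector overlap: number of neurons activated by both stimuli."""
    return len(set(int(i) for i in setA) & set(int(i) for i in setB))


def group_weight_summary(state, conn, groups: dict) -> dict:
    """Mean synaptic weight per (source group -> target group) pair.

    ``groups`` maps a name to memory-neuron indices (e.g. HA1, HA2, RR) or,
    with the prefix convention 'I...', to input-neuron indices (e.g. I1, I2).
    Averages run over *existing* connections only; a pair with no existing
    connection is reported as NaN.

    Returns {"rec": {(src, dst): mean}, "ff": {(src, dst): mean}} where rec
    pairs use memory groups on both sides and ff pairs use an input-area
    source group and a memory-area target group."""
    mem_groups = {k: np.asarray(v, dtype=int) for k, v in groups.items()
                  if not k.startswith("I")}
    in_groups = {k: np.asarray(v, dtype=int) for k, v in groups.items()
                 if k.startswith("I")}
    W = sp.csr_matrix(state.W_rec)
    C = conn.c_rec.tocsr()
    out = {"rec": {}, "ff": {}}
    for src_name, src in mem_groups.items():
        for dst_name, dst in mem_groups.items():
            mask = C[dst][:, src]
            n_exist = mask.nnz
            if n_exist == 0:
                out["rec"][(src_name, dst_name)] = float("nan")
                continue
            w = W[dst][:, src]
            out["rec"][(src_name, dst_name)] = float(w.sum() / n_exist)
    for src_name, src in in_groups.items():
        for dst_name, dst in mem_groups.items():
            cmask = conn.c_ff[np.ix_(dst, src)]
            n_exist = int(cmask.sum())
            if n_exist == 0:
                out["ff"][(src_name, dst_name)] = float("nan")
                continue
            out["ff"][(src_name, dst_name)] = float(
                state.W_ff[np.ix_(dst, src)][cmask].sum() / n_exist
            )
    return out


def relative_recruitment(memberships, regions, nM: int) -> float:
    """Recruitment probability of manipulated neurons relative to control.

    For each repetition r, ``memberships[r]`` is the set of assembly members
    and ``regions[r]`` the manipulated neuron indices.  Per repetition the
    recruitment probability is estimated inside and outside the region; the
    ratio of the across-repetition mean probabilities is returned.

    Raises if the control probability is zero in every repetition (the factor
    is then not estimable)."""
    if len(memberships) != len(regions) or len(memberships) < 2:
        raise ValueError("need >= 2 repetitions with matching regions")
    p_manip, p_ctrl = [], []
    for members, region in zip(memberships, regions):
        members = set(int(i) for i in members)
        region = set(int(i) for i in region)
        control = set(range(nM)) - region
        p_manip.append(len(members & region) / len(region))
        p_ctrl.append(len(members & control) / len(control))
    mean_ctrl = float(np.mean(p_ctrl))
    if mean_ctrl == 0.0:
        raise ZeroDivisionError("control recruitment probability is zero; "
                                "relative factor not estimable")
    return float(np.mean(p_manip)) / mean_ctrl
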