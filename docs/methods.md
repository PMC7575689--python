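# Methods

## Model

`engramnet` simulates a two-area rate network: an input area of `nI = 36`
excitatory neurons whose firing rates are imposed (0 or 130 Hz), a memory
area of `nM = 900` excitatory neurons on a 30×30 grid with torus-like
periodic boundaries, and one global inhibitory unit standing in for an
inhibitory population. Every memory neuron is a leaky integrator,

    du_i/dt = −u_i/τ + R ( Σ_j w_rec_ij F_j − w_i,inh F_inh + Σ_k w_ff_ik I_k ),

with a sigmoidal potential-to-rate transfer

    F(u) = α / (1 + exp(β(ϵ − u))),

and the inhibitory unit integrates the summed memory-area rate with its own
time constant. The inhibitory weight onto memory neurons is stored as the
magnitude 1200 and applied with negative sign; the unit is inhibitory, so
its recurrent term enters the membrane equation subtractively.

Excitatory synapses (feed-forward and recurrent) are plastic under Hebbian
growth combined with synaptic scaling,

    dw/dt = μ ( F_post · F_pre + κ⁻¹ (F_T − F_post) w² ),

restricted to existing connections. The scaling term pushes the
postsynaptic rate toward the target F_T = 0.1 Hz and, because it is
proportional to w², it bounds the otherwise divergent Hebbian growth: a
synapse whose pre- and postsynaptic partners both saturate at α settles at
the balance weight ŵ = sqrt(κ F_pre F_post / (F_post − F_T)), ≈77.5 for
recurrent synapses (κ_rec = 60) and ≈306.1 for feed-forward synapses driven
at 130 Hz (κ_ff = 720).

### Wiring and initial conditions

Each memory neuron connects recurrently to every neuron within Euclidean
distance 4 on the periodic grid (48 neighbors) and receives feed-forward
synapses from exactly 4 input neurons drawn uniformly without replacement.
Recurrent weights start homogeneously at 0.25·ŵ_rec; feed-forward weights
are drawn i.i.d. from the continuous uniform distribution on
[0, 0.7·ŵ_ff]. One integer seed per repetition drives the wiring, the
initial weights and all pattern draws.

### Integration

Explicit Euler with dt = 5 ms. The step is stable for all state variables
(dt/τ = 0.5, dt/τ_inh = 0.25; the linearized scaling relaxation rate at ŵ
is ≈17 s⁻¹, far from the Euler stability bound). Weights are clamped at
zero after each plastic step as a guard against overshoot at this step
size; in the continuum limit the w² depression term cannot cross zero, which
the test suite verifies on a finely resolved single synapse. A compiled
(numba) kernel fuses the per-step operations over the sparse recurrent
edge list; it is numerically identical to the pure-numpy reference step up
to summation order, which the suite also asserts.

## Protocols

A stimulus activates half of the input neurons (18 of 36) at 130 Hz. A
learning phase presents the stimulus 10 times for 5 s with 1 s silent
pauses in between; plasticity stays on during pauses. Test phases present
each stimulus for 0.5 s with plasticity frozen. The standard schedule is
test0 · learn S1 · test1 · learn S2 · test2.

**Probing from quiescence.** A formed assembly is self-sustaining: its
recurrent drive alone holds it above the transfer inflection even with all
inputs silent. Sequentially presenting test stimuli without a reset would
therefore measure mostly the history of the preceding phase. At the onset
of every test presentation the membrane potentials (u, u_inh) are reset to
zero — the same convention the phase-space analyses use — so each probe
measures the response the weight structure produces from rest. Weights are
never touched by the reset.

**Recall cues.** Degraded recall presents a uniformly drawn subset of the
learned input pattern. Near the ignition threshold (about half the
inputs) pattern completion takes on the order of a second, so recall
probes run for 2 s rather than the 0.5 s used in structural test phases;
the reported recall fraction is taken at the end of the probe.

**Excitability manipulations.** A circular disk of grid radius 5.3
(89 neurons, ~10% of the memory area, center uniform per repetition) has
its transfer inflection shifted by Δϵ (negative = more excitable) before
learning; optionally all incoming plastic weights of the disk are
pre-scaled by a factor. The default |Δϵ| = 28 is calibrated so that
pre-scaling the incoming weights by 0.1 counterbalances the excitability
advantage — the published prediction for that manipulation pair. The
relative recruitment factor divides the mean recruitment probability of
manipulated neurons by that of the unmanipulated remainder, probabilities
estimated per repetition and averaged before taking the ratio.

## Measures

- **Active set:** neurons with F ≥ α/2 at the final step of a test
  presentation. After learning the rate distribution is strongly bimodal,
  so membership is insensitive to the threshold over roughly [0.3, 0.7]·α.
  Before learning no neuron comes near α/2, so the ASPL of the
  pre-learning response uses a relative criterion, F ≥ 0.5·max F; the two
  coincide once an assembly saturates.
- **Assembly report:** members, size, mean within-assembly recurrent
  in-degree, and mean number of feed-forward connections from the learned
  stimulus's active inputs. The latter two are the inputs (n_rec, n_ff) of
  the reduced population model; measured values across seeds are ≈34 and
  ≈2.3 for the reference parameters.
- **ASPL:** mean hop count between pairs of active neurons on the
  undirected, unweighted recurrent wiring graph; paths may pass through
  inactive neurons. Mutually unreachable pairs are excluded from the mean
  and reported separately. 1 means every active pair is directly wired.
- **RVO:** the number of memory neurons activated by both of two stimuli in
  the same test phase — the pattern-separation readout.
- **Group weights:** means over existing connections for each
  (source group → target group) pair, with groups {I1, I2, HA1, HA2, RR}
  determined retroactively from the detected assemblies.

## Reduced population model

Two candidate assemblies of N = 120 neurons interact only through the
shared inhibitory unit. Each population carries its mean potential, mean
recurrent weight and mean feed-forward weights from the two input
populations: nine ODEs with the same parameters as the network plus the
measured averages n_rec = 35 (recurrent in-degree) and n_ff = 2.3 (fan-in
from active inputs).

**Fixed points.** The 9-D steady-state problem reduces to the (ū1, ū2)
plane: the inhibitory potential and all six weights have closed-form steady
states given the two rates (w* = sqrt(κ F_post F_pre/(F_post − F_T)); a
silent input's weight rests at 0, a neutrally stable equilibrium that is
attracting from w > 0 and is excluded from the stability classification).
Sign changes of the two residual potential equations on a grid seed a
Newton-type root polish; roots are mapped back to the full state, their
residuals verified below 1e-8, and classified through the eigenvalues of a
central-finite-difference Jacobian (h = 1e-6 per-coordinate scale) of the
dynamically active dimensions. The search window ū ∈ [−10, 320] contains
every state with F > F_T; below F_T the weight dynamics has no finite
balance, so no fixed point exists there.

At the working amplitude Ī_A = 130 the portrait has two stable asymmetric
fixed points (one population potentiated to ŵ_rec, the loser's recurrent
weight at ~7.5% of it), a saddle on the identity line, and a cluster of
high/high states that is unreachable from weak initial weights. Trained
full networks land within a few percent of the potentiated fixed point.

**Bifurcation scan.** Two thresholds are reported. Stable asymmetric fixed
points *exist* over a wide amplitude range (down to ~43 Hz, where the
suppressed population's rate meets F_T — though with its feed-forward
weight far above ŵ). Formation from a blank network is governed instead by
the stable symmetric low-activity branch: it persists up to ≈129 Hz and
only above that amplitude is the system forced to an assembly state. The
scan's `threshold` field reports this formation threshold; the full network,
whose quenched fan-in heterogeneity effectively hands some neurons a larger
n_ff, starts forming assemblies from ≈115 Hz.

**Basins.** Basin maps integrate a grid of initial (w1A_ff, w1_rec)
combinations (u ≡ 0, competitor weights fixed, silent input's synapses
neglected) for 100 s, batched over all cells, and call a population active
if its final rate exceeds α/2 (labels pop1/pop2/none/both; default grid
50×50). The feed-forward change map integrates the scalar weight ODE at
clamped pre/post rates for one learning phase's stimulus-on time (50 s) and
classifies homosynaptic potentiation, heterosynaptic depression, and the
two negligible low-postsynaptic-activity cases with a 5%·ŵ_ff band.

## Simulation sizes and repetitions

Summary statistics use 10 fresh seeds (assembly statistics, recall,
separation) and 20 repetitions for the recruitment experiment; the original
analyses used 100. All repetition counts are parameters. A full two-phase
run integrates ~122 s of model time (24,400 Euler steps); a single-phase
training ~61 s. The acceptance script (`scripts/acceptance.py`) re-derives
every reported quantity from scratch at these sizes.

## What the generator does and does not emulate

All inputs are synthetic by construction (the model is the object of
study): binary input patterns, random wiring, uniform initial weights.
The model abstracts away spiking, conductances, dendritic structure,
multiple inhibitory populations, plasticity of inhibitory synapses, and
calcium-mediated delays in the scaling signal (deviation detection is
instantaneous). Passing tests show the self-organization properties of
this rate-level model, not of biological tissue.

## Known limitations

- The formation threshold of the reduced model (≈129 Hz) sits above the
  full network's (≈115 Hz); the mean-field reduction ignores fan-in
  heterogeneity, which seeds ignition in the full network.
- Recall ignition near threshold is all-or-none per cue draw: a cue keeping
  half of the learned inputs ignites the assembly only part of the time
  (when it does, ~80% of members activate), and reliable completion needs
  ~55–60% of the inputs. The completion curve is correspondingly steep
  between one half and two thirds of the cue.
- Sequential storage interferes once patterns overlap substantially;
  half-size patterns on 36 inputs cannot have pairwise overlap below ~7
  shared inputs for five stimuli (counting bound), so the capacity probe
  uses a minimal-overlap construction rather than a hard cap.
- Stability classification treats eigenvalues within 1e-6 of zero as
  neutral (silent-input weight directions).
- With dt = 5 ms the explicit Euler endpoint differs from a fine-dt
  reference by O(dt); all reported statistics are threshold-based and
  insensitive at this resolution.
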