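# Methods

`snnpong` is a closed-loop sensorimotor model: a spiking network watches a
racket-ball court through a simple retina, decides every action interval
whether to move its racket up or down, and learns from reward-modulated
spike-timing-dependent plasticity (STDP-RL).  This note documents the model,
its parameters, the numerical choices, and what the desk-scale experiments
do and do not show.

## The game

A 160x160-pixel court contains a 4x4 ball and a 4x16 racket fixed at column
140.  Serves start at the left edge at one of five rows {40, 60, 80, 100,
120} with displacement (dx, dy) drawn from {1,2,3}x{1,2,3} per game-step;
the vertical sign of the serve is drawn uniformly.  Top and bottom walls
reflect the vertical velocity without other change.  The left wall and the
racket reverse the horizontal velocity and redraw the vertical velocity
(magnitude uniform on {1,2,3}, sign uniform); contact with the racket's
outer quarters additionally doubles both velocity components, capped at 6
px/step per component so that a swept (sub-pixel) collision test can never
be tunnelled through.  Hits score +1, misses score -1 and trigger an
immediate re-serve.  Coordinates are image-frame (origin top-left, y grows
downward); "UP" decreases y.  The racket moves 4 px per action, a
configurable default chosen so the racket can out-run any un-doubled serve.

The projected-intercept oracle extrapolates the ball center to the racket
column assuming wall reflections and no racket.  Because reflections
preserve vertical speed, the trajectory is a triangle wave and the crossing
row folds in closed form with integer arithmetic; a rational-arithmetic ray
tracer in the test suite confirms exact agreement.

### Intermediate reward

Each action earns +0.1 if it moved the racket center toward the projected
intercept row, or held it on target — within half a racket step, the finest
alignment a 4-px actuator can reach — and -0.01 otherwise.  Holding still
away from the ball, or pressing into the court wall (a clamped move that
changes nothing), counts as not contributing and is punished.  This last
point matters: if unchanged distance were rewarded, a racket pinned against
a wall would collect +0.1 every 20 ms forever, and targeted RL would
amplify that into a one-action policy.  No projection exists while the ball
moves away from the racket; those steps carry no intermediate critic.

## Neurons

Cells are event-driven rule-based units with three classes (Table below):
excitatory E, fast-spiking inhibitory I, low-threshold inhibitory IL.

| class | V_rest | V_thresh | V_block | tau_AR | W_RR | tau_RR | dV_AHP | tau_AHP |
|-------|--------|----------|---------|--------|------|--------|--------|---------|
| E     | -65    | -40      | -25     | 5 ms   | 0.75 | 8 ms   | 1 mV   | 400 ms  |
| I     | -63    | -40      | -10     | 2.5    | 0.25 | 1.5    | 0.5    | 50      |
| IL    | -65    | -47      | -10     | 2.5    | 0.25 | 1.5    | 0.5    | 50      |

The membrane voltage is composed additively from per-synapse-type voltages,
the after-hyperpolarization variable and rest:

    V_m = V_rest + V_AM2 + V_NM2 - V_GA - V_GA2 - V_AHP

Every component decays exponentially with its own time constant, so between
events the state is advanced analytically (lazy evaluation); thresholds are
checked only at event times, which loses no crossings because V_m moves
monotonically toward rest between events.  A spike requires V_m at or above
the dynamic threshold, at or below the blockade voltage V_block
(depolarization blockade: an over-driven cell fails to spike), and an
expired absolute refractory clock.  After a spike, V_AHP increments by
dV_AHP (hyperpolarizing V_m), the threshold jumps by W_RR (V_block -
V_thresh) and relaxes back with tau_RR, and the refractory clock is set to
tau_AR.  There is no separate leak: V_m relaxes to rest through the decay
of its components.

## Synapses

Four kinds: AM2 (AMPA, E_syn +65 mV rel. rest, tau 10 ms), NM2 (NMDA, +90,
300 ms), GA (somatic GABA-A, -15, 10 ms), GA2 (dendritic GABA-A, -15,
20 ms).  An event increments the matching synaptic voltage stepwise by

    dV = W_syn (1 - V_dev / E_syn)

with V_dev the deviation from rest, so increments vanish at the reversal
potential.  GABA-A voltages accumulate through the same formula and are
subtracted from V_m, which hyperpolarizes at rest and clamps at -15 mV.
Delays are fixed at wiring time: dendritic synapses (AM2/NM2/GA2) uniform
3-5 ms, somatic (GA) 1.8-2.2 ms, external drive 1.8-2.2 ms.  NM2 is treated
as dendritic; no extra NMDA voltage dependence beyond the driving-force
formula is modeled.  Plastic weights live in a configurable corridor
[w_min_mult, w_max_mult] x initial weight (defaults 0 and 4).

## Architectures

The **feedforward** model: 6400 location-encoding EV1 neurons (one per
input pixel), eight 400-neuron direction-selective populations (EV1D, one
per compass direction on a coarser 20x20 grid), two 1400-neuron association
layers EA and EA2, two 300-neuron motor populations EMUP/EMDOWN, and motor
interneurons (206 IM, 94 IML).  Wiring is random convergent with exact
in-degrees (e.g. each EA neuron receives 128 EV1 and 8 inputs from each
EV1D population; each motor neuron 30 EA and 30 EA2); only EA→EM and
EA2→EM AMPA synapses are plastic.  The **recurrent** model drops the
direction populations and adds recurrence (EA→EA, EA2→EA2, EM→EM),
feedback (EA2→EA, EM→EA, EM→EA2), interneurons in every area, reciprocal
motor-subpopulation inhibition wired independently at p = 0.125, and a
background Poisson noise drive (default 5 Hz, weight 0.1x the target
population's mean excitatory input weight) to association and motor
populations to keep minimum rates and exploration.  Plasticity extends to
the recurrent/feedback excitatory projections.  `validate_network` audits
every projection's in-degrees, initial weights, delay class and plasticity
flag against the table and reports any deviation.

Where a projection runs through both AMPA and NMDA with equal convergence,
both kinds share one partner draw (each anatomical input is implemented by
an AMPA and an NMDA synapse).  Autapses are excluded in recurrent
projections.

### Desk-scale reduction

`scale = k` shrinks the court by k and the network accordingly (input
pixels fall quadratically).  Two regimes are scaled differently:

* **Visual input rows** (EV1/EV1D sources): per-neuron *total* initial
  input weight is preserved while convergence shrinks, with per-event
  weights capped at 20 mV (below the 25 mV threshold gap).  The driven
  pixel count shrinks with the court, so without this boost the association
  layer would fall silent.
* **Deeper rows** keep their original convergence and weight, clipped to
  the smaller pools.  This preserves the number of coincident presynaptic
  events a cell needs to fire.  Preserving totals here instead would
  multiply per-event weights ~k-fold, lifting single EPSPs past threshold
  and into depolarization blockade; measured consequences were dense,
  stimulus-insensitive motor firing and a degenerate winner-take-all.

The same principle — tune initial weights so every area fires stably in a
physiological range — is how the full-size models' weights were set by
hand in the first place.

## Encoding and decoding

Frames are binarized and 2x block-downsampled (a block is set if any
constituent pixel is set) to 80x80.  Each set pixel drives its EV1 neuron
through an independent Poisson process (20 Hz feedforward / 35 Hz
recurrent), all-or-none, sampled by exponential inter-arrival times within
each game-step.  Object motion is computed from the last two frames:
connected components are matched by nearest centroid, displacement is
quantized to the nearest of 8 compass bins (north = screen-up), and the
object's pixels drive the matching direction population at the same rate.
Unmoved objects drive nothing.  The external drive weight (40 mV) makes a
visual neuron relay its Poisson input approximately one-to-one.

Actions are decoded winner-take-all from raw motor spike counts per action
interval (20 ms feedforward / 50 ms recurrent, equal to the game-step):
more EMUP spikes → UP, more EMDOWN → DOWN, tie → STAY.

## Learning rule

A causal pre→post spike pair within the 10 ms STDP window tags the synapse
with an eligibility trace (value 1 at the post-spike time, replace on
re-tag, exponential decay with tau = 50 ms for intermediate rewards, 10 s
for sparse rewards).  Traces persist through critic deliveries.  A critic
of value c changes each eligible plastic weight by

    dW = learning_rate * gain(c) * c * trace * mode_scale

with gain asymmetric (punishment_gain < reward_gain; defaults 0.5 vs 1.0).
Modes: `non_targeted` applies the critic to every plastic synapse;
`targeted` applies it fully to synapses onto the motor population that
generated the action and with opposite sign times `opposite_fraction` to
the other motor population (STAY generates no targeted critic);
`retrograde_targeted` additionally reaches plastic synapses k excitatory
hops upstream of the motor layer, scaled by `retrograde_decay_per_hop**k`.
Weights clip to the configured corridor.

## The desk-scale study

`snnpong.loop.desk_scale_study` is the package's canonical reduced
experiment: a 4x-reduced feedforward model on a 40x40 court, trained for
10 episodes x 60 s with targeted RL and the combined reward stream
(intermediate ±0.1/−0.01 and hit/miss ±1 through the single 50 ms trace,
as in the full feedforward protocol), and evaluated with frozen weights
for 6 x 20 s repeats on distinct initial ball/racket positions before and
after training.  Before/after evaluations share serve sequences and
initial positions (a paired design), so their difference reflects only the
learned weights.

Performance is the mean of the six per-repeat cumulative hit/miss ratios.

Its learning parameters (`DESK_PLASTICITY`) were calibrated by pilot runs
and then frozen: learning_rate 0.15, w_max 2x initial, w_min 0.25x
initial, opposite_fraction 0.1, punishment_gain 0.25.  The choices address
three failure modes observed during calibration: weight growth into the
blockade regime (hence the tight w_max), permanent silencing of the losing
motor population (a zero weight can never be re-tagged; hence w_min > 0),
and winner-take-all monoculture (hence the small opposite fraction and the
combined reward stream, whose large miss punishments counterweight the
intermediate reward's +0.1/-0.01 asymmetry; the punishment gain is kept
well below the reward gain so that those miss punishments reshape rather
than erase a policy that already plays well).

What passing shows: the three-factor rule assigns credit well enough, at
1/16 the neuron count and 1/50 the training time of the full model, for
behavior to improve reproducibly.  What it does not show: the full-size
models' absolute performance figures, their 20-40-episode learning curves,
or robustness to the recurrent model's richer dynamics — those require
cluster-scale runs of the full architectures.  Training can still degrade
seeds whose random initial wiring happens to play unusually well, the same
regression the full model shows for some ball trajectories.

## Numerics and determinism

All decays are exact closed-form exponentials; the event engine matches a
0.01 ms fixed-step reference integrator to 1e-6 mV and the scalar reference
cell to float precision.  Pending deliveries live in a calendar queue (ring
of 0.2 ms buckets); every synaptic delay exceeds the bucket width, so a
bucket can be sorted and drained without receiving new events, making the
queue O(1) per event.  Every random stream (serves, wiring, retina, noise)
descends from one master seed through named SeedSequence spawn keys;
replays are bit-identical, evaluation never mutates weights (enforced by
checksum), and checkpoints (HDF5) round-trip byte-identically.

## Known limitations

* No reward-prediction error: the critic is raw reward, so well-learned
  states keep being rewritten (the "forgetting" regime).
* No homeostatic scaling or synaptic turnover; the weight corridor is a
  blunt substitute.
* One eligibility timescale at a time; combining intermediate and sparse
  critics shares one trace, as in the full feedforward protocol.
* The retina tracks whole objects; no receptive fields, no speed tuning.
* Desk-scale statistics rest on 10 seeds and ~400 scoring events per
  evaluation; per-seed outcomes carry +/-0.05 ratio noise.
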