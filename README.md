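# snnpong

Spiking neuronal network models of visual-motor cortex that learn to play a
racket-ball game through reward-modulated spike-timing-dependent plasticity
(STDP-RL).

The package is for computational neuroscientists studying how biologically
plausible three-factor learning rules — eligibility traces gated by a scalar
reward/punishment "critic" — can train a sensorimotor circuit in a *dynamic*
environment, and how circuit architecture (feedforward vs recurrent/feedback)
shapes that learning.  It provides:

* a Pong-like **racket-ball environment** (160x160 court, bouncing ball,
  motor-controlled racket) with a projected-intercept oracle for per-action
  "intermediate" rewards;
* a **retina** that turns frames into Poisson spike trains for
  location-encoding and 8-way direction-selective populations;
* an exact **event-driven simulator** of rule-based point neurons
  (adaptation, relative/absolute refractoriness, depolarization blockade)
  with AMPA/NMDA/GABA-A synapses and distance-dependent delays;
* the **feedforward** (~13,300 neurons) and **recurrent** (~8,650 neurons)
  architectures with their full connectivity tables, plus principled
  desk-scale reductions;
* **STDP-RL** with exponentially decaying eligibility traces and three
  credit-assignment variants (non-targeted, targeted, retrograde-targeted),
  driven by intermediate (+0.1/-0.01) and/or sparse (+1/-1) critics;
* winner-take-all **motor decoding**, the closed **sense-spike-decide-act-
  reward loop**, HDF5 checkpointing, and the performance/participation
  **analyses** (cumulative hit/miss curves, per-trajectory learning curves,
  correct-move heatmaps, motor-neuron participation matrices).

## The learning rule

When a postsynaptic spike follows a presynaptic spike within a short window
(10 ms), the synapse is tagged with an eligibility trace that decays
exponentially (tau = 50 ms for intermediate rewards, 10 s for sparse).  A
critic of value c arriving at time t changes each eligible plastic weight by

    dW = eta * gain(c) * c * exp(-(t - t_tag)/tau) * mode_scale

where `gain` is asymmetric (punishments scaled down) and `mode_scale`
implements targeting: the motor population that generated the action gets
the full critic, the opposite population an attenuated critic of opposite
sign, and (in the retrograde variant) populations k synapses upstream a
critic scaled by a per-hop decay factor.  Actions are read out winner-take-
all from motor spike counts every 20 ms (feedforward) or 50 ms (recurrent).

## Worked example

The smallest end-to-end demonstration is the spiking two-armed bandit: one
input neuron, plastic synapses onto an UP and a DOWN motor neuron, targeted
RL with a fixed correct action:

```python
from snnpong.bandit import run_bandit

result = run_bandit(seed=1)
print(result["final_correct_fraction"])   # 0.73
print(result["reached_criterion"])        # True (trailing rate exceeded 0.75)
print(result["weights"])
# {'IN->EMUP:AM2': 40.0, 'IN->EMDOWN:AM2': 7.42}
```

Over 500 decisions the rewarded synapse potentiates to its bound (40, from
10) until the input alone drives UP, while the opposite synapse depresses
(7.4) — the weight separation *is* the learned policy.

The closed-loop equivalent at desk scale (a 4x-reduced feedforward model on
a 40x40 court, ~1,500 neurons, two minutes on one core):

```python
from snnpong.loop import desk_scale_study

r = desk_scale_study(seed=0)
print(r["pre_ratio"], r["post_ratio"])    # e.g. 0.43 -> 0.55
```

`pre_ratio`/`post_ratio` are mean cumulative hit/miss ratios over six
frozen-weight evaluations before and after 10 x 60 s training episodes: the
trained network hits the ball substantially more often per miss.  Full-size
models are built and audited the same way:

```bash
snnpong validate            # builds the full feedforward net, audits wiring
snnpong train --out runs/ff --episodes 2   # writes checkpoints + summaries
snnpong evaluate --checkpoint runs/ff/final.h5 --repeats 6
```

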