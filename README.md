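# idipnet

Spiking-network simulations of **input-dependent inhibitory plasticity
(IDIP)** — a network-centred homeostatic rule in which each inhibitory
neuron scales *all* of its outgoing inhibitory synapses according to the
synaptic input it receives, rather than to any single neuron's firing
rate.  The package is for computational neuroscientists who want to
reproduce, probe, or extend two circuit models built around this rule:

1. a **hippocampal CA3→CA1 place-cell circuit** on a 1D annular track, in
   which IDIP plus Hebbian feedforward plasticity produces active and
   silent place cells, rapid homeostatic remapping when the active map is
   optogenetically silenced, and consolidation of the alternative map
   under repeated silencing;
2. a **sparse random recurrent network** (80E/20I, lognormal weights,
   Poisson drive), in which IDIP turns pathologically high activity into
   a low asynchronous state while preserving firing-rate heterogeneity,
   stimulus representation, and persistent activity of an encoded memory
   ensemble — in contrast to the neuron-centred iSTDP baseline.

## The rule

Each inhibitory neuron *i* integrates its excitatory synaptic input,

    dy_i/dt = −y_i/τ_IDIP + Σ_j g_ij^E(t),        τ_IDIP = 160 ms

so y_i is an amplified running average of the summed input conductance
(fixed point τ_IDIP·⟨Σg⟩, in nS).  Whenever neuron *i* spikes, every
outgoing inhibitory weight moves by

    Δw = η_IDIP (y_i − θ_in)

— additively (clipped at 0) in the hippocampal model, or through a
multiplicative bound `w ← w + (W_max−w)Δw` (potentiation) /
`w ← w + wΔw` (depression) in the recurrent model.  The empirical fixed
point is that the *spike-triggered* average of y equals the target θ_in
(200 nS hippocampal, 550 nS recurrent), which pins the network's total
excitatory rate budget without assigning any neuron its own set point.
Model equations, parameter tables, unit conventions, and the reasoning
behind every choice the source material leaves open are in
[docs/methods.md](docs/methods.md).

## Worked example

Stabilize the recurrent network (IDIP enabled at 15 s, run until the
block-mean rate settles), then inspect the converged state:

```python
from idipnet.recurrent import build_recurrent_net, run_stabilization

rnet = build_recurrent_net(seed=1)
res = run_stabilization(rnet, max_duration=600_000.0,
                        final_window=100_000.0)
print(f"pre-plasticity rate : {res.rate_windows[0]:.1f} Hz")
print(f"converged mean rate : {res.final_rate:.2f} Hz")
print(f"spike-triggered y   : {res.sta_y:.0f} nS (target 550)")
```

prints, for this seed,

```
pre-plasticity rate : 91.9 Hz
converged mean rate : 4.21 Hz
spike-triggered y   : 530 nS (target 550)
```

i.e. the unstabilised network fires pathologically (~92 Hz); after
inhibitory learning the excitatory population settles to a low
asynchronous rate a few hertz above zero, and each interneuron's
spike-triggered input trace sits within a few percent of the 550 nS
target — the rule's fixed point.  The same experiment from
the shell:

```
idipnet recurrent stabilize --seed 1 --out results/stab
idipnet hippocampus explore --seed 1 --laps 100 --out results/explore
idipnet hippocampus silence --seed 1 --out results/silence
idipnet recurrent memory --seed 1 --rule idip --out results/memory
```

Each command writes delimited tables (spike logs, place-map reports,
weight snapshots) plus a JSON manifest carrying the seed and a config
hash.  `--config file.yaml` overrides any model parameter.

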