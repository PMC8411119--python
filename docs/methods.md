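# Methods

`idipnet` simulates two spiking circuit models that share one plasticity
idea: **input-dependent inhibitory plasticity (IDIP)**, a network-centred
homeostat in which each inhibitory neuron scales all of its outgoing
inhibitory synapses according to the difference between a slow running
integral of the excitatory synaptic input it receives and a fixed target.
Because the input to a densely connected interneuron is a proxy for the
activity of its whole local network, the rule regulates the *population*
rate while leaving individual neurons free to differ — in contrast to
neuron-centred rules such as inhibitory STDP, which impose a per-neuron
rate set point.

This note records the model equations as implemented, the unit and
integration conventions, the parameters that matter (with defaults and the
reasoning behind every value the source material leaves open), what the
protocols emulate, and the model's known limitations.

## Neuron and synapse model

Leaky integrate-and-fire neurons with conductance-based synapses:

    tau_m dV_i/dt = (V_REST - V_i) + gE_i (V_E - V_i) + gI_i (V_I - V_i) + R I_ex
    tau_s dg_ij/dt = -g_ij + gbar W_ij S_j(t)

with V_REST = -60 mV, threshold -50 mV, reset to V_REST, absolute
refractory period 2 ms (the membrane is held at rest — the neuron "cannot
be stimulated"), tau_m = 20 ms, R = 100 MOhm, V_E = 0 mV, V_I = -80 mV,
tau_E = 5 ms, tau_I = 10 ms, gbar = 1 nS, dt = 1 ms.

Integration conventions:

- **Membrane: exponential (semi-implicit) Euler.**  Each step solves the
  locally linear membrane equation exactly:
  `V <- V_inf + (V - V_inf) exp(-a dt / tau_m)` with `a = 1 + gE + gI`.
  This is unconditionally stable, keeps V inside the reversal bounds for
  arbitrarily strong conductances, and reduces to the exact closed form
  when conductances are constant (forward Euler at dt = 1 ms is unstable
  whenever `a dt > tau_m`, which strong synaptic bombardment reaches).
- **Conductances and plasticity traces: exact exponential decay** between
  spikes; each presynaptic spike increments the conductance by
  `gbar * W_ij` (unit-delta convention, making "gbar = 1 nS, basic weight
  unit" literal).  The steady-state mean conductance of a synapse driven
  at rate r is therefore `W gbar r tau_eff` with
  `tau_eff = dt / (1 - exp(-dt/tau))` (about 5.52 ms for tau_E = 5 ms).
- **Spike propagation:** spikes detected in step t reach their targets at
  the start of step t+1; there are no further axonal delays.  A neuron
  whose voltage is at or above threshold on entering a step spikes.
- **Initial conditions:** V = V_REST everywhere, all conductances zero.

**Synaptic efficacy scale.**  Weights are dimensionless and conductances
are kept in nS (the plasticity trace reads them on that scale).  The
dimensionless gain per nS in the membrane equation — the product
R x 1 nS — is a per-model constant: **0.2 in the recurrent model** and
**2.0 in the hippocampal model**.  These are deliberate modelling choices,
fixed before any experiment protocol was run and then frozen.  The
recurrent value is the regime in which (i) the unstabilised network shows
the pathologically high initial activity the stabilization protocol starts
from, (ii) IDIP converges smoothly rather than overshooting into slow
rate oscillations, and (iii) the inhibitory weight bound W_max = 1.0 is
an interior constraint rather than a ceiling the homeostat saturates.
The hippocampal value is the smallest efficacy at which every CA1 cell
fires on the first lap ("all place cells are active ... with varying
amplitudes") given the peak in-field CA3 rate (~63 Hz at A_c = 200 pA)
and initial feedforward weights around 0.5.  A single shared scale cannot
satisfy both circuits because the hippocampal cells are driven by one
effective feedforward synapse while the recurrent neurons integrate
dozens of inputs.

## The IDIP rule

Each inhibitory neuron i keeps a leaky integral of the summed excitatory
synaptic conductance it receives (all excitatory afferents, including the
external Poisson synapses in the recurrent model):

    dy_i/dt = -y_i / tau_IDIP + sum_j g_ij^E(t),      tau_IDIP = 160 ms

so the fixed point of y is `tau_IDIP * <sum_j g_ij^E>`, i.e. the trace is
an (amplified) running average of the input on the nS scale on which the
targets theta_in are quoted: 200 nS in the hippocampal model, 550 nS in
the recurrent model.  At every spike of neuron i, **all** of its outgoing
inhibitory weights move together:

    dw = eta_IDIP (y_i - theta_in)

applied **additively with clipping at zero** in the hippocampal model
(eta = 1e-5) and through the **multiplicative bound** in the recurrent
model (eta = 1e-7, W_max = 1.0):

    w <- w + (W_max - w) dw    if dw > 0
    w <- w + w dw              if dw < 0

which provably confines weights to [0, W_max].

The rule's empirical fixed point is that each neuron's *spike-triggered*
average of y equals theta_in.  Two systematic deviations are worth
knowing about: spike-triggered sampling weights moments of elevated input
(pushing the equilibrium average slightly above the time average), and
the multiplicative bound weights potentiation by (W_max - w) and
depression by w, which biases the equilibrium downward when w < W_max/2.
In practice both effects are a few percent of theta_in.

**Rate scale set by the rule.**  Because y is (approximately) tau_IDIP
times the mean summed input conductance, theta_in fixes a *total
excitatory rate budget* through each interneuron's afferents.  In the
hippocampal model (100 CA1 cells at W = 2.0 onto every interneuron) the
budget is a CA1 population mean near 1.1 Hz; in the recurrent model
(20 recurrent inputs of mean weight 1, plus the external slice of y,
about 440 nS) it pins the excitatory mean near 5-6 Hz.

### Rule variants

Five variants replace parts of the base rule (all exposed as
`IDIPRule(variant=...)`):

- **v1** weights each input conductance by the instantaneous driving
  force (V_E - V_i); y then carries nS*mV and theta_in must be rescaled
  (roughly by the mean driving force, ~60 mV at rest).
- **v2** replaces the spike gate by a presynaptic trace x_i
  (tau_st = 20 ms default) and updates every step; as tau_st -> 0 it
  reproduces the base rule's cumulative update on the same spike train.
- **v3** subtracts inhibitory input conductances from the trace input
  (meaningful when I->I synapses exist, `p_II > 0`).
- **v4** moves the spiking neuron's firing threshold instead of its
  weights; the sign of eta must be negative for the loop to be
  homeostatic (input above target -> lower threshold -> more inhibitory
  firing), and thresholds are confined to [V_REST + 1 mV, 0 mV] so no
  unit can be silenced irreversibly.
- **v5** replaces the input target by a rate target: a running spike-count
  estimator x_est (tau_est = 1000 ms) is compared against theta_x
  (default 0.005 spikes/ms = 5 Hz) at spike times.

v2/v5 constants are package defaults chosen at the matching time scales
of the base rule; they are config-exposed.

## Hippocampal CA3->CA1 model

Populations: 10 CA3 cells, 100 CA1 excitatory cells in 10 groups of 10,
20 CA1 interneurons.  E<->I connectivity is full and bidirectional
(W_IE = 2.0 fixed; W_EI starts at 1e-3 and is plastic under IDIP).  Every
CA1 cell receives all 10 CA3 inputs; its initial weight vector is the
group's Gaussian tuning curve evaluated at the field-center distances,

    w_nk = 0.52 * T(d(c_k, c_g(n))) + s_n   (clipped at 0),

where the per-neuron amplitude offset s_n comes from one vector of 10
draws from N(0, 0.05), shuffled independently within each group — the
within-group variability that later decides which cells stay active.
0.52 is theta_homeo / N_CA3, so the homeostatic drift of the summed
weight is modest at the start.

The simulated mouse moves at constant speed on a 1D annular track with 10
equally spaced field centers, 3 s between adjacent centers (one lap =
30 s).  The track is 100 a.u. around with 10 a.u. spacing — a choice, not
a printed value; sigma_pc = 6.54 a.u. then tiles the track with
overlapping fields.  CA3 cell k receives the place current
`I(p) = A_c exp(-d(p, c_k)^2 / 2 sigma_pc^2)` with A_c = 200 pA and d the
circular distance.  Uniform baseline currents: 0.01 nA to CA1 E cells and
0.5 nA to the interneurons.  The inhibitory baseline is read on the nA
scale deliberately: it drives the interneurons tonically (~150 Hz), which
the homeostat requires — inhibitory weights can only *decrease* at
inhibitory spikes, so the interneurons must keep firing when excitatory
input is low.  This tonic drive is what makes place-map silencing
reversible (the "slow phase" of disinhibition during silencing).

CA3->CA1 weights are plastic under symmetric Hebbian plasticity with a
homeostatic sum constraint (integrated every step as an ODE in the
traces):

    tau_hebb dx_i/dt = -x_i + S_i(t),         tau_hebb = 20 ms
    dw_ji/dt = eta_hebb (W_max - w_ji) x_i x_j - eta_homeo (sum_i w_ji - theta_homeo)

with eta_hebb = 1e-3/ms, eta_homeo = 1e-4/ms, W_max = 1.5,
theta_homeo = 5.2, and clipping at zero (the assumed lower bound).

Protocols:

- **Exploration** (`run_exploration`): both rules are enabled after the
  first lap; over subsequent laps the interplay of Hebbian sharpening and
  rising IDIP inhibition splits every group into active and silent cells,
  with the cells' initial amplitude offsets biasing who wins.
- **Silencing** (`run_silencing`): all active cells are voltage-clamped at
  rest for one lap (idealised optogenetic silencing; conductances keep
  decaying) and released.  With IDIP on, interneuron input falls below
  target, inhibition is scaled down, and the silent cells' maps are
  unmasked at near the original map's rate; the control freezes IDIP at
  silencing onset, and the alternative map then stays weak.  ON rates are
  measured after the first 5 s of the lap so the slow plastic phase is
  reflected.
- **Consolidation** (`run_consolidation`): the original map is silenced
  for 4 consecutive laps, released for one test lap, repeated for 10
  trials with all plasticity on.  During the silencing laps the
  alternative cells fire and their CA3 weights sharpen under the Hebbian
  term, so the alternative map's test-lap rate grows across trials while
  the original map's declines.  Trial 0 is a plain post-exploration lap.

"Active" cells are classified per lap as those whose in-field rate
exceeds 10% of the population's peak in-field rate on that lap
(scale-free; the in-field window is +-half the field spacing around the
group's center).  The threshold is exposed in the config.

## Recurrent network model

80 excitatory and 20 inhibitory LIF neurons with **fixed in-degrees**:
each E cell receives exactly 8 E inputs (p_EE = 0.1, no self-connections)
and 5 I inputs (p_EI = 0.25); each I cell receives 20 E inputs
(p_IE = 0.25); no I->I synapses (p_II = 0; setting p_II > 0 adds them).
Every neuron receives 20 of the 100 external Poisson units (p_ex = 0.2)
firing at F = 10 Hz.  Recurrent and input weights are lognormal with mean
1.0 and s.d. 0.1 (the moments of the weights themselves); initial I->E
weights are a draw from the same family scaled by 0.1 ("ten times
weaker").  The x2.5 input gain is applied to the interneurons' external
weights: it is what keeps the interneuron population strongly driven
(~100 Hz) so that inhibition has the reach the homeostat needs, while the
excitatory cells' external drive leaves them in a fluctuation-driven
regime once inhibition has grown.

Protocols:

- **Stabilization** (`run_stabilization`): IDIP is off for the first
  15 s, during which the network fires pathologically (~90 Hz,
  synchronous).  After IDIP is enabled the I->E weights grow to ~0.4 and
  the excitatory population settles to a low asynchronous state near
  4.2-4.5 Hz with heterogeneous per-neuron rates; the spike-triggered average
  of y settles a few percent below theta_in = 550 nS (the
  multiplicative-bound bias described above).  The run proceeds in 50-s
  blocks until the block mean rate changes by <2% (or a maximum duration)
  and then measures the converged rate and trace statistics over a final
  window.
- **Target/connectivity sweep** (`sweep_theta_connectivity`): converged
  rate as a function of theta_in and p_EI (or p_EE), mean +- s.d. over
  seeds.
- **Subset drive** (`run_subset_drive`): a random subset of E cells has
  its external weights scaled (x1.5) from the start; after convergence
  the boosted subset sustains a rate well above the rest while global
  inhibition suppresses the rest below baseline.
- **Rank preservation** (`compute_rank_report`): per-neuron mean rates in
  15-s bins; Spearman rank correlation (average-rank ties) of each bin
  against the first bin (pre-plasticity).  A bin with zero rate variance
  yields a missing coefficient.
- **Associative memory** (`run_memory_task`): after stabilization
  (600 s) the recurrent synapses among a random ensemble of 12 E cells
  are scaled x5; after re-convergence (1200 s) the external weights of 2
  ensemble cells are raised 50%.  Under IDIP the ensemble's elevated rate
  persists through re-convergence and the cue re-activates the non-cued
  members (pattern completion); under the iSTDP baseline the elevation is
  homeostatically erased.

## iSTDP baseline

The neuron-centred comparison rule on the same I->E synapses
(tau_iSTDP = 20 ms, eta = 5e-5, alpha = 0.2):

    w <- w + eta (x_j - alpha)   at presynaptic (inhibitory) spikes
    w <- w + eta x_i             at postsynaptic (excitatory) spikes

driving each excitatory neuron toward the rate implied by alpha
(alpha / (2 tau) = 5 Hz).  Weights are clipped at zero and not bounded
above.

## Multi-seed quantification

`ensemble_run` executes an experiment at seeds `base_seed + k` and
reports mean +- s.d.; each seed feeds independent connectivity and input
sub-streams (numpy `SeedSequence` spawning).  Failed seeds are excluded
with a warning and recorded; undefined statistics (e.g. rank coefficients
of empty bins) are excluded from summaries with their count reported.
The protocols were quantified over 20 seeds in full-scale use; the
package's own acceptance checks use 10 seeds for the recurrent
stabilization and scaled-down runs elsewhere (30 exploration laps rather
than 100; 300-700 s of recurrent simulated time), sizes chosen so the
statistics of interest (converged mean rate, spike-triggered trace
average, map-rate trends) are already stable.

## What the simulations do and do not emulate

All inputs are synthetic by design (the models are the object of study):
place-tuned currents are noiseless and perfectly tiled, external drive is
homogeneous-rate Poisson, and every neuron shares identical membrane
parameters.  Consequences worth keeping in mind: the hippocampal
network's dynamics are deterministic given the build (CA3 spike trains
repeat exactly every lap), so within-group competition is decided by the
amplitude offsets and the deterministic transient, not by trial-to-trial
noise; rate heterogeneity in the recurrent model comes only from the 10%
weight dispersion and the fixed random wiring, so its firing-rate
distribution is broad but not as heavy-tailed as cortical data.  Passing
tests therefore validate the mechanisms (homeostatic convergence,
remapping, consolidation, persistence) rather than any quantitative match
to biological variability.

## Numerical and edge-case choices

- Weight matrices are dense (post x pre) with boolean structural masks;
  absent synapses stay exactly zero under all rules (the multiplicative
  bound is masked explicitly, since (W_max - 0) dw would otherwise create
  weight on non-existent synapses).
- All-zero in-field rates classify every cell silent, with a warning.
- A requested fixed in-degree larger than the eligible presynaptic pool
  is a configuration error raised before simulation.
- Non-finite membrane potentials abort with the population, neuron index
  and time (checked every 500 steps).
- Refractory neurons' synaptic conductances keep decaying (only the
  membrane is frozen); clamped neurons likewise.
- Spike-triggered trace averages are computed per neuron and then
  averaged over neurons that spiked in the collection window.

## Known limitations

- The two circuit models use different synaptic efficacy scales (see
  above); neither is derived from first principles.
- The global rate budget in the recurrent model is dominated by the
  external slice of the interneuron input trace, so whole-network
  homeostasis under perturbations is approximate (within tens of
  percent), while the hippocampal budget is fully network-driven and
  tight.
- No synaptic delays, short-term plasticity, multi-compartment dynamics,
  2-D environments, theta modulation, or CA3 recurrence.
- The convergence criterion (<2% block-to-block change of the mean rate)
  can trigger during slow drift or never trigger under converged
  fluctuations; protocols therefore also honour explicit duration caps.
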