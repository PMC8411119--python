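"""Plasticity rules: IDIP (base rule and variants v1-v5), symmetric Hebbian
plasticity with a homeostatic term, and the Vogels-style inhibitory STDP
baseline.

All rules share the engine's two-phase interface: ``update_traces(dt)`` is
called once per step after conductances have been updated, and
``on_spikes(spikes, dt)`` after spike detection, so a spike-triggered update
sees the trace value of its own step.

IDIP
----
Each inhibitory neuron *i* keeps a leaky integral of the summed excitatory
conductance it receives from the network's excitatory population::

    dy_i/dt = -y_i / tau_IDIP + sum_j g_ij^E(t)

so the fixed point of ``y`` is ``tau_IDIP`` times the mean summed input
conductance.  The targets ``theta_in`` live on this (nS) scale.  When neuron
*i* spikes, every outgoing inhibitory weight moves by
``eta * (y_i - theta_in)``: additively (clipped at 0) in the hippocampal
model, or through the multiplicative bound

    w <- w + (W_max - w) dw   if dw > 0
    w <- w + w dw             if dw < 0

in the recurrent model, which confines weights to [0, W_max].
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from . import _kernels
from .core import NeuronPopulation, SynapticProjection

__all__ = ["IDIPRule", "HebbianHomeostaticRule", "ISTDPRule"]

IDIP_VARIANTS = ("base", "v1", "v2", "v3", "v4", "v5")


class IDIPRule:
    """Input-dependent inhibitory plasticity.

    Parameters
    ----------
    pop : the inhibitory population whose spikes trigger the updates.
    proj_out : outgoing I->E projection whose weights are adjusted.
    input_projs : excitatory projections onto ``pop`` whose summed
        conductances drive the trace ``y``.
    eta : learning rate (1/(ms nS)); per-spike weight change is
        ``eta * (y - theta_in)``.
    theta_in : target input (nS), identical for all inhibitory neurons.
    tau_idip : trace time constant (ms).
    w_max : if given, the multiplicative bound is applied and weights stay
        in [0, w_max]; otherwise updates are additive with clipping at 0.
    variant : one of ``base, v1, v2, v3, v4, v5``:
        v1 weights each input conductance by the driving force (V_E - V_i);
        v2 replaces the spike indicator by a synaptic trace (tau_st) and
        updates every step; v3 subtracts inhibitory input conductances
        (``inh_input_projs``); v4 moves the spiking neuron's firing
        threshold instead of its weights; v5 compares a running rate
        estimator against a target rate ``theta_x``.
    """

    def __init__(self, pop: NeuronPopulation,
                 proj_out: SynapticProjection | None,
                 input_projs: Sequence[SynapticProjection],
                 eta: float, theta_in: float, tau_idip: float = 160.0,
                 w_max: float | None = None, variant: str = "base",
                 v_rev_e: float = 0.0,
                 inh_input_projs: Sequence[SynapticProjection] = (),
                 tau_st: float = 20.0,
                 tau_est: float = 1000.0, theta_x: float = 0.005,
                 theta_bounds: tuple[float, float] | None = None) -> None:
        if variant not in IDIP_VARIANTS:
            raise ValueError(f"unknown IDIP variant '{variant}'")
        if variant != "v4" and proj_out is None:
            raise ValueError("proj_out is required for weight-based variants")
        self.pop = pop
        self.proj_out = proj_out
        self.input_projs = list(input_projs)
        self.inh_input_projs = list(inh_input_projs)
        self.eta = float(eta)
        self.theta_in = float(theta_in)
        self.tau_idip = float(tau_idip)
        self.w_max = w_max
        self.variant = variant
        self.v_rev_e = v_rev_e
        self.frozen = False
        self.y = np.zeros(pop.size, dtype=np.float64)
        # variant state
        self.tau_st = tau_st
        self.x_trace = np.zeros(pop.size)      # v2
        self.tau_est = tau_est                 # v5
        self.theta_x = theta_x
        self.x_est = np.zeros(pop.size)
        if theta_bounds is None:
            theta_bounds = (pop.params.v_rest + 1.0, 0.0)   # v4
        self.theta_bounds = theta_bounds
        # spike-triggered-average collection
        self._sta_on = False
        self._sta_sum = np.zeros(pop.size)
        self._sta_n = np.zeros(pop.size, dtype=np.int64)

    # -- trace phase --------------------------------------------------
    def _input(self) -> np.ndarray:
        if self.variant == "v1":
            total = np.zeros(self.pop.size)
            for proj in self.input_projs:
                total = total + proj.g
            return total * (self.v_rev_e - self.pop.V)
        total = np.zeros(self.pop.size)
        for proj in self.input_projs:
            total = total + proj.g
        if self.variant == "v3":
            for proj in self.inh_input_projs:
                total = total - proj.g
        return total

    _decay_cache: dict | None = None

    def _decays(self, dt: float) -> tuple[float, float, float]:
        c = self._decay_cache
        if c is None or c[0] != dt:
            c = (dt, float(np.exp(-dt / self.tau_idip)),
                 float(np.exp(-dt / self.tau_st)),
                 float(np.exp(-dt / self.tau_est)))
            self._decay_cache = c
        return c[1], c[2], c[3]

    def update_traces(self, dt: float) -> None:
        d_y, d_st, d_est = self._decays(dt)
        self.y *= d_y
        self.y += dt * self._input()
        if self.variant == "v2":
            self.x_trace *= d_st
        elif self.variant == "v5":
            self.x_est *= d_est

    # -- spike phase --------------------------------------------------
    def _apply_dw(self, idx: np.ndarray, dw: np.ndarray) -> None:
        """Apply per-presynaptic-neuron deltas to columns of proj_out.W."""
        W = self.proj_out.W
        mask = self.proj_out.mask
        cols = W[:, idx]
        if self.w_max is not None:
            upd = np.where(dw >= 0.0, (self.w_max - cols) * dw, cols * dw)
        else:
            upd = np.broadcast_to(dw, cols.shape)
        W[:, idx] = np.clip(cols + upd * mask[:, idx], 0.0,
                            self.w_max if self.w_max is not None else np.inf)

    def on_spikes(self, spikes: dict[str, np.ndarray], dt: float) -> None:
        idx = spikes.get(self.pop.name, np.empty(0, dtype=np.int64))
        if self.variant == "v2" and idx.size:
            self.x_trace[idx] += 1.0
        if self.variant == "v5" and idx.size:
            self.x_est[idx] += 1.0
        if self._sta_on and idx.size:
            self._sta_sum[idx] += self.y[idx]
            self._sta_n[idx] += 1
        if self.frozen:
            return
        if self.variant == "v2":
            # continuous, trace-gated update over all inhibitory neurons
            active = np.flatnonzero(self.x_trace > 0.0)
            if active.size:
                dw = self.eta * (self.y[active] - self.theta_in) \
                    * self.x_trace[active]
                self._apply_dw(active, dw)
            return
        if idx.size == 0:
            return
        if self.variant == "v4":
            dtheta = self.eta * (self.y[idx] - self.theta_in)
            self.pop.theta[idx] = np.clip(self.pop.theta[idx] + dtheta,
                                          *self.theta_bounds)
            return
        if self.variant == "v5":
            dw = self.eta * (self.x_est[idx] / self.tau_est - self.theta_x)
        else:  # base, v1, v3
            dw = self.eta * (self.y[idx] - self.theta_in)
        self._apply_dw(idx, dw)

    # -- spike-triggered average of y ---------------------------------
    def start_sta(self) -> None:
        self._sta_on = True
        self._sta_sum[:] = 0.0
        self._sta_n[:] = 0

    def sta(self) -> tuple[float, np.ndarray]:
        """Mean over neurons of each neuron's spike-triggered mean of y.

        Neurons that never spiked in the collection window are excluded.
        """
        with np.errstate(invalid="ignore"):
            per_neuron = np.where(self._sta_n > 0,
                                  self._sta_sum / np.maximum(self._sta_n, 1),
                                  np.nan)
        valid = per_neuron[np.isfinite(per_neuron)]
        return (float(valid.mean()) if valid.size else float("nan")), per_neuron


class HebbianHomeostaticRule:
    """Symmetric Hebbian plasticity with a homeostatic sum constraint.

    Applied to the CA3->CA1 feedforward projection.  Pre- and postsynaptic
    traces follow ``tau_hebb dx/dt = -x + S(t)`` (unit increment per spike)
    and the weights integrate, every step,

        dw_ji/dt = eta_hebb (W_max - w_ji) x_i x_j
                   - eta_homeo (sum_i w_ji - theta_homeo)

    with clipping at zero.  The homeostatic term redistributes synaptic
    resources: it holds each postsynaptic neuron's summed input weight near
    ``theta_homeo`` while the Hebbian term concentrates weight on co-active
    inputs.
    """

    def __init__(self, proj: SynapticProjection,
                 eta_hebb: float = 1e-3, eta_homeo: float = 1e-4,
                 theta_homeo: float = 5.2, w_max: float = 1.5,
                 tau_hebb: float = 20.0) -> None:
        self.proj = proj
        self.eta_hebb = eta_hebb
        self.eta_homeo = eta_homeo
        self.theta_homeo = theta_homeo
        self.w_max = w_max
        self.tau_hebb = tau_hebb
        self.x_pre = np.zeros(proj.pre.size)
        self.x_post = np.zeros(proj.post.size)
        self.frozen = False
        self._decay = None
        self._dense = bool(proj.mask.all())

    def update_traces(self, dt: float) -> None:
        f = self._decay
        if f is None or f[0] != dt:
            f = (dt, float(np.exp(-dt / self.tau_hebb)))
            self._decay = f
        self.x_pre *= f[1]
        self.x_post *= f[1]

    def on_spikes(self, spikes: dict[str, np.ndarray], dt: float) -> None:
        pre_idx = spikes.get(self.proj.pre.name, np.empty(0, dtype=np.int64))
        post_idx = spikes.get(self.proj.post.name, np.empty(0, dtype=np.int64))
        if pre_idx.size:
            self.x_pre[pre_idx] += 1.0
        if post_idx.size:
            self.x_post[post_idx] += 1.0
        if self.frozen:
            return
        W = self.proj.W
        if self._dense:
            _kernels.hebb_homeo_update(W, self.x_post, self.x_pre,
                                       self.eta_hebb, self.eta_homeo,
                                       self.theta_homeo, self.w_max, dt)
        else:
            hebb = self.eta_hebb * (self.w_max - W) * np.outer(self.x_post,
                                                               self.x_pre)
            homeo = self.eta_homeo * (W.sum(axis=1) - self.theta_homeo)
            W += dt * (hebb - homeo[:, None]) * self.proj.mask
            np.clip(W, 0.0, None, out=W)


class ISTDPRule:
    """Vogels-style inhibitory spike-timing-dependent plasticity.

    Neuron-centred baseline rule: with traces
    ``tau_iSTDP dx/dt = -x + S(t)`` on both sides of an I->E projection,

        w_ji <- w_ji + eta (x_j - alpha)   when presynaptic i spikes
        w_ji <- w_ji + eta x_i             when postsynaptic j spikes

    which drives each excitatory neuron toward the target rate implied by
    the depression factor ``alpha`` (rho0 = alpha / (2 tau_iSTDP)).
    Weights are clipped at zero; no upper bound.
    """

    def __init__(self, proj: SynapticProjection, eta: float = 5e-5,
                 alpha: float = 0.2, tau_istdp: float = 20.0) -> None:
        self.proj = proj
        self.eta = eta
        self.alpha = alpha
        self.tau_istdp = tau_istdp
        self.x_pre = np.zeros(proj.pre.size)    # inhibitory
        self.x_post = np.zeros(proj.post.size)  # excitatory
        self.frozen = False
        self._decay = None

    def update_traces(self, dt: float) -> None:
        f = self._decay
        if f is None or f[0] != dt:
            f = (dt, float(np.exp(-dt / self.tau_istdp)))
            self._decay = f
        self.x_pre *= f[1]
        self.x_post *= f[1]

    def on_spikes(self, spikes: dict[str, np.ndarray], dt: float) -> None:
        pre_idx = spikes.get(self.proj.pre.name, np.empty(0, dtype=np.int64))
        post_idx = spikes.get(self.proj.post.name, np.empty(0, dtype=np.int64))
        if pre_idx.size:
            self.x_pre[pre_idx] += 1.0
        if post_idx.size:
            self.x_post[post_idx] += 1.0
        if self.frozen:
            return
        W = self.proj.W
        mask = self.proj.mask
        if pre_idx.size:
            W[:, pre_idx] += self.eta * (self.x_post[:, None] - self.alpha) \
                * mask[:, pre_idx]
        if post_idx.size:
            W[post_idx, :] += self.eta * self.x_pre[None, :] \
                * mask[post_idx, :]
        np.clip(W, 0.0, None, out=W)
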