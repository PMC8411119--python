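"""Clocked simulation engine for conductance-based LIF networks.

The engine advances populations of leaky integrate-and-fire neurons on a
fixed grid (default ``dt`` = 1 ms).  Synapses are conductance based: each
projection keeps a per-postsynaptic-neuron summed conductance that decays
exponentially (exact update) and jumps by ``g_bar * W[post, pre]`` whenever the presynaptic
neuron fired on the previous step (one-step axonal delay, no further
propagation delays).

Unit conventions
----------------
Voltages are in mV, times in ms, currents in nA, and conductances in units
of the basic conductance ``g_bar``.  The membrane equation is

    tau_m dV/dt = (V_REST - V) + gE (V_E - V) + gI (V_I - V) + R I_ex

where the dimensionless products ``gE``/``gI`` are the summed synaptic
conductances (nS) times the per-projection ``coupling`` factor (the
dimensionless R * 1 nS product; see docs/methods.md) and ``R`` is in MOhm
so that ``R * I_ex`` is in mV.  The voltage update is a
semi-implicit (exponential) Euler step, which is unconditionally stable and
keeps V inside the reversal-potential bounds even for very large
conductances; conductance decay is the exact exponential.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from . import _kernels

__all__ = [
    "NeuronParams",
    "NeuronPopulation",
    "SynapseParams",
    "SynapticProjection",
    "PoissonSource",
    "SpikeRecord",
    "ExperimentProtocol",
    "Network",
]


# ---------------------------------------------------------------------------
# neurons
# ---------------------------------------------------------------------------

@dataclass
class NeuronParams:
    """Leaky integrate-and-fire membrane parameters.

    Attributes
    ----------
    v_rest : resting membrane potential (mV); also the reset value.
    theta_m : spike threshold (mV).
    r_m : membrane resistance (MOhm).
    tau_m : membrane time constant (ms).
    t_ref : absolute refractory period (ms).
    i_ex : baseline external current (nA).
    """

    v_rest: float = -60.0
    theta_m: float = -50.0
    r_m: float = 100.0
    tau_m: float = 20.0
    t_ref: float = 2.0
    i_ex: float = 0.0

    def __post_init__(self) -> None:
        if self.tau_m <= 0:
            raise ValueError("tau_m must be positive")
        if self.t_ref < 0:
            raise ValueError("t_ref must be non-negative")
        if self.theta_m <= self.v_rest:
            raise ValueError("theta_m must exceed v_rest")


class NeuronPopulation:
    """State of one population of LIF neurons.

    ``theta`` is kept per neuron so that threshold-plasticity rules can move
    individual thresholds; it is initialised to ``params.theta_m``.
    Clamped neurons (see :meth:`set_clamp`) are held at rest and cannot
    spike — an idealisation of optogenetic silencing.  During the absolute
    refractory period a neuron is likewise held at rest ("cannot be
    stimulated").
    """

    def __init__(self, size: int, params: NeuronParams | None = None,
                 name: str = "pop") -> None:
        if size <= 0:
            raise ValueError("population size must be positive")
        self.size = int(size)
        self.params = params if params is not None else NeuronParams()
        self.name = name
        self.V = np.full(size, self.params.v_rest, dtype=np.float64)
        self.theta = np.full(size, self.params.theta_m, dtype=np.float64)
        self.ref_remaining = np.zeros(size, dtype=np.float64)
        self.clamped = np.zeros(size, dtype=bool)
        # scratch buffers for the fused step
        self._g_exc = np.zeros(size)
        self._g_inh = np.zeros(size)
        self._gv = np.zeros(size)
        self._drive = np.zeros(size)
        self._spiked = np.zeros(size, dtype=bool)

    def begin_step(self) -> None:
        self._g_exc.fill(0.0)
        self._g_inh.fill(0.0)
        self._gv.fill(0.0)

    def set_clamp(self, idx, on: bool = True) -> None:
        self.clamped[idx] = on
        if on:
            self.V[idx] = self.params.v_rest

    def check_finite(self, t: float) -> None:
        if not np.all(np.isfinite(self.V)):
            bad = int(np.flatnonzero(~np.isfinite(self.V))[0])
            raise FloatingPointError(
                f"non-finite membrane potential in population '{self.name}' "
                f"(neuron {bad}) at t = {t:.1f} ms")

    def step(self, g_exc: np.ndarray | float, g_inh: np.ndarray | float,
             gv_sum: np.ndarray | float, i_ext: np.ndarray | float,
             dt: float, t: float = 0.0) -> np.ndarray:
        """Advance the membrane by one step and return the spike mask.

        ``g_exc``/``g_inh`` are the summed dimensionless conductances per
        neuron and ``gv_sum`` is ``sum_k g_k * V_rev_k`` (mV-weighted), so
        arbitrary reversal potentials are supported.  ``i_ext`` is in nA.

        Refractory and clamped neurons hold V = v_rest; a neuron entering
        the step at or above threshold spikes.  Finiteness is enforced via
        :meth:`check_finite` (called periodically by the run loop).
        """
        self._g_exc[:] = g_exc
        self._g_inh[:] = g_inh
        self._gv[:] = gv_sum
        return self.step_buffered(i_ext, dt)

    def step_buffered(self, i_ext, dt: float) -> np.ndarray:
        """As :meth:`step`, but reading the conductance sums from the
        scratch buffers filled by the run loop."""
        p = self.params
        self._drive[:] = p.r_m * (p.i_ex + i_ext)
        _kernels.lif_step(self.V, self.theta, self.ref_remaining,
                          self.clamped, self._g_exc, self._g_inh, self._gv,
                          self._drive, self._spiked, dt, p.tau_m, p.v_rest,
                          p.t_ref)
        return self._spiked


# ---------------------------------------------------------------------------
# synapses
# ---------------------------------------------------------------------------

@dataclass
class SynapseParams:
    """Conductance-synapse parameters.

    ``g_bar`` (nS) is the basic conductance unit, ``v_rev`` (mV) the
    reversal potential, ``tau`` (ms) the decay constant.  ``coupling`` is
    the dimensionless membrane gain per nS of conductance, i.e. the product
    R * (1 nS) in the membrane equation; 0.1 is the literal value for
    R = 100 MOhm.  Conductance state is kept in nS (plasticity traces read
    it on that scale); only the voltage update applies ``coupling``.
    """

    g_bar: float = 1.0
    v_rev: float = 0.0
    tau: float = 5.0
    coupling: float = 0.1

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")


class SynapticProjection:
    """Weighted connections from one population (or source) to another.

    The weight matrix ``W`` is (post x pre) and non-negative; entries where
    ``mask`` is False are structurally absent and stay zero.  Because all
    synapses of a projection share the same time constant, only the
    per-postsynaptic-neuron summed conductance ``g`` needs to be integrated:
    it decays as ``g *= exp(-dt/tau)`` and jumps by ``g_bar * W[:, j]`` when
    presynaptic neuron ``j`` fires.
    """

    def __init__(self, pre, post: NeuronPopulation, W: np.ndarray,
                 params: SynapseParams, mask: np.ndarray | None = None,
                 name: str = "") -> None:
        W = np.asarray(W, dtype=np.float64)
        if W.shape != (post.size, pre.size):
            raise ValueError(
                f"weight matrix shape {W.shape} does not match "
                f"(post={post.size}, pre={pre.size})")
        if np.any(W < 0):
            raise ValueError("synaptic weights must be non-negative")
        self.pre = pre
        self.post = post
        self.params = params
        self.mask = (np.ones_like(W, dtype=bool) if mask is None
                     else np.asarray(mask, dtype=bool))
        self.W = np.where(self.mask, W, 0.0)
        self.g = np.zeros(post.size, dtype=np.float64)
        self.name = name or f"{getattr(pre, 'name', 'pre')}->{post.name}"
        self._decay_cache: tuple[float, float] | None = None

    @property
    def is_excitatory(self) -> bool:
        return self.params.v_rev > -40.0

    def decay(self, dt: float) -> None:
        # exact exponential decay between deliveries
        cache = self._decay_cache
        if cache is None or cache[0] != dt:
            cache = (dt, float(np.exp(-dt / self.params.tau)))
            self._decay_cache = cache
        self.g *= cache[1]

    def deliver(self, pre_spike_idx: np.ndarray) -> None:
        if pre_spike_idx.size:
            _kernels.deliver(self.W, pre_spike_idx, self.params.g_bar,
                             self.g)

    def check(self) -> None:
        if np.any(self.W < 0):
            raise FloatingPointError(
                f"negative weight in projection '{self.name}'")


class PoissonSource:
    """Population of independent Poisson units (Bernoulli per time bin)."""

    def __init__(self, size: int, rate: float, rng: np.random.Generator,
                 name: str = "ext") -> None:
        if rate < 0:
            raise ValueError("rate must be non-negative")
        self.size = int(size)
        self.rate = float(rate)
        self.rng = rng
        self.name = name

    def draw(self, dt: float) -> np.ndarray:
        if self.rate == 0.0:
            return np.zeros(self.size, dtype=bool)
        p = self.rate * dt / 1000.0
        return self.rng.random(self.size) < p


# ---------------------------------------------------------------------------
# recording
# ---------------------------------------------------------------------------

class SpikeRecord:
    """Event log of (population, neuron index, spike time)."""

    def __init__(self, populations: Iterable[str]) -> None:
        self._times: dict[str, list] = {p: [] for p in populations}
        self._idx: dict[str, list] = {p: [] for p in populations}
        self.duration = 0.0
        self.t_start = None

    def add(self, pop: str, t: float, idx: np.ndarray) -> None:
        if self.t_start is None:
            self.t_start = t
        if idx.size:
            self._times[pop].append(np.full(idx.size, t, dtype=np.float64))
            self._idx[pop].append(idx.astype(np.int32))

    def spikes(self, pop: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (times, neuron indices) for one population."""
        if self._times[pop]:
            return (np.concatenate(self._times[pop]),
                    np.concatenate(self._idx[pop]))
        return np.empty(0), np.empty(0, dtype=np.int32)

    @property
    def populations(self) -> list[str]:
        return list(self._times)

    def n_spikes(self, pop: str) -> int:
        return int(sum(a.size for a in self._idx[pop]))

    def events(self) -> list[tuple[str, int, float]]:
        out = []
        for p in self._times:
            t, i = self.spikes(p)
            out.extend(zip([p] * len(t), i.tolist(), t.tolist()))
        out.sort(key=lambda e: e[2])
        return out

    def extend(self, other: "SpikeRecord") -> None:
        for p in other._times:
            if p not in self._times:
                self._times[p] = []
                self._idx[p] = []
            self._times[p].extend(other._times[p])
            self._idx[p].extend(other._idx[p])
        self.duration = max(self.duration, other.duration)


class ExperimentProtocol:
    """Timed schedule of interventions.

    Each event is ``(time_ms, callback)`` where the callback receives the
    :class:`Network`.  Events fire once, at the first step whose time is >=
    the scheduled time.
    """

    def __init__(self, events: Sequence[tuple[float, Callable]] = ()) -> None:
        self.events = sorted(events, key=lambda e: e[0])
        self._next = 0

    def add(self, time_ms: float, fn: Callable) -> None:
        self.events.append((time_ms, fn))
        self.events.sort(key=lambda e: e[0])

    def apply_due(self, t: float, net: "Network") -> None:
        while self._next < len(self.events) and self.events[self._next][0] <= t:
            self.events[self._next][1](net)
            self._next += 1


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

class Network:
    """Container wiring populations, sources, projections and plasticity
    rules together, plus the main simulation loop.

    The per-step order is:

    1. due protocol events are applied;
    2. every projection's conductance decays, then spikes from the previous
       step are delivered (one-step delay);
    3. plasticity traces are updated from the new conductances (so a spike
       in this step "sees" the current IDIP trace);
    4. membrane potentials advance and spikes are detected; Poisson sources
       draw their spikes for this step;
    5. spike-triggered plasticity updates are applied.

    The network keeps its running clock, so successive :meth:`run` calls
    continue one simulation.
    """

    def __init__(self, dt: float = 1.0) -> None:
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.dt = float(dt)
        self.populations: dict[str, NeuronPopulation] = {}
        self.sources: dict[str, PoissonSource] = {}
        self.projections: dict[str, SynapticProjection] = {}
        self.rules: list = []
        self.t = 0.0
        self._incoming: dict[str, list[SynapticProjection]] | None = None
        self.external_current: dict[str, Callable[[float], np.ndarray]] = {}

    # -- construction -------------------------------------------------
    def add_population(self, pop: NeuronPopulation) -> NeuronPopulation:
        self.populations[pop.name] = pop
        self._incoming = None
        return pop

    def add_source(self, src: PoissonSource) -> PoissonSource:
        self.sources[src.name] = src
        return src

    def connect(self, proj: SynapticProjection) -> SynapticProjection:
        self.projections[proj.name] = proj
        self._incoming = None
        return proj

    def add_rule(self, rule) -> None:
        self.rules.append(rule)

    # -- helpers ------------------------------------------------------
    def _build_incoming(self) -> None:
        self._incoming = {name: [] for name in self.populations}
        for proj in self.projections.values():
            self._incoming[proj.post.name].append(proj)

    def conductance_sums(self, pop_name: str):
        """(gE, gI, sum g*v_rev) onto one population, from current state."""
        g_exc = 0.0
        g_inh = 0.0
        gv = 0.0
        if self._incoming is None:
            self._build_incoming()
        for proj in self._incoming[pop_name]:
            g_eff = proj.g * proj.params.coupling
            if proj.is_excitatory:
                g_exc = g_exc + g_eff
            else:
                g_inh = g_inh + g_eff
            gv = gv + g_eff * proj.params.v_rev
        return g_exc, g_inh, gv

    # -- simulation ---------------------------------------------------
    def run(self, duration: float,
            protocol: ExperimentProtocol | None = None,
            record: SpikeRecord | None = None,
            record_pops: Sequence[str] | None = None,
            monitors: Sequence = ()) -> SpikeRecord:
        """Advance the network by ``duration`` ms and return the spike log.

        ``monitors`` are objects with ``interval`` (ms) and
        ``sample(network, t)``; they are polled on the step grid.
        """
        if self._incoming is None:
            self._build_incoming()
        if protocol is not None:
            for t_ev, _ in protocol.events:
                if not (0.0 <= t_ev <= self.t + duration):
                    raise ValueError(
                        f"protocol event at {t_ev} ms outside [0, "
                        f"{self.t + duration}] ms")
        dt = self.dt
        n_steps = int(round(duration / dt))
        pop_names = list(self.populations)
        if record_pops is None:
            record_pops = pop_names
        if record is None:
            record = SpikeRecord(pop_names)
        prev_spikes: dict[str, np.ndarray] = {
            name: np.empty(0, dtype=np.int64)
            for name in [*pop_names, *self.sources]}
        projs = list(self.projections.values())
        next_monitor = {id(m): self.t for m in monitors}
        rules = self.rules
        sources = list(self.sources.items())
        # per-population step plan: (pop, incoming projections, current fn,
        # record flag)
        plan = [(self.populations[name], self._incoming[name],
                 self.external_current.get(name), name in record_pops, name)
                for name in pop_names]
        empty = np.empty(0, dtype=np.int64)
        check_every = 500

        for istep in range(n_steps):
            t = self.t
            if protocol is not None:
                protocol.apply_due(t, self)

            for proj in projs:
                proj.decay(dt)
                sp = prev_spikes[proj.pre.name]
                if sp.size:
                    _kernels.deliver(proj.W, sp, proj.params.g_bar, proj.g)

            for rule in rules:
                rule.update_traces(dt)

            spikes_now: dict[str, np.ndarray] = {}
            for pop, incoming, i_fn, do_record, name in plan:
                pop.begin_step()
                for proj in incoming:
                    sp = proj.params
                    buf = pop._g_exc if sp.v_rev > -40.0 else pop._g_inh
                    _kernels.accumulate(proj.g, sp.coupling, sp.v_rev,
                                        buf, pop._gv)
                i_val = i_fn(t) if i_fn is not None else 0.0
                spiked = pop.step_buffered(i_val, dt)
                idx = np.flatnonzero(spiked)
                spikes_now[name] = idx if idx.size else empty
                if do_record:
                    record.add(name, t, idx)
            for name, src in sources:
                sp = np.flatnonzero(src.draw(dt))
                spikes_now[name] = sp if sp.size else empty

            for rule in rules:
                rule.on_spikes(spikes_now, dt)

            if monitors:
                for m in monitors:
                    if t >= next_monitor[id(m)]:
                        m.sample(self, t)
                        next_monitor[id(m)] += m.interval

            prev_spikes = spikes_now
            self.t = t + dt
            if istep % check_every == 0:
                for pop, *_ in plan:
                    pop.check_finite(t)

        record.duration = self.t
        return record


def run_network(populations: Sequence[NeuronPopulation],
                projections: Sequence[SynapticProjection],
                rules: Sequence = (),
                protocol: ExperimentProtocol | None = None,
                duration: float = 1000.0,
                sources: Sequence[PoissonSource] = (),
                dt: float = 1.0,
                monitors: Sequence = ()) -> tuple[SpikeRecord, Network]:
    """Convenience wrapper: build a :class:`Network` and run it once."""
    net = Network(dt=dt)
    for pop in populations:
        net.add_population(pop)
    for src in sources:
        net.add_source(src)
    for proj in projections:
        net.connect(proj)
    for rule in rules:
        net.add_rule(rule)
    rec = net.run(duration, protocol=protocol, monitors=monitors)
    return rec, net
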