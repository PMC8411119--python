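"""Sparse random recurrent network: construction and experimental
protocols (stabilization, target/connectivity sweeps, subset drive, firing
rate rank preservation, associative memory).

The network has N_E excitatory and N_I inhibitory LIF neurons with fixed
in-degrees (every neuron of a class receives exactly the same number of
inputs of each type), lognormal recurrent weights, and external drive from
a pool of Poisson units.  Only the I->E weights are plastic, either under
IDIP with a multiplicative weight bound or under the iSTDP baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (ExperimentProtocol, Network, NeuronParams,
                   NeuronPopulation, PoissonSource, SpikeRecord,
                   SynapseParams, SynapticProjection)
from .plasticity import IDIPRule, ISTDPRule
from .analysis import bin_rates, spearman

__all__ = [
    "RecurrentNetSpec", "MemoryProtocolSpec", "RecurrentNet",
    "build_recurrent_net", "run_stabilization", "sweep_theta_connectivity",
    "run_subset_drive", "compute_rank_report", "run_memory_task",
]


@dataclass
class RecurrentNetSpec:
    """Structural and plasticity parameters of the recurrent model."""

    n_exc: int = 80
    n_inh: int = 20
    n_ext: int = 100
    p_ee: float = 0.1
    p_ie: float = 0.25          # E -> I
    p_ei: float = 0.25          # I -> E
    p_ii: float = 0.0
    p_ext: float = 0.2
    mu_w: float = 1.0           # mean of the lognormal weight distribution
    sigma_wrec: float = 0.1     # s.d. of the recurrent weights
    sigma_win: float = 0.1      # s.d. of the input weights
    input_gain: float = 2.5     # scaling of the inhibitory population's
                                # external input weights (keeps the
                                # interneurons strongly driven)
    wi_we_ratio: float = 0.1    # initial inhibitory / excitatory weight ratio
    rate_ext: float = 10.0      # Hz
    # synapse constants
    g_bar: float = 1.0
    v_rev_e: float = 0.0
    v_rev_i: float = -80.0
    tau_e: float = 5.0
    tau_i: float = 10.0
    coupling: float = 0.2       # dimensionless R * g_bar
    # plasticity
    eta_idip: float = 1e-7
    theta_in: float = 550.0
    tau_idip: float = 160.0
    w_max_ei: float = 1.0
    eta_istdp: float = 5e-5
    alpha_istdp: float = 0.2
    tau_istdp: float = 20.0
    neuron: NeuronParams = field(default_factory=NeuronParams)

    def in_degrees(self) -> dict[str, int]:
        return {
            "ee": int(round(self.n_exc * self.p_ee)),
            "ei": int(round(self.n_inh * self.p_ei)),   # inhibitory inputs per E
            "ie": int(round(self.n_exc * self.p_ie)),   # excitatory inputs per I
            "ii": int(round(self.n_inh * self.p_ii)),
            "ext": int(round(self.n_ext * self.p_ext)),
        }


@dataclass
class MemoryProtocolSpec:
    """Timing and strength of the associative-memory protocol."""

    stabilization_end: float = 600_000.0   # ms
    ensemble_size: int = 12
    potentiation_factor: float = 5.0
    recall_time: float = 1_200_000.0       # ms
    recall_end: float = 1_500_000.0        # ms
    cue_size: int = 2
    cue_gain: float = 1.5                  # x on the cue neurons' Win
    probe_window: float = 50_000.0         # ms around each probe point


class RecurrentNet:
    """Bundle of the built network and handles to its pieces."""

    def __init__(self, net: Network, spec: RecurrentNetSpec,
                 rule, seed: int) -> None:
        self.net = net
        self.spec = spec
        self.rule = rule
        self.seed = seed

    @property
    def exc(self) -> NeuronPopulation:
        return self.net.populations["E"]

    @property
    def inh(self) -> NeuronPopulation:
        return self.net.populations["I"]

    def proj(self, name: str) -> SynapticProjection:
        return self.net.projections[name]


def _fixed_indegree(rng: np.random.Generator, n_post: int, n_pre: int,
                    k: int, no_self: bool = False) -> np.ndarray:
    """Boolean (post x pre) mask with exactly k inputs per postsynaptic
    neuron, sampled uniformly without replacement."""
    pool = n_pre - (1 if no_self else 0)
    if k > pool:
        raise ValueError(
            f"requested in-degree {k} exceeds available presynaptic pool "
            f"({pool})")
    mask = np.zeros((n_post, n_pre), dtype=bool)
    for post in range(n_post):
        candidates = np.arange(n_pre)
        if no_self and post < n_pre:
            candidates = np.delete(candidates, post)
        chosen = rng.choice(candidates, size=k, replace=False)
        mask[post, chosen] = True
    return mask


def build_recurrent_net(spec: RecurrentNetSpec | None = None,
                        seed: int = 0,
                        rule: str = "idip") -> RecurrentNet:
    """Build the sparse recurrent network.

    Connectivity uses fixed in-degrees; recurrent and input weights are
    drawn from the same lognormal family (parameters of the underlying
    normal of ln w); input weights are scaled by ``input_gain``; initial
    I->E weights are a lognormal draw scaled by ``wi_we_ratio``.

    ``rule`` selects the plastic rule on the I->E projection ("idip" or
    "istdp"); the rule starts frozen and is enabled by the protocols.
    """
    spec = spec or RecurrentNetSpec()
    ss = np.random.SeedSequence(seed)
    rng_conn, rng_input = [np.random.default_rng(s) for s in ss.spawn(2)]
    deg = spec.in_degrees()

    net = Network(dt=1.0)
    exc = net.add_population(NeuronPopulation(spec.n_exc, spec.neuron, "E"))
    inh = net.add_population(NeuronPopulation(spec.n_inh, spec.neuron, "I"))
    ext = net.add_source(PoissonSource(spec.n_ext, spec.rate_ext,
                                       rng_input, "ext"))

    syn_e = SynapseParams(spec.g_bar, spec.v_rev_e, spec.tau_e, spec.coupling)
    syn_i = SynapseParams(spec.g_bar, spec.v_rev_i, spec.tau_i, spec.coupling)

    def lognormal(shape, sigma):
        # mu_w / sigma are the mean and s.d. of the weights themselves;
        # convert to the parameters of the underlying normal of ln(w)
        s2 = np.log1p((sigma / spec.mu_w) ** 2)
        return rng_conn.lognormal(np.log(spec.mu_w) - s2 / 2.0, np.sqrt(s2),
                                  size=shape)

    m_ee = _fixed_indegree(rng_conn, spec.n_exc, spec.n_exc, deg["ee"],
                           no_self=True)
    w_ee = lognormal(m_ee.shape, spec.sigma_wrec) * m_ee
    net.connect(SynapticProjection(exc, exc, w_ee, syn_e, m_ee, "EE"))

    m_ie = _fixed_indegree(rng_conn, spec.n_inh, spec.n_exc, deg["ie"])
    w_ie = lognormal(m_ie.shape, spec.sigma_wrec) * m_ie
    net.connect(SynapticProjection(exc, inh, w_ie, syn_e, m_ie, "IE"))

    m_ei = _fixed_indegree(rng_conn, spec.n_exc, spec.n_inh, deg["ei"])
    w_ei = lognormal(m_ei.shape, spec.sigma_wrec) * spec.wi_we_ratio * m_ei
    net.connect(SynapticProjection(inh, exc, w_ei, syn_i, m_ei, "EI"))

    if deg["ii"] > 0:
        m_ii = _fixed_indegree(rng_conn, spec.n_inh, spec.n_inh, deg["ii"],
                               no_self=True)
        w_ii = lognormal(m_ii.shape, spec.sigma_wrec) * spec.wi_we_ratio * m_ii
        net.connect(SynapticProjection(inh, inh, w_ii, syn_i, m_ii, "II"))

    m_xe = _fixed_indegree(rng_conn, spec.n_exc, spec.n_ext, deg["ext"])
    w_xe = lognormal(m_xe.shape, spec.sigma_win) * m_xe
    net.connect(SynapticProjection(ext, exc, w_xe, syn_e, m_xe, "extE"))

    m_xi = _fixed_indegree(rng_conn, spec.n_inh, spec.n_ext, deg["ext"])
    w_xi = lognormal(m_xi.shape, spec.sigma_win) * spec.input_gain * m_xi
    net.connect(SynapticProjection(ext, inh, w_xi, syn_e, m_xi, "extI"))

    ei = net.projections["EI"]
    # the IDIP trace integrates all excitatory input onto the inhibitory
    # neurons: recurrent E->I plus the external Poisson synapses
    exc_inputs = [net.projections["IE"], net.projections["extI"]]
    inh_inputs = [net.projections["II"]] if "II" in net.projections else []
    if rule == "idip":
        plastic = IDIPRule(inh, ei, exc_inputs, eta=spec.eta_idip,
                           theta_in=spec.theta_in, tau_idip=spec.tau_idip,
                           w_max=spec.w_max_ei,
                           inh_input_projs=inh_inputs)
    elif rule == "istdp":
        plastic = ISTDPRule(ei, eta=spec.eta_istdp, alpha=spec.alpha_istdp,
                            tau_istdp=spec.tau_istdp)
        # keep an IDIP-style trace alongside for diagnostics of y
        plastic.y_monitor = IDIPRule(inh, ei, exc_inputs, eta=0.0,
                                     theta_in=spec.theta_in,
                                     tau_idip=spec.tau_idip,
                                     w_max=spec.w_max_ei)
        plastic.y_monitor.frozen = True
        net.add_rule(plastic.y_monitor)
    else:
        raise ValueError(f"unknown rule '{rule}'")
    plastic.frozen = True
    net.add_rule(plastic)
    return RecurrentNet(net, spec, plastic, seed)


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------

@dataclass
class StabilizationResult:
    record: SpikeRecord
    rate_windows: list[float]          # mean E rate per 50-s window (Hz)
    weight_windows: list[float]        # mean plastic I->E weight per window
    converged_at: float | None         # ms, start of first converged window
    final_rate: float                  # mean E rate over the final 100 s
    sta_y: float                       # spike-triggered mean of y (final 100 s)
    sta_y_per_neuron: np.ndarray


def run_stabilization(rnet: RecurrentNet,
                      idip_on_at: float = 15_000.0,
                      max_duration: float = 700_000.0,
                      min_duration: float = 200_000.0,
                      window: float = 50_000.0,
                      tol: float = 0.02,
                      final_window: float = 100_000.0) -> StabilizationResult:
    """Run the stabilization protocol on a freshly built network.

    Inhibitory learning is off for the first ``idip_on_at`` ms.  The run
    continues in ``window``-ms blocks until the mean excitatory rate
    changes by less than ``tol`` (relative) between consecutive blocks, or
    ``max_duration`` is reached; it then continues for ``final_window`` ms
    during which the converged rate and the spike-triggered average of the
    IDIP trace y are measured.
    """
    net = rnet.net
    rule = rnet.rule
    proto = ExperimentProtocol([(idip_on_at,
                                 lambda n: setattr(rule, "frozen", False))])
    record = SpikeRecord(list(net.populations))
    record_pops = ("E",)
    rates: list[float] = []
    weights: list[float] = []
    converged_at = None
    n_e = rnet.spec.n_exc
    ei = rnet.proj("EI")

    t_end = net.t
    while t_end < max_duration:
        block = SpikeRecord(list(net.populations))
        net.run(window, protocol=proto if net.t < idip_on_at else None,
                record=block, record_pops=record_pops)
        t_end = net.t
        times, _ = block.spikes("E")
        rates.append(len(times) / n_e / (window / 1000.0))
        weights.append(float(ei.W[ei.mask].mean()))
        record.extend(block)
        if len(rates) >= 2 and t_end >= min_duration:
            prev, cur = rates[-2], rates[-1]
            if prev > 0 and abs(cur - prev) / prev < tol:
                converged_at = t_end - window
                break

    # measurement window
    sta_rule = rule if isinstance(rule, IDIPRule) else rule.y_monitor
    sta_rule.start_sta()
    meas = SpikeRecord(list(net.populations))
    t0 = net.t
    net.run(final_window, record=meas, record_pops=record_pops)
    record.extend(meas)
    times, _ = meas.spikes("E")
    final_rate = len(times) / n_e / (final_window / 1000.0)
    sta_mean, sta_per = sta_rule.sta()
    record.duration = net.t
    return StabilizationResult(record, rates, weights, converged_at,
                               final_rate, sta_mean, sta_per)


def sweep_theta_connectivity(theta_values: Sequence[float],
                             p_ei_values: Sequence[float],
                             n_seeds: int = 20, base_seed: int = 0,
                             spec: RecurrentNetSpec | None = None,
                             p_ee_values: Sequence[float] | None = None,
                             **stab_kwargs) -> pd.DataFrame:
    """Grid of converged mean rates over target input and I->E connectivity.

    Each grid cell re-derives the inhibitory in-degree from its ``p_ei``
    and averages the converged excitatory rate over ``n_seeds`` networks.
    If ``p_ee_values`` is given the excitatory connectivity is swept
    instead of ``p_ei``.
    """
    spec = spec or RecurrentNetSpec()
    rows = []
    sweep_name = "p_ee" if p_ee_values is not None else "p_ei"
    sweep_vals = p_ee_values if p_ee_values is not None else p_ei_values
    for theta in theta_values:
        for p in sweep_vals:
            cell = []
            for k in range(n_seeds):
                s = replace(spec, theta_in=theta, **{sweep_name: p})
                rnet = build_recurrent_net(s, seed=base_seed + k)
                res = run_stabilization(rnet, **stab_kwargs)
                cell.append(res.final_rate)
            rows.append({"theta_in": theta, sweep_name: p,
                         "mean_rate_hz": float(np.mean(cell)),
                         "std_rate_hz": float(np.std(cell)),
                         "n_seeds": n_seeds})
    return pd.DataFrame(rows)


@dataclass
class SubsetDriveResult:
    record: SpikeRecord
    subset: np.ndarray
    rate_subset: float       # mean rate of boosted subset, final window (Hz)
    rate_rest: float
    rate_all: float
    rate_traces: pd.DataFrame


def run_subset_drive(rnet: RecurrentNet, subset_fraction: float = 0.25,
                     input_gain: float = 1.5,
                     idip_on_at: float = 15_000.0,
                     duration: float = 300_000.0,
                     final_window: float = 50_000.0,
                     trace_bin: float = 5_000.0) -> SubsetDriveResult:
    """Boost the external input weights of a random subset of excitatory
    neurons by ``input_gain`` from the start of the run, then stabilize.

    Returns the final mean rates of the boosted subset, the rest, and the
    whole excitatory population, plus binned rate traces of both subsets.
    """
    net = rnet.net
    rng = np.random.default_rng(np.random.SeedSequence(rnet.seed).spawn(3)[-1])
    n_sub = int(round(rnet.spec.n_exc * subset_fraction))
    subset = np.sort(rng.choice(rnet.spec.n_exc, size=n_sub, replace=False))
    ext_e = rnet.proj("extE")
    ext_e.W[subset, :] *= input_gain

    rule = rnet.rule
    proto = ExperimentProtocol([(idip_on_at,
                                 lambda n: setattr(rule, "frozen", False))])
    record = net.run(duration, protocol=proto, record_pops=("E",))

    trace = bin_rates(record, trace_bin, "E", rnet.spec.n_exc)
    in_sub = np.zeros(rnet.spec.n_exc, dtype=bool)
    in_sub[subset] = True
    traces = pd.DataFrame({
        "t_ms": trace.centers,
        "rate_subset_hz": trace.rates[in_sub].mean(axis=0),
        "rate_rest_hz": trace.rates[~in_sub].mean(axis=0),
    })
    times, idx = record.spikes("E")
    sel = times >= (net.t - final_window)
    idx_f = idx[sel]
    secs = final_window / 1000.0
    rate_subset = float(np.isin(idx_f, subset).sum() / n_sub / secs)
    rate_rest = float((~np.isin(idx_f, subset)).sum()
                      / (rnet.spec.n_exc - n_sub) / secs)
    rate_all = float(len(idx_f) / rnet.spec.n_exc / secs)
    return SubsetDriveResult(record, subset, rate_subset, rate_rest,
                             rate_all, traces)


def compute_rank_report(record: SpikeRecord, n_exc: int,
                        bin_ms: float = 15_000.0,
                        pop: str = "E") -> pd.DataFrame:
    """Spearman rank correlation of per-neuron mean rates in each time bin
    against the first bin (the activity before any inhibitory plasticity).

    Ties are handled by average ranks.  A bin whose rate vector has zero
    variance (e.g. no spikes at all) yields a missing coefficient.
    """
    if record.duration < 2 * bin_ms:
        raise ValueError("record shorter than two rank bins")
    trace = bin_rates(record, bin_ms, pop, n_exc)
    first = trace.rates[:, 0]
    rows = []
    for b in range(trace.rates.shape[1]):
        rho = spearman(first, trace.rates[:, b])
        rows.append({"bin": b, "t_start_ms": trace.edges[b],
                     "spearman": rho})
    return pd.DataFrame(rows)


@dataclass
class MemoryTaskResult:
    record: SpikeRecord
    ensemble: np.ndarray
    cue: np.ndarray
    probes: pd.DataFrame     # per-neuron mean rates at the four probe points
    summary: pd.DataFrame    # ensemble vs rest mean rates per probe


def run_memory_task(rnet: RecurrentNet,
                    protocol: MemoryProtocolSpec | None = None,
                    idip_on_at: float = 15_000.0) -> MemoryTaskResult:
    """Associative-memory protocol.

    stabilize -> encode (scale the recurrent synapses within a random
    ensemble by ``potentiation_factor``) -> re-converge -> recall (scale the
    external input weights of ``cue_size`` ensemble neurons by
    ``cue_gain``).  Mean rates of the ensemble and of the rest are measured
    in ``probe_window``-ms windows before/after encoding and recall.
    """
    prot = protocol or MemoryProtocolSpec()
    net = rnet.net
    spec = rnet.spec
    rng = np.random.default_rng(np.random.SeedSequence(rnet.seed).spawn(4)[-1])
    ensemble = np.sort(rng.choice(spec.n_exc, size=prot.ensemble_size,
                                  replace=False))
    cue = ensemble[:prot.cue_size]
    ee = rnet.proj("EE")
    ext_e = rnet.proj("extE")
    rule = rnet.rule

    def encode(n):
        sub = np.ix_(ensemble, ensemble)
        ee.W[sub] *= prot.potentiation_factor

    def recall(n):
        ext_e.W[cue, :] *= prot.cue_gain

    proto = ExperimentProtocol([
        (idip_on_at, lambda n: setattr(rule, "frozen", False)),
        (prot.stabilization_end, encode),
        (prot.recall_time, recall),
    ])
    record = net.run(prot.recall_end, protocol=proto, record_pops=("E",))

    w = prot.probe_window
    probe_points = {
        "pre_encoding": (prot.stabilization_end - w, prot.stabilization_end),
        "post_encoding": (prot.stabilization_end, prot.stabilization_end + w),
        "pre_recall": (prot.recall_time - w, prot.recall_time),
        "post_recall": (prot.recall_time, prot.recall_time + w),
    }
    times, idx = record.spikes("E")
    in_ens = np.zeros(spec.n_exc, dtype=bool)
    in_ens[ensemble] = True
    probe_rows, summary_rows = [], []
    for label, (t0, t1) in probe_points.items():
        sel = (times >= t0) & (times < t1)
        counts = np.bincount(idx[sel], minlength=spec.n_exc)
        rates = counts / ((t1 - t0) / 1000.0)
        for n, r in enumerate(rates):
            probe_rows.append({"probe": label, "neuron": n,
                               "rate_hz": float(r),
                               "group": "ensemble" if in_ens[n] else "rest"})
        summary_rows.append({
            "probe": label,
            "rate_ensemble_hz": float(rates[in_ens].mean()),
            "rate_rest_hz": float(rates[~in_ens].mean()),
            "rate_noncue_ensemble_hz": float(
                rates[in_ens & ~np.isin(np.arange(spec.n_exc), cue)].mean()),
        })
    return MemoryTaskResult(record, ensemble, cue,
                            pd.DataFrame(probe_rows),
                            pd.DataFrame(summary_rows))
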