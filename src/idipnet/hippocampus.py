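"""Hippocampal CA3->CA1 place-cell model and its protocols: exploration,
place-map silencing, and consolidation by repeated silencing.

A simulated mouse runs at constant speed around a 1D annular track tiled
with equally spaced place fields.  Each CA3 neuron receives a Gaussian
place-tuned current; CA3 projects to CA1 excitatory neurons (divided into
groups sharing a field identity), which are fully and bidirectionally
connected to CA1 inhibitory neurons.  The CA3->CA1 synapses are plastic
under Hebbian plasticity with a homeostatic sum constraint; the CA1 I->E
synapses are plastic under IDIP (additive updates, clipped at zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (Network, NeuronParams, NeuronPopulation, SpikeRecord,
                   SynapseParams, SynapticProjection)
from .plasticity import HebbianHomeostaticRule, IDIPRule

__all__ = [
    "TrackGeometry", "HippocampalConfig", "HippocampalNet", "place_current",
    "build_hippocampal_net", "run_exploration", "classify_place_cells",
    "run_silencing", "run_consolidation", "PlaceMapReport",
]


@dataclass
class TrackGeometry:
    """1D annular track with equally spaced place-field centers.

    The track length is an arbitrary-unit choice (the tuning width is
    printed in a.u. without an anchoring circumference); 100 a.u. with one
    field every 10 a.u. gives overlapping Gaussian fields that tile the
    track.  The mouse takes 3 s between adjacent field centers, so one lap
    lasts ``n_fields * 3 s``.
    """

    n_fields: int = 10
    circumference: float = 100.0       # a.u.
    sigma_pc: float = 6.54             # a.u., tuning width
    a_c: float = 200.0                 # pA, current amplitude
    secs_between_fields: float = 3.0

    @property
    def spacing(self) -> float:
        return self.circumference / self.n_fields

    @property
    def centers(self) -> np.ndarray:
        return self.spacing * np.arange(self.n_fields)

    @property
    def speed(self) -> float:
        """a.u. per ms."""
        return self.spacing / (self.secs_between_fields * 1000.0)

    @property
    def lap_ms(self) -> float:
        return self.n_fields * self.secs_between_fields * 1000.0

    def circ_distance(self, p, q):
        d = np.abs(np.asarray(p) - np.asarray(q))
        return np.minimum(d, self.circumference - d)

    def position(self, t_ms: float) -> float:
        return (self.speed * t_ms) % self.circumference


def place_current(track: TrackGeometry, position: float,
                  field_index: int | np.ndarray | None = None) -> np.ndarray:
    """Gaussian place-tuned current (pA): ``A_c exp(-d^2 / 2 sigma^2)``
    with ``d`` the circular distance from the field center."""
    centers = track.centers if field_index is None \
        else track.centers[np.atleast_1d(field_index)]
    d = track.circ_distance(position, centers)
    out = track.a_c * np.exp(-d ** 2 / (2.0 * track.sigma_pc ** 2))
    return out if out.size > 1 else float(out[0])


@dataclass
class HippocampalConfig:
    """Sizes, weights and plasticity constants of the CA3->CA1 model."""

    n_ca3: int = 10
    n_exc: int = 100
    n_inh: int = 20
    n_groups: int = 10
    track: TrackGeometry = field(default_factory=TrackGeometry)
    # synaptic weights
    w_ie: float = 2.0          # E -> I
    w_ei_init: float = 1e-3    # initial I -> E
    w_ff_base: float = 0.52    # peak of the initial CA3->CA1 tuning profile
    sigma_offset: float = 0.05 # s.d. of the per-neuron amplitude offsets
    # uniform external currents (nA).  The inhibitory baseline drives the
    # interneurons tonically (~150 Hz): IDIP can then weaken inhibition
    # whenever the synaptic input falls below target, which is what makes
    # place-map silencing reversible.
    i_ex_e: float = 0.01
    i_ex_i: float = 0.5
    # synapse constants
    g_bar: float = 1.0
    v_rev_e: float = 0.0
    v_rev_i: float = -80.0
    tau_e: float = 5.0
    tau_i: float = 10.0
    coupling: float = 2.0      # dimensionless R * g_bar for this model
    # IDIP
    eta_idip: float = 1e-5
    theta_in: float = 200.0
    tau_idip: float = 160.0
    # Hebbian + homeostatic (CA3 -> CA1)
    eta_hebb: float = 1e-3
    eta_homeo: float = 1e-4
    theta_homeo: float = 5.2
    w_max_ff: float = 1.5
    tau_hebb: float = 20.0
    # classification
    active_threshold_frac: float = 0.1
    neuron: NeuronParams = field(default_factory=NeuronParams)


class HippocampalNet:
    """Built CA3->CA1 network plus handles used by the protocols."""

    def __init__(self, net: Network, cfg: HippocampalConfig,
                 offsets: np.ndarray, group_of: np.ndarray,
                 hebb: HebbianHomeostaticRule, idip: IDIPRule,
                 seed: int) -> None:
        self.net = net
        self.cfg = cfg
        self.offsets = offsets          # per-CA1-E-neuron amplitude offset s
        self.group_of = group_of        # group index of each CA1 E neuron
        self.hebb = hebb
        self.idip = idip
        self.seed = seed
        self.labels: np.ndarray | None = None   # True = active

    @property
    def ca3(self) -> NeuronPopulation:
        return self.net.populations["CA3"]

    @property
    def ca1e(self) -> NeuronPopulation:
        return self.net.populations["CA1E"]

    @property
    def ca1i(self) -> NeuronPopulation:
        return self.net.populations["CA1I"]


def build_hippocampal_net(cfg: HippocampalConfig | None = None,
                          seed: int = 0) -> HippocampalNet:
    """Build the CA3->CA1 network.

    Every CA1 excitatory neuron is connected to all N_CA3 CA3 neurons; its
    initial weight vector is the Gaussian tuning profile of its group's
    field evaluated at the field-center distances, scaled to peak
    ``w_ff_base``, plus the neuron's amplitude offset ``s`` (one vector of
    N_E/N_g normal draws, shuffled independently within each group, added
    to the whole profile; negative weights are clipped at zero).  E<->I
    connectivity is full and bidirectional; I->E starts at ``w_ei_init``.
    """
    cfg = cfg or HippocampalConfig()
    if cfg.n_exc % cfg.n_groups:
        raise ValueError("n_exc must be divisible by n_groups")
    per_group = cfg.n_exc // cfg.n_groups
    ss = np.random.SeedSequence(seed)
    rng_build, _ = [np.random.default_rng(s) for s in ss.spawn(2)]

    net = Network(dt=1.0)
    ca3 = net.add_population(NeuronPopulation(cfg.n_ca3, cfg.neuron, "CA3"))
    ca1e = net.add_population(NeuronPopulation(cfg.n_exc, cfg.neuron, "CA1E"))
    ca1i = net.add_population(NeuronPopulation(cfg.n_inh, cfg.neuron, "CA1I"))

    syn_e = SynapseParams(cfg.g_bar, cfg.v_rev_e, cfg.tau_e, cfg.coupling)
    syn_i = SynapseParams(cfg.g_bar, cfg.v_rev_i, cfg.tau_i, cfg.coupling)

    # amplitude offsets: same multiset per group, shuffled independently
    base_offsets = rng_build.normal(0.0, cfg.sigma_offset, size=per_group)
    offsets = np.empty(cfg.n_exc)
    group_of = np.repeat(np.arange(cfg.n_groups), per_group)
    for g in range(cfg.n_groups):
        offsets[group_of == g] = rng_build.permutation(base_offsets)

    # CA3 -> CA1E: tuning-profile weights
    track = cfg.track
    d = track.circ_distance(track.centers[group_of][:, None],
                            track.centers[None, :])
    profile = np.exp(-d ** 2 / (2.0 * track.sigma_pc ** 2))
    w_ff = np.clip(cfg.w_ff_base * profile + offsets[:, None], 0.0, None)
    ff = net.connect(SynapticProjection(ca3, ca1e, w_ff, syn_e, None, "FF"))

    # full bidirectional E <-> I
    w_ie = np.full((cfg.n_inh, cfg.n_exc), cfg.w_ie)
    ie = net.connect(SynapticProjection(ca1e, ca1i, w_ie, syn_e, None, "IE"))
    w_ei = np.full((cfg.n_exc, cfg.n_inh), cfg.w_ei_init)
    ei = net.connect(SynapticProjection(ca1i, ca1e, w_ei, syn_i, None, "EI"))

    hebb = HebbianHomeostaticRule(ff, cfg.eta_hebb, cfg.eta_homeo,
                                  cfg.theta_homeo, cfg.w_max_ff,
                                  cfg.tau_hebb)
    idip = IDIPRule(ca1i, ei, [ie], eta=cfg.eta_idip, theta_in=cfg.theta_in,
                    tau_idip=cfg.tau_idip, w_max=None)
    hebb.frozen = True
    idip.frozen = True
    net.add_rule(hebb)
    net.add_rule(idip)

    # place-tuned current into CA3, uniform baselines into CA1
    centers = track.centers
    amp_na = 1e-3 * track.a_c                               # pA -> nA
    inv_two_sig2 = 1.0 / (2.0 * track.sigma_pc ** 2)
    speed, circ = track.speed, track.circumference

    def ca3_current(t_ms: float) -> np.ndarray:
        p = (speed * t_ms) % circ
        d = np.abs(p - centers)
        np.minimum(d, circ - d, out=d)
        return amp_na * np.exp(-(d * d) * inv_two_sig2)

    net.external_current["CA3"] = ca3_current
    net.external_current["CA1E"] = lambda t: cfg.i_ex_e
    net.external_current["CA1I"] = lambda t: cfg.i_ex_i
    return HippocampalNet(net, cfg, offsets, group_of, hebb, idip, seed)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def _lap_report(hnet: HippocampalNet, record: SpikeRecord, lap_starts,
                lap_index_offset: int = 0) -> pd.DataFrame:
    """Per-neuron per-lap mean and in-field rates for CA1 E cells."""
    cfg = hnet.cfg
    track = cfg.track
    times, idx = record.spikes("CA1E")
    lap_ms = track.lap_ms
    rows = []
    centers = track.centers[hnet.group_of]
    # in-field window: within spacing/2 of the group's field center
    half_window_ms = (track.spacing / 2.0) / track.speed
    for k, t0 in enumerate(lap_starts):
        sel = (times >= t0) & (times < t0 + lap_ms)
        counts = np.bincount(idx[sel], minlength=cfg.n_exc)
        # in-field spike counts: position of each spike vs neuron's center
        pos = (track.speed * times[sel]) % track.circumference
        dist = track.circ_distance(pos, centers[idx[sel]])
        infield = dist <= track.spacing / 2.0
        counts_if = np.bincount(idx[sel][infield], minlength=cfg.n_exc)
        rate = counts / (lap_ms / 1000.0)
        rate_if = counts_if / (2.0 * half_window_ms / 1000.0)
        for n in range(cfg.n_exc):
            rows.append({"neuron": n, "lap": lap_index_offset + k,
                         "group": int(hnet.group_of[n]),
                         "rate_hz": float(rate[n]),
                         "in_field_rate_hz": float(rate_if[n])})
    return pd.DataFrame(rows)


@dataclass
class PlaceMapReport:
    """Lap-resolved rates with active/silent labels."""

    rates: pd.DataFrame                 # neuron, lap, rate_hz, in_field_rate_hz
    labels: np.ndarray | None = None    # True = active
    record: SpikeRecord | None = None   # full spike log of the run

    def lap(self, k: int) -> pd.DataFrame:
        return self.rates[self.rates["lap"] == k]

    def map_rate(self, lap: int, active: bool) -> float:
        """Mean rate over the active (or silent) map's cells on one lap."""
        if self.labels is None:
            raise ValueError("labels not set")
        df = self.lap(lap)
        sel = self.labels[df["neuron"].to_numpy()] == active
        return float(df["rate_hz"].to_numpy()[sel].mean())


def classify_place_cells(report: pd.DataFrame, lap: int,
                         threshold_frac: float = 0.1) -> np.ndarray:
    """Label CA1 cells active/silent from one lap.

    A cell is active when its in-field lap rate exceeds ``threshold_frac``
    times the population's peak in-field rate on that lap (scale-free,
    robust to overall rate changes).  All-zero rates give all-silent.
    """
    df = report[report["lap"] == lap].sort_values("neuron")
    rates = df["in_field_rate_hz"].to_numpy()
    peak = rates.max()
    if peak <= 0.0:
        import warnings
        warnings.warn("all cells silent on the classification lap",
                      stacklevel=2)
        return np.zeros(rates.size, dtype=bool)
    return rates > threshold_frac * peak


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------

def run_exploration(hnet: HippocampalNet, n_laps: int = 100,
                    plasticity_on_after_lap: int = 1,
                    collect_sta_laps: int = 0) -> PlaceMapReport:
    """Exploration phase: ``n_laps`` at constant speed; the Hebbian and
    IDIP rules become plastic after ``plasticity_on_after_lap`` laps.

    If ``collect_sta_laps`` > 0, the spike-triggered average of the IDIP
    trace is collected over the final laps.
    """
    net = hnet.net
    lap_ms = hnet.cfg.track.lap_ms
    record = SpikeRecord(list(net.populations))
    lap_starts = []
    for lap in range(n_laps):
        if lap == plasticity_on_after_lap:
            hnet.hebb.frozen = False
            hnet.idip.frozen = False
        if collect_sta_laps and lap == n_laps - collect_sta_laps:
            hnet.idip.start_sta()
        lap_starts.append(net.t)
        net.run(lap_ms, record=record, record_pops=("CA1E", "CA1I"))
    report = PlaceMapReport(_lap_report(hnet, record, lap_starts),
                            record=record)
    report.labels = classify_place_cells(report.rates, n_laps - 1,
                                         hnet.cfg.active_threshold_frac)
    hnet.labels = report.labels
    return report


def run_silencing(hnet: HippocampalNet, with_idip: bool = True,
                  measure_skip_ms: float = 5000.0) -> pd.DataFrame:
    """One-lap silencing of the active place map.

    Runs one pre lap (OFF rates), one lap with all active cells clamped
    (ON rates of the alternative map), and one release lap.  If
    ``with_idip`` is False the IDIP updates are frozen at silencing onset
    (the control: an alternative map emerges but stays weak).  ON-lap map
    rates are measured after ``measure_skip_ms`` so the slow (plasticity)
    phase is reflected.

    Returns a tidy frame with, per phase, the mean rate of the originally
    active cells, of the originally silent cells, and of the whole CA1
    excitatory population.  The population mean is the natural
    network-centred readout of the expressed map's total activity: the
    homeostat conserves it across silencing regardless of how many cells
    carry each map.
    """
    if hnet.labels is None or not hnet.labels.any():
        raise ValueError("no active cells labeled; run exploration first")
    net = hnet.net
    cfg = hnet.cfg
    lap_ms = cfg.track.lap_ms
    active_idx = np.flatnonzero(hnet.labels)
    record = SpikeRecord(list(net.populations))

    t_pre = net.t
    net.run(lap_ms, record=record, record_pops=("CA1E", "CA1I"))
    idip_was_frozen = hnet.idip.frozen
    if not with_idip:
        hnet.idip.frozen = True
    hnet.ca1e.set_clamp(active_idx, True)
    t_on = net.t
    net.run(lap_ms, record=record, record_pops=("CA1E", "CA1I"))
    hnet.ca1e.set_clamp(active_idx, False)
    hnet.idip.frozen = idip_was_frozen
    t_post = net.t
    net.run(lap_ms, record=record, record_pops=("CA1E", "CA1I"))

    times, idx = record.spikes("CA1E")
    silent_idx = np.flatnonzero(~hnet.labels)

    def mean_rate(neurons, t0, t1):
        sel = (times >= t0) & (times < t1) & np.isin(idx, neurons)
        return float(sel.sum() / len(neurons) / ((t1 - t0) / 1000.0))

    rows = []
    all_idx = np.arange(cfg.n_exc)
    for phase, (t0, t1) in {
            "pre": (t_pre, t_pre + lap_ms),
            "silencing": (t_on + measure_skip_ms, t_on + lap_ms),
            "post": (t_post, t_post + lap_ms)}.items():
        rows.append({"phase": phase,
                     "original_map_hz": mean_rate(active_idx, t0, t1),
                     "alternative_map_hz": mean_rate(silent_idx, t0, t1),
                     "population_hz": mean_rate(all_idx, t0, t1)})
    return pd.DataFrame(rows)


def run_consolidation(hnet: HippocampalNet, n_trials: int = 10,
                      silencing_laps: int = 4,
                      test_laps: int = 1) -> pd.DataFrame:
    """Repeated-silencing consolidation protocol.

    Each trial silences the originally active map for ``silencing_laps``
    laps, then releases it for ``test_laps`` testing lap(s).  Trial 0 is
    the network's activity just after exploration (a plain lap before any
    further silencing).  Hebbian plasticity and IDIP stay active
    throughout.  Returns per-trial test-lap mean rates of the original
    (active) and alternative (silent) maps.
    """
    if hnet.labels is None or not hnet.labels.any():
        raise ValueError("no active cells labeled; run exploration first")
    net = hnet.net
    lap_ms = hnet.cfg.track.lap_ms
    active_idx = np.flatnonzero(hnet.labels)
    silent_idx = np.flatnonzero(~hnet.labels)
    rows = []

    def test_lap_rates(trial):
        record = SpikeRecord(list(net.populations))
        t0 = net.t
        net.run(test_laps * lap_ms, record=record, record_pops=("CA1E",))
        times, idx = record.spikes("CA1E")
        secs = test_laps * lap_ms / 1000.0
        rows.append({
            "trial": trial,
            "original_map_hz":
                float(np.isin(idx, active_idx).sum() / len(active_idx) / secs),
            "alternative_map_hz":
                float(np.isin(idx, silent_idx).sum() / len(silent_idx) / secs),
        })

    test_lap_rates(0)
    for trial in range(1, n_trials + 1):
        hnet.ca1e.set_clamp(active_idx, True)
        net.run(silencing_laps * lap_ms)
        hnet.ca1e.set_clamp(active_idx, False)
        test_lap_rates(trial)
    return pd.DataFrame(rows)
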