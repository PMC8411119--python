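"""Shared metrics and multi-seed aggregation.

Rate binning keeps exact spike bookkeeping (sum over bins of
rate * bin_width * n_neurons recovers the total spike count), and the rank
statistics use Spearman's coefficient with average-rank tie handling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable
import warnings

import numpy as np
from scipy import stats

from .core import SpikeRecord

__all__ = ["RateTrace", "bin_rates", "population_rate", "spearman",
           "SeedEnsemble", "ensemble_run"]


@dataclass
class RateTrace:
    """Per-neuron binned firing rates (Hz)."""

    edges: np.ndarray        # bin edges, ms (len n_bins + 1)
    rates: np.ndarray        # (n_neurons, n_bins), Hz

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])


def bin_rates(record: SpikeRecord, bin_width: float, pop: str,
              n_neurons: int, t_start: float | None = None,
              t_stop: float | None = None) -> RateTrace:
    """Bin one population's spikes into per-neuron rates in Hz."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    times, idx = record.spikes(pop)
    if t_start is None:
        t_start = record.t_start if record.t_start is not None else 0.0
    if t_stop is None:
        t_stop = record.duration
    n_bins = max(int(np.ceil((t_stop - t_start) / bin_width)), 1)
    edges = t_start + bin_width * np.arange(n_bins + 1)
    counts = np.zeros((n_neurons, n_bins))
    if len(times):
        sel = (times >= t_start) & (times < edges[-1])
        b = ((times[sel] - t_start) // bin_width).astype(np.int64)
        np.add.at(counts, (idx[sel], b), 1.0)
    return RateTrace(edges, counts / (bin_width / 1000.0))


def population_rate(record: SpikeRecord, pop: str, n_neurons: int,
                    t_start: float, t_stop: float) -> float:
    """Mean firing rate (Hz) of a population over a time window."""
    times, _ = record.spikes(pop)
    n = int(np.count_nonzero((times >= t_start) & (times < t_stop)))
    return n / n_neurons / ((t_stop - t_start) / 1000.0)


def spearman(x, y) -> float:
    """Spearman rank correlation with average-rank ties.

    Returns NaN (reported as missing) when either input has zero variance,
    e.g. a time bin without any spikes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("inputs must be equal-length vectors of size >= 3")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return float("nan")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


@dataclass
class SeedEnsemble:
    """Per-seed results plus their summary; the summary is always
    recomputable from ``values``."""

    seeds: list[int]
    values: list[float]
    failed: list[int]

    @property
    def mean(self) -> float:
        vals = [v for v in self.values if np.isfinite(v)]
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def std(self) -> float:
        vals = [v for v in self.values if np.isfinite(v)]
        return float(np.std(vals)) if vals else float("nan")

    @property
    def n_valid(self) -> int:
        return int(sum(np.isfinite(v) for v in self.values))


def ensemble_run(experiment: Callable[[int], float], n_seeds: int = 20,
                 base_seed: int = 0) -> SeedEnsemble:
    """Run ``experiment(seed)`` for seeds ``base_seed + k`` and aggregate.

    Seeds that raise are recorded and excluded with a warning, never
    silently dropped.  NaN results (e.g. undefined correlations) are kept
    in ``values`` but excluded from the summary.
    """
    seeds, values, failed = [], [], []
    for k in range(n_seeds):
        seed = base_seed + k
        try:
            values.append(float(experiment(seed)))
            seeds.append(seed)
        except Exception as err:  # noqa: BLE001 - reported, not swallowed
            warnings.warn(f"seed {seed} failed and is excluded: {err}",
                          stacklevel=2)
            failed.append(seed)
    return SeedEnsemble(seeds, values, failed)
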