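"""Synthetic MT population: tuning model, Poisson spiking, KDE rates, averaging.

The decision models downstream consume *population-averaged* firing rates of
direction- and depth-tuned MT neurons.  The recordings those averages would
normally come from are not available, so this module generates a stand-in
population with a parametric tuning model and reduces it exactly the way a
recorded population would be reduced: per-trial spike trains -> kernel-density
rate estimates -> per-neuron condition means -> population mean.

Conventions
-----------
* Stimulus strengths ``c_dir`` (signed motion coherence) and ``c_dep`` (signed
  binocular correlation) are expressed in each neuron's *preferred* frame:
  positive values mean coherence/correlation toward the neuron's preferred
  direction or depth.  The strength grid is symmetric, so simulating the
  "recording" directly on the preferred-frame grid is equivalent to presenting
  lab-frame stimuli and re-signing per neuron.
* Rates are spikes/ms throughout (gains and baselines are specified in the
  familiar spikes/s and converted internally).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as _signal
from scipy import stats as _stats

from .timebase import DT, N_BINS, STIM_OFF, T_START, time_grid

logger = logging.getLogger(__name__)

#: default signed strength levels for both stimulus features
DEFAULT_LEVELS = np.array(
    [-0.5, -0.25, -0.125, -0.0625, 0.0, 0.0625, 0.125, 0.25, 0.5]
)

TASKS = ("direction", "depth")

_QUADRANTS = (("up", "far"), ("down", "far"), ("up", "near"), ("down", "near"))


class MissingDataError(ValueError):
    """A (neuron, condition, task) cell required for averaging has no trials."""


@dataclass(frozen=True)
class NeuronSpec:
    """Tuning parameters of one synthetic MT neuron.

    Rates follow ``baseline + step(t >= latency) * evoked`` where the evoked
    term is linear in the preferred-frame strengths and optionally carries a
    multiplicative onset transient decaying with time constant
    ``transient_tau``.  Negative rates are clipped to zero.
    """

    id: int
    pref_dir: str  # {"up", "down"}
    pref_depth: str  # {"far", "near"}
    baseline_rate: float  # spikes/s
    dir_gain: float  # spikes/s per unit signed coherence
    depth_gain: float  # spikes/s per unit signed correlation
    latency: float = 100.0  # ms
    transient_amp: float = 0.0  # dimensionless, >= 0
    transient_tau: float = 50.0  # ms, > 0

    def __post_init__(self):
        if self.baseline_rate < 0 or self.latency < 0:
            raise ValueError("baseline_rate and latency must be >= 0")
        if self.transient_amp < 0 or self.transient_tau <= 0:
            raise ValueError("transient_amp >= 0 and transient_tau > 0 required")
        if self.pref_dir not in ("up", "down") or self.pref_depth not in ("far", "near"):
            raise ValueError("unknown preference labels")


@dataclass(frozen=True)
class TuningConfig:
    """Distributions the population generator draws neuron parameters from.

    Defaults emulate the features the decision models rely on: ~100 ms
    response latency, joint direction x depth tuning, direction tuning that
    is on average stronger than depth tuning, and broad (lognormal)
    heterogeneity of tuning strengths, so a subpopulation with roughly equal
    direction and depth sensitivity exists for the balanced-readout analysis.
    Gains are lognormal with the given mean and SD (spikes/s per unit signed
    strength); baselines are gamma.
    """

    baseline_mean: float = 20.0  # spikes/s, gamma-distributed
    baseline_shape: float = 4.0
    dir_gain_mean: float = 40.0  # spikes/s per unit coherence
    dir_gain_sd: float = 20.0
    depth_gain_mean: float = 20.0  # spikes/s per unit correlation
    depth_gain_sd: float = 15.0
    latency_mean: float = 100.0  # ms
    latency_sd: float = 8.0
    transient_amp_range: tuple[float, float] = (0.0, 0.5)
    transient_tau_range: tuple[float, float] = (30.0, 80.0)

    @classmethod
    def balanced(cls) -> "TuningConfig":
        """Equal average direction and depth sensitivity (for control runs)."""
        return cls(dir_gain_mean=30.0, dir_gain_sd=3.0,
                   depth_gain_mean=30.0, depth_gain_sd=3.0)


@dataclass
class SpikeTrain:
    """One trial of one neuron: binary 1-ms bins on the common trial grid."""

    neuron_id: int
    task: str
    c_dir: float
    c_dep: float
    bins: np.ndarray  # uint8 {0,1}, length N_BINS, origin at stimulus onset
    choice: str = "none"  # {"up", "down", "none"}

    def __post_init__(self):
        self.bins = np.asarray(self.bins, dtype=np.uint8)
        if self.bins.ndim != 1 or self.bins.size != N_BINS:
            raise ValueError(f"bins must be a length-{N_BINS} 1-ms series")
        if not np.isin(self.bins, (0, 1)).all():
            raise ValueError("bins must contain only 0/1")

    @property
    def spike_times(self) -> np.ndarray:
        """Spike times in ms (left bin edges) relative to stimulus onset."""
        return time_grid()[self.bins.astype(bool)]


@dataclass
class PopulationRateTable:
    """Population-mean firing rate r(tau; c_dir, c_dep, task) in spikes/ms.

    ``rates[task]`` has shape (n_levels, n_levels, n_bins), indexed by the
    preferred-frame strength grid ``levels`` (sorted, symmetric) for c_dir and
    c_dep, on the common 1-ms trial grid.
    """

    levels: np.ndarray
    rates: dict[str, np.ndarray]
    n_neurons: int = 0

    def __post_init__(self):
        self.levels = np.asarray(self.levels, dtype=float)
        for task, arr in self.rates.items():
            if arr.shape != (self.levels.size, self.levels.size, N_BINS):
                raise ValueError(f"rate grid for task {task!r} has wrong shape")
            if (arr < 0).any():
                raise ValueError("rates must be >= 0")

    @property
    def tau(self) -> np.ndarray:
        return time_grid()

    def _level_index(self, c: float) -> int:
        hits = np.flatnonzero(np.isclose(self.levels, c, atol=1e-12))
        if hits.size == 0:
            raise LookupError(
                f"strength {c} not on the table grid {self.levels.tolist()}; "
                "no interpolation is performed"
            )
        return int(hits[0])

    def lookup(self, c_dir: float, c_dep: float, task: str) -> np.ndarray:
        """Rate series (spikes/ms) for one preferred-frame condition."""
        if task not in self.rates:
            raise LookupError(f"task {task!r} not in table")
        return self.rates[task][self._level_index(c_dir), self._level_index(c_dep)]

    def to_frame(self) -> pd.DataFrame:
        """Long-format view (tau_ms, c_dir, c_dep, task, rate_spikes_per_ms)."""
        recs = []
        tau = self.tau
        for task, arr in self.rates.items():
            for i, cd in enumerate(self.levels):
                for j, cp in enumerate(self.levels):
                    recs.append(pd.DataFrame({
                        "tau_ms": tau, "c_dir": cd, "c_dep": cp,
                        "task": task, "rate_spikes_per_ms": arr[i, j],
                    }))
        return pd.concat(recs, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, n_neurons: int = 0) -> "PopulationRateTable":
        levels = np.sort(df["c_dir"].unique())
        rates = {}
        for task, sub in df.groupby("task"):
            arr = np.zeros((levels.size, levels.size, N_BINS))
            for (cd, cp), cell in sub.groupby(["c_dir", "c_dep"]):
                cell = cell.sort_values("tau_ms")
                i = int(np.searchsorted(levels, cd))
                j = int(np.searchsorted(levels, cp))
                arr[i, j] = cell["rate_spikes_per_ms"].to_numpy()
            rates[str(task)] = arr
        return cls(levels=levels, rates=rates, n_neurons=n_neurons)


# ---------------------------------------------------------------------------
# population generation and the single-neuron rate model
# ---------------------------------------------------------------------------

def make_population(n_neurons: int, seed: int,
                    tuning: TuningConfig | None = None) -> list[NeuronSpec]:
    """Draw a synthetic MT population.

    Preference quadrants (up/far, down/far, up/near, down/near) are assigned
    round-robin so every quadrant is populated whenever ``n_neurons >= 4``.
    Deterministic for a fixed seed.
    """
    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    cfg = tuning or TuningConfig()
    rng = np.random.default_rng(seed)

    def lognormal(mean, sd):
        sigma2 = np.log1p((sd / mean) ** 2)
        return rng.lognormal(np.log(mean) - sigma2 / 2, np.sqrt(sigma2))

    specs = []
    for i in range(n_neurons):
        pref_dir, pref_depth = _QUADRANTS[i % 4]
        baseline = rng.gamma(cfg.baseline_shape,
                             cfg.baseline_mean / cfg.baseline_shape)
        dir_gain = lognormal(cfg.dir_gain_mean, cfg.dir_gain_sd)
        depth_gain = lognormal(cfg.depth_gain_mean, cfg.depth_gain_sd)
        latency = float(np.clip(rng.normal(cfg.latency_mean, cfg.latency_sd),
                                60.0, 160.0))
        specs.append(NeuronSpec(
            id=i, pref_dir=pref_dir, pref_depth=pref_depth,
            baseline_rate=baseline, dir_gain=dir_gain, depth_gain=depth_gain,
            latency=latency,
            transient_amp=rng.uniform(*cfg.transient_amp_range),
            transient_tau=rng.uniform(*cfg.transient_tau_range),
        ))
    return specs


def rate_function(spec: NeuronSpec, c_dir: float, c_dep: float,
                  tau) -> np.ndarray | float:
    """Instantaneous firing rate (spikes/ms) at time(s) ``tau`` (ms from onset).

    rate = max(0, baseline + [latency <= tau < offset+latency]
                 * (dir_gain*c_dir + depth_gain*c_dep) * (1 + transient(tau)))
    with all spikes/s quantities converted to spikes/ms.  Strengths are in the
    neuron's preferred frame; the evoked term switches on at the response
    latency and off one latency after stimulus offset.
    """
    if not (-1.0 <= c_dir <= 1.0) or not (-1.0 <= c_dep <= 1.0):
        raise ValueError("stimulus strengths must lie in [-1, 1]")
    tau = np.asarray(tau, dtype=float)
    evoked_on = (tau >= spec.latency) & (tau < STIM_OFF + spec.latency)
    transient = 1.0 + spec.transient_amp * np.exp(
        -(tau - spec.latency) / spec.transient_tau)
    evoked = (spec.dir_gain * c_dir + spec.depth_gain * c_dep) * transient
    rate_sps = spec.baseline_rate + np.where(evoked_on, evoked, 0.0)
    out = np.maximum(rate_sps, 0.0) / 1000.0
    return out if out.ndim else float(out)


def rate_series(spec: NeuronSpec, c_dir: float, c_dep: float) -> np.ndarray:
    """Rate on the full trial grid (spikes/ms per 1-ms bin)."""
    return np.asarray(rate_function(spec, c_dir, c_dep, time_grid()))


def generate_spike_train(rates: np.ndarray, seed) -> np.ndarray:
    """Bernoulli-per-bin spiking: spike probability min(rate*DT, 1) per 1-ms bin.

    ``seed`` may be an int or a ``numpy.random.Generator``.  This is the 1-ms
    discretization of a Poisson process (at most one spike per bin).
    """
    rates = np.asarray(rates, dtype=float)
    if (rates < 0).any():
        raise ValueError("rates must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = np.minimum(rates * DT, 1.0)
    return (rng.random(rates.shape) < p).astype(np.uint8)


# ---------------------------------------------------------------------------
# kernel-density rate estimation and population averaging
# ---------------------------------------------------------------------------

KDE_SD = 20.0  # ms, Gaussian kernel standard deviation
KDE_HALF_WIDTH = 60.0  # ms, kernel support truncated at +/- 60 ms


def kde_kernel() -> np.ndarray:
    """Truncated Gaussian kernel (SD 20 ms, support +/-60 ms) on the 1-ms grid.

    The kernel is deliberately *not* renormalized after truncation; it carries
    ~99.73% of the full Gaussian mass.
    """
    t = np.arange(-KDE_HALF_WIDTH, KDE_HALF_WIDTH + DT, DT)
    return _stats.norm.pdf(t, loc=0.0, scale=KDE_SD) * DT


def kde_rate(train: SpikeTrain | np.ndarray) -> np.ndarray:
    """Kernel-density rate estimate (spikes/ms) of a spike train.

    Works on a :class:`SpikeTrain` or directly on a 0/1 (or averaged) bin
    series; an empty train gives an identically zero series.
    """
    bins = train.bins if isinstance(train, SpikeTrain) else np.asarray(train)
    return _smooth(bins.astype(float)[None, :])[0]


def _smooth(mean_trains: np.ndarray) -> np.ndarray:
    """Convolve rows with the KDE kernel ('same' extent, edges zero-padded)."""
    out = _signal.fftconvolve(mean_trains, kde_kernel()[None, :], mode="same",
                              axes=1)
    # scrub FFT round-off: negatives and sub-1e-12 residue outside the
    # kernel support (true KDE values are never that small)
    out[out < 1e-12] = 0.0
    return out


def average_population_rates(trains: list[SpikeTrain],
                             levels: np.ndarray | None = None,
                             tasks: tuple[str, ...] = TASKS,
                             ) -> PopulationRateTable:
    """Reduce per-trial spike trains to the population-mean rate table.

    For every (neuron, condition, task) cell the per-trial KDE rates are
    averaged; the table entry is the mean of those per-neuron means across
    neurons.  Every neuron must contribute at least one trial to every cell
    of the grid for both tasks, otherwise :class:`MissingDataError` is raised
    naming the first missing cell.
    """
    if not trains:
        raise ValueError("no spike trains supplied")
    neuron_ids = sorted({t.neuron_id for t in trains})
    if levels is None:
        levels = np.unique([t.c_dir for t in trains] + [t.c_dep for t in trains])
    levels = np.sort(np.asarray(levels, dtype=float))

    groups: dict[tuple, list[np.ndarray]] = {}
    for t in trains:
        groups.setdefault((t.neuron_id, t.task, t.c_dir, t.c_dep), []).append(t.bins)

    rates = {}
    for task in tasks:
        acc = np.zeros((levels.size, levels.size, N_BINS))
        for nid in neuron_ids:
            for i, cd in enumerate(levels):
                for j, cp in enumerate(levels):
                    key = (nid, task, cd, cp)
                    if key not in groups:
                        raise MissingDataError(
                            f"no trials for neuron {nid}, task {task!r}, "
                            f"c_dir={cd}, c_dep={cp}")
                    mean_train = np.mean(groups[key], axis=0, dtype=float)
                    acc[i, j] += kde_rate(mean_train)
        rates[task] = acc / len(neuron_ids)
    return PopulationRateTable(levels=levels, rates=rates,
                               n_neurons=len(neuron_ids))


def build_rate_table(population: list[NeuronSpec],
                     levels: np.ndarray | None = None,
                     trials_per_condition: int = 10,
                     seed: int = 0,
                     tasks: tuple[str, ...] = TASKS) -> PopulationRateTable:
    """Simulate a 'recording' of the population and average it into a table.

    Each neuron is run for ``trials_per_condition`` Poisson trials at every
    preferred-frame grid condition, separately per task; per-neuron condition
    means are KDE-smoothed and averaged across neurons.  The per-bin mean
    across trials is sampled directly as Binomial(n, p)/n, which is
    distributionally identical to averaging individual Bernoulli trains.
    """
    if trials_per_condition < 1:
        raise ValueError("trials_per_condition must be >= 1")
    levels = np.sort(np.asarray(DEFAULT_LEVELS if levels is None else levels,
                                dtype=float))
    rng = np.random.default_rng(seed)
    n_lev = levels.size
    rates = {task: np.zeros((n_lev, n_lev, N_BINS)) for task in tasks}
    for spec in population:
        # expected-rate grid for this neuron, shared by both tasks
        p = np.empty((n_lev, n_lev, N_BINS))
        for i, cd in enumerate(levels):
            for j, cp in enumerate(levels):
                p[i, j] = np.minimum(rate_series(spec, cd, cp) * DT, 1.0)
        for task in tasks:
            mean_trains = rng.binomial(trials_per_condition, p) / trials_per_condition
            rates[task] += _smooth(mean_trains.reshape(-1, N_BINS)).reshape(p.shape)
    for task in tasks:
        rates[task] /= len(population)
    return PopulationRateTable(levels=levels, rates=rates,
                               n_neurons=len(population))


# ---------------------------------------------------------------------------
# per-neuron trial counts (for neurometric analysis)
# ---------------------------------------------------------------------------

def neuron_level_counts(spec: NeuronSpec, feature: str,
                        levels: np.ndarray, n_trials: int, seed: int,
                        window: tuple[float, float] = (0.0, float(STIM_OFF)),
                        ) -> pd.DataFrame:
    """Spike counts of one neuron at +/- each strength level of one feature.

    Counts are taken over ``window`` (ms from onset, default the stimulus
    epoch); the other feature is held at zero.  Returns a long DataFrame with
    columns (signed_level, trial, count).
    """
    if feature not in ("dir", "depth"):
        raise ValueError("feature must be 'dir' or 'depth'")
    rng = np.random.default_rng(seed)
    lo = int(round(window[0] - T_START))
    hi = int(round(window[1] - T_START))
    recs = []
    for lev in np.asarray(levels, dtype=float):
        for sgn in (+1.0, -1.0):
            c = sgn * lev
            cd, cp = (c, 0.0) if feature == "dir" else (0.0, c)
            p = np.minimum(rate_series(spec, cd, cp)[lo:hi] * DT, 1.0)
            counts = (rng.random((n_trials, hi - lo)) < p).sum(axis=1)
            recs.append(pd.DataFrame({
                "signed_level": c, "trial": np.arange(n_trials), "count": counts,
            }))
    return pd.concat(recs, ignore_index=True)


def subset_population(population: list[NeuronSpec],
                      ids: list[int]) -> list[NeuronSpec]:
    """Pick the neurons with the given ids (order preserved)."""
    keep = set(ids)
    return [s for s in population if s.id in keep]
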