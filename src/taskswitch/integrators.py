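"""Two-accumulator evidence-integration models and the trial simulation loops.

The general model keeps task-relevant and task-irrelevant differential
signals in two accumulators updated in 1-ms steps over the integration
window [tau0, tau1) (100 ms after stimulus onset to 100 ms after offset):

    I_rel <- (I_rel + i_rel(tau) * dt) * exp(-k_relevant * dt)
    I_irr <- (I_irr + w(tau) * i_irr(tau) * dt) * exp(-k_irrelevant * dt)

so evidence arriving at time ``tau`` enters the decision variable
``I = I_rel + I_irr`` with weight ``exp(-k (tau1 - tau))`` (leak) times
``w(tau)`` (gate).  The choice is the sign of I at tau1 (fair coin on an
exact tie).  Four named variants:

* ``gated``             k_rel = k_irr = 0, w(tau) = w constant.
* ``time_varying_gate`` k_rel = k_irr = 0, w(tau) = exp(k (tau - tau1)).
* ``single_leaky``      k_rel = k_irr = k, w(tau) = w constant.
* ``double_leaky``      k_rel = 0, k_irr = k, w = 1.

Because ``exp(-k (tau1 - tau))`` and ``exp(k (tau - tau1))`` are the same
number, the double-leaky and time-varying-gate models with a shared k make
identical choices on identical spike trains — exactly, not statistically.
The per-step decay uses the exact factor ``exp(-k dt)`` (not forward Euler)
so this identity holds in discrete time.

``run_experiment`` drives the full pipeline (rate table -> bank rates ->
Poisson spikes -> differential signals -> integration -> choice) over a
stimulus grid; ``run_late_commitment`` additionally models trials in which
the task is committed to only at time t_c within the trial, with both
accumulators initially open (integrating everything) or closed (integrating
nothing) before t_c.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .readout import DEP_COEF, DIR_COEF, bank_rates
from .synthetic_mt import PopulationRateTable
from .timebase import DT, T_START, TAU0, TAU1, bin_index, time_grid

VARIANTS = ("gated", "time_varying_gate", "single_leaky", "double_leaky")


class ConfigError(ValueError):
    """Integrator configuration violates its variant's definition."""


@dataclass(frozen=True)
class IntegratorConfig:
    """One model variant with its parameters.

    ``w`` is the constant gate weight (gated / single_leaky); ``k`` is the
    leak or gate rate in 1/ms (time_varying_gate / single_leaky /
    double_leaky).  A time constant of T ms corresponds to ``k = 1/T``.
    """

    variant: str
    w: float | None = None
    k: float | None = None
    tau0: float = TAU0
    tau1: float = TAU1

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ConfigError(f"unknown variant {self.variant!r}")
        needs_w = self.variant in ("gated", "single_leaky")
        needs_k = self.variant in ("time_varying_gate", "single_leaky",
                                   "double_leaky")
        if needs_w:
            if self.w is None or not 0.0 <= self.w <= 1.0:
                raise ConfigError(f"{self.variant} requires w in [0, 1]")
        elif self.w is not None:
            raise ConfigError(f"{self.variant} does not take w")
        if needs_k:
            if self.k is None or self.k < 0:
                raise ConfigError(f"{self.variant} requires k >= 0 (1/ms)")
        elif self.k is not None and self.k != 0.0:
            raise ConfigError(f"{self.variant} has no leak (k must be unset)")
        if self.tau1 <= self.tau0:
            raise ConfigError("tau1 must exceed tau0")

    @property
    def k_relevant(self) -> float:
        return self.k if self.variant == "single_leaky" else 0.0

    @property
    def k_irrelevant(self) -> float:
        return self.k if self.variant in ("single_leaky", "double_leaky") else 0.0

    def weight(self, tau: np.ndarray | float):
        """Gate w(tau) on the irrelevant signal (1.0 for double_leaky)."""
        if self.variant in ("gated", "single_leaky"):
            return np.broadcast_to(self.w, np.shape(tau)) if np.ndim(tau) else self.w
        if self.variant == "time_varying_gate":
            return np.exp(self.k * (np.asarray(tau, dtype=float) - self.tau1))
        return np.broadcast_to(1.0, np.shape(tau)) if np.ndim(tau) else 1.0


@dataclass
class TrialRecord:
    task: str
    c_dir: float  # lab-frame signed coherence C_dir
    c_dep: float  # lab-frame signed correlation C_dep
    trial: int
    final_value: float  # I(tau1), signed accumulated evidence
    choice: str  # {"up", "down"}
    t_c: float | None = None  # task-commitment time, ms (None: pre-committed)
    regime: str = "none"  # {"open", "closed", "none"}


# ---------------------------------------------------------------------------
# effective per-bin evidence weights
# ---------------------------------------------------------------------------

def evidence_weights(config: IntegratorConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin weights (a, b) such that I = sum a*i_rel + sum b*i_irr.

    Closed form of the step recursion over the window bins
    tau = tau0 .. tau1-1: evidence at tau carries leak factor
    exp(-k (tau1 - tau)) and gate factor w(tau).
    """
    tau = np.arange(config.tau0, config.tau1, DT)
    decay_rel = np.exp(-config.k_relevant * (config.tau1 - tau))
    decay_irr = np.exp(-config.k_irrelevant * (config.tau1 - tau))
    a = decay_rel * DT
    b = decay_irr * np.asarray(config.weight(tau), dtype=float) * DT
    return a, b


def commitment_weights(config: IntegratorConfig, t_c: float,
                       initial_regime: str) -> tuple[np.ndarray, np.ndarray]:
    """Evidence weights for a trial whose task commitment completes at t_c.

    Before t_c both accumulators are either *open* (both features integrated
    with weight 1, no leak) or *closed* (nothing integrated).  From t_c the
    variant's own regime applies: the gated model drops the irrelevant weight
    to w; the leaky models start decaying the irrelevant accumulator, so
    open-start evidence stored before t_c decays by exp(-k (tau1 - t_c)); the
    time-varying gate re-anchors its schedule to the commitment time,
    w(tau) = exp(k (tau - (t_c + (tau1 - tau0)))).  t_c below tau0 is clamped
    to tau0 (commitment completed before integration starts).
    """
    if initial_regime not in ("open", "closed"):
        raise ValueError(f"unknown initial regime {initial_regime!r}")
    t_c = float(np.clip(t_c, config.tau0, config.tau1))
    tau = np.arange(config.tau0, config.tau1, DT)
    pre = tau < t_c

    # post-commitment weights per variant
    k = config.k or 0.0
    if config.variant == "gated":
        a_post = np.ones_like(tau)
        b_post = np.full_like(tau, config.w)
    elif config.variant == "time_varying_gate":
        a_post = np.ones_like(tau)
        b_post = np.exp(k * (tau - (t_c + (config.tau1 - config.tau0))))
    elif config.variant == "double_leaky":
        a_post = np.ones_like(tau)
        b_post = np.exp(-k * (config.tau1 - tau))
    else:  # single_leaky: both accumulators leak once committed
        a_post = np.exp(-k * (config.tau1 - np.maximum(tau, t_c)))
        b_post = config.w * np.exp(-k * (config.tau1 - tau))

    if initial_regime == "closed":
        a = np.where(pre, 0.0, a_post)
        b = np.where(pre, 0.0, b_post)
    else:
        # open: pre-commitment evidence fully integrated; under the leaky
        # variants it then decays from t_c to tau1
        a_pre = np.where(
            config.variant == "single_leaky",
            np.exp(-k * (config.tau1 - t_c)), 1.0)
        b_pre = (np.exp(-k * (config.tau1 - t_c))
                 if config.variant in ("double_leaky", "single_leaky") else 1.0)
        a = np.where(pre, a_pre, a_post)
        b = np.where(pre, b_pre, b_post)
    return a * DT, b * DT


# ---------------------------------------------------------------------------
# single-trial reference implementation
# ---------------------------------------------------------------------------

def _choices_from_values(values: np.ndarray, rng: np.random.Generator
                         ) -> np.ndarray:
    """Sign rule with a fair-coin tie break at exactly zero."""
    up = values > 0
    ties = values == 0
    if ties.any():
        up = up | (ties & (rng.random(values.shape) < 0.5))
    return np.where(up, "up", "down")


def integrate_trial(i_dir: np.ndarray, i_dep: np.ndarray, task: str,
                    config: IntegratorConfig, seed,
                    t0: float = T_START) -> TrialRecord:
    """Integrate one trial's differential signals step by step.

    ``i_dir``/``i_dep`` are spikes/ms series starting at ``t0`` and must
    cover the window [tau0, tau1).  The relevant signal is ``i_dir`` in the
    direction task and ``i_dep`` in the depth task.  This is the loop-form
    reference implementation; the batch engine uses the closed-form
    :func:`evidence_weights` and is tested to agree trial-for-trial.
    """
    if task not in ("direction", "depth"):
        raise ValueError(f"unknown task {task!r}")
    i_dir = np.asarray(i_dir, dtype=float)
    i_dep = np.asarray(i_dep, dtype=float)
    if i_dir.shape != i_dep.shape or i_dir.ndim != 1:
        raise ValueError("signals must be equal-length 1-d series")
    lo = int(round((config.tau0 - t0) / DT))
    hi = int(round((config.tau1 - t0) / DT))
    if lo < 0 or hi > i_dir.size:
        raise ValueError("signals do not cover the integration window")
    i_rel, i_irr = (i_dir, i_dep) if task == "direction" else (i_dep, i_dir)

    d_rel = float(np.exp(-config.k_relevant * DT))
    d_irr = float(np.exp(-config.k_irrelevant * DT))
    I_rel = 0.0
    I_irr = 0.0
    for j in range(lo, hi):
        tau = t0 + j * DT
        I_rel = (I_rel + i_rel[j] * DT) * d_rel
        I_irr = (I_irr + float(config.weight(tau)) * i_irr[j] * DT) * d_irr
    final = I_rel + I_irr

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    choice = str(_choices_from_values(np.asarray(final), rng))
    return TrialRecord(task=task, c_dir=np.nan, c_dep=np.nan, trial=0,
                       final_value=final, choice=choice)


# ---------------------------------------------------------------------------
# batch simulation engine
# ---------------------------------------------------------------------------

CP_BIN_STARTS = np.arange(-100, 700, 100)  # eight 100-ms analysis bins


def _simulate_cell(rates8: np.ndarray, a: np.ndarray, b: np.ndarray,
                   task: str, n_trials: int, rng: np.random.Generator,
                   collect_counts: bool, collect_spikes: bool):
    """Simulate one (task, C_dir, C_dep) cell; returns (I, counts, spikes).

    ``rates8``: (8, N_BINS) bank rates on the full trial grid.  Spikes are
    sampled over the full grid when per-bin counts or spike times are
    requested, otherwise only over the integration window.
    """
    win = slice(bin_index(TAU0), bin_index(TAU1))
    full = collect_counts or collect_spikes
    sl = slice(None) if full else win
    p = np.minimum(rates8[:, sl] * DT, 1.0)
    spikes = rng.random((n_trials,) + p.shape) < p  # (n_trials, 8, nb)

    s_win = spikes[:, :, win] if full else spikes
    i_dir = np.tensordot(s_win, DIR_COEF, axes=([1], [0]))  # (n_trials, 500)
    i_dep = np.tensordot(s_win, DEP_COEF, axes=([1], [0]))
    i_rel, i_irr = (i_dir, i_dep) if task == "direction" else (i_dep, i_dir)
    I = i_rel @ a + i_irr @ b

    counts = None
    if collect_counts:
        counts = spikes.reshape(n_trials, 8, len(CP_BIN_STARTS), 100).sum(axis=3)
    return I, counts, (spikes if collect_spikes else None)


def _run(table: PopulationRateTable, weights_for_task, levels, tasks,
         trials_per_condition: int, seed: int, collect_counts: bool,
         collect_spikes: bool, t_c=None, regime="none"):
    if trials_per_condition < 1:
        raise ValueError("trials_per_condition must be >= 1")
    levels = np.asarray(table.levels if levels is None else levels, dtype=float)
    ss = np.random.SeedSequence(seed)
    cells = list(product(tasks, levels, levels))
    child = ss.spawn(len(cells))

    recs, count_recs, spike_recs = [], [], []
    tgrid = time_grid()
    for (task, cd, cp), cseed in zip(cells, child):
        rng = np.random.default_rng(cseed)
        rates8 = bank_rates(table, cd, cp, task)
        a, b = weights_for_task
        I, counts, spikes = _simulate_cell(
            rates8, a, b, task, trials_per_condition, rng,
            collect_counts, collect_spikes)
        choices = _choices_from_values(I, rng)
        recs.append(pd.DataFrame({
            "task": task, "c_dir": cd, "c_dep": cp,
            "trial": np.arange(trials_per_condition),
            "final_value": I, "choice": choices,
            "t_c": np.nan if t_c is None else float(t_c), "regime": regime,
        }))
        if collect_counts:
            n, _, nbin = counts.shape
            count_recs.append(pd.DataFrame({
                "task": task, "c_dir": cd, "c_dep": cp,
                "trial": np.repeat(np.arange(n), 8 * nbin),
                "neuron": np.tile(np.repeat(np.arange(1, 9), nbin), n),
                "bin_start": np.tile(CP_BIN_STARTS, 8 * n),
                "count": counts.reshape(-1),
                "choice": np.repeat(choices, 8 * nbin),
            }))
        if collect_spikes:
            tr, nrn, tb = np.nonzero(spikes)
            spike_recs.append(pd.DataFrame({
                "trial_id": tr, "neuron_id": nrn + 1, "task": task,
                "c_dir": cd, "c_dep": cp,
                "choice": choices[tr], "spike_time_ms": tgrid[tb],
            }))
    trials = pd.concat(recs, ignore_index=True)
    out = [trials]
    if collect_counts:
        out.append(pd.concat(count_recs, ignore_index=True))
    if collect_spikes:
        out.append(pd.concat(spike_recs, ignore_index=True))
    return out[0] if len(out) == 1 else tuple(out)


def run_experiment(table: PopulationRateTable, config: IntegratorConfig,
                   levels=None, trials_per_condition: int = 1000,
                   seed: int = 0, tasks=("direction", "depth"),
                   collect_counts: bool = False, collect_spikes: bool = False):
    """Simulate the full grid of conditions for both tasks.

    For every (task, C_dir, C_dep) cell, ``trials_per_condition`` independent
    trials run through bank rates -> Poisson spikes -> differential signals ->
    integration -> sign-rule choice.  Reproducible for a fixed seed.  Returns
    a trials DataFrame, plus a per-100-ms-bin spike-count DataFrame if
    ``collect_counts`` and a long spike-times DataFrame if ``collect_spikes``.
    """
    return _run(table, evidence_weights(config), levels, tasks,
                trials_per_condition, seed, collect_counts, collect_spikes)


def run_late_commitment(table: PopulationRateTable, config: IntegratorConfig,
                        t_c: float, initial_regime: str, levels=None,
                        trials_per_condition: int = 1000, seed: int = 0,
                        tasks=("direction", "depth")):
    """Simulate trials with task commitment completing only at t_c ms.

    See :func:`commitment_weights` for the pre/post-commitment regimes.
    """
    w = commitment_weights(config, t_c, initial_regime)
    return _run(table, w, levels, tasks, trials_per_condition, seed,
                False, False, t_c=t_c, regime=initial_regime)
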