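"""SR-matching parameter calibration for the gated and time-varying-gate models.

The gated model's weight w (and the time-varying gate's time constant) are
free parameters fixed by matching the simulated switch ratio to a behavioral
target (0.70 in the study conditions this package emulates).  The search
simulates the full stimulus grid once and evaluates every candidate
parameter on the *same* spike trains (common random numbers): for the gated
model the decision variable is affine in w, I = I_rel + w * I_irr, and for
the exponential gate it is a matrix product of the irrelevant signal with
per-parameter weight columns.  This removes simulation noise from the shape
of the SR-vs-parameter curve; the selected parameter should then be
re-simulated with fresh seeds for an unbiased SR estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .integrators import _choices_from_values
from .psychometrics import fit_logistic_task, switch_ratio
from .readout import DEP_COEF, DIR_COEF, bank_rates
from .synthetic_mt import PopulationRateTable
from .timebase import DT, TAU0, TAU1, bin_index


@dataclass
class CalibrationResult:
    parameter: str  # "w" or "tau_ms"
    best: float  # parameter value whose SR is closest to target
    target_sr: float
    achieved_sr: float  # SR at `best` on the search simulation
    curve: pd.DataFrame  # (parameter value, sr, sr_se)
    target_achievable: bool
    sr_range: tuple[float, float]  # achievable SR interval on the sweep


def _sr_curve(table: PopulationRateTable, param_values: np.ndarray,
              irr_weights: np.ndarray, levels, trials_per_condition: int,
              seed: int) -> pd.DataFrame:
    """Simulate once, score SR for every candidate irrelevant-weight column.

    ``irr_weights``: (n_window_bins, n_params) per-bin weights on the
    irrelevant signal; the relevant signal always carries weight 1 (no leak
    in either model being calibrated).
    """
    levels = np.asarray(table.levels if levels is None else levels, float)
    win = slice(bin_index(TAU0), bin_index(TAU1))
    ss = np.random.SeedSequence(seed)
    cells = list(product(("direction", "depth"), levels, levels))
    children = ss.spawn(len(cells))

    frames: list[pd.DataFrame] = []
    for (task, cd, cp), cseed in zip(cells, children):
        rng = np.random.default_rng(cseed)
        p = np.minimum(bank_rates(table, cd, cp, task)[:, win] * DT, 1.0)
        spikes = rng.random((trials_per_condition,) + p.shape) < p
        i_dir = np.tensordot(spikes, DIR_COEF, axes=([1], [0]))
        i_dep = np.tensordot(spikes, DEP_COEF, axes=([1], [0]))
        i_rel, i_irr = (i_dir, i_dep) if task == "direction" else (i_dep, i_dir)
        I = (i_rel.sum(axis=1) * DT)[:, None] + (i_irr @ irr_weights) * DT
        ties_rng = np.random.default_rng(cseed.spawn(1)[0])
        for j in range(param_values.size):
            choices = _choices_from_values(I[:, j], ties_rng)
            frames.append(pd.DataFrame({
                "param_index": j, "task": task, "c_dir": cd, "c_dep": cp,
                "choice": choices,
            }))
    allt = pd.concat(frames, ignore_index=True)

    rows = []
    for j, val in enumerate(param_values):
        sub = allt[allt["param_index"] == j]
        fits = {t: fit_logistic_task(sub[sub["task"] == t])
                for t in ("direction", "depth")}
        sr = switch_ratio(fits["direction"], fits["depth"])
        rows.append({"value": float(val), "sr": sr.value, "sr_se": sr.se})
    return pd.DataFrame(rows)


def _select(curve: pd.DataFrame, target_sr: float, parameter: str
            ) -> CalibrationResult:
    if not 0.0 <= target_sr <= 1.0:
        raise ValueError("target_sr must lie in [0, 1]")
    idx = int((curve["sr"] - target_sr).abs().idxmin())
    sr_lo, sr_hi = float(curve["sr"].min()), float(curve["sr"].max())
    achievable = sr_lo - 0.05 <= target_sr <= sr_hi + 0.05
    return CalibrationResult(
        parameter=parameter, best=float(curve["value"].iloc[idx]),
        target_sr=target_sr, achieved_sr=float(curve["sr"].iloc[idx]),
        curve=curve, target_achievable=achievable, sr_range=(sr_lo, sr_hi))


def calibrate_weight(table: PopulationRateTable, target_sr: float = 0.70,
                     levels=None, trials_per_condition: int = 300,
                     step: float = 0.02, seed: int = 0) -> CalibrationResult:
    """Grid search of the gated model's weight (0 to 1 in steps of ``step``).

    Returns the weight whose simulated SR is closest to the target together
    with the full SR-vs-weight curve.
    """
    ws = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
    n_bins = bin_index(TAU1) - bin_index(TAU0)
    irr = np.broadcast_to(ws, (n_bins, ws.size))
    curve = _sr_curve(table, ws, irr, levels, trials_per_condition, seed)
    res = _select(curve, target_sr, "w")
    if not res.target_achievable:
        raise ValueError(
            f"target SR {target_sr} outside achievable range {res.sr_range}")
    return res


def calibrate_time_constant(table: PopulationRateTable,
                            target_sr: float = 0.70, levels=None,
                            trials_per_condition: int = 300,
                            tau_grid: np.ndarray | None = None,
                            seed: int = 0) -> CalibrationResult:
    """Line search of the time-varying gate's time constant (ms).

    The gate is w(tau) = exp((tau - tau1) / T); the search covers
    ``tau_grid`` (default 10 to 500 ms in 10-ms steps).
    """
    taus = np.arange(10.0, 501.0, 10.0) if tau_grid is None else \
        np.asarray(tau_grid, dtype=float)
    t = np.arange(TAU0, TAU1, DT)
    irr = np.exp((t[:, None] - TAU1) / taus[None, :])
    curve = _sr_curve(table, taus, irr, levels, trials_per_condition, seed)
    res = _select(curve, target_sr, "tau_ms")
    if not res.target_achievable:
        raise ValueError(
            f"target SR {target_sr} outside achievable range {res.sr_range}")
    return res
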