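"""Eight-neuron MT bank and instantaneous differential direction/depth signals.

The decision models read the synthetic population through a fixed bank of
eight simulated neurons, two per preference quadrant.  Congruent neurons
(preferring up/far or down/near, i.e. the same saccade in both tasks) feed
both the direction and the depth readout; each incongruent neuron feeds
exactly one of them:

====== ========== =========== ========== ============
neuron pref. dir  pref. depth congruent  contributes
====== ========== =========== ========== ============
1      up         far         yes        both
2      up         far         yes        both
3      down       far         no         depth
4      down       far         no         direction
5      up         near        no         depth
6      up         near        no         direction
7      down       near        yes        both
8      down       near        yes        both
====== ========== =========== ========== ============

The instantaneous differential signals are the difference in firing between
the two opposing groups of (two congruent + one incongruent) neurons, with
congruent responses halved so each group weighs congruent and incongruent
evidence equally:

    i_dir = [(s1+s2)/2 + s6] - [(s7+s8)/2 + s4]
    i_dep = [(s1+s2)/2 + s3] - [(s7+s8)/2 + s5]
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic_mt import PopulationRateTable


@dataclass(frozen=True)
class BankNeuron:
    index: int  # 1..8
    pref_dir: str
    pref_depth: str
    congruent: bool
    contributes: str  # {"both", "direction", "depth"}


#: the fixed eight-neuron bank (see module docstring)
BANK: tuple[BankNeuron, ...] = (
    BankNeuron(1, "up", "far", True, "both"),
    BankNeuron(2, "up", "far", True, "both"),
    BankNeuron(3, "down", "far", False, "depth"),
    BankNeuron(4, "down", "far", False, "direction"),
    BankNeuron(5, "up", "near", False, "depth"),
    BankNeuron(6, "up", "near", False, "direction"),
    BankNeuron(7, "down", "near", True, "both"),
    BankNeuron(8, "down", "near", True, "both"),
)

# signal weights per neuron (1..8), halving congruent contributions
DIR_COEF = np.array([0.5, 0.5, 0.0, -1.0, 0.0, 1.0, -0.5, -0.5])
DEP_COEF = np.array([0.5, 0.5, 1.0, 0.0, -1.0, 0.0, -0.5, -0.5])


def preferred_choice(neuron: BankNeuron, task: str) -> str:
    """Saccade choice associated with the neuron's preferred stimulus."""
    if task == "direction":
        return "up" if neuron.pref_dir == "up" else "down"
    if task == "depth":
        return "up" if neuron.pref_depth == "far" else "down"
    raise ValueError(f"unknown task {task!r}")


def signed_strengths(neuron: BankNeuron, c_dir: float, c_dep: float
                     ) -> tuple[float, float]:
    """Lab-frame stimulus strengths re-signed into the neuron's preferred frame.

    Positive lab-frame values mean upward motion / far depth, so an
    up-preferring neuron keeps ``c_dir`` and a down-preferring one flips it
    (likewise far/near for ``c_dep``).
    """
    sd = c_dir if neuron.pref_dir == "up" else -c_dir
    sp = c_dep if neuron.pref_depth == "far" else -c_dep
    return sd, sp


def bank_rates(table: PopulationRateTable, c_dir: float, c_dep: float,
               task: str) -> np.ndarray:
    """Rate series (8, n_bins) of the bank for one lab-frame stimulus.

    Each neuron's series is the table row at its preferred-frame strengths;
    strengths absent from the table grid raise a lookup error (no
    interpolation).
    """
    return np.stack([
        table.lookup(*signed_strengths(n, c_dir, c_dep), task) for n in BANK
    ])


def differential_signals(spikes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous differential signals (i_dir, i_dep) in spikes/ms.

    ``spikes`` stacks the eight aligned trains along axis -2 (shape
    ``(..., 8, n_bins)``); the returned series live on the same time grid and
    are bounded in [-2, 2] spikes/ms.
    """
    spikes = np.asarray(spikes, dtype=float)
    if spikes.shape[-2] != 8:
        raise ValueError("expected eight aligned spike trains on axis -2")
    i_dir = np.tensordot(DIR_COEF, np.moveaxis(spikes, -2, 0), axes=1)
    i_dep = np.tensordot(DEP_COEF, np.moveaxis(spikes, -2, 0), axes=1)
    return i_dir, i_dep
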