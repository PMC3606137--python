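"""Shared trial time base.

All times are in milliseconds relative to stimulus onset.  Every spike
train, rate series and differential signal in the package lives on the
same 1-ms grid spanning [-100, 700) ms; bin ``j`` covers
``[T_START + j, T_START + j + 1)``.
"""

import numpy as np

DT = 1.0  # ms; the simulation step everywhere

T_START = -100  # ms, first bin edge of the trial window
T_END = 700  # ms, one past the last bin edge

STIM_ON = 0  # ms, stimulus onset
STIM_OFF = 500  # ms, stimulus offset (500 ms presentation)

#: integration window: starts 100 ms after onset (MT response latency),
#: ends 100 ms after offset; 500 ms of integration.
TAU0 = 100
TAU1 = 600

N_BINS = int((T_END - T_START) / DT)


def time_grid() -> np.ndarray:
    """Left edges of the 1-ms bins of the trial window."""
    return np.arange(T_START, T_END, DT)


def bin_index(t_ms: float) -> int:
    """Index of the bin whose left edge is ``t_ms``."""
    idx = int(round((t_ms - T_START) / DT))
    if not 0 <= idx <= N_BINS:
        raise ValueError(f"time {t_ms} ms outside the trial window")
    return idx


def window_slice(tau0: float = TAU0, tau1: float = TAU1) -> slice:
    """Slice of the trial grid covering the integration window [tau0, tau1)."""
    return slice(bin_index(tau0), bin_index(tau1))
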