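"""Choice probability: z-scoring, ROC area, pooled time courses, bootstrap.

Choice probability (CP) is the ROC area separating a neuron's response
distributions on trials ending in its preferred vs its null choice: 0.5 when
responses and choices do not covary, 1 under complete covariation.  Time
courses use eight 100-ms bins starting -100, 0, ..., 600 ms after stimulus
onset.  Responses are z-scored within each stimulus condition (so stimulus
tuning cannot masquerade as choice covariation), pooled across neurons and
conditions within a group, and split by choice; conditions in which the
up-choice fraction is below 1/4 or above 3/4 are excluded before pooling
(boundary values retained).  Confidence intervals are percentile bootstrap
over independent resampling with replacement from the two pooled z-scored
distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .readout import BANK, preferred_choice

logger = logging.getLogger(__name__)

CONDITION_KEYS = ["neuron", "task", "c_dir", "c_dep", "bin_start"]


def zscore_by_condition(counts: pd.DataFrame, value: str = "count",
                        keys: list[str] | None = None) -> pd.DataFrame:
    """Standardize spike counts within each (neuron, condition, task, bin) cell.

    Uses the n-1 SD convention.  Cells with fewer than two trials or zero
    variance get NaN z-scores (logged and excluded downstream).
    """
    keys = CONDITION_KEYS if keys is None else keys
    out = counts.copy()
    grp = out.groupby(keys)[value]
    mean = grp.transform("mean")
    sd = grp.transform("std")  # ddof=1
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (out[value] - mean) / sd
    z = z.where(sd > 0)
    n_bad = int(z.isna().sum())
    if n_bad:
        logger.info("zscore_by_condition: %d values in degenerate cells "
                    "(constant or singleton) set to NaN", n_bad)
    out["z"] = z
    return out


def roc_area(pref, null) -> float:
    """ROC area = P(X_pref > X_null) + 0.5 P(X_pref = X_null).

    Computed through the Mann-Whitney rank identity (midranks give ties the
    half-weight convention, equal to the trapezoidal ROC area).
    """
    pref = np.asarray(pref, dtype=float)
    null = np.asarray(null, dtype=float)
    if pref.size == 0 or null.size == 0:
        raise ValueError("both response sets must be non-empty")
    ranks = rankdata(np.concatenate([pref, null]))
    u = ranks[:pref.size].sum() - pref.size * (pref.size + 1) / 2.0
    return float(u / (pref.size * null.size))


def _bootstrap_ci(pref: np.ndarray, null: np.ndarray, n_boot: int,
                  rng: np.random.Generator, chunk: int = 200
                  ) -> tuple[float, float, np.ndarray]:
    """Percentile CI (2.5/97.5) of the ROC area under independent resampling."""
    n1, n2 = pref.size, null.size
    aucs = np.empty(n_boot)
    done = 0
    while done < n_boot:
        m = min(chunk, n_boot - done)
        bp = pref[rng.integers(0, n1, (m, n1))]
        bn = null[rng.integers(0, n2, (m, n2))]
        ranks = rankdata(np.concatenate([bp, bn], axis=1), axis=1)
        u = ranks[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2.0
        aucs[done:done + m] = u / (n1 * n2)
        done += m
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(lo), float(hi), aucs


@dataclass
class CPResult:
    group: str  # {"congruent", "incongruent"}
    task_relation: str  # {"direction", "depth", "relevant", "irrelevant"}
    bin_start: float  # ms
    cp: float | None
    ci_low: float | None
    ci_high: float | None
    n_pref: int
    n_null: int
    note: str = ""


def _group_relation(neuron, task: str) -> tuple[str, str]:
    if neuron.congruent:
        return "congruent", task
    return ("incongruent",
            "relevant" if neuron.contributes == task else "irrelevant")


def cp_timecourse(counts: pd.DataFrame, n_boot: int = 10000,
                  seed: int = 0) -> pd.DataFrame:
    """CP time course pooled over neurons and conditions, by group.

    ``counts`` holds per-trial 100-ms-bin spike counts of the eight-neuron
    bank with columns (task, c_dir, c_dep, trial, neuron, bin_start, count,
    choice).  Congruent neurons are pooled per task; incongruent neurons per
    relevant/irrelevant relation (a neuron is relevant in the task it
    contributes to).  Returns one row per (group, task_relation, bin_start);
    groups with no surviving data carry a null CP and a reason note.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)

    # per-(task, condition) up-choice fraction over unique trials
    trial_choice = counts.drop_duplicates(
        subset=["task", "c_dir", "c_dep", "trial"])
    frac = trial_choice.groupby(["task", "c_dir", "c_dep"])["choice"].agg(
        lambda c: (c == "up").mean())
    keep = frac[(frac >= 0.25) & (frac <= 0.75)].index
    n_dropped = len(frac) - len(keep)
    if n_dropped:
        logger.info("cp_timecourse: excluded %d lopsided conditions", n_dropped)
    kept = counts.set_index(["task", "c_dir", "c_dep"]).loc[keep].reset_index()

    z = zscore_by_condition(kept).dropna(subset=["z"])
    bank = {n.index: n for n in BANK}
    z["is_pref"] = [
        choice == preferred_choice(bank[nrn], task)
        for choice, nrn, task in zip(z["choice"], z["neuron"], z["task"])
    ]
    gr = [(_group_relation(bank[nrn], task))
          for nrn, task in zip(z["neuron"], z["task"])]
    z["group"] = [g for g, _ in gr]
    z["task_relation"] = [r for _, r in gr]

    rows = []
    relations = [("congruent", "direction"), ("congruent", "depth"),
                 ("incongruent", "relevant"), ("incongruent", "irrelevant")]
    for (group, relation) in relations:
        sub = z[(z["group"] == group) & (z["task_relation"] == relation)]
        for bin_start in np.sort(counts["bin_start"].unique()):
            cell = sub[sub["bin_start"] == bin_start]
            pref = cell.loc[cell["is_pref"], "z"].to_numpy()
            null = cell.loc[~cell["is_pref"], "z"].to_numpy()
            if pref.size == 0 or null.size == 0:
                rows.append(CPResult(group, relation, bin_start, None, None,
                                     None, pref.size, null.size,
                                     note="no surviving data"))
                continue
            cp = roc_area(pref, null)
            lo, hi, _ = _bootstrap_ci(pref, null, n_boot, rng)
            rows.append(CPResult(group, relation, bin_start, cp, lo, hi,
                                 pref.size, null.size))
    return pd.DataFrame([r.__dict__ for r in rows])
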