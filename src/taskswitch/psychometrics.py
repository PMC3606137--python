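"""Behavioral analysis: logistic fits, wrong-task mixture, switch ratio,
psychometric and neurometric thresholds, balanced-neuron selection.

Choices in each task are modeled with a four-parameter logistic,

    p_up = logistic(b0 + b1*C_dir + b2*C_dep + b3*C_dir*C_dep),

fitted per task (the "eight-parameter model" across the two tasks).  A
nine-parameter mixture adds a single wrong-task probability p_err shared by
both tasks: with probability p_err the choice follows the *other* task's
logistic applied to the same stimulus.  The switch ratio contrasts each
feature's sensitivity when relevant vs irrelevant,

    SR = 1/2 [ (b1^dir - b1^dep) / (b1^dir + b1^dep)
             + (b2^dep - b2^dir) / (b2^dep + b2^dir) ],

which is 1 for perfect switching (irrelevant sensitivities exactly zero) and
0 when the two tasks are indistinguishable.  Accuracy-based thresholds use a
cumulative Weibull, p_correct = 1 - 0.5 exp(-(c/alpha)^beta), evaluated at
the 75%-correct criterion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import expit

from .choice_probability import roc_area
from .synthetic_mt import NeuronSpec, neuron_level_counts

logger = logging.getLogger(__name__)

TASKS = ("direction", "depth")


# ---------------------------------------------------------------------------
# logistic (4 parameters per task) and mixture (9 parameters) fits
# ---------------------------------------------------------------------------

@dataclass
class LogisticFit:
    task: str
    beta: np.ndarray  # (b0, b1, b2, b3)
    bse: np.ndarray
    cov: np.ndarray
    llf: float  # Bernoulli log-likelihood (no binomial-coefficient terms)
    converged: bool
    separation: bool  # perfect/quasi separation was flagged during fitting

    @property
    def aic(self) -> float:
        return 2 * 4 - 2 * self.llf


@dataclass
class MixtureFit:
    beta_dir: np.ndarray  # direction-task (b0..b3)
    beta_dep: np.ndarray  # depth-task (b0..b3)
    p_err: float
    llf: float
    converged: bool

    @property
    def aic(self) -> float:
        return 2 * 9 - 2 * self.llf


@dataclass
class SwitchRatio:
    value: float
    component_dir: float  # (b1^dir - b1^dep) / (b1^dir + b1^dep)
    component_dep: float  # (b2^dep - b2^dir) / (b2^dep + b2^dir)
    se: float | None = None  # delta-method standard error


def _aggregate(trials: pd.DataFrame) -> pd.DataFrame:
    """Collapse trials to per-condition (n_up, n) counts."""
    g = trials.groupby(["c_dir", "c_dep"], as_index=False).agg(
        n_up=("choice", lambda c: int((c == "up").sum())),
        n=("choice", "size"))
    return g


def _design(c_dir: np.ndarray, c_dep: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(c_dir), c_dir, c_dep, c_dir * c_dep])


def _bernoulli_llf(beta, X, n_up, n) -> float:
    p = np.clip(expit(X @ beta), 1e-12, 1 - 1e-12)
    return float(n_up @ np.log(p) + (n - n_up) @ np.log1p(-p))


def fit_logistic_task(trials: pd.DataFrame) -> LogisticFit:
    """Maximum-likelihood logistic fit of one task's choices.

    Requires at least two distinct conditions and both choices observed.
    Perfect separation does not abort the fit: the estimates are returned
    with ``separation=True`` and a logged warning.
    """
    tasks = trials["task"].unique()
    if len(tasks) != 1:
        raise ValueError("fit_logistic_task expects trials of a single task")
    agg = _aggregate(trials)
    if len(agg) < 2:
        raise ValueError("need >= 2 distinct stimulus conditions")
    if agg["n_up"].sum() == 0 or (agg["n"] - agg["n_up"]).sum() == 0:
        raise ValueError("both choices must be observed")
    X = _design(agg["c_dir"].to_numpy(float), agg["c_dep"].to_numpy(float))
    y = np.column_stack([agg["n_up"], agg["n"] - agg["n_up"]])

    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
    for w in caught:
        if "separat" in str(w.message).lower():
            separation = True
    if separation:
        logger.warning("possible separation in logistic fit for task %s; "
                       "estimates reported as-is", tasks[0])
    beta = np.asarray(res.params, dtype=float)
    llf = _bernoulli_llf(beta, X, agg["n_up"].to_numpy(float),
                         agg["n"].to_numpy(float))
    return LogisticFit(task=str(tasks[0]), beta=beta,
                       bse=np.asarray(res.bse, float),
                       cov=np.asarray(res.cov_params(), float),
                       llf=llf, converged=bool(res.converged),
                       separation=separation)


def fit_both_tasks(trials: pd.DataFrame) -> dict[str, LogisticFit]:
    """Per-task logistic fits (the eight-parameter model)."""
    return {task: fit_logistic_task(trials[trials["task"] == task])
            for task in TASKS}


def _mixture_negll(theta, Xd, ud, nd, Xp, up_, np_) -> float:
    bd, bp, pe = theta[:4], theta[4:8], theta[8]
    p_dir = (1 - pe) * expit(Xd @ bd) + pe * expit(Xd @ bp)
    p_dep = (1 - pe) * expit(Xp @ bp) + pe * expit(Xp @ bd)
    ll = 0.0
    for p, u, n in ((p_dir, ud, nd), (p_dep, up_, np_)):
        p = np.clip(p, 1e-12, 1 - 1e-12)
        ll += u @ np.log(p) + (n - u) @ np.log1p(-p)
    return -float(ll)


def fit_mixture(trials: pd.DataFrame, n_restarts: int = 5,
                seed: int = 0) -> MixtureFit:
    """Joint nine-parameter wrong-task mixture fit over both tasks.

    One shared p_err in [0, 1]; on a wrong-task trial the choice follows the
    other task's logistic evaluated at the same stimulus.  Bounded L-BFGS-B
    with ``n_restarts`` random restarts; the eight-parameter solution with
    p_err = 0 is always among the starting points, so the mixture
    log-likelihood can never fall below the eight-parameter one.
    """
    if set(trials["task"].unique()) != set(TASKS):
        raise ValueError("fit_mixture requires trials from both tasks")
    base = fit_both_tasks(trials)
    agg = {task: _aggregate(trials[trials["task"] == task]) for task in TASKS}
    args = []
    for task in TASKS:
        a = agg[task]
        args += [_design(a["c_dir"].to_numpy(float), a["c_dep"].to_numpy(float)),
                 a["n_up"].to_numpy(float), a["n"].to_numpy(float)]
    args = tuple(args)

    theta0 = np.concatenate([base["direction"].beta, base["depth"].beta, [0.0]])
    rng = np.random.default_rng(seed)
    starts = [theta0]
    for _ in range(max(n_restarts - 1, 0)):
        starts.append(np.concatenate([
            theta0[:8] * rng.normal(1.0, 0.2, 8), [rng.uniform(0.0, 0.3)]]))

    bounds = [(-60.0, 60.0)] * 8 + [(0.0, 1.0)]
    best_theta, best_f, converged = theta0, _mixture_negll(theta0, *args), False
    for s in starts:
        res = minimize(_mixture_negll, s, args=args, method="L-BFGS-B",
                       bounds=bounds, options={"maxiter": 500, "ftol": 1e-10})
        if res.fun < best_f:
            best_theta, best_f, converged = res.x, float(res.fun), bool(res.success)
        elif res.success:
            converged = True
    if not converged:
        logger.warning("mixture fit did not report convergence; "
                       "returning best of %d starts", len(starts))
    return MixtureFit(beta_dir=best_theta[:4], beta_dep=best_theta[4:8],
                      p_err=float(best_theta[8]), llf=-best_f,
                      converged=converged)


def compare_models(trials: pd.DataFrame, n_restarts: int = 5,
                   seed: int = 0) -> dict:
    """Fit the 8- and 9-parameter models side by side and report both AICs."""
    fits = fit_both_tasks(trials)
    llf8 = fits["direction"].llf + fits["depth"].llf
    mix = fit_mixture(trials, n_restarts=n_restarts, seed=seed)
    return {
        "logistic": fits,
        "mixture": mix,
        "llf_8param": llf8,
        "aic_8param": 2 * 8 - 2 * llf8,
        "llf_9param": mix.llf,
        "aic_9param": mix.aic,
    }


# ---------------------------------------------------------------------------
# switch ratio
# ---------------------------------------------------------------------------

def switch_ratio(dir_task_fit: LogisticFit,
                 dep_task_fit: LogisticFit) -> SwitchRatio:
    """Average switch ratio from the two tasks' fitted sensitivities.

    Per feature, the normalized difference of its sensitivity when relevant
    vs irrelevant; SR is the mean over the two features.  Raises on a zero
    denominator (sensitivities exactly cancelling).
    """
    b1_dir, b2_dir = dir_task_fit.beta[1], dir_task_fit.beta[2]
    b1_dep, b2_dep = dep_task_fit.beta[1], dep_task_fit.beta[2]
    den1 = b1_dir + b1_dep
    den2 = b2_dep + b2_dir
    if den1 == 0 or den2 == 0:
        raise ZeroDivisionError("switch ratio undefined: zero sensitivity sum")
    comp_dir = (b1_dir - b1_dep) / den1
    comp_dep = (b2_dep - b2_dir) / den2
    # delta method over the four sensitivities (fits are independent)
    g = np.array([  # d SR / d (b1_dir, b2_dir, b1_dep, b2_dep)
        0.5 * 2 * b1_dep / den1 ** 2,
        0.5 * -2 * b2_dep / den2 ** 2,
        0.5 * -2 * b1_dir / den1 ** 2,
        0.5 * 2 * b2_dir / den2 ** 2,
    ])
    cov = np.zeros((4, 4))
    cov[:2, :2] = dir_task_fit.cov[1:3, 1:3]
    cov[2:, 2:] = dep_task_fit.cov[1:3, 1:3]
    se = float(np.sqrt(g @ cov @ g))
    return SwitchRatio(value=0.5 * (comp_dir + comp_dep),
                       component_dir=comp_dir, component_dep=comp_dep, se=se)


# ---------------------------------------------------------------------------
# percent correct and 75% thresholds
# ---------------------------------------------------------------------------

def _correct_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Trials with nonzero relevant strength, with a 'correct' column.

    Correctness compares the choice with the sign of the task-relevant
    strength; trials at zero relevant strength have no defined correct answer
    and are excluded.
    """
    task = trials["task"].unique()
    if len(task) != 1:
        raise ValueError("expected trials of a single task")
    rel = "c_dir" if task[0] == "direction" else "c_dep"
    t = trials[trials[rel] != 0].copy()
    t["level"] = t[rel].abs()
    t["correct"] = (t["choice"] == "up") == (t[rel] > 0)
    return t


def percent_correct(trials: pd.DataFrame) -> tuple[float, float, int]:
    """Fraction correct (with binomial SE and n), zero-relevant excluded."""
    t = _correct_trials(trials)
    n = len(t)
    pc = float(t["correct"].mean())
    return pc, float(np.sqrt(pc * (1 - pc) / n)), n


@dataclass
class ThresholdResult:
    threshold: float | None  # strength fraction at 75% correct
    flag: str  # {"ok", "below_min", "above_max"}
    alpha: float | None = None  # Weibull scale
    beta: float | None = None  # Weibull shape
    levels: np.ndarray | None = None
    pc_by_level: np.ndarray | None = None
    se: float | None = None  # parametric-bootstrap SE, when requested


def _weibull_p(c, alpha, beta):
    return 1.0 - 0.5 * np.exp(-np.power(c / alpha, beta))


def _fit_weibull_ml(levels: np.ndarray, n_correct: np.ndarray,
                    n_total: np.ndarray) -> tuple[float, float]:
    """ML cumulative-Weibull fit on binomial accuracy data (multi-start)."""

    def negll(x):
        alpha, beta = np.exp(x)
        p = np.clip(_weibull_p(levels, alpha, beta), 0.5, 1 - 1e-12)
        return -float(n_correct @ np.log(p)
                      + (n_total - n_correct) @ np.log1p(-p))

    best = None
    for a0 in (levels.min(), np.median(levels), levels.max(), 2 * levels.max()):
        for b0 in (1.0, 2.0):
            res = minimize(negll, np.log([a0, b0]), method="Nelder-Mead",
                           options={"xatol": 1e-8, "fatol": 1e-10,
                                    "maxiter": 2000})
            if best is None or res.fun < best.fun:
                best = res
    alpha, beta = np.exp(best.x)
    return float(alpha), float(beta)


def threshold_75(trials: pd.DataFrame, n_boot: int = 0,
                 seed: int = 0) -> ThresholdResult:
    """75%-correct threshold of one task from a cumulative-Weibull fit.

    Accuracy is pooled over irrelevant-strength levels at each absolute
    relevant strength (>= 3 nonzero levels required).  If accuracy never
    reaches 75% the threshold is reported as an ``above_max`` flag; a fitted
    threshold below the smallest tested level is returned with ``below_min``.
    Optionally attaches a parametric-bootstrap SE (``n_boot`` resamples) as
    attribute ``se``.
    """
    t = _correct_trials(trials)
    g = t.groupby("level", as_index=False).agg(
        n_correct=("correct", "sum"), n=("correct", "size"))
    if len(g) < 3:
        raise ValueError("need >= 3 nonzero relevant-strength levels")
    levels = g["level"].to_numpy(float)
    n_correct = g["n_correct"].to_numpy(float)
    n_total = g["n"].to_numpy(float)
    pc = n_correct / n_total

    if pc.max() < 0.75:
        return ThresholdResult(threshold=None, flag="above_max",
                               levels=levels, pc_by_level=pc)
    alpha, beta = _fit_weibull_ml(levels, n_correct, n_total)
    thr = float(alpha * np.log(2.0) ** (1.0 / beta))
    flag = "ok"
    if thr < levels.min():
        flag = "below_min"
    elif thr > levels.max():
        flag = "above_max"
    result = ThresholdResult(threshold=thr, flag=flag, alpha=alpha, beta=beta,
                             levels=levels, pc_by_level=pc)
    if n_boot:
        rng = np.random.default_rng(seed)
        boots = []
        for _ in range(n_boot):
            k = rng.binomial(n_total.astype(int), np.clip(pc, 0, 1))
            if (k / n_total).max() < 0.75:
                continue
            a, b = _fit_weibull_ml(levels, k.astype(float), n_total)
            boots.append(a * np.log(2.0) ** (1.0 / b))
        result.se = float(np.std(boots, ddof=1)) if len(boots) > 1 else np.inf
    return result


# ---------------------------------------------------------------------------
# neurometric thresholds and balanced selection
# ---------------------------------------------------------------------------

@dataclass
class NeurometricResult:
    neuron_id: int
    feature: str
    threshold: float | None
    flag: str  # {"ok", "excluded"}
    levels: np.ndarray | None = None
    auc_by_level: np.ndarray | None = None


def neurometric_threshold(counts: pd.DataFrame, neuron_id: int = -1,
                          feature: str = "") -> NeurometricResult:
    """Ideal-observer threshold of one neuron for one feature.

    ``counts`` holds per-trial spike counts with a ``signed_level`` column
    (positive = preferred).  At each absolute level the ROC area between the
    preferred-sign and null-sign count distributions gives the neurometric
    accuracy; a cumulative Weibull through those points is read out at 75%.
    Degenerate response distributions (accuracy pinned at chance) yield an
    excluded result with a log entry.
    """
    levels = np.unique(np.abs(counts["signed_level"]))
    levels = levels[levels > 0]
    if levels.size < 3:
        raise ValueError("need >= 3 nonzero levels per feature")
    aucs = []
    for lev in levels:
        pref = counts.loc[counts["signed_level"] == lev, "count"].to_numpy()
        null = counts.loc[counts["signed_level"] == -lev, "count"].to_numpy()
        aucs.append(roc_area(pref, null))
    aucs = np.asarray(aucs)
    if np.ptp(aucs) < 1e-12 or aucs.max() <= 0.5:
        logger.info("neuron %s feature %s: degenerate responses, excluded",
                    neuron_id, feature)
        return NeurometricResult(neuron_id, feature, None, "excluded",
                                 levels, aucs)
    # pseudo-count ML fit of the Weibull through the ROC accuracies
    n_pseudo = np.full(levels.size, 100.0)
    try:
        alpha, beta = _fit_weibull_ml(levels, np.clip(aucs, 0.5, 1) * n_pseudo,
                                      n_pseudo)
        thr = float(alpha * np.log(2.0) ** (1.0 / beta))
    except Exception:  # pragma: no cover - fit pathologies
        logger.info("neuron %s feature %s: Weibull fit failed, excluded",
                    neuron_id, feature)
        return NeurometricResult(neuron_id, feature, None, "excluded",
                                 levels, aucs)
    if not np.isfinite(thr):
        return NeurometricResult(neuron_id, feature, None, "excluded",
                                 levels, aucs)
    return NeurometricResult(neuron_id, feature, thr, "ok", levels, aucs)


def population_neurometrics(population: list[NeuronSpec], levels: np.ndarray,
                            n_trials: int = 100, seed: int = 0) -> pd.DataFrame:
    """Direction and depth neurometric thresholds for every neuron.

    Returns a DataFrame (neuron_id, thr_dir, thr_dep, ratio) with excluded
    neurons dropped.
    """
    ss = np.random.SeedSequence(seed)
    seeds = ss.spawn(len(population))
    recs = []
    for spec, s in zip(population, seeds):
        rngs = s.spawn(2)
        out = {}
        for feature, child in zip(("dir", "depth"), rngs):
            counts = neuron_level_counts(
                spec, feature, levels, n_trials,
                np.random.default_rng(child).integers(2 ** 31))
            res = neurometric_threshold(counts, spec.id, feature)
            out[feature] = res.threshold
        if out["dir"] is None or out["depth"] is None:
            continue
        recs.append({"neuron_id": spec.id, "thr_dir": out["dir"],
                     "thr_dep": out["depth"],
                     "ratio": out["dir"] / out["depth"]})
    return pd.DataFrame(recs)


def select_balanced(neurometrics: pd.DataFrame, k: int = 40) -> list[int]:
    """Pick k neurons with direction and depth sensitivity equal on average.

    Neurons are sorted by their direction/depth threshold ratio; among the
    contiguous runs of k, the one whose *average* direction and depth
    thresholds are closest to equal (ratio of window means nearest 1 on a
    log scale) is returned.
    """
    if len(neurometrics) < k:
        raise ValueError(f"need >= {k} neurons with defined thresholds")
    s = neurometrics.sort_values("ratio").reset_index(drop=True)
    kern = np.ones(k) / k
    mean_dir = np.convolve(s["thr_dir"].to_numpy(), kern, mode="valid")
    mean_dep = np.convolve(s["thr_dep"].to_numpy(), kern, mode="valid")
    start = int(np.argmin(np.abs(np.log(mean_dir / mean_dep))))
    return s["neuron_id"].iloc[start:start + k].tolist()


# ---------------------------------------------------------------------------
# synthetic behavioral datasets (for parameter-recovery studies)
# ---------------------------------------------------------------------------

def simulate_choices(beta_dir: np.ndarray, beta_dep: np.ndarray,
                     p_err: float, levels: np.ndarray,
                     trials_per_condition: int, seed: int = 0) -> pd.DataFrame:
    """Draw choices from the nine-parameter mixture observer on a full grid."""
    rng = np.random.default_rng(seed)
    levels = np.asarray(levels, dtype=float)
    recs = []
    for task in TASKS:
        own, other = ((beta_dir, beta_dep) if task == "direction"
                      else (beta_dep, beta_dir))
        for cd in levels:
            for cp in levels:
                x = np.array([1.0, cd, cp, cd * cp])
                p = (1 - p_err) * expit(x @ own) + p_err * expit(x @ other)
                ups = rng.random(trials_per_condition) < p
                recs.append(pd.DataFrame({
                    "task": task, "c_dir": cd, "c_dep": cp,
                    "trial": np.arange(trials_per_condition),
                    "choice": np.where(ups, "up", "down"),
                }))
    return pd.concat(recs, ignore_index=True)
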