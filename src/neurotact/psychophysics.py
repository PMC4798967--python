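"""Three-alternative forced-choice texture discrimination.

A session presents 16 trials: the four paired surfaces (D0.0, D1.0,
D2.0, D2.5) four times each, twice in '+' order and twice in '-',
randomly interleaved.  After each pair the subject answers whether the
first half felt coarser, finer, or the same as the second.

An ideal-observer decoder stands in for the subject: it reads the signed
inter-burst-interval difference between the two halves, adds Gaussian
decision noise, and answers "same" when the noisy difference falls
within +/- tau.  Behavioral statistics: confusion matrices, exact
Clopper-Pearson binomial intervals against the 1/3 chance level, and
logistic psychometric fits of the fraction perceived different.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .spike_coding import PairFeatures
from .synthetic_touch import PAIR_SP_MAP, StimulusPair, make_stimulus_pair

__all__ = [
    "SessionPlan",
    "TrialRecord",
    "ConfusionMatrix",
    "LogisticFit",
    "RESPONSES",
    "CHANCE_LEVEL",
    "build_session",
    "correct_response",
    "ideal_observer",
    "score",
    "clopper_pearson",
    "logistic_fit",
    "fraction_different_by_dsp",
]

RESPONSES = ("first_coarser", "second_coarser", "same")
CHANCE_LEVEL = 1.0 / 3.0
SESSION_SIZE = 16
DEFAULT_TAU_MS = 50.0


@dataclass
class SessionPlan:
    trials: list[StimulusPair]

    @property
    def session_size(self) -> int:
        return len(self.trials)


@dataclass
class TrialRecord:
    pair: StimulusPair
    response: str
    correct: bool
    features: PairFeatures | None = None


@dataclass
class ConfusionMatrix:
    """Stimulus x response count table (rows: stimulus label+order)."""

    counts: pd.DataFrame

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=1)


@dataclass
class LogisticFit:
    intercept: float
    slope: float
    r_squared: float
    pearson_p: float
    fitted: np.ndarray
    converged: bool
    message: str = ""
    conf_int: np.ndarray | None = None  # (2, 2): rows intercept/slope, 95%


def build_session(seed: int) -> SessionPlan:
    """Random session plan: 4 presentations of each surface, 2 per order,
    uniformly permuted; reproducible from ``seed``."""
    rng = np.random.default_rng(seed)
    trials = [
        make_stimulus_pair(label, order)
        for label in sorted(PAIR_SP_MAP)
        for order in ("+", "-")
        for _ in range(2)
    ]
    order = rng.permutation(len(trials))
    return SessionPlan(trials=[trials[i] for i in order])


def correct_response(pair: StimulusPair) -> str:
    """The response matching the sign of first_sp - second_sp."""
    if pair.first_sp > pair.second_sp:
        return "first_coarser"
    if pair.first_sp < pair.second_sp:
        return "second_coarser"
    return "same"


def ideal_observer(
    features: PairFeatures,
    tau: float = DEFAULT_TAU_MS,
    decision_noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> str:
    """Decide from the signed delta-IBI (ms): noisy difference within
    +/- tau reads "same", otherwise the half with the larger IBI is
    called coarser.  An undefined delta-IBI forces a uniform guess."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if not features.defined or not np.isfinite(features.delta_ibi):
        return str(rng.choice(RESPONSES))
    noisy = features.delta_ibi + decision_noise_sd * rng.standard_normal()
    if abs(noisy) < tau:
        return "same"
    return "first_coarser" if noisy > 0 else "second_coarser"


def score(trials: Sequence[TrialRecord]) -> tuple[ConfusionMatrix, float]:
    """Tabulate responses by stimulus and return the proportion correct."""
    if not trials:
        raise ValueError("no trials to score")
    rows = sorted({f"{t.pair.label}{t.pair.order}" for t in trials})
    counts = pd.DataFrame(0, index=rows, columns=list(RESPONSES), dtype=int)
    n_correct = 0
    for t in trials:
        counts.loc[f"{t.pair.label}{t.pair.order}", t.response] += 1
        n_correct += bool(t.correct)
    return ConfusionMatrix(counts=counts), n_correct / len(trials)


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial confidence interval via beta quantiles.

    Lower bound 0 at k = 0 and upper bound 1 at k = n.
    """
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"require 0 <= k <= n with n >= 1, got k={k}, n={n}")
    lower = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lower, upper


def logistic_fit(
    delta: Sequence[float],
    fraction_different: Sequence[float],
    trials_per_point: int | Sequence[int],
) -> LogisticFit:
    """Binomial GLM with logit link of the fraction perceived different on
    |delta| (one covariate plus intercept).

    R^2 is the squared Pearson correlation between observed and fitted
    fractions.  Perfect separation yields a capped-coefficient result
    flagged as unconverged rather than an exception.
    """
    x = np.abs(np.asarray(delta, dtype=float))
    frac = np.asarray(fraction_different, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.any((frac < 0) | (frac > 1)):
        raise ValueError("fractions must lie in [0, 1]")
    n = np.broadcast_to(np.asarray(trials_per_point, dtype=float), x.shape)
    successes = frac * n
    X = sm.add_constant(x)
    endog = np.column_stack([successes, n - successes])
    converged = True
    message = ""
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(endog, X, family=sm.families.Binomial())
            res = model.fit(maxiter=100)
        params = res.params
        converged = bool(res.converged) and bool(np.all(np.abs(params) < 1e3))
        fitted = res.predict(X)
        conf = np.asarray(res.conf_int())
    except Exception as exc:  # perfect separation and friends
        converged = False
        message = str(exc)
        params = np.array([np.nan, np.nan])
        fitted = np.full_like(frac, np.nan)
        conf = None
    if not converged and np.all(np.isfinite(fitted)):
        message = message or "coefficients capped (quasi-separation)"
    if np.ptp(frac) == 0 or not np.all(np.isfinite(fitted)):
        r2, p = 0.0, float("nan")
        if np.ptp(frac) == 0:
            message = message or "constant observed fractions: R^2 undefined"
    else:
        r, p = stats.pearsonr(frac, fitted)
        r2 = float(r**2)
    return LogisticFit(
        intercept=float(params[0]),
        slope=float(params[1]),
        r_squared=r2,
        pearson_p=float(p),
        fitted=np.asarray(fitted, dtype=float),
        converged=converged,
        message=message,
        conf_int=conf,
    )


def fraction_different_by_dsp(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """Fraction of trials answered "different" (not "same") per |delta-SP|
    level, aggregated over the two presentation orders."""
    levels: dict[float, list[bool]] = {}
    for t in trials:
        dsp = abs(t.pair.delta_sp)
        levels.setdefault(dsp, []).append(t.response != "same")
    if len(levels) < 2:
        raise ValueError("trials must cover at least 2 delta-SP levels")
    rows = [
        {"delta_sp": dsp, "fraction_different": float(np.mean(v)), "n": len(v)}
        for dsp, v in sorted(levels.items())
    ]
    return pd.DataFrame(rows)
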