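"""Backward learning curves and constrained logistic-growth fitting.

A backward learning curve aligns every subject at the point where they
reached the learning criterion and averages performance over the preceding
units (19 trials for humans, 8 sessions for rats, plus the criterion point
itself), isolating the shape of acquisition from variable training
durations.  The averaged curve is summarized with a three-parameter
logistic growth model on top of a fixed baseline ``b``:

    p(x) = b + b * L / (1 + exp(-k * (x - x0)))

with asymptote parameter ``L``, learning rate ``k`` and midpoint ``x0``
(half-way between baseline and asymptotic performance), fitted by bounded
nonlinear least squares.  Cohorts that never learn get an ordinary linear
fit instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .behavior_sim import (
    Protocol,
    SimulatedSubject,
    apply_criterion,
    records_to_frame,
    session_accuracies,
)

__all__ = [
    "BackwardCurve",
    "LogisticFit",
    "LinearFit",
    "LogisticGrowthCurve",
    "logistic_growth",
    "backward_curve",
    "terminal_curve",
    "fit_logistic",
    "fit_linear",
    "model_selection_report",
    "DEFAULT_BASELINE",
    "species_start",
    "species_bounds",
]

DEFAULT_BASELINE = 0.55

#: start values (L, k, x0) and bounds per species; the k interval is the
#: corrected form of the printed constraint table (lower/upper transposed).
_START = {"human": (0.5, 0.3, 10.0), "rat": (0.5, 0.3, 5.0)}
_BOUNDS = {
    "human": ((0.0, -1.0, 0.0), (1.0, 1.0, 20.0)),
    "rat": ((0.0, -1.0, 0.0), (1.0, 1.0, 10.0)),
}

#: backward-curve window length (criterion point included) per species unit
WINDOWS = {"human": 20, "rat": 9}


def species_start(species: str) -> tuple[float, float, float]:
    return _START[species]


def species_bounds(species: str) -> tuple[tuple, tuple]:
    return _BOUNDS[species]


def logistic_growth(x, L, k, x0, baseline: float = DEFAULT_BASELINE):
    """Logistic growth on a fixed baseline: b + b*L / (1 + exp(-k(x - x0)))."""
    x = np.asarray(x, dtype=np.float64)
    return baseline + baseline * L / (1.0 + np.exp(-k * (x - x0)))


@dataclass
class BackwardCurve:
    """Criterion-aligned mean accuracy curve across subjects.

    ``x`` counts units (trials or sessions) from 1 at the earliest included
    point to ``window`` at the criterion point, so midpoint bounds such as
    x0 <= 20 are on the same scale.  ``aligned`` is False for terminal-aligned
    curves of cohorts that never reached criterion.
    """

    x: np.ndarray
    y: np.ndarray
    se: np.ndarray
    n_subjects: int
    unit: str  # "trial" | "session"
    n_excluded: int = 0
    aligned: bool = True


@dataclass
class LogisticFit:
    """Fitted logistic growth parameters and diagnostics."""

    L: float
    k: float
    x0: float
    baseline: float
    sse: float
    converged: bool
    start: tuple
    bounds: tuple

    def predict(self, x):
        return logistic_growth(x, self.L, self.k, self.x0, self.baseline)


@dataclass
class LinearFit:
    slope: float
    intercept: float
    sse: float

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


class LogisticGrowthCurve(BaseEstimator, RegressorMixin):
    """Bounded nonlinear least-squares fitter for the logistic growth model.

    Parameters
    ----------
    baseline : float
        The fixed baseline constant ``b`` (0.55 by default; 0.5 gives a
        chance-level baseline instead).
    start, bounds : parameter triple and (lower, upper) triples for
        (L, k, x0); defaults are the human settings.
    tol : float
        Cost tolerance of the trust-region solver.
    max_nfev : int
        Evaluation budget.

    Attributes (after ``fit``)
    --------------------------
    L_, k_, x0_ : fitted parameters (within bounds)
    sse_ : sum of squared residuals
    converged_ : solver success flag
    """

    def __init__(self, baseline: float = DEFAULT_BASELINE,
                 start: tuple = _START["human"],
                 bounds: tuple = _BOUNDS["human"],
                 tol: float = 1e-10, max_nfev: int = 10000):
        self.baseline = baseline
        self.start = start
        self.bounds = bounds
        self.tol = tol
        self.max_nfev = max_nfev

    def fit(self, X, y):
        x = np.asarray(X, dtype=np.float64).ravel()
        y = np.asarray(y, dtype=np.float64).ravel()
        if x.size != y.size:
            raise ValueError("x and y must have equal length")
        if x.size < 4:
            raise ValueError("need more points than parameters (>=4)")
        lo, hi = (np.asarray(b, dtype=float) for b in self.bounds)
        if np.any(lo >= hi):
            raise ValueError(f"invalid bounds: lower {lo} not below upper {hi}")
        start = np.clip(np.asarray(self.start, dtype=float), lo, hi)

        def residuals(theta):
            return logistic_growth(x, *theta, baseline=self.baseline) - y

        res = least_squares(
            residuals, start, bounds=(lo, hi), method="trf",
            ftol=self.tol, xtol=self.tol, gtol=self.tol, max_nfev=self.max_nfev,
        )
        self.L_, self.k_, self.x0_ = (float(v) for v in res.x)
        self.sse_ = float(np.sum(res.fun**2))
        self.converged_ = bool(res.success)
        self.result_ = res
        return self

    def predict(self, X):
        return logistic_growth(np.asarray(X, dtype=float).ravel(),
                               self.L_, self.k_, self.x0_, self.baseline)

    @property
    def fit_(self) -> LogisticFit:
        return LogisticFit(self.L_, self.k_, self.x0_, self.baseline,
                           self.sse_, self.converged_, tuple(self.start),
                           tuple(self.bounds))


# ---------------------------------------------------------------------------
# curve construction
# ---------------------------------------------------------------------------


def _subject_series(subj: SimulatedSubject, protocol: Protocol) -> np.ndarray:
    """Per-unit accuracy series: per-trial 0/1 (human) or per-session (rat)."""
    df = subj.frame()
    df = df[~df["correction_trial"]]
    if protocol.species == "human":
        return df["correct"].to_numpy(dtype=float)
    return session_accuracies(df).to_numpy(dtype=float)


def backward_curve(
    subjects: list[SimulatedSubject],
    protocol: Protocol,
    window: int | None = None,
) -> BackwardCurve:
    """Criterion-aligned average curve over a cohort.

    Subjects without a criterion point, or with fewer than ``window - 1``
    units before it, are excluded (and counted in ``n_excluded``) so that
    every point of the curve averages the same subjects.
    """
    window = window or WINDOWS[protocol.species]
    rows, n_excluded = [], 0
    for subj in subjects:
        crit = apply_criterion(subj.frame(), protocol)
        if crit is None or crit < window:
            n_excluded += 1
            warnings.warn(
                f"subject {subj.subject} excluded from backward curve "
                f"(criterion={crit})", stacklevel=2)
            continue
        series = _subject_series(subj, protocol)
        rows.append(series[crit - window : crit])
    if not rows:
        raise ValueError("no subject reached criterion; backward curve is empty")
    Y = np.stack(rows)
    n = Y.shape[0]
    se = Y.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(Y.shape[1])
    unit = "trial" if protocol.species == "human" else "session"
    return BackwardCurve(np.arange(1, window + 1, dtype=float), Y.mean(axis=0),
                         se, n, unit, n_excluded=n_excluded)


def terminal_curve(
    subjects: list[SimulatedSubject],
    protocol: Protocol,
    window: int | None = None,
) -> BackwardCurve:
    """End-of-training-aligned curve for cohorts that never reach criterion.

    Aligns subjects at their final unit instead of a criterion point; used
    to display and linearly fit non-learning cohorts.
    """
    window = window or WINDOWS[protocol.species]
    rows, n_excluded = [], 0
    for subj in subjects:
        series = _subject_series(subj, protocol)
        if len(series) < window:
            n_excluded += 1
            continue
        rows.append(series[-window:])
    if not rows:
        raise ValueError("no subject has enough units for the requested window")
    Y = np.stack(rows)
    n = Y.shape[0]
    se = Y.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(Y.shape[1])
    unit = "trial" if protocol.species == "human" else "session"
    return BackwardCurve(np.arange(1, window + 1, dtype=float), Y.mean(axis=0),
                         se, n, unit, n_excluded=n_excluded, aligned=False)


def fit_logistic(
    curve: BackwardCurve | tuple,
    start: tuple | None = None,
    bounds: tuple | None = None,
    baseline: float = DEFAULT_BASELINE,
    species: str | None = None,
) -> LogisticFit:
    """Fit the logistic growth model to a curve (species picks start/bounds)."""
    x, y = (curve.x, curve.y) if isinstance(curve, BackwardCurve) else curve
    if species is None:
        species = "human" if len(np.asarray(x)) >= 15 else "rat"
    est = LogisticGrowthCurve(
        baseline=baseline,
        start=start or _START[species],
        bounds=bounds or _BOUNDS[species],
    ).fit(x, y)
    return est.fit_


def fit_linear(curve: BackwardCurve | tuple) -> LinearFit:
    """Ordinary least-squares line through a curve."""
    x, y = (curve.x, curve.y) if isinstance(curve, BackwardCurve) else curve
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 points for a line")
    slope, intercept = np.polyfit(x, y, 1)
    sse = float(np.sum((slope * x + intercept - y) ** 2))
    return LinearFit(float(slope), float(intercept), sse)


def model_selection_report(
    curves: dict[str, tuple[BackwardCurve, str]],
    baseline: float = DEFAULT_BASELINE,
) -> pd.DataFrame:
    """Fit table across cohorts: logistic for learners, linear for non-learners.

    ``curves`` maps a cohort name to ``(curve, species)``; criterion-aligned
    curves get the logistic growth fit, terminal-aligned curves (cohorts
    that never learned) get the linear fallback.
    """
    rows = []
    for name, (curve, species) in curves.items():
        if curve.aligned:
            f = fit_logistic(curve, baseline=baseline, species=species)
            rows.append({"cohort": name, "model": "logistic", "L": f.L, "k": f.k,
                         "x0": f.x0, "slope": np.nan, "intercept": np.nan,
                         "sse": f.sse, "converged": f.converged})
        else:
            f = fit_linear(curve)
            rows.append({"cohort": name, "model": "linear", "L": np.nan,
                         "k": np.nan, "x0": np.nan, "slope": f.slope,
                         "intercept": f.intercept, "sse": f.sse, "converged": True})
    cols = ["cohort", "model", "L", "k", "x0", "slope", "intercept", "sse", "converged"]
    return pd.DataFrame(rows, columns=cols)
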