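"""Template-strategy analysis of behavior on the manipulated stimulus set.

Three fixed template models — *full* canvas, *upper* visual field, *lower*
visual field — each predict per-pair discrimination performance: chance
(0.5) when the two stimuli of a pair are identical within the model's
region, above-chance otherwise.  Correlating these predictions with
observed per-pair accuracies across the manipulated-pair matrix reveals
which part of the stimulus drives behavior.  The module also computes
per-pair accuracies with exact (Clopper-Pearson) binomial confidence
intervals and the old/new-pair transfer analysis for staged designs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .behavior_sim import TrialRecord, records_to_frame
from .stimuli import StimulusGeometry, StimulusPair, pixel_distance, render

__all__ = [
    "TemplateModel",
    "PairPrediction",
    "PairPerformance",
    "template_prediction",
    "prediction_matrix",
    "prediction_performance_correlation",
    "per_pair_performance",
    "chance_interval",
    "transfer_analysis",
]


@dataclass(frozen=True)
class TemplateModel:
    """A fixed read-out region over the stimulus canvas.

    ``upper_field`` and ``lower_field`` split the canvas at a horizontal
    boundary (a configurable fraction of the height, default the midline);
    ``full`` covers the whole canvas, so upper and lower jointly cover full.
    """

    kind: Literal["full", "upper_field", "lower_field"]
    boundary_fraction: float = 0.5

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        rows, cols = shape
        cut = int(round(rows * self.boundary_fraction))
        m = np.zeros(shape, dtype=bool)
        if self.kind == "full":
            m[:] = True
        elif self.kind == "upper_field":
            m[:cut] = True
        elif self.kind == "lower_field":
            m[cut:] = True
        else:
            raise ValueError(f"unknown template kind {self.kind!r}")
        return m


@dataclass(frozen=True)
class PairPrediction:
    pair_id: str
    predicted: float  # in [0.5, 1.0]


@dataclass(frozen=True)
class PairPerformance:
    pair_id: str
    successes: int
    trials: int
    accuracy: float
    ci_low: float
    ci_high: float
    level: float = 0.95


def template_prediction(
    model: TemplateModel,
    pair: StimulusPair,
    geometry: StimulusGeometry | None = None,
    mode: Literal["binary", "graded"] = "binary",
) -> PairPrediction:
    """Predicted performance on one pair under a template model.

    A strategy reading only the model's region cannot do better than chance
    (0.5) when the two stimuli are identical there.  In ``binary`` mode any
    in-region difference predicts 1.0; in ``graded`` mode the prediction is
    0.5 + 0.5 * (fraction of in-region pixels that differ), giving the full
    model non-degenerate variance across pairs.
    """
    geometry = geometry or StimulusGeometry()
    a = render(pair.positive, geometry).pixels
    b = render(pair.negative, geometry).pixels
    if a.shape != b.shape:
        raise ValueError("pair stimuli rendered under different geometries")
    m = model.mask(a.shape)
    diff = (a[m] != b[m])
    if not diff.any():
        return PairPrediction(pair.id, 0.5)
    if mode == "binary":
        return PairPrediction(pair.id, 1.0)
    return PairPrediction(pair.id, 0.5 + 0.5 * float(diff.mean()))


def prediction_matrix(
    models: Sequence[TemplateModel],
    pairs: Sequence[StimulusPair],
    geometry: StimulusGeometry | None = None,
    mode: Literal["binary", "graded"] = "binary",
) -> pd.DataFrame:
    """Per-pair predictions of several template models, one column per model."""
    out = {"pair_id": [p.id for p in pairs]}
    for m in models:
        out[m.kind] = [template_prediction(m, p, geometry, mode).predicted for p in pairs]
    return pd.DataFrame(out).set_index("pair_id")


def prediction_performance_correlation(
    predictions: Iterable[PairPrediction] | dict[str, float],
    observed: Iterable[PairPerformance] | dict[str, float],
    n_permutations: int = 0,
    seed: int | None = None,
) -> dict:
    """Pearson correlation between model predictions and observed accuracies.

    Pairs are matched by id; needs >=3 matched pairs.  Returns r and a
    two-sided t-approximation p-value, plus an optional seeded permutation
    p-value.  Zero variance on the prediction side (e.g. the full model in
    binary mode when every pair differs somewhere) is flagged instead of
    silently returning a value.
    """
    pred = (predictions if isinstance(predictions, dict)
            else {p.pair_id: p.predicted for p in predictions})
    obs = (observed if isinstance(observed, dict)
           else {o.pair_id: o.accuracy for o in observed})
    ids = sorted(set(pred) & set(obs))
    if len(ids) < 3:
        raise ValueError("need at least 3 matched pairs")
    x = np.array([pred[i] for i in ids], dtype=float)
    y = np.array([obs[i] for i in ids], dtype=float)
    if x.std() == 0 or y.std() == 0:
        return {"r": np.nan, "p": np.nan, "n": len(ids), "degenerate": True,
                "note": "zero variance; graded prediction mode recommended"}
    r, p = stats.pearsonr(x, y)
    out = {"r": float(r), "p": float(p), "n": len(ids), "degenerate": False}
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            rp = np.corrcoef(x, rng.permutation(y))[0, 1]
            if abs(rp) >= abs(r):
                count += 1
        out["p_permutation"] = (count + 1) / (n_permutations + 1)
    return out


def chance_interval(n_trials: int, level: float = 0.95) -> tuple[float, float]:
    """Central binomial acceptance region around chance (p = 0.5), as accuracies.

    The tightest interval obtainable for ``n_trials`` Bernoulli(0.5) trials:
    observed accuracies inside it are consistent with chance responding.
    """
    lo, hi = stats.binom.interval(level, n_trials, 0.5)
    return lo / n_trials, hi / n_trials


def per_pair_performance(
    records: Iterable[TrialRecord] | pd.DataFrame,
    last_sessions: int | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Per-pair accuracy with exact binomial CIs over an analysis window.

    Correction trials are excluded.  ``last_sessions`` restricts the window
    to the final N sessions of the log (the end-of-training window view);
    None uses all non-correction trials.  Each row carries the exact
    Clopper-Pearson interval around the observed accuracy, the chance
    acceptance region for that trial count, and a within-chance flag.
    Pairs with zero trials are reported with NaN accuracy, not dropped.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df = df[~df["correction_trial"]]
    all_pairs = sorted(df["pair_id"].unique())
    if last_sessions is not None:
        sessions = sorted(df["session"].unique())
        df = df[df["session"].isin(sessions[-last_sessions:])]
    rows = []
    for pair_id in all_pairs:
        sub = df[df["pair_id"] == pair_id]
        n = len(sub)
        k = int(sub["correct"].sum())
        if n == 0:
            rows.append({"pair_id": pair_id, "successes": 0, "trials": 0,
                         "accuracy": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                         "chance_low": np.nan, "chance_high": np.nan,
                         "within_chance": np.nan})
            continue
        lo, hi = proportion_confint(k, n, alpha=1 - level, method="beta")
        clo, chi = chance_interval(n, level)
        acc = k / n
        rows.append({"pair_id": pair_id, "successes": k, "trials": n,
                     "accuracy": acc, "ci_low": float(lo), "ci_high": float(hi),
                     "chance_low": clo, "chance_high": chi,
                     "within_chance": bool(clo <= acc <= chi)})
    return pd.DataFrame(rows)


def _pair_session_acc(df: pd.DataFrame, pair_id: str) -> pd.Series:
    sub = df[df["pair_id"] == pair_id]
    return sub.groupby("session")["correct"].mean()


def transfer_analysis(
    records: Iterable[TrialRecord] | pd.DataFrame,
    old_pair: str,
    new_pair: str,
    level: float = 0.95,
) -> dict:
    """Old- vs new-pair performance after a staged pair introduction.

    Expects a staged (Experiment-A style) log whose stage column steps from
    0 (initial pair only) to 1 (old + new intermixed).  Reports each pair's
    accuracy with exact binomial CI in the introduction session (the first
    session of stage 1) and the Pearson correlation of per-session old/new
    accuracies over the remaining sessions.  Zero variance on either side
    leaves the correlation NaN with ``degenerate`` set.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df = df[~df["correction_trial"]]
    if "stage" not in df.columns or df["stage"].max() < 1:
        raise ValueError("transfer analysis needs a staged log (stage column with stage >= 1)")
    stage1 = df[df["stage"] == 1]
    intro_session = int(stage1["session"].min())
    out: dict = {"intro_session": intro_session}
    intro = df[df["session"] == intro_session]
    for label, pair_id in (("old", old_pair), ("new", new_pair)):
        sub = intro[intro["pair_id"] == pair_id]
        n, k = len(sub), int(sub["correct"].sum())
        if n == 0:
            raise ValueError(f"{label} pair {pair_id!r} absent from introduction session")
        lo, hi = proportion_confint(k, n, alpha=1 - level, method="beta")
        out[label] = {"pair_id": pair_id, "successes": k, "trials": n,
                      "accuracy": k / n, "ci_low": float(lo), "ci_high": float(hi)}
    post = df[(df["stage"] >= 1) & (df["session"] > intro_session)]
    acc_old = _pair_session_acc(post, old_pair)
    acc_new = _pair_session_acc(post, new_pair)
    joined = pd.concat([acc_old, acc_new], axis=1, keys=["old", "new"]).dropna()
    if len(joined) >= 3 and joined["old"].std() > 0 and joined["new"].std() > 0:
        r, p = stats.pearsonr(joined["old"], joined["new"])
        out["correlation"] = {"r": float(r), "p": float(p), "n": len(joined),
                              "degenerate": False}
    else:
        out["correlation"] = {"r": np.nan, "p": np.nan, "n": len(joined),
                              "degenerate": True}
    return out
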