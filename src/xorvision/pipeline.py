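"""End-to-end seeded reproduction of the computational analyses.

``run_all`` drives every stage from one config: stimulus rendering and
dissimilarity matrices, the perceptron separability analysis on raw pixels
and V1 features, simulated behavioral cohorts, backward learning curves
with logistic/linear fits, and the template strategy analysis on the
manipulated-pair matrix.  All randomness derives from one global seed via
a fixed per-stage scheme (CRC32 of the stage name XOR the seed), so stages
can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior_sim as bs
from . import learning_curves as lc
from . import strategy_analysis as sa
from .perceptron import Perceptron, separability_certificate
from .stimuli import (
    StimulusGeometry,
    build_manipulated_pairs,
    class_distance_summary,
    linear_task,
    make_base_set,
    nonlinear_task,
    pixel_distance,
    render,
)
from .v1_model import FilterBankSpec, ModelStageParams, response_matrix

__all__ = ["RunConfig", "run_all", "validate_config", "stage_seed"]


def stage_seed(base_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: CRC32(stage name) XOR base, below 2^31."""
    return (zlib.crc32(stage.encode()) ^ base_seed) & 0x7FFFFFFF


@dataclass
class RunConfig:
    """Everything a full reproduction run needs, with study defaults."""

    seed: int = 0
    pixels_per_degree: float = 2.0
    stride: int = 4
    max_epochs: int = 20
    baseline: float = lc.DEFAULT_BASELINE
    n_subjects: int = 3
    rat_session_size: int = 100
    rat_max_sessions: int = 30
    human_max_trials: int = 600
    strategy: str = "linear_template"
    out_dir: str = "runs/demo"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def validate_config(config: RunConfig) -> list[str]:
    """Check every config invariant; returns a list of violation messages."""
    v: list[str] = []
    if config.pixels_per_degree <= 0:
        v.append("pixels_per_degree must be positive")
    if config.stride < 1:
        v.append("stride must be >= 1")
    if config.max_epochs < 1:
        v.append("max_epochs must be >= 1")
    if config.n_subjects < 1:
        v.append("n_subjects must be >= 1")
    if not 0 < config.baseline <= 1:
        v.append("baseline must lie in (0, 1]")
    if config.rat_session_size < 12:
        v.append("rat_session_size must hold at least one 12-trial block")
    if config.seed < 0 or config.seed >= 2**31:
        v.append("seed must lie in [0, 2^31)")
    lo, hi = lc.species_bounds("human")
    if any(a >= b for a, b in zip(lo, hi)):
        v.append("fit bounds invalid: lower not below upper")
    try:
        StimulusGeometry(pixels_per_degree=config.pixels_per_degree)
    except ValueError as e:
        v.append(str(e))
    return v


def _save_png(pixels: np.ndarray, path: Path) -> None:
    from PIL import Image

    Image.fromarray((pixels * 255).astype(np.uint8), mode="L").save(path)


def run_stimuli(config: RunConfig, out: Path) -> dict:
    geom = StimulusGeometry(pixels_per_degree=config.pixels_per_degree)
    base = make_base_set()
    manifest = []
    img_dir = out / "stimuli"
    img_dir.mkdir(parents=True, exist_ok=True)
    configs = sorted(set(base) | {c for p in build_manipulated_pairs(linear_task)
                                  for c in (p.positive, p.negative)})
    for cfg in configs:
        img = render(cfg, geom)
        fn = f"{cfg.id}.png"
        _save_png(img.pixels, img_dir / fn)
        manifest.append({
            "config_id": cfg.id, "file": f"stimuli/{fn}",
            "left_arm": cfg.left_arm.value, "right_arm": cfg.right_arm.value,
            "is_base": cfg.is_base,
            "linear_class": linear_task.class_of(cfg),
            "nonlinear_class": nonlinear_task.class_of(cfg),
        })
    pd.DataFrame(manifest).to_csv(out / "stimulus_manifest.csv", index=False)

    ids = [c.id for c in base]
    imgs = [render(c, geom) for c in base]
    D_px = np.array([[pixel_distance(a, b) for b in imgs] for a in imgs])
    pd.DataFrame(D_px, index=ids, columns=ids).to_csv(out / "pixel_distances.csv")
    _, D_model = response_matrix(imgs, stride=config.stride,
                                 pixels_per_degree=config.pixels_per_degree)
    pd.DataFrame(D_model, index=ids, columns=ids).to_csv(out / "model_distances.csv")

    pairs = build_manipulated_pairs(linear_task)
    pd.DataFrame({"pair_id": [p.id for p in pairs],
                  "positive": [p.positive.id for p in pairs],
                  "negative": [p.negative.id for p in pairs]}
                 ).to_csv(out / "manipulated_pairs.csv", index=False)

    summary = {}
    for task, name in ((linear_task, "linear"), (nonlinear_task, "nonlinear")):
        w_px, b_px = class_distance_summary(task, pixel_distance, geometry=geom)
        model_metric = lambda a, b: 1.0 - np.corrcoef(a, b)[0, 1]
        resp = {c: r for c, r in zip(base, response_matrix(
            imgs, stride=config.stride, pixels_per_degree=config.pixels_per_degree)[0])}
        w_m, b_m = class_distance_summary(task, model_metric, images=resp)
        summary[name] = {"pixel_within": w_px, "pixel_between": b_px,
                         "model_within": w_m, "model_between": b_m}
    return {"n_manipulated_pairs": len(pairs), "class_distances": summary}


def run_perceptron(config: RunConfig, out: Path) -> dict:
    geom = StimulusGeometry(pixels_per_degree=config.pixels_per_degree)
    base = make_base_set()
    imgs = [render(c, geom) for c in base]
    X_px = np.stack([i.pixels.ravel().astype(float) for i in imgs])
    X_v1, _ = response_matrix(imgs, stride=config.stride,
                              pixels_per_degree=config.pixels_per_degree)
    results, histories = {}, {}
    for task, tname in ((linear_task, "linear"), (nonlinear_task, "nonlinear")):
        y = np.array([1 if task.class_of(c) == "target" else -1 for c in base])
        for X, fname in ((X_px, "pixels"), (X_v1, "v1")):
            clf = Perceptron(max_epochs=config.max_epochs).fit(X, y)
            key = f"{tname}_{fname}"
            results[key] = {"converged": clf.converged_, "epochs": clf.epochs_run_,
                            "certificate": separability_certificate(X, y, max_epochs=200)}
            histories[key] = clf.epoch_history_
    hist_df = pd.DataFrame({k: pd.Series(v) for k, v in histories.items()})
    hist_df.index.name = "epoch"
    hist_df.to_csv(out / "perceptron_epoch_history.csv")
    _plot_epochs(histories, out / "perceptron_training.png")
    return results


def _plot_epochs(histories: dict, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for k, h in histories.items():
        ax.plot(range(1, len(h) + 1), h, marker="o", label=k)
    ax.set_xlabel("training epoch")
    ax.set_ylabel("training accuracy")
    ax.set_ylim(0, 1.05)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_cohorts(config: RunConfig, out: Path) -> dict:
    """Simulate the four rat cohorts and two human cohorts; fit their curves."""
    summary: dict = {}
    logs_dir = out / "logs"
    logs_dir.mkdir(parents=True, exist_ok=True)
    curves: dict[str, tuple[lc.BackwardCurve, str]] = {}
    for species in ("rat", "human"):
        proto = (bs.Protocol.rat(session_size=config.rat_session_size,
                                 max_sessions=config.rat_max_sessions)
                 if species == "rat"
                 else bs.Protocol.human(max_trials=config.human_max_trials))
        for task, tname in ((linear_task, "linear"), (nonlinear_task, "nonlinear")):
            name = f"{species}_{tname}"
            cohort = bs.simulate_cohort(
                lambda sp=species, tn=tname: bs.default_cohort_strategy(sp, tn),
                task, proto, config.n_subjects, seed=stage_seed(config.seed, name))
            frame = pd.concat([s.frame() for s in cohort])
            frame.to_csv(logs_dir / f"{name}.csv", index=False)
            reached = [s.criterion_reached for s in cohort]
            summary[name] = {
                "n_subjects": len(cohort),
                "n_reached_criterion": int(sum(reached)),
                "criterion_points": [s.criterion_point for s in cohort],
            }
            try:
                curves[name] = (lc.backward_curve(cohort, proto), species)
            except ValueError:
                curves[name] = (lc.terminal_curve(cohort, proto), species)
    report = lc.model_selection_report(curves, baseline=config.baseline)
    report.to_csv(out / "fit_report.csv", index=False)
    for name, (curve, _) in curves.items():
        pd.DataFrame({"x": curve.x, "y": curve.y, "se": curve.se}).to_csv(
            out / f"curve_{name}.csv", index=False)
    summary["fits"] = report.to_dict(orient="records")
    return summary


def run_strategy_analysis(config: RunConfig, out: Path) -> dict:
    """Template correlations on the manipulated-pair matrix plus transfer signs."""
    geom = StimulusGeometry(pixels_per_degree=config.pixels_per_degree)
    pairs = build_manipulated_pairs(linear_task)
    models = [sa.TemplateModel("full"), sa.TemplateModel("upper_field"),
              sa.TemplateModel("lower_field")]
    preds = sa.prediction_matrix(models, pairs, geom, mode="graded")
    preds.to_csv(out / "template_predictions.csv")

    # cohort of upper-field readers on the 32 manipulated pairs
    upper_mask = sa.TemplateModel("upper_field").mask(geom.shape)
    proto = bs.Protocol.rat(session_size=len(pairs) * 4, max_sessions=10,
                            block_length=len(pairs), correction_trials=False)
    seed = stage_seed(config.seed, "strategy_analysis")
    cohort = bs.simulate_cohort(
        lambda: bs.RegionExemplarStrategy(upper_mask),
        linear_task, proto, config.n_subjects, seed=seed, pairs=pairs, geometry=geom)
    frame = pd.concat([s.frame() for s in cohort])
    perf = sa.per_pair_performance(frame)
    perf.to_csv(out / "per_pair_performance.csv", index=False)
    obs = dict(zip(perf["pair_id"], perf["accuracy"]))
    corr = {m.kind: sa.prediction_performance_correlation(
        preds[m.kind].to_dict(), obs) for m in models}

    transfer = {}
    for task, tname in ((linear_task, "linear"), (nonlinear_task, "nonlinear")):
        stages = bs.experiment_a_stages(task)
        subj = bs.simulate_subject(
            bs.default_cohort_strategy("rat", tname), task,
            bs.Protocol.rat(session_size=config.rat_session_size,
                            max_sessions=config.rat_max_sessions),
            seed=stage_seed(config.seed, f"transfer_{tname}"), stages=stages)
        old_id, new_id = stages[0][0].id, stages[1][1].id
        try:
            transfer[tname] = sa.transfer_analysis(subj.frame(), old_id, new_id)
        except ValueError as e:
            transfer[tname] = {"error": str(e)}
    return {"template_correlations": corr, "transfer": transfer}


def _upper_template(geom: StimulusGeometry) -> np.ndarray:
    """A template that weights only the upper visual field of the linear rule.

    Difference of linear-task class means, masked to the upper half: the
    signature of an upper-field reader.
    """
    base = make_base_set()
    pos = np.mean([render(c, geom).pixels for c in linear_task.targets(base)], axis=0)
    neg = np.mean([render(c, geom).pixels for c in linear_task.distractors(base)], axis=0)
    diff = pos - neg
    mask = sa.TemplateModel("upper_field").mask(diff.shape)
    return diff * mask


def run_all(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute every stage; writes artifacts and returns the summary dict."""
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = {"config": dataclasses.asdict(config), "config_hash": config.hash(),
               "seed": config.seed}
    for name, fn in (("stimuli", run_stimuli), ("perceptron", run_perceptron),
                     ("cohorts", run_cohorts), ("strategy", run_strategy_analysis)):
        try:
            summary[name] = fn(config, out)
        except Exception as e:
            raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=_json_default))
    return summary


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
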