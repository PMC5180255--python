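"""Synthetic two-alternative discrimination sessions under the rat and human protocols.

Emulates the data-generating process of the touchscreen (rat) and
keyboard (human) experiments: pseudo-randomized 12-trial blocks in which
each stimulus pair appears equally often and the target is on the left
exactly half the time; rat sessions with correction trials (errors are
re-presented and excluded from analysis) and an ">80% correct over two
consecutive sessions" learning criterion; human trial streams with a
running-mean-of-last-20-trials criterion.  Candidate decision strategies
(learned linear template, symmetry oracle, pixel-similarity prototypes,
random guessing) generate the choices, so every downstream analysis stage
can be exercised without the original behavioral data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .stimuli import (
    StimulusConfig,
    StimulusGeometry,
    StimulusPair,
    TaskMapping,
    make_base_set,
    render,
)

__all__ = [
    "Protocol",
    "TrialRecord",
    "SimulatedSubject",
    "Strategy",
    "RandomStrategy",
    "SymmetryOracleStrategy",
    "LinearTemplateStrategy",
    "PixelSimilarityStrategy",
    "make_strategy",
    "schedule_block",
    "simulate_subject",
    "simulate_cohort",
    "apply_criterion",
    "mixed_pairs",
    "experiment_a_stages",
    "records_to_frame",
    "session_accuracies",
]


@dataclass(frozen=True)
class Protocol:
    """Training protocol parameters for one species.

    Rats run daily sessions (``session_size`` non-correction trials, capped
    at ``max_sessions``) with correction trials after each error; criterion
    is >``criterion_accuracy`` in each of ``criterion_sessions`` consecutive
    sessions.  Humans run a single stream of trials (capped at
    ``max_trials``); criterion is a running mean over the last
    ``criterion_window`` trials exceeding ``criterion_accuracy``.
    """

    species: Literal["rat", "human"]
    block_length: int = 12
    criterion_accuracy: float = 0.80
    # rat fields
    session_size: int = 100
    max_sessions: int = 40
    criterion_sessions: int = 2
    correction_trials: bool = False
    max_corrections: int = 25  # bounds re-presentation loops; corrections are excluded anyway
    # human fields
    max_trials: int = 600
    criterion_window: int = 20

    @classmethod
    def rat(cls, **kw) -> "Protocol":
        kw.setdefault("correction_trials", True)
        return cls(species="rat", **kw)

    @classmethod
    def human(cls, **kw) -> "Protocol":
        return cls(species="human", correction_trials=False, **kw)

    def validate_block(self, n_pairs: int) -> None:
        if self.block_length % n_pairs != 0:
            raise ValueError(
                f"block length {self.block_length} is not divisible by {n_pairs} pairs"
            )
        if self.block_length % 2 != 0:
            raise ValueError("block length must be even to balance target sides")


@dataclass(frozen=True)
class TrialRecord:
    """One behavioral trial of a two-alternative discrimination."""

    subject: int
    session: int
    trial: int
    pair_id: str
    target_side: Literal["left", "right"]
    chosen_side: Literal["left", "right"]
    correct: bool
    correction_trial: bool
    stage: int = 0


@dataclass
class SimulatedSubject:
    """A subject's full trial log plus criterion bookkeeping per stage."""

    subject: int
    records: list[TrialRecord]
    criterion_reached: bool
    criterion_point: int | None  # session (rat) or trial (human) index, 1-based
    stage_boundaries: list[int]  # first session (rat) / trial (human) of each stage

    def frame(self) -> pd.DataFrame:
        return records_to_frame(self.records)


def records_to_frame(records: Iterable[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


# ---------------------------------------------------------------------------
# decision strategies
# ---------------------------------------------------------------------------


def _normalize(img: np.ndarray) -> np.ndarray:
    x = np.asarray(img, dtype=np.float64).ravel()
    x = x - x.mean()
    n = np.linalg.norm(x)
    return x / n if n > 0 else x


class Strategy:
    """Base class: maps a (left image, right image) display to a choice.

    ``choose`` returns "left" or "right"; ``update`` receives the revealed
    target/distractor images after feedback.  Subclasses must keep all
    randomness on the generator passed in (one seeded generator per subject).
    """

    kind = "abstract"

    def __init__(self, lapse_rate: float = 0.0):
        if not 0 <= lapse_rate < 1:
            raise ValueError("lapse_rate must lie in [0, 1)")
        self.lapse_rate = lapse_rate

    def _maybe_lapse(self, rng: np.random.Generator) -> str | None:
        if self.lapse_rate > 0 and rng.random() < self.lapse_rate:
            return "left" if rng.random() < 0.5 else "right"
        return None

    def choose(self, img_left: np.ndarray, img_right: np.ndarray,
               rng: np.random.Generator) -> str:
        raise NotImplementedError

    def update(self, img_target: np.ndarray, img_distractor: np.ndarray,
               correct: bool, rng: np.random.Generator) -> None:
        pass


class RandomStrategy(Strategy):
    kind = "random"

    def choose(self, img_left, img_right, rng):
        return "left" if rng.random() < 0.5 else "right"


class SymmetryOracleStrategy(Strategy):
    """Picks the mirror-symmetric image; solves the nonlinear task perfectly."""

    kind = "symmetry_oracle"

    def choose(self, img_left, img_right, rng):
        lapse = self._maybe_lapse(rng)
        if lapse:
            return lapse
        sym_l = np.array_equal(img_left, img_left[:, ::-1])
        sym_r = np.array_equal(img_right, img_right[:, ::-1])
        if sym_l == sym_r:
            return "left" if rng.random() < 0.5 else "right"
        return "left" if sym_l else "right"


class LinearTemplateStrategy(Strategy):
    """Approach the image matching an internal linear template best.

    The template is a weight image ``w``; the decision variable is the
    difference of template correlations with the two displayed images,
    passed through a logistic choice rule with gain ``choice_gain``.  On
    error trials the template moves toward the revealed target and away
    from the distractor (error-driven delta rule).  A fixed template with
    ``learning_rate=0`` models the frozen strategies probed by the
    template analysis; the learned version acquires the linear task but
    provably cannot acquire XOR (the average update over the four mixed
    pairs is zero because the class means collide).
    """

    kind = "linear_template"

    def __init__(self, template: np.ndarray | None = None, learning_rate: float = 0.1,
                 choice_gain: float = 4.0, lapse_rate: float = 0.05,
                 region_mask: np.ndarray | None = None):
        super().__init__(lapse_rate)
        self.region_mask = None if region_mask is None else np.asarray(region_mask, dtype=bool)
        self.template = None if template is None else _normalize(self._masked(template))
        self.learning_rate = learning_rate
        self.choice_gain = choice_gain

    def _masked(self, img: np.ndarray) -> np.ndarray:
        """Restrict the strategy's view to its region (e.g. the upper field)."""
        if self.region_mask is None:
            return np.asarray(img, dtype=np.float64)
        return np.asarray(img, dtype=np.float64) * self.region_mask

    def _score(self, img: np.ndarray) -> float:
        if self.template is None:
            return 0.0
        return float(self.template @ _normalize(self._masked(img)))

    def choose(self, img_left, img_right, rng):
        lapse = self._maybe_lapse(rng)
        if lapse:
            return lapse
        d = self.choice_gain * (self._score(img_left) - self._score(img_right))
        p_left = 1.0 / (1.0 + np.exp(-np.clip(d, -30, 30)))
        return "left" if rng.random() < p_left else "right"

    def update(self, img_target, img_distractor, correct, rng):
        if self.learning_rate <= 0 or correct:
            return
        delta = _normalize(self._masked(img_target)) - _normalize(self._masked(img_distractor))
        w = (self.template if self.template is not None else np.zeros_like(delta))
        self.template = w + self.learning_rate * delta


class PixelSimilarityStrategy(Strategy):
    """Prototype matching: approach the image closer to the learned target prototype.

    Maintains running-average target and distractor prototypes updated from
    feedback; the decision variable is the difference of (target-prototype
    similarity minus distractor-prototype similarity) between the two sides.
    On the symmetry task the two prototypes converge to the same mean image,
    leaving the strategy at chance.
    """

    kind = "pixel_similarity"

    def __init__(self, learning_rate: float = 0.2, choice_gain: float = 4.0,
                 lapse_rate: float = 0.05):
        super().__init__(lapse_rate)
        self.learning_rate = learning_rate
        self.choice_gain = choice_gain
        self.proto_target: np.ndarray | None = None
        self.proto_distractor: np.ndarray | None = None

    def _score(self, img: np.ndarray) -> float:
        x = _normalize(img)
        s = 0.0
        if self.proto_target is not None:
            s += float(_normalize(self.proto_target) @ x)
        if self.proto_distractor is not None:
            s -= float(_normalize(self.proto_distractor) @ x)
        return s

    def choose(self, img_left, img_right, rng):
        lapse = self._maybe_lapse(rng)
        if lapse:
            return lapse
        d = self.choice_gain * (self._score(img_left) - self._score(img_right))
        p_left = 1.0 / (1.0 + np.exp(-np.clip(d, -30, 30)))
        return "left" if rng.random() < p_left else "right"

    def update(self, img_target, img_distractor, correct, rng):
        t = np.asarray(img_target, dtype=np.float64).ravel()
        d = np.asarray(img_distractor, dtype=np.float64).ravel()
        lr = self.learning_rate
        self.proto_target = t.copy() if self.proto_target is None else (1 - lr) * self.proto_target + lr * t
        self.proto_distractor = (
            d.copy() if self.proto_distractor is None else (1 - lr) * self.proto_distractor + lr * d
        )


class RegionExemplarStrategy(Strategy):
    """Configural learner restricted to one region of the canvas.

    Remembers, for each displayed pair of region-restricted appearances,
    which appearance was rewarded (exemplar/configural learning), and
    chooses by a logistic rule on the learned values.  Because the agent
    only sees its region, pairs that are identical there stay at chance
    exactly, and pairs whose region-appearance context recurs with
    conflicting rewards stay near chance — the behavioral signature that
    the template analysis is designed to recover.
    """

    kind = "region_exemplar"

    def __init__(self, region_mask: np.ndarray, learning_rate: float = 0.3,
                 choice_gain: float = 5.0, lapse_rate: float = 0.05):
        super().__init__(lapse_rate)
        self.region_mask = np.asarray(region_mask, dtype=bool)
        self.learning_rate = learning_rate
        self.choice_gain = choice_gain
        self.values: dict[tuple, float] = {}

    def _key(self, img: np.ndarray) -> bytes:
        return np.asarray(img)[self.region_mask].tobytes()

    def choose(self, img_left, img_right, rng):
        lapse = self._maybe_lapse(rng)
        if lapse:
            return lapse
        kl, kr = self._key(img_left), self._key(img_right)
        ctx = tuple(sorted((kl, kr)))
        d = self.choice_gain * (self.values.get((ctx, kl), 0.0)
                                - self.values.get((ctx, kr), 0.0))
        p_left = 1.0 / (1.0 + np.exp(-np.clip(d, -30, 30)))
        return "left" if rng.random() < p_left else "right"

    def update(self, img_target, img_distractor, correct, rng):
        kt, kd = self._key(img_target), self._key(img_distractor)
        ctx = tuple(sorted((kt, kd)))
        lr = self.learning_rate
        self.values[(ctx, kt)] = self.values.get((ctx, kt), 0.0) + lr * (1 - self.values.get((ctx, kt), 0.0))
        self.values[(ctx, kd)] = self.values.get((ctx, kd), 0.0) + lr * (-1 - self.values.get((ctx, kd), 0.0))


def default_cohort_strategy(species: str, task_id: str) -> Strategy:
    """Study-condition agents: what a typical subject of each group does.

    Humans are fast template learners on the linear task and can read out
    symmetry directly on the nonlinear task (criterion within tens of
    trials); rats are slow similarity-driven template learners in both
    tasks (criterion after tens of sessions on the linear task, never on
    the nonlinear task).  Parameters are fixed cohort conventions of the
    generator, chosen to land learning speeds in the regimes the protocols
    were designed around.
    """
    if species == "human":
        if task_id == "nonlinear":
            return SymmetryOracleStrategy(lapse_rate=0.1)
        return LinearTemplateStrategy(learning_rate=0.05, choice_gain=4.0, lapse_rate=0.1)
    return LinearTemplateStrategy(learning_rate=0.001, choice_gain=4.0, lapse_rate=0.1)


def make_strategy(kind: str, **kwargs) -> Strategy:
    """Factory for strategies by name (used by the CLI and pipeline)."""
    table = {
        "random": RandomStrategy,
        "symmetry_oracle": SymmetryOracleStrategy,
        "linear_template": LinearTemplateStrategy,
        "pixel_similarity": PixelSimilarityStrategy,
        "region_exemplar": RegionExemplarStrategy,
    }
    try:
        return table[kind](**kwargs)
    except KeyError:
        raise ValueError(f"unknown strategy kind {kind!r}") from None


# ---------------------------------------------------------------------------
# scheduling and simulation
# ---------------------------------------------------------------------------


def schedule_block(
    pairs: Sequence[StimulusPair],
    seed: int | np.random.Generator | None = None,
    block_length: int = 12,
) -> list[tuple[StimulusPair, str]]:
    """One pseudo-randomized block: each pair equally often, sides balanced.

    Pair order and target-side assignment are randomized independently, as
    in the human protocol: with 4 pairs and a 12-trial block each pair
    appears 3x and the target is on the left in exactly 6 trials.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(pairs)
    if n == 0 or block_length % n != 0:
        raise ValueError(f"block length {block_length} is not divisible by {n} pairs")
    if block_length % 2 != 0:
        raise ValueError("block length must be even to balance target sides")
    pair_seq = list(pairs) * (block_length // n)
    rng.shuffle(pair_seq)
    sides = ["left"] * (block_length // 2) + ["right"] * (block_length // 2)
    rng.shuffle(sides)
    return list(zip(pair_seq, sides))


def mixed_pairs(task: TaskMapping) -> list[StimulusPair]:
    """All target x distractor combinations of the four base stimuli (4 pairs)."""
    base = make_base_set()
    return [StimulusPair(p, n) for p in task.targets(base) for n in task.distractors(base)]


def experiment_a_stages(task: TaskMapping) -> list[list[StimulusPair]]:
    """Staged pair introduction: initial pair, then old+new intermixed, then all pairs.

    The initial and second pair are shared between tasks (first and second
    row of the design); for the nonlinear task the second pair's target is
    the linear rule's non-target, which is what produces the below-chance
    transfer signature.
    """
    pairs = {p.id: p for p in mixed_pairs(task)}
    base = make_base_set()
    tgt, dst = task.targets(base), task.distractors(base)
    first = StimulusPair(tgt[0], dst[0])
    second = StimulusPair(tgt[1], dst[1])
    assert first.id in pairs and second.id in pairs
    return [[first], [first, second], list(pairs.values())]


def _trial_stream(pairs, protocol, rng, n_trials):
    """Yield (pair, side) from consecutive pseudo-random blocks, truncated."""
    out: list[tuple[StimulusPair, str]] = []
    while len(out) < n_trials:
        out.extend(schedule_block(pairs, rng, protocol.block_length))
    return out[:n_trials]


def simulate_subject(
    strategy: Strategy,
    task: TaskMapping,
    protocol: Protocol,
    seed: int | None = 0,
    pairs: Sequence[StimulusPair] | None = None,
    stages: Sequence[Sequence[StimulusPair]] | None = None,
    geometry: StimulusGeometry | None = None,
    subject: int = 0,
) -> SimulatedSubject:
    """Run one subject to criterion or cap; returns the full trial log.

    ``stages`` (a list of pair lists) expresses staged designs: each stage
    runs until its criterion is met, then the next pair set is introduced;
    the final stage ends the run.  Correction trials (rat protocol) are
    flagged and excluded from all accuracy computations.
    """
    geometry = geometry or StimulusGeometry()
    if stages is None:
        stages = [list(pairs) if pairs is not None else mixed_pairs(task)]
    rng = np.random.default_rng(seed)
    images: dict[str, np.ndarray] = {}
    for stage_pairs in stages:
        for p in stage_pairs:
            for cfg in (p.positive, p.negative):
                images.setdefault(cfg.id, render(cfg, geometry).pixels)

    records: list[TrialRecord] = []
    stage_boundaries: list[int] = []
    criterion_reached = False
    criterion_point: int | None = None

    if protocol.species == "rat":
        session = 0
        for stage_idx, stage_pairs in enumerate(stages):
            protocol.validate_block(len(stage_pairs))
            stage_boundaries.append(session + 1)
            stage_done = False
            consecutive = 0
            while session < protocol.max_sessions and not stage_done:
                session += 1
                sched = _trial_stream(stage_pairs, protocol, rng, protocol.session_size)
                n_correct = 0
                trial_no = sum(1 for r in records if not r.correction_trial)
                for pair, side in sched:
                    correct, n_corr = _run_trial(
                        records, strategy, pair, side, images, rng,
                        subject, session, stage_idx, protocol, trial_counter=trial_no,
                    )
                    trial_no += 1
                    n_correct += int(correct)
                acc = n_correct / protocol.session_size
                consecutive = consecutive + 1 if acc > protocol.criterion_accuracy else 0
                if consecutive >= protocol.criterion_sessions:
                    stage_done = True
            if not stage_done:
                break
            if stage_idx == len(stages) - 1:
                criterion_reached = True
                criterion_point = session
    else:  # human: one continuous trial stream per stage
        trial = 0
        for stage_idx, stage_pairs in enumerate(stages):
            protocol.validate_block(len(stage_pairs))
            stage_boundaries.append(trial + 1)
            stage_done = False
            recent: list[bool] = []
            stage_start = trial
            while trial - stage_start < protocol.max_trials and not stage_done:
                sched = _trial_stream(stage_pairs, protocol, rng, protocol.block_length)
                for pair, side in sched:
                    correct, _ = _run_trial(
                        records, strategy, pair, side, images, rng,
                        subject, 0, stage_idx, protocol, trial_counter=trial,
                    )
                    trial += 1
                    recent.append(correct)
                    if len(recent) >= protocol.criterion_window:
                        window = recent[-protocol.criterion_window :]
                        if np.mean(window) > protocol.criterion_accuracy:
                            stage_done = True
                            break
                    if trial - stage_start >= protocol.max_trials:
                        break
            if not stage_done:
                break
            if stage_idx == len(stages) - 1:
                criterion_reached = True
                criterion_point = trial
    return SimulatedSubject(subject, records, criterion_reached, criterion_point, stage_boundaries)


def _run_trial(records, strategy, pair, side, images, rng, subject, session,
               stage, protocol, trial_counter):
    """One scheduled trial plus any correction trials; returns first-try outcome."""
    img_t = images[pair.positive.id]
    img_d = images[pair.negative.id]
    img_left, img_right = (img_t, img_d) if side == "left" else (img_d, img_t)
    chosen = strategy.choose(img_left, img_right, rng)
    correct = chosen == side
    records.append(
        TrialRecord(subject, session, trial_counter + 1, pair.id, side, chosen,
                    correct, correction_trial=False, stage=stage)
    )
    strategy.update(img_t, img_d, correct, rng)
    n_corr = 0
    if protocol.correction_trials and not correct:
        fixed = correct
        while not fixed and n_corr < protocol.max_corrections:
            n_corr += 1
            chosen = strategy.choose(img_left, img_right, rng)
            fixed = chosen == side
            records.append(
                TrialRecord(subject, session, trial_counter + 1, pair.id, side,
                            chosen, fixed, correction_trial=True, stage=stage)
            )
            strategy.update(img_t, img_d, fixed, rng)
    return correct, n_corr


def simulate_cohort(
    strategy_factory,
    task: TaskMapping,
    protocol: Protocol,
    n_subjects: int,
    seed: int = 0,
    stages: Sequence[Sequence[StimulusPair]] | None = None,
    pairs: Sequence[StimulusPair] | None = None,
    geometry: StimulusGeometry | None = None,
) -> list[SimulatedSubject]:
    """Simulate ``n_subjects`` independent subjects (seed + index each).

    ``strategy_factory`` is called once per subject so learned state is not
    shared across subjects.
    """
    return [
        simulate_subject(
            strategy_factory(), task, protocol, seed=seed + i, subject=i,
            stages=stages, pairs=pairs, geometry=geometry,
        )
        for i in range(n_subjects)
    ]


# ---------------------------------------------------------------------------
# criterion
# ---------------------------------------------------------------------------


def session_accuracies(records: Iterable[TrialRecord] | pd.DataFrame) -> pd.Series:
    """Non-correction accuracy per session index (rat logs)."""
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df = df[~df["correction_trial"]]
    return df.groupby("session")["correct"].mean()


def apply_criterion(records: Iterable[TrialRecord] | pd.DataFrame,
                    protocol: Protocol) -> int | None:
    """Find the criterion point in a trial log, or None.

    Human rule: the first trial at which the running mean of the last
    ``criterion_window`` non-correction trials exceeds the threshold
    (undefined before a full window has elapsed).  Rat rule: the first
    session s such that sessions s-1 and s both exceed the threshold.
    Returns a 1-based trial (human) or session (rat) index.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df = df[~df["correction_trial"]]
    if df.empty:
        return None
    if protocol.species == "human":
        vals = df["correct"].to_numpy(dtype=float)
        w = protocol.criterion_window
        if len(vals) < w:
            return None
        means = np.convolve(vals, np.ones(w) / w, mode="valid")
        hits = np.nonzero(means > protocol.criterion_accuracy)[0]
        return int(hits[0] + w) if hits.size else None
    acc = session_accuracies(df)
    above = (acc > protocol.criterion_accuracy).to_numpy()
    sessions = acc.index.to_numpy()
    need = protocol.criterion_sessions
    run = 0
    for i, ok in enumerate(above):
        run = run + 1 if ok else 0
        if run >= need:
            return int(sessions[i])
    return None
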