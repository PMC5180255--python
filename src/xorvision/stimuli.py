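"""Cross-arm stimulus grammar, rendering, task mappings and pixel dissimilarity.

Each stimulus is a vertical central arm with a horizontal arm on the left and
on the right side, positioned near the top or the bottom edge.  Two
stimulus-response mappings are defined on the four base figures:

* **linear task** — target iff the *right* arm sits at the top; solvable from
  a single local cue (a linear template over pixels).
* **nonlinear task** — target iff left and right arms agree (the figure is
  mirror-symmetric); an XOR of the two arm heights, not linearly separable
  in pixel space.

A single-arm add/remove edit operator generates the manipulated stimulus set
used for template (classification-image style) analysis.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterable, Literal

import numpy as np

__all__ = [
    "Occupancy",
    "StimulusConfig",
    "StimulusGeometry",
    "StimulusImage",
    "TaskMapping",
    "StimulusPair",
    "make_base_set",
    "render",
    "pixel_distance",
    "enumerate_manipulations",
    "build_manipulated_pairs",
    "class_distance_summary",
    "linear_task",
    "nonlinear_task",
]


class Occupancy(str, Enum):
    """Horizontal-arm occupancy of one side: which vertical slots hold an arm."""

    TOP = "top"
    BOTTOM = "bottom"
    BOTH = "both"
    NONE = "none"

    @property
    def slots(self) -> frozenset[str]:
        return {
            Occupancy.TOP: frozenset({"top"}),
            Occupancy.BOTTOM: frozenset({"bottom"}),
            Occupancy.BOTH: frozenset({"top", "bottom"}),
            Occupancy.NONE: frozenset(),
        }[self]

    @staticmethod
    def from_slots(slots: frozenset[str]) -> "Occupancy":
        for occ in Occupancy:
            if occ.slots == slots:
                return occ
        raise ValueError(f"no occupancy for slots {slots!r}")


@dataclass(frozen=True, order=True)
class StimulusConfig:
    """Symbolic description of one stimulus: per-side horizontal-arm occupancy.

    The central vertical arm is always present and is never edited by the
    manipulation operator.
    """

    left_arm: Occupancy
    right_arm: Occupancy

    def __post_init__(self) -> None:
        object.__setattr__(self, "left_arm", Occupancy(self.left_arm))
        object.__setattr__(self, "right_arm", Occupancy(self.right_arm))

    @property
    def is_base(self) -> bool:
        """True for the four original stimuli: exactly one arm per side."""
        single = (Occupancy.TOP, Occupancy.BOTTOM)
        return self.left_arm in single and self.right_arm in single

    @property
    def is_symmetric(self) -> bool:
        """Mirror symmetry about the vertical midline."""
        return self.left_arm == self.right_arm

    @property
    def id(self) -> str:
        return f"L{self.left_arm.value}-R{self.right_arm.value}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.id


@dataclass(frozen=True)
class StimulusGeometry:
    """Canvas and arm metrics in visual degrees plus the raster scale.

    Defaults reproduce the study display: a 61.92 x 69.98 deg canvas with a
    17.06 deg-wide central arm.  Horizontal arms are as thick as the central
    arm, run from the central arm's edge to the lateral canvas edge, and sit
    flush with the top/bottom edge.  ``pixels_per_degree`` controls raster
    resolution (2 px/deg -> a 124 x 140 px image).
    """

    total_width: float = 61.92
    total_height: float = 69.98
    central_arm_width: float = 17.06
    pixels_per_degree: float = 2.0
    horizontal_arm_thickness: float = 17.06
    horizontal_arm_length: float | None = None  # None -> to the canvas edge
    arm_vertical_offset: float = 0.0  # degrees inward from the top/bottom edge
    luminance_cd_m2: float = 124.0  # recorded display metadata only

    def __post_init__(self) -> None:
        if self.pixels_per_degree <= 0:
            raise ValueError("pixels_per_degree must be positive")
        if not self.central_arm_width < self.total_width:
            raise ValueError("central arm must be narrower than the canvas")
        flank = (self.total_width - self.central_arm_width) / 2.0
        length = self.horizontal_arm_length
        if length is not None and not 0 < length <= flank:
            raise ValueError("horizontal arms must fit between the central arm and the canvas edge")
        if self.arm_vertical_offset + self.horizontal_arm_thickness > self.total_height / 2.0:
            raise ValueError("horizontal arms must stay within their half of the canvas")

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) of the rendered raster."""
        return (
            int(round(self.total_height * self.pixels_per_degree)),
            int(round(self.total_width * self.pixels_per_degree)),
        )

    def _px_x(self, deg: float) -> int:
        return int(round(deg * self.pixels_per_degree))

    def _px_y(self, deg: float) -> int:
        return int(round(deg * self.pixels_per_degree))


@dataclass(frozen=True)
class StimulusImage:
    """Binary raster (white = 1, black = 0) with its provenance."""

    pixels: np.ndarray
    source_config: StimulusConfig
    geometry: StimulusGeometry

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if not np.isin(px, (0, 1)).all():
            raise ValueError("stimulus images must be binary (0/1)")
        object.__setattr__(self, "pixels", px.astype(np.uint8))


TaskId = Literal["linear", "nonlinear"]


@dataclass(frozen=True)
class TaskMapping:
    """Assignment of stimuli to target / distractor under one task rule."""

    task_id: TaskId

    def class_of(self, config: StimulusConfig) -> str:
        if self.task_id == "linear":
            return "target" if config.right_arm == Occupancy.TOP else "distractor"
        return "target" if config.is_symmetric else "distractor"

    def targets(self, configs: Iterable[StimulusConfig]) -> list[StimulusConfig]:
        return [c for c in configs if self.class_of(c) == "target"]

    def distractors(self, configs: Iterable[StimulusConfig]) -> list[StimulusConfig]:
        return [c for c in configs if self.class_of(c) == "distractor"]


linear_task = TaskMapping("linear")
nonlinear_task = TaskMapping("nonlinear")


@dataclass(frozen=True)
class StimulusPair:
    """A target/distractor pair as shown on screen."""

    positive: StimulusConfig
    negative: StimulusConfig

    @property
    def id(self) -> str:
        return f"{self.positive.id}|{self.negative.id}"


def make_base_set() -> list[StimulusConfig]:
    """The four base stimuli: {top, bottom} x {top, bottom} arm placements."""
    single = (Occupancy.TOP, Occupancy.BOTTOM)
    return [StimulusConfig(l, r) for l, r in itertools.product(single, single)]


def _arm_rows(geometry: StimulusGeometry, slot: str) -> tuple[int, int]:
    rows, _ = geometry.shape
    t = geometry._px_y(geometry.horizontal_arm_thickness)
    off = geometry._px_y(geometry.arm_vertical_offset)
    if slot == "top":
        return off, off + t
    return rows - off - t, rows - off


def render(config: StimulusConfig, geometry: StimulusGeometry | None = None) -> StimulusImage:
    """Rasterize a stimulus config to a binary image (white figure on black).

    The central vertical arm spans the full canvas height; each occupied slot
    adds a horizontal arm from the central arm's edge outward.  Rendering is
    the union of the bars and is deterministic.
    """
    geometry = geometry or StimulusGeometry()
    rows, cols = geometry.shape
    px = np.zeros((rows, cols), dtype=np.uint8)

    flank_deg = (geometry.total_width - geometry.central_arm_width) / 2.0
    c0 = geometry._px_x(flank_deg)
    c1 = geometry._px_x(flank_deg + geometry.central_arm_width)
    px[:, c0:c1] = 1  # central arm, full height

    length = geometry.horizontal_arm_length
    arm_px = geometry._px_x(length) if length is not None else c0
    for side, occ in (("left", config.left_arm), ("right", config.right_arm)):
        for slot in sorted(occ.slots):
            r0, r1 = _arm_rows(geometry, slot)
            if side == "left":
                px[r0:r1, c0 - arm_px : c0] = 1
            else:
                px[r0:r1, c1 : c1 + arm_px] = 1
    return StimulusImage(px, config, geometry)


def pixel_distance(img_i: StimulusImage | np.ndarray, img_j: StimulusImage | np.ndarray) -> float:
    """Normalized pixel-wise squared distance, sum((p_i - p_j)^2) / n.

    ``n`` is the total pixel count, so the value lies in [0, 1] for binary
    images (1 = opposite corners of the n-dimensional hypercube).
    """
    a = img_i.pixels if isinstance(img_i, StimulusImage) else np.asarray(img_i)
    b = img_j.pixels if isinstance(img_j, StimulusImage) else np.asarray(img_j)
    if a.shape != b.shape:
        raise ValueError(f"image dimensions differ: {a.shape} vs {b.shape}")
    diff = a.astype(np.float64) - b.astype(np.float64)
    return float((diff**2).sum() / diff.size)


def enumerate_manipulations(config: StimulusConfig) -> set[StimulusConfig]:
    """All configs one single-arm edit away from a base stimulus.

    The four edits: remove the existing left arm, remove the existing right
    arm, add the missing left slot, add the missing right slot.  The central
    arm is never touched.
    """
    if not config.is_base:
        raise ValueError("manipulations are defined on base stimuli only")
    out: set[StimulusConfig] = set()
    for side in ("left_arm", "right_arm"):
        occ: Occupancy = getattr(config, side)
        present = occ.slots
        all_slots = frozenset({"top", "bottom"})
        edits = [present - {s} for s in present] + [present | {s} for s in all_slots - present]
        for new_slots in edits:
            kwargs = {
                "left_arm": config.left_arm,
                "right_arm": config.right_arm,
                side: Occupancy.from_slots(frozenset(new_slots)),
            }
            out.add(StimulusConfig(**kwargs))
    out.discard(config)
    return out


def manipulated_classes(task: TaskMapping = linear_task) -> tuple[list[StimulusConfig], list[StimulusConfig]]:
    """Unique manipulated positives and negatives for a task (sorted for stable ids)."""
    base = make_base_set()
    pos: set[StimulusConfig] = set()
    neg: set[StimulusConfig] = set()
    for c in task.targets(base):
        pos |= enumerate_manipulations(c)
    for c in task.distractors(base):
        neg |= enumerate_manipulations(c)
    return sorted(pos), sorted(neg)


def build_manipulated_pairs(task: TaskMapping = linear_task) -> list[StimulusPair]:
    """Manipulated positives x negatives, dropping pairs of identical stimuli.

    For the linear task this is the 6 x 6 = 36 raw combinations of which 4
    pair a stimulus with itself, leaving 32 analysis pairs.
    """
    pos, neg = manipulated_classes(task)
    return [StimulusPair(p, n) for p, n in itertools.product(pos, neg) if p != n]


def class_distance_summary(
    task: TaskMapping,
    metric: Callable[[StimulusImage, StimulusImage], float] | None = None,
    configs: Iterable[StimulusConfig] | None = None,
    geometry: StimulusGeometry | None = None,
    images: dict[StimulusConfig, object] | None = None,
) -> tuple[float, float]:
    """Mean within-class and between-class dissimilarity under a task mapping.

    Returns ``(within, between)`` where *within* averages the metric over
    unordered same-class pairs (i != j) and *between* over cross-class pairs.
    ``images`` may supply precomputed per-config objects (e.g. model response
    vectors) on which ``metric`` operates; otherwise configs are rendered.
    """
    metric = metric or pixel_distance
    configs = list(configs) if configs is not None else make_base_set()
    if images is None:
        images = {c: render(c, geometry) for c in configs}
    tgt = task.targets(configs)
    dst = task.distractors(configs)
    if len(tgt) < 2 or len(dst) < 2:
        raise ValueError("each class needs at least 2 stimuli for a within-class mean")
    within = [metric(images[a], images[b]) for grp in (tgt, dst) for a, b in itertools.combinations(grp, 2)]
    between = [metric(images[a], images[b]) for a in tgt for b in dst]
    return float(np.mean(within)), float(np.mean(between))
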