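"""Stimulus-scene geometry, balanced stimulus-set enumeration and session scheduling.

The display shows an avatar portrait at screen center surrounded by 12
drawn objects (hands and houses) arranged in four linear arrays of three
objects each.  Arrays lie at fixed angles on placement circles centred
on the avatar's nasion; an object's position is fully determined by the
circle radius, the array angle on the circle, and the anterior distance
of the circle's plane from the nasion.  Radius and distance are coupled
through a right triangle at the nasion with a fixed tangent, so that the
avatar's gaze vector toward any object of an array passes (nearly)
through all three of its objects - which is what makes the spoken
category cue necessary to disambiguate the target.

Conditions:

``unambiguous``
    the spoken word names a category with exactly one exemplar on the
    gazed-at array (one candidate target),
``ambiguous_informative``
    the word names a category with two exemplars (two candidates),
``ambiguous_uninformative``
    the word is "none" (three candidates).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConstraintViolationError, InvalidGeometryError

#: Array angles on the placement circle, degrees clockwise from the
#: upward vertical as seen by the observer.
ARRAY_ANGLES: tuple[float, ...] = (120.0, 150.0, 210.0, 240.0)

#: The two lower visual hemifields spanned by the arrays.
RIGHT_HEMIFIELD: tuple[float, float] = (120.0, 150.0)
LEFT_HEMIFIELD: tuple[float, float] = (210.0, 240.0)

#: Circle radii (virtual mm) per array angle, slot 0 (near) to 2 (far).
#: The 120/240 arrays use smaller radii than 150/210 so the layout
#: exploits the full screen width.
DEFAULT_RADII: Mapping[float, tuple[int, int, int]] = {
    120.0: (335, 480, 580),
    240.0: (335, 480, 580),
    150.0: (380, 510, 590),
    210.0: (380, 510, 590),
}

#: Fixed tangent of the nasion right triangle linking radius and
#: anterior distance.
DEFAULT_TAN_ALPHA: float = 0.268

#: Anterior distances as printed in the study's stimulus table.  Five of
#: the six agree with round(radius * 0.268); radius 580 is printed as
#: 151 although the formula gives 155.  Both values are exposed and
#: neither is silently "fixed": pass ``use_printed_distances=True`` to
#: reproduce the printed table verbatim.
PRINTED_DISTANCES: Mapping[int, int] = {
    335: 90,
    480: 129,
    580: 151,  # formula value: round(580 * 0.268) = 155
    380: 102,
    510: 137,
    590: 158,
}

CATEGORIES = ("hand", "house")
CONDITIONS = ("unambiguous", "ambiguous_informative", "ambiguous_uninformative")

#: Degrees of visual angle per virtual mm used when projecting object
#: positions to the observer's screen (nasion at screen centre).
DEG_PER_VIRTUAL_MM: float = 0.02


def _round_half_away(x: float) -> int:
    """Round half away from zero, matching the printed integer distances."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


@dataclass(frozen=True)
class ObjectSpec:
    """One placed object: category plus full placement geometry."""

    category: str
    array_angle: float
    circle_radius: float
    anterior_distance: int
    planar_position: tuple[float, float]
    slot: int


@dataclass(frozen=True)
class SceneLayout:
    """The 12-object scene around the avatar.

    Objects are ordered by array (120, 150, 210, 240 degrees) and, within
    an array, by slot from near to far, so object index = 3 * array_index
    + slot.
    """

    objects: tuple[ObjectSpec, ...]
    avatar_origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    tan_alpha: float = DEFAULT_TAN_ALPHA

    def positions(self) -> np.ndarray:
        """(12, 2) planar positions in virtual mm."""
        return np.array([o.planar_position for o in self.objects])

    def positions_deg(self, deg_per_mm: float = DEG_PER_VIRTUAL_MM) -> np.ndarray:
        """(12, 2) object positions in degrees of visual angle on screen."""
        return self.positions() * deg_per_mm

    def array_of(self, index: int) -> float:
        return self.objects[index].array_angle

    def array_members(self, array_angle: float) -> list[int]:
        return [i for i, o in enumerate(self.objects) if o.array_angle == array_angle]

    def array_composition(self, array_angle: float) -> tuple[int, int]:
        """(n_hands, n_houses) on one array."""
        cats = [self.objects[i].category for i in self.array_members(array_angle)]
        return cats.count("hand"), cats.count("house")


@dataclass(frozen=True)
class StimulusSet:
    """A realizable trial stimulus: layout, target and instruction."""

    layout: SceneLayout
    target_index: int
    condition: str
    instruction_word: str

    @property
    def target_category(self) -> str:
        return self.layout.objects[self.target_index].category

    @property
    def target_array(self) -> float:
        return self.layout.objects[self.target_index].array_angle


@dataclass
class SessionSchedule:
    """An ordered 180-trial session of six 30-trial blocks."""

    trials: list[StimulusSet]
    block_boundaries: list[int]
    rng_seed: int

    def blocks(self) -> list[list[StimulusSet]]:
        bounds = [0] + self.block_boundaries
        return [self.trials[a:b] for a, b in zip(bounds[:-1], bounds[1:])]


def place_object(
    array_angle: float,
    circle_radius: float,
    tan_alpha: float = DEFAULT_TAN_ALPHA,
    *,
    category: str = "hand",
    slot: int = 0,
    use_printed_distances: bool = False,
) -> ObjectSpec:
    """Place one object from its array angle, circle radius and the fixed tangent.

    The anterior distance is the adjacent leg of a right triangle at the
    avatar's nasion whose opposite leg is the circle radius, hence
    ``round(radius * tan_alpha)``.  The planar position is measured with
    0 degrees at the upward vertical, increasing clockwise.
    """
    if circle_radius <= 0:
        raise InvalidGeometryError(f"circle_radius must be positive, got {circle_radius}")
    if tan_alpha < 0:
        raise InvalidGeometryError(f"tan_alpha must be non-negative, got {tan_alpha}")
    if use_printed_distances and int(circle_radius) in PRINTED_DISTANCES:
        distance = PRINTED_DISTANCES[int(circle_radius)]
    else:
        distance = _round_half_away(circle_radius * tan_alpha)
    theta = math.radians(array_angle)
    planar = (circle_radius * math.sin(theta), circle_radius * math.cos(theta))
    return ObjectSpec(
        category=category,
        array_angle=float(array_angle),
        circle_radius=float(circle_radius),
        anterior_distance=distance,
        planar_position=planar,
        slot=int(slot),
    )


def _validate_compositions(array_compositions: Mapping[float, tuple[int, int]]) -> None:
    if set(array_compositions) != set(ARRAY_ANGLES):
        raise ConstraintViolationError(
            f"compositions must cover arrays {ARRAY_ANGLES}, got {sorted(array_compositions)}"
        )
    for angle, (n_hands, n_houses) in array_compositions.items():
        if sorted((n_hands, n_houses)) != [1, 2]:
            raise ConstraintViolationError(
                f"array {angle} must hold two hands and one house or one hand "
                f"and two houses, got {(n_hands, n_houses)}"
            )
    for hemi in (RIGHT_HEMIFIELD, LEFT_HEMIFIELD):
        hands = sum(array_compositions[a][0] for a in hemi)
        if hands != 3:
            raise ConstraintViolationError(
                f"hemifield {hemi} must hold exactly 3 hands (and 3 houses), got {hands} hands"
            )


def build_scene(
    array_compositions: Mapping[float, tuple[int, int]],
    object_order: Optional[Mapping[float, Sequence[str]]] = None,
    tan_alpha: float = DEFAULT_TAN_ALPHA,
    *,
    radii: Mapping[float, tuple[int, int, int]] = DEFAULT_RADII,
    use_printed_distances: bool = False,
) -> SceneLayout:
    """Build a full 12-object scene from per-array category compositions.

    ``array_compositions`` maps array angle to (n_hands, n_houses); each
    array must hold {2 hands, 1 house} or {1 hand, 2 houses} and each
    hemifield exactly 3 hands and 3 houses.  ``object_order`` optionally
    fixes the category-to-slot assignment per array (a sequence of three
    category names from near to far); the default puts hands on the
    nearer slots.
    """
    _validate_compositions(array_compositions)
    objects: list[ObjectSpec] = []
    for angle in ARRAY_ANGLES:
        n_hands, n_houses = array_compositions[angle]
        if object_order is not None and angle in object_order:
            cats = list(object_order[angle])
            if cats.count("hand") != n_hands or cats.count("house") != n_houses:
                raise ConstraintViolationError(
                    f"object_order for array {angle} ({cats}) does not match "
                    f"composition {(n_hands, n_houses)}"
                )
        else:
            cats = ["hand"] * n_hands + ["house"] * n_houses
        for slot, (radius, cat) in enumerate(zip(radii[angle], cats)):
            objects.append(
                place_object(
                    angle,
                    radius,
                    tan_alpha,
                    category=cat,
                    slot=slot,
                    use_printed_distances=use_printed_distances,
                )
            )
    return SceneLayout(objects=tuple(objects), tan_alpha=tan_alpha)


def candidate_count(condition: str, target_array_composition: tuple[int, int]) -> int:
    """Number of candidate targets left after the spoken instruction.

    An unambiguous word singles out one object, an ambiguous-informative
    word leaves the two exemplars of its category, and an uninformative
    word removes nothing from the three objects the gaze vector hits.
    """
    if sorted(target_array_composition) != [1, 2]:
        raise ConstraintViolationError(
            f"invalid array composition {target_array_composition}"
        )
    if condition == "unambiguous":
        return 1
    if condition == "ambiguous_informative":
        return 2
    if condition == "ambiguous_uninformative":
        return 3
    raise ValueError(f"unknown condition {condition!r}")


def _complement(category: str) -> str:
    return "house" if category == "hand" else "hand"


def realize_stimulus_set(
    condition: str,
    target_category: str,
    target_position: int,
    *,
    tan_alpha: float = DEFAULT_TAN_ALPHA,
    use_printed_distances: bool = False,
) -> StimulusSet:
    """Construct a concrete scene realizing one (condition, category, position) cell.

    The target array's composition follows from the condition: the
    target category has one exemplar under ``unambiguous`` and two under
    the ambiguous conditions; the same-hemifield partner array takes the
    complementary composition and the opposite hemifield a canonical
    balanced pair, so all scene invariants hold by construction.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if target_category not in CATEGORIES:
        raise ValueError(f"unknown category {target_category!r}")
    if not 0 <= target_position < 12:
        raise ValueError("target_position must be in 0..11")
    array_idx, slot = divmod(target_position, 3)
    target_angle = ARRAY_ANGLES[array_idx]
    n_target_cat = 1 if condition == "unambiguous" else 2
    comp_target = (
        (n_target_cat, 3 - n_target_cat)
        if target_category == "hand"
        else (3 - n_target_cat, n_target_cat)
    )
    hemi = RIGHT_HEMIFIELD if target_angle in RIGHT_HEMIFIELD else LEFT_HEMIFIELD
    other_hemi = LEFT_HEMIFIELD if hemi is RIGHT_HEMIFIELD else RIGHT_HEMIFIELD
    partner_angle = hemi[0] if hemi[1] == target_angle else hemi[1]
    compositions = {
        target_angle: comp_target,
        partner_angle: (3 - comp_target[0], 3 - comp_target[1]),
        other_hemi[0]: (2, 1),
        other_hemi[1]: (1, 2),
    }
    # Category-to-slot order on the target array: target category at the
    # target slot, remaining exemplars on the first free slots.
    n_tc = comp_target[0] if target_category == "hand" else comp_target[1]
    order = [None] * 3
    order[slot] = target_category
    remaining_tc = n_tc - 1
    for s in range(3):
        if order[s] is None:
            if remaining_tc > 0:
                order[s] = target_category
                remaining_tc -= 1
            else:
                order[s] = _complement(target_category)
    layout = build_scene(
        compositions,
        object_order={target_angle: order},
        tan_alpha=tan_alpha,
        use_printed_distances=use_printed_distances,
    )
    instruction = target_category if condition != "ambiguous_uninformative" else "none"
    return StimulusSet(
        layout=layout,
        target_index=target_position,
        condition=condition,
        instruction_word=instruction,
    )


def enumerate_stimulus_sets(
    *,
    conditions: Sequence[str] = CONDITIONS,
    categories: Sequence[str] = CATEGORIES,
    positions: Sequence[int] = tuple(range(12)),
    tan_alpha: float = DEFAULT_TAN_ALPHA,
) -> list[StimulusSet]:
    """Enumerate the full balanced cross of category x condition x position.

    With the defaults (2 categories, 3 conditions, 12 positions) this
    yields 72 stimulus sets, each realized as a concrete scene.
    """
    sets = []
    for condition in conditions:
        for category in categories:
            for position in positions:
                sets.append(
                    realize_stimulus_set(condition, category, position, tan_alpha=tan_alpha)
                )
    return sets


def check_stimulus_set(s: StimulusSet) -> None:
    """Raise ConstraintViolationError unless all stimulus-set invariants hold."""
    _validate_compositions(
        {a: s.layout.array_composition(a) for a in ARRAY_ANGLES}
    )
    comp = s.layout.array_composition(s.target_array)
    members = s.layout.array_members(s.target_array)
    n_target_cat = sum(
        1 for i in members if s.layout.objects[i].category == s.target_category
    )
    if s.condition == "unambiguous":
        if s.instruction_word != s.target_category or n_target_cat != 1:
            raise ConstraintViolationError("unambiguous set must name a 1-exemplar category")
    elif s.condition == "ambiguous_informative":
        if s.instruction_word != s.target_category or n_target_cat != 2:
            raise ConstraintViolationError(
                "ambiguous_informative set must name a 2-exemplar category"
            )
    elif s.condition == "ambiguous_uninformative":
        if s.instruction_word != "none":
            raise ConstraintViolationError("ambiguous_uninformative instruction must be 'none'")
    else:
        raise ConstraintViolationError(f"unknown condition {s.condition!r}")
    candidate_count(s.condition, comp)


def schedule_session(
    sets: Sequence[StimulusSet],
    rng_seed: int,
    *,
    n_blocks: int = 6,
    trials_per_block: int = 30,
    max_tries: int = 10_000,
) -> SessionSchedule:
    """Schedule a session: every stimulus set twice plus balanced residual draws.

    The 72 enumerated sets appear twice each (144 trials); the residual
    36 trials are drawn pseudo-randomly (rejection sampling under a
    seeded generator) so that target-category, condition and position
    counts stay balanced.  Trials are then arranged into ``n_blocks``
    blocks with exactly ``trials_per_block / len(conditions)`` trials per
    condition per block.
    """
    rng = np.random.default_rng(rng_seed)
    conditions = sorted({s.condition for s in sets})
    n_total = n_blocks * trials_per_block
    n_residual = n_total - 2 * len(sets)
    if n_residual < 0 or trials_per_block % len(conditions) != 0:
        raise ConstraintViolationError(
            f"{n_blocks} x {trials_per_block} trials cannot host {len(sets)} sets "
            f"twice with balanced conditions"
        )
    by_key = {(s.condition, s.target_category, s.target_index): s for s in sets}
    positions = sorted({s.target_index for s in sets})
    trials: list[StimulusSet] = [s for s in sets for _ in range(2)]
    if n_residual:
        # One residual trial per (position, condition); categories drawn
        # by rejection until globally balanced.
        assert n_residual == len(positions) * len(conditions), (
            "residual draw expects one trial per position x condition"
        )
        target_hands = n_residual // 2
        for _ in range(max_tries):
            cats = rng.choice(CATEGORIES, size=n_residual)
            if np.sum(cats == "hand") == target_hands:
                break
        else:  # pragma: no cover - astronomically unlikely
            raise ConstraintViolationError("residual draw failed to balance categories")
        k = 0
        for pos in positions:
            for cond in conditions:
                trials.append(by_key[(cond, str(cats[k]), pos)])
                k += 1
    # Per-condition balanced assignment to blocks, then within-block shuffle.
    per_block = trials_per_block // len(conditions)
    pools = {c: [t for t in trials if t.condition == c] for c in conditions}
    for c in conditions:
        rng.shuffle(pools[c])
    ordered: list[StimulusSet] = []
    for b in range(n_blocks):
        block = []
        for c in conditions:
            block.extend(pools[c][b * per_block : (b + 1) * per_block])
        order = rng.permutation(len(block))
        ordered.extend(block[i] for i in order)
    boundaries = [trials_per_block * (b + 1) for b in range(n_blocks)]
    return SessionSchedule(trials=ordered, block_boundaries=boundaries, rng_seed=rng_seed)


def schedule_to_frame(schedule: SessionSchedule) -> pd.DataFrame:
    """Tabulate a schedule, one row per trial with per-object columns."""
    rows = []
    bounds = [0] + schedule.block_boundaries
    for block_idx, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
        for trial_idx, s in enumerate(schedule.trials[a:b]):
            row = {
                "block": block_idx,
                "trial": trial_idx,
                "condition": s.condition,
                "instruction_word": s.instruction_word,
                "target_index": s.target_index,
                "target_category": s.target_category,
            }
            for i, o in enumerate(s.layout.objects):
                row[f"obj{i}_category"] = o.category
                row[f"obj{i}_angle"] = o.array_angle
                row[f"obj{i}_radius"] = o.circle_radius
                row[f"obj{i}_distance"] = o.anterior_distance
            rows.append(row)
    return pd.DataFrame(rows)


def schedule_to_tsv(schedule: SessionSchedule, path) -> None:
    schedule_to_frame(schedule).to_csv(path, sep="\t", index=False)


def schedule_from_frame(df: pd.DataFrame, rng_seed: int = -1) -> SessionSchedule:
    """Rebuild a SessionSchedule from its tabulated form (inverse of
    :func:`schedule_to_frame`)."""
    trials = []
    boundaries = []
    for _, row in df.iterrows():
        objects = []
        for i in range(12):
            angle = float(row[f"obj{i}_angle"])
            radius = float(row[f"obj{i}_radius"])
            theta = math.radians(angle)
            objects.append(
                ObjectSpec(
                    category=str(row[f"obj{i}_category"]),
                    array_angle=angle,
                    circle_radius=radius,
                    anterior_distance=int(row[f"obj{i}_distance"]),
                    planar_position=(radius * math.sin(theta), radius * math.cos(theta)),
                    slot=i % 3,
                )
            )
        trials.append(
            StimulusSet(
                layout=SceneLayout(objects=tuple(objects)),
                target_index=int(row["target_index"]),
                condition=str(row["condition"]),
                instruction_word=str(row["instruction_word"]),
            )
        )
    counts = df.groupby("block").size()
    acc = 0
    for b in sorted(counts.index):
        acc += int(counts[b])
        boundaries.append(acc)
    return SessionSchedule(trials=trials, block_boundaries=boundaries, rng_seed=rng_seed)


def geometry_config(tan_alpha: float = DEFAULT_TAN_ALPHA) -> dict:
    """JSON-serializable record of the scene geometry parameters."""
    return {
        "tan_alpha": tan_alpha,
        "array_angles": list(ARRAY_ANGLES),
        "radii": {str(int(a)): list(r) for a, r in DEFAULT_RADII.items()},
        "printed_distances": {str(k): v for k, v in PRINTED_DISTANCES.items()},
        "deg_per_virtual_mm": DEG_PER_VIRTUAL_MM,
    }


def write_geometry_config(path, tan_alpha: float = DEFAULT_TAN_ALPHA) -> None:
    with open(path, "w") as fh:
        json.dump(geometry_config(tan_alpha), fh, indent=2)
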