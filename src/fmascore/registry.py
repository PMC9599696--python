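"""Registry of the 30 voluntary FMA-UE items and their 17 motion tasks.

The Fugl-Meyer Assessment for the upper extremity (FMA-UE) contains 33
items scored 0/1/2.  The three reflex items (1, 2 and 18) need externally
applied forces and are excluded here, leaving 30 voluntary items grouped
into four categories:

* Shoulder/Elbow   — 13 items (3-13, 15, 16), skeleton-tracked, scored by
  random-forest classifiers on kinematic features;
* Wrist/Hand       —  9 items (14, 17, 19-25), hand-tracked, rule-based;
* Grasp            —  5 items (26-30), instrumented grip tools, rule-based;
* Coordination/Speed — 3 items (31-33), skeleton-tracked finger-to-nose,
  rule-based.

Several scale items share one recorded motion (items 3-11 are all parsed
from motion I; 13 and 16 from the single 0-180 deg shoulder-flexion motion
III; the wrist items 19/20 and 21/22 each share a recording), and items 14
and 17 are composites of a positioning motion and a pronation/supination
motion.  Seventeen distinct motion tasks cover all 30 items.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

from .exceptions import LookupFMAError

# Categories
SHOULDER_ELBOW = "ShoulderElbow"
WRIST_HAND = "WristHand"
GRASP = "Grasp"
COORDINATION_SPEED = "CoordinationSpeed"

CATEGORIES = (SHOULDER_ELBOW, WRIST_HAND, GRASP, COORDINATION_SPEED)

#: the 17 motion tasks
MOTION_CODES = (
    "I", "II", "III", "IV", "V",
    "VI90", "VI0", "VII90", "VII0", "VIII", "IX",
    "X", "XI", "XII", "XIII", "XIV", "XV",
)

#: which sensor stream records each motion
MOTION_KIND = {
    "I": "skeleton", "II": "skeleton", "III": "skeleton", "IV": "skeleton",
    "V": "skeleton", "XV": "skeleton",
    "VI90": "hand", "VI0": "hand", "VII90": "hand", "VII0": "hand",
    "VIII": "hand", "IX": "hand",
    "X": "grasp", "XI": "grasp", "XII": "grasp", "XIII": "grasp",
    "XIV": "grasp",
}

#: instrumented tool per grasp motion
GRASP_TOOLS = {
    "X": "hook",
    "XI": "thumb_adduction",
    "XII": "pincer",
    "XIII": "cylinder",
    "XIV": "sphere",
}


@dataclass(frozen=True)
class ItemSpec:
    """One voluntary FMA-UE item and how the system measures it."""

    item_id: int
    label: str
    category: str
    motions: tuple[str, ...]
    sensors: frozenset[str]
    method: str                       # "RF" | "RB"
    prerequisite_kind: str = "none"   # none | reach_initial_position | point_to_nose
    merged_with: int | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sensors"] = sorted(self.sensors)
        d["motions"] = list(self.motions)
        return d


def _se(item_id, label, motion):
    return ItemSpec(item_id, label, SHOULDER_ELBOW, (motion,),
                    frozenset({"skeleton"}), "RF")


def _grasp(item_id, label, motion):
    return ItemSpec(item_id, label, GRASP, (motion,),
                    frozenset({"force"}), "RB")


_ITEMS: tuple[ItemSpec, ...] = (
    _se(3, "Shoulder elevation", "I"),
    _se(4, "Shoulder retraction", "I"),
    _se(5, "Shoulder abduction (90 deg)", "I"),
    _se(6, "Shoulder external rotation", "I"),
    _se(7, "Elbow flexion", "I"),
    _se(8, "Forearm supination", "I"),
    _se(9, "Shoulder adduction/internal rotation", "I"),
    _se(10, "Elbow extension", "I"),
    _se(11, "Forearm pronation", "I"),
    _se(12, "Hand to lumbar spine", "II"),
    _se(13, "Shoulder flexion 0-90 deg", "III"),
    ItemSpec(14, "Forearm pronation-supination, elbow at 90 deg", WRIST_HAND,
             ("IV", "VI90"), frozenset({"skeleton", "hand"}), "RB",
             prerequisite_kind="reach_initial_position"),
    _se(15, "Shoulder abduction 0-90 deg", "V"),
    _se(16, "Shoulder flexion 90-180 deg", "III"),
    ItemSpec(17, "Forearm pronation-supination, elbow at 0 deg", WRIST_HAND,
             ("III", "VI0"), frozenset({"skeleton", "hand"}), "RB",
             prerequisite_kind="reach_initial_position"),
    ItemSpec(19, "Wrist stability at 15 deg dorsiflexion, elbow 90 deg",
             WRIST_HAND, ("VII90",), frozenset({"hand"}), "RB",
             merged_with=20),
    ItemSpec(20, "Repeated dorsiflexion/volar flexion, elbow 90 deg",
             WRIST_HAND, ("VII90",), frozenset({"hand"}), "RB",
             merged_with=19),
    ItemSpec(21, "Wrist stability at 15 deg dorsiflexion, elbow 0 deg",
             WRIST_HAND, ("VII0",), frozenset({"hand"}), "RB",
             merged_with=22),
    ItemSpec(22, "Repeated dorsiflexion/volar flexion, elbow 0 deg",
             WRIST_HAND, ("VII0",), frozenset({"hand"}), "RB",
             merged_with=21),
    ItemSpec(23, "Wrist circumduction", WRIST_HAND, ("VIII",),
             frozenset({"hand"}), "RB"),
    ItemSpec(24, "Mass flexion", WRIST_HAND, ("IX",),
             frozenset({"hand"}), "RB"),
    ItemSpec(25, "Mass extension", WRIST_HAND, ("IX",),
             frozenset({"hand"}), "RB"),
    _grasp(26, "Hook grasp", "X"),
    _grasp(27, "Thumb adduction", "XI"),
    _grasp(28, "Pincer grasp", "XII"),
    _grasp(29, "Cylinder grasp", "XIII"),
    _grasp(30, "Sphere grasp", "XIV"),
    ItemSpec(31, "Tremor", COORDINATION_SPEED, ("XV",),
             frozenset({"skeleton"}), "RB"),
    ItemSpec(32, "Dysmetria", COORDINATION_SPEED, ("XV",),
             frozenset({"skeleton"}), "RB"),
    ItemSpec(33, "Time", COORDINATION_SPEED, ("XV",),
             frozenset({"skeleton"}), "RB",
             prerequisite_kind="point_to_nose"),
)

ITEM_IDS = tuple(spec.item_id for spec in _ITEMS)
RF_ITEM_IDS = tuple(s.item_id for s in _ITEMS if s.method == "RF")
RB_ITEM_IDS = tuple(s.item_id for s in _ITEMS if s.method == "RB")

#: maximum total over the 30 voluntary items
MAX_TOTAL = 2 * len(_ITEMS)


def build_registry() -> list[ItemSpec]:
    """Return the full validated registry of the 30 voluntary items."""
    _validate(_ITEMS)
    return list(_ITEMS)


def get_item(item_id: int) -> ItemSpec:
    for spec in _ITEMS:
        if spec.item_id == item_id:
            return spec
    raise LookupFMAError(f"unknown FMA item id: {item_id}")


def items_for_motion(motion_code: str) -> list[ItemSpec]:
    """All items (partly) measured from one motion task."""
    if motion_code not in MOTION_CODES:
        raise LookupFMAError(f"unknown motion code: {motion_code!r}")
    return [s for s in _ITEMS if motion_code in s.motions]


def rf_motion_for_item(item_id: int) -> str:
    """The skeleton motion whose feature vector feeds an RF-scored item."""
    spec = get_item(item_id)
    if spec.method != "RF":
        raise LookupFMAError(f"item {item_id} is not RF-scored")
    return spec.motions[0]


def registry_to_json(path=None) -> str:
    """Export the registry as JSON (one object per item)."""
    payload = json.dumps([s.to_dict() for s in build_registry()], indent=2)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(payload)
    return payload


def _validate(items) -> None:
    ids = [s.item_id for s in items]
    assert len(items) == 30, "registry must hold exactly 30 items"
    assert len(set(ids)) == 30
    assert set(ids) == (set(range(3, 18)) | set(range(19, 34))), \
        "reflex items 1, 2, 18 must be absent"
    assert sum(s.method == "RF" for s in items) == 13
    motions = {m for s in items for m in s.motions}
    assert motions == set(MOTION_CODES) and len(motions) == 17
    counts = {c: sum(s.category == c for s in items) for c in CATEGORIES}
    assert counts == {SHOULDER_ELBOW: 13, WRIST_HAND: 9, GRASP: 5,
                      COORDINATION_SPEED: 3}
    assert all(len(s.sensors) >= 1 for s in items)
    assert all(s.method in ("RF", "RB") for s in items)
    prereq = {s.item_id for s in items if s.prerequisite_kind != "none"}
    assert prereq == {14, 17, 33}


_validate(_ITEMS)
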