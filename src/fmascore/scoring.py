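"""Per-item 0/1/2 scoring.

Two scoring layers mirror the clinical scale's structure:

* the 13 Shoulder/Elbow items are predicted by per-item random-forest
  classifiers (100 trees, 6 features considered per split) trained on
  the 36-entry kinematic feature vectors with therapist scores as
  labels;
* the 17 Wrist/Hand, Grasp and Coordination/Speed items use an
  IF-ELSEIF-ELSE rule: the paretic-side feature is compared with a
  reference (the subject's own less-affected side, subscript h, or the
  cohort normal constant, subscript N) and the performance ratio is cut
  at lambda1 = 1/3 and lambda2 = 2/3 into three equal divisions.  Items
  14, 17 and 33 additionally require a prerequisite (reaching the
  start position, or touching the nose); an unmet prerequisite scores 0.

Score-1 band is [lambda1, lambda2), score 2 is [lambda2, inf), so a
performance ratio of exactly 1 is unambiguously a 2.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .exceptions import ParameterError, ValidationError
from .features import SHOULDER_ELBOW_FEATURES
from .registry import (CATEGORIES, ITEM_IDS, MAX_TOTAL, RB_ITEM_IDS,
                       RF_ITEM_IDS, build_registry, get_item,
                       rf_motion_for_item)

LAMBDA1 = 1.0 / 3.0
LAMBDA2 = 2.0 / 3.0

#: fraction of the less-affected reference that counts as "reached the
#: initial position" (items 14/17)
PREREQ_POSITION_FRACTION = LAMBDA2
#: wrist-nose distance (m) below which "point to the nose" counts as
#: met (an accurate fingertip touch leaves the wrist roughly a
#: hand-length from the nose, so the cut sits well above that)
NOSE_REACH_THRESHOLD_M = 0.25


@dataclass(frozen=True)
class RuleSpec:
    """One sub-rule of a rule-based item."""

    item_id: int
    feature: str
    reference_mode: str               # "h" | "N"
    direction: str                    # "higher_better" | "lower_better"
    lambda1: float = LAMBDA1
    lambda2: float = LAMBDA2

    def __post_init__(self):
        if not 0 < self.lambda1 < self.lambda2 < 1:
            raise ParameterError(
                f"need 0 < lambda1 < lambda2 < 1, got "
                f"{self.lambda1}, {self.lambda2}")
        if self.reference_mode not in ("h", "N"):
            raise ParameterError(
                f"reference_mode must be h/N, got {self.reference_mode!r}")
        if self.direction not in ("higher_better", "lower_better"):
            raise ParameterError(f"bad direction {self.direction!r}")


@dataclass(frozen=True)
class ItemRule:
    """Full rule model of one item: sub-rules (minimum combined), an
    optional prerequisite and the per-finger model flag (items 24/25)."""

    item_id: int
    subrules: tuple[RuleSpec, ...]
    prerequisite_kind: str = "none"
    prerequisite_feature: str | None = None
    finger_model: bool = False
    finger_template: str | None = None


def load_rules(lambda1: float = LAMBDA1,
               lambda2: float = LAMBDA2) -> dict[int, ItemRule]:
    """Load the per-item rule bindings shipped with the package."""
    raw = json.loads(
        resources.files("fmascore.data").joinpath("rules.json").read_text())
    rules: dict[int, ItemRule] = {}
    for entry in raw["items"]:
        item_id = entry["item_id"]
        prereq = entry.get("prerequisite", {})
        if entry.get("finger_model"):
            tmpl = entry["finger_feature_template"]
            subrules = tuple(
                RuleSpec(item_id, tmpl.format(i=i), entry["reference"],
                         entry["direction"], lambda1, lambda2)
                for i in range(1, 5))
            rules[item_id] = ItemRule(
                item_id, subrules, finger_model=True, finger_template=tmpl)
        else:
            subrules = tuple(
                RuleSpec(item_id, r["feature"], r["reference"],
                         r["direction"], lambda1, lambda2)
                for r in entry["rules"])
            rules[item_id] = ItemRule(
                item_id, subrules,
                prerequisite_kind=prereq.get("kind", "none"),
                prerequisite_feature=prereq.get("feature"))
    missing = set(RB_ITEM_IDS) - set(rules)
    if missing:
        raise ValidationError(f"rules file lacks items {sorted(missing)}")
    return rules


def apply_rule(x_p: float, reference: float, rule: RuleSpec,
               prerequisite_met: bool = True) -> int:
    """Score one feature against its reference on the 0/1/2 scale."""
    if not prerequisite_met:
        return 0
    if rule.direction == "higher_better":
        if reference <= 0:
            raise ValidationError(
                f"item {rule.item_id}: non-positive reference "
                f"{reference} for higher_better rule")
        ratio = x_p / reference
    else:
        if x_p <= 0:          # no residual at all: perfect performance
            return 2
        ratio = reference / x_p
    if ratio < rule.lambda1:
        return 0
    if ratio < rule.lambda2:
        return 1
    return 2


def score_mass_flexion_extension(item_id: int, finger_values_p: dict,
                                 references: dict,
                                 lambda1: float = LAMBDA1,
                                 lambda2: float = LAMBDA2) -> int:
    """Items 24/25: score each finger 0/1/2, then feed the 4-finger
    total (0-8) through the same three-way rule with reference 8."""
    if item_id not in (24, 25):
        raise ValidationError("finger model applies to items 24/25 only")
    rules = load_rules(lambda1, lambda2)[item_id]
    total = 0
    for sub in rules.subrules:
        if sub.feature not in finger_values_p:
            raise ValidationError(
                f"item {item_id}: missing finger feature {sub.feature!r}")
        total += apply_rule(finger_values_p[sub.feature],
                            references[sub.feature], sub)
    final = RuleSpec(item_id, "finger_total", "N", "higher_better",
                     lambda1, lambda2)
    return apply_rule(float(total), 8.0, final)


def _prerequisite_met(rule: ItemRule, paretic: dict, less_affected: dict,
                      nose_reach_threshold_m: float,
                      lambda2: float) -> bool:
    if rule.prerequisite_kind == "none":
        return True
    feat = rule.prerequisite_feature
    if feat not in paretic:
        raise ValidationError(
            f"item {rule.item_id}: missing prerequisite feature {feat!r}")
    if rule.prerequisite_kind == "reach_initial_position":
        return paretic[feat] >= lambda2 * less_affected[feat]
    if rule.prerequisite_kind == "point_to_nose":
        return paretic[feat] <= nose_reach_threshold_m
    raise ValidationError(
        f"unknown prerequisite kind {rule.prerequisite_kind!r}")


def score_rb_item(item_id: int, paretic_features: dict,
                  less_affected_features: dict,
                  normal_refs: dict | None = None, *,
                  lambda1: float = LAMBDA1, lambda2: float = LAMBDA2,
                  nose_reach_threshold_m: float = NOSE_REACH_THRESHOLD_M,
                  rules: dict[int, ItemRule] | None = None) -> int:
    """Score one rule-based item from per-side feature dictionaries
    (keys ``"<motion>:<feature>"``)."""
    if get_item(item_id).method != "RB":
        raise ValidationError(f"item {item_id} is not rule-based")
    rules = rules if rules is not None else load_rules(lambda1, lambda2)
    rule = rules[item_id]
    if rule.finger_model:
        keys = [s.feature for s in rule.subrules]
        return score_mass_flexion_extension(
            item_id, {k: paretic_features[k] for k in keys},
            {k: less_affected_features[k] for k in keys}, lambda1, lambda2)
    if not _prerequisite_met(rule, paretic_features, less_affected_features,
                             nose_reach_threshold_m, lambda2):
        return 0
    scores = []
    for sub in rule.subrules:
        if sub.feature not in paretic_features:
            raise ValidationError(
                f"item {item_id}: missing paretic feature {sub.feature!r}")
        if sub.reference_mode == "h":
            if sub.feature not in less_affected_features:
                raise ValidationError(
                    f"item {item_id}: missing less-affected reference "
                    f"{sub.feature!r}")
            ref = less_affected_features[sub.feature]
        else:
            if normal_refs is None or sub.feature not in normal_refs:
                raise ValidationError(
                    f"item {item_id}: missing normal reference "
                    f"{sub.feature!r}")
            ref = normal_refs[sub.feature]
        scores.append(apply_rule(paretic_features[sub.feature], ref, sub))
    return min(scores)


# ---------------------------------------------------------------------------
# random-forest layer

@dataclass(frozen=True)
class RFConfig:
    """Random-forest hyperparameters: number of trees and features
    considered at each split."""

    n_trees: int = 100
    f: int = 6
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1:
            raise ParameterError("n_trees must be >= 1")
        if not 1 <= self.f <= len(SHOULDER_ELBOW_FEATURES):
            raise ParameterError(
                f"f must be in [1, {len(SHOULDER_ELBOW_FEATURES)}]")


class ConstantClassifier:
    """Fallback when an item's training labels hold a single class."""

    def __init__(self, value: int):
        self.value = int(value)

    def predict(self, X) -> np.ndarray:
        return np.full(len(X), self.value, dtype=int)


def vectorize_features(feature_map: dict) -> np.ndarray:
    """Order a 36-entry Shoulder/Elbow feature dict canonically."""
    missing = [k for k in SHOULDER_ELBOW_FEATURES if k not in feature_map]
    if missing:
        raise ValidationError(f"feature vector missing {missing[:3]}...")
    return np.array([feature_map[k] for k in SHOULDER_ELBOW_FEATURES],
                    dtype=float)


@dataclass
class SubjectFeatures:
    """Everything scoring needs about one subject: the paretic-side
    36-feature vectors per skeleton motion (RF input), the rule-feature
    dictionaries per side, and optional reference scores (labels)."""

    subject_id: str
    rf: dict = field(default_factory=dict)        # motion -> 36-feature dict
    rb_paretic: dict = field(default_factory=dict)
    rb_less_affected: dict = field(default_factory=dict)
    reference_scores: dict | None = None

    @property
    def reference_total(self) -> int:
        if not self.reference_scores:
            raise ValidationError(
                f"{self.subject_id}: no reference scores present")
        return int(sum(self.reference_scores.values()))


def fit_rf_items(cohort: list[SubjectFeatures],
                 config: RFConfig = RFConfig()) -> dict:
    """Fit the 13 per-item Shoulder/Elbow classifiers on a cohort with
    reference scores; reproducible given the seed."""
    if len(cohort) < 2:
        raise ValidationError("fit_rf_items needs >= 2 training subjects")
    models: dict[int, object] = {}
    for item_id in RF_ITEM_IDS:
        motion = rf_motion_for_item(item_id)
        X = np.stack([vectorize_features(s.rf[motion]) for s in cohort])
        y = np.array([s.reference_scores[item_id] for s in cohort], dtype=int)
        if len(np.unique(y)) < 2:
            warnings.warn(
                f"item {item_id}: single-class training labels "
                f"({y[0]}); using a constant classifier", stacklevel=2)
            models[item_id] = ConstantClassifier(y[0])
            continue
        clf = RandomForestClassifier(
            n_estimators=config.n_trees, max_features=config.f,
            random_state=config.seed + item_id)
        clf.fit(X, y)
        models[item_id] = clf
    return models


def predict_rf_items(models: dict, feats: SubjectFeatures) -> dict[int, int]:
    out = {}
    for item_id, model in models.items():
        x = vectorize_features(feats.rf[rf_motion_for_item(item_id)])
        out[item_id] = int(model.predict(x[None, :])[0])
    return out


# ---------------------------------------------------------------------------
# reports and cohort protocols

@dataclass
class ScoreReport:
    """Per-item 0/1/2 scores for one subject, with totals."""

    subject_id: str
    scores: dict                      # item_id -> 0/1/2
    seed: int | None = None

    def __post_init__(self):
        if set(self.scores) != set(ITEM_IDS):
            raise ValidationError(
                f"{self.subject_id}: report must cover all 30 items")
        if any(v not in (0, 1, 2) for v in self.scores.values()):
            raise ValidationError(f"{self.subject_id}: scores must be 0/1/2")

    @property
    def total(self) -> int:
        t = int(sum(self.scores.values()))
        assert 0 <= t <= MAX_TOTAL
        return t

    @property
    def category_subtotals(self) -> dict:
        reg = {s.item_id: s.category for s in build_registry()}
        out = {c: 0 for c in CATEGORIES}
        for item_id, score in self.scores.items():
            out[reg[item_id]] += score
        return out

    def to_dict(self) -> dict:
        return {"subject_id": self.subject_id,
                "scores": {str(k): int(v)
                           for k, v in sorted(self.scores.items())},
                "category_subtotals": self.category_subtotals,
                "total": self.total,
                "seed": self.seed}


def normal_references(cohort: list[SubjectFeatures],
                      exclude_subject: str | None = None) -> dict:
    """Cohort normal constants: mean of all subjects' less-affected-side
    rule features (optionally excluding one held-out subject)."""
    rows = [s.rb_less_affected for s in cohort
            if s.subject_id != exclude_subject]
    if not rows:
        raise ValidationError("normal_references: empty cohort")
    keys = set(rows[0])
    for r in rows[1:]:
        keys &= set(r)
    return {k: float(np.mean([r[k] for r in rows])) for k in keys}


def score_subject(feats: SubjectFeatures, rf_models: dict,
                  normal_refs: dict, *,
                  lambda1: float = LAMBDA1, lambda2: float = LAMBDA2,
                  nose_reach_threshold_m: float = NOSE_REACH_THRESHOLD_M,
                  seed: int | None = None,
                  rules: dict[int, ItemRule] | None = None) -> ScoreReport:
    """Assemble one subject's full 30-item report."""
    rules = rules if rules is not None else load_rules(lambda1, lambda2)
    scores = predict_rf_items(rf_models, feats)
    for item_id in RB_ITEM_IDS:
        scores[item_id] = score_rb_item(
            item_id, feats.rb_paretic, feats.rb_less_affected, normal_refs,
            lambda1=lambda1, lambda2=lambda2,
            nose_reach_threshold_m=nose_reach_threshold_m, rules=rules)
    return ScoreReport(feats.subject_id, scores, seed=seed)


def loocv_scores(cohort: list[SubjectFeatures],
                 rf_config: RFConfig = RFConfig(), *,
                 lambda1: float = LAMBDA1, lambda2: float = LAMBDA2,
                 nose_reach_threshold_m: float = NOSE_REACH_THRESHOLD_M
                 ) -> list[ScoreReport]:
    """Leave-one-subject-out protocol: each subject's RF items are
    predicted by classifiers trained on everyone else; the normal
    constants for N-referenced rules likewise exclude the held-out
    subject."""
    if len(cohort) < 3:
        raise ValidationError("loocv needs a cohort of >= 3 subjects")
    rules = load_rules(lambda1, lambda2)
    reports = []
    for held_out in cohort:
        train = [s for s in cohort if s.subject_id != held_out.subject_id]
        models = fit_rf_items(train, rf_config)
        refs = normal_references(cohort, exclude_subject=held_out.subject_id)
        reports.append(score_subject(
            held_out, models, refs, lambda1=lambda1, lambda2=lambda2,
            nose_reach_threshold_m=nose_reach_threshold_m,
            seed=rf_config.seed, rules=rules))
    return reports


def online_split(cohort: list) -> tuple[list, list]:
    """Simulated-online protocol: rank subjects ascending by reference
    total (ties broken by subject id); odd ranks form the training set,
    even ranks the test set."""
    if len(cohort) % 2 != 0 or len(cohort) == 0:
        raise ParameterError(
            "online_split needs a non-empty even-sized cohort")
    ranked = sorted(cohort,
                    key=lambda s: (s.reference_total, s.subject_id))
    return ranked[0::2], ranked[1::2]
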