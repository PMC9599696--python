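"""End-to-end orchestration: recordings -> features -> scores.

For each subject the pipeline SSA-filters every recording, segments the
skeleton motions on the (filtered) wrist speed, extracts the 36-entry
Shoulder/Elbow vectors for the random-forest layer (averaged over the
two repetitions of motions I/II/III/V) and the per-motion scalar
features for the rule layer, then scores the cohort under the
leave-one-subject-out or simulated-online protocol.

Segmentation always runs on the default (L=15, k=2) SSA output, whose
residual noise is small enough for a stable speed threshold; motion XV's
features are then computed from the k=6 reconstruction of the same
segment so tremor is preserved.
"""

from __future__ import annotations

import numpy as np

from .config import PipelineConfig
from .exceptions import ValidationError
from .features import (coordination_features, grasp_features, hand_features,
                       shoulder_elbow_vector)
from .io import SubjectRecord
from .preprocess import (endpoint_speed, segment_motion, ssa_filter_hand,
                         ssa_filter_skeleton)
from .registry import MOTION_KIND
from .scoring import (ScoreReport, SubjectFeatures, fit_rf_items,
                      loocv_scores, normal_references, online_split,
                      score_subject)

_RF_MOTIONS = ("I", "II", "III", "V")
_SKELETON_RF = ("I", "II", "III", "IV", "V")


def _body_side(record: SubjectRecord, side: str) -> str:
    if side == "paretic":
        return record.paretic_side
    return "right" if record.paretic_side == "left" else "left"


def _sparc_kwargs(config: PipelineConfig) -> dict:
    return {"sparc_cutoff_hz": config.sparc_cutoff_hz,
            "sparc_amp_threshold": config.sparc_amp_threshold}


def _skeleton_vector(seq, body_side: str, config: PipelineConfig) -> dict:
    filt = ssa_filter_skeleton(seq, config.ssa)
    seg = segment_motion(endpoint_speed(filt, f"wrist_{body_side[0]}"))
    return shoulder_elbow_vector(filt, seg, body_side,
                                 **_sparc_kwargs(config))


def _coordination(seq, body_side: str, config: PipelineConfig) -> dict:
    # segmentation, wrist-nose distance and time want the smooth trend;
    # only the smoothness metric needs the tremor-preserving
    # reconstruction
    base = ssa_filter_skeleton(seq, config.ssa)
    seg = segment_motion(endpoint_speed(base, f"wrist_{body_side[0]}"))
    detail = ssa_filter_skeleton(seq, config.ssa_for("XV"))
    out = coordination_features(
        base, seg, body_side,
        cutoff_hz=config.sparc_cutoff_hz,
        amp_threshold=config.sparc_amp_threshold)
    sal = coordination_features(
        detail, seg, body_side,
        cutoff_hz=config.sparc_cutoff_hz,
        amp_threshold=config.sparc_amp_threshold)
    out["sparc"] = sal["sparc"]
    out["sparc_magnitude"] = sal["sparc_magnitude"]
    return out


def extract_subject_features(record: SubjectRecord,
                             config: PipelineConfig = PipelineConfig()
                             ) -> SubjectFeatures:
    """All feature inputs scoring needs for one subject."""
    feats = SubjectFeatures(record.subject_id,
                            reference_scores=record.reference_scores)
    for motion, sides in record.recordings.items():
        kind = MOTION_KIND[motion]
        if kind == "skeleton" and motion in _RF_MOTIONS:
            reps = [_skeleton_vector(seq, _body_side(record, "paretic"),
                                     config)
                    for seq in sides["paretic"]]
            feats.rf[motion] = {k: float(np.mean([r[k] for r in reps]))
                                for k in reps[0]}
        elif kind == "skeleton" and motion == "XV":
            for side, store in (("paretic", feats.rb_paretic),
                                ("less_affected", feats.rb_less_affected)):
                vals = _coordination(sides[side][0],
                                     _body_side(record, side), config)
                for k, v in vals.items():
                    store[f"{motion}:{k}"] = v
        elif kind == "hand":
            for side, store in (("paretic", feats.rb_paretic),
                                ("less_affected", feats.rb_less_affected)):
                filt = ssa_filter_hand(sides[side][0], config.ssa)
                for k, v in hand_features(filt).items():
                    store[f"{motion}:{k}"] = v
        elif kind == "grasp":
            for side, store in (("paretic", feats.rb_paretic),
                                ("less_affected", feats.rb_less_affected)):
                for k, v in grasp_features(sides[side][0]).items():
                    store[f"{motion}:{k}"] = v
        # skeleton motion IV is recorded for completeness but item 14 is
        # scored from the hand stream, so no features are taken from it
    return feats


def extract_cohort_features(records: list[SubjectRecord],
                            config: PipelineConfig = PipelineConfig()
                            ) -> list[SubjectFeatures]:
    return [extract_subject_features(r, config) for r in records]


def score_cohort_loocv(records: list[SubjectRecord],
                       config: PipelineConfig = PipelineConfig()
                       ) -> list[ScoreReport]:
    """Leave-one-subject-out scoring of a cohort of raw recordings."""
    cohort = extract_cohort_features(records, config)
    return loocv_scores(cohort, config.rf, lambda1=config.lambda1,
                        lambda2=config.lambda2,
                        nose_reach_threshold_m=config.nose_reach_threshold_m)


def score_cohort_online(records: list[SubjectRecord],
                        config: PipelineConfig = PipelineConfig()
                        ) -> tuple[list[ScoreReport], list[str]]:
    """Simulated-online protocol: rank by reference total, train the RF
    layer on every other subject, score the held-out half.  Returns the
    test-set reports plus the training subject ids."""
    cohort = extract_cohort_features(records, config)
    train, test = online_split(cohort)
    models = fit_rf_items(train, config.rf)
    refs = normal_references(train)
    reports = [score_subject(s, models, refs, lambda1=config.lambda1,
                             lambda2=config.lambda2,
                             nose_reach_threshold_m=(
                                 config.nose_reach_threshold_m),
                             seed=config.rf.seed)
               for s in test]
    return reports, [s.subject_id for s in train]


def rb_scores_only(records: list[SubjectRecord],
                   config: PipelineConfig = PipelineConfig()
                   ) -> list[dict]:
    """Rule-based item scores for a cohort (no RF layer); useful when
    only the Wrist/Hand, Grasp and Coordination motions were recorded."""
    from .scoring import RB_ITEM_IDS, load_rules, score_rb_item

    cohort = extract_cohort_features(records, config)
    rules = load_rules(config.lambda1, config.lambda2)
    out = []
    for feats in cohort:
        refs = normal_references(cohort, exclude_subject=feats.subject_id)
        out.append({item: score_rb_item(
            item, feats.rb_paretic, feats.rb_less_affected, refs,
            lambda1=config.lambda1, lambda2=config.lambda2,
            nose_reach_threshold_m=config.nose_reach_threshold_m,
            rules=rules) for item in RB_ITEM_IDS})
    return out
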