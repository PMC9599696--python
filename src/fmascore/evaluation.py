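"""Agreement metrics between system and reference scores, and the
two-stage sample-size utility for Pearson-correlation study designs.

Per-item accuracy is the percentage of exact matches and MAE the mean
absolute score difference.  The pooled 3x3 confusion matrix over all
(subject, item) pairs yields linear-weighted Cohen's kappa and the
macro-averaged F1, precision, sensitivity and specificity; classes
absent from the reference are excluded from the macro averages.
Segment aggregates (random-forest part, rule-based part, all items)
are unweighted means over the items in each segment, with macro
metrics recomputed from each segment's pooled confusion matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import cohen_kappa_score, confusion_matrix

from .exceptions import DegenerateInputError, ParameterError, ValidationError
from .registry import ITEM_IDS, RF_ITEM_IDS

CLASSES = (0, 1, 2)


def pearson_total_correlation(system_totals, reference_totals
                              ) -> tuple[float, float]:
    """Sample Pearson r between total scores with a two-sided p-value."""
    x = np.asarray(system_totals, dtype=float)
    y = np.asarray(reference_totals, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValidationError(
            "need two equal-length total-score vectors, n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateInputError("correlation undefined for constant totals")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def weighted_kappa(scores_a, scores_b, weights: str = "linear") -> float:
    """Chance-corrected agreement for paired ordinal 0/1/2 scores with
    linear disagreement weights."""
    a = np.asarray(scores_a, dtype=int)
    b = np.asarray(scores_b, dtype=int)
    if a.shape != b.shape or a.ndim != 1 or len(a) == 0:
        raise ValidationError("need two equal-length non-empty score vectors")
    if not (set(a) | set(b)) <= set(CLASSES):
        raise ValidationError("scores must lie in {0, 1, 2}")
    if np.array_equal(a, b) and len(set(a)) == 1:
        return 1.0          # degenerate margins, perfect agreement
    return float(cohen_kappa_score(a, b, labels=list(CLASSES),
                                   weights=weights))


def _macro_metrics(cm: np.ndarray) -> dict:
    """Macro F1/precision/sensitivity/specificity (%) from a confusion
    matrix with reference on rows; classes absent from the reference
    rows are excluded from the averages."""
    present = np.nonzero(cm.sum(axis=1) > 0)[0]
    total = cm.sum()
    precs, senss, specs, f1s = [], [], [], []
    for c in present:
        tp = cm[c, c]
        fn = cm[c].sum() - tp
        fp = cm[:, c].sum() - tp
        tn = total - tp - fn - fp
        prec = tp / (tp + fp) if tp + fp > 0 else 0.0
        sens = tp / (tp + fn)
        spec = tn / (tn + fp) if tn + fp > 0 else 0.0
        f1 = 2 * prec * sens / (prec + sens) if prec + sens > 0 else 0.0
        precs.append(prec)
        senss.append(sens)
        specs.append(spec)
        f1s.append(f1)
    return {"f1": 100 * float(np.mean(f1s)),
            "precision": 100 * float(np.mean(precs)),
            "sensitivity": 100 * float(np.mean(senss)),
            "specificity": 100 * float(np.mean(specs))}


@dataclass
class CohortEvaluation:
    """Agreement between system and reference scores for one cohort."""

    n_subjects: int
    pearson_r: float
    pearson_p: float
    kappa_linear: float
    confusion: np.ndarray             # 3x3, reference rows, system columns
    item_accuracy: dict               # item_id -> %
    item_mae: dict                    # item_id -> points
    segments: dict = field(default_factory=dict)
    # segments[name] = {accuracy, mae, f1, precision, sensitivity, specificity}

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "pearson_r": self.pearson_r,
            "pearson_p": self.pearson_p,
            "kappa_linear": self.kappa_linear,
            "confusion": self.confusion.tolist(),
            "item_accuracy": {str(k): v
                              for k, v in sorted(self.item_accuracy.items())},
            "item_mae": {str(k): v for k, v in sorted(self.item_mae.items())},
            "segments": self.segments,
        }


def item_metrics(predicted: list[dict], reference: list[dict]
                 ) -> CohortEvaluation:
    """Evaluate paired per-subject score dictionaries (item_id -> 0/1/2)
    covering all 30 items."""
    if len(predicted) != len(reference) or not predicted:
        raise ValidationError("predicted/reference cohort size mismatch")
    for p, r in zip(predicted, reference):
        if set(p) != set(ITEM_IDS) or set(r) != set(ITEM_IDS):
            raise ValidationError(
                "every subject needs scores for all 30 items")
    items = list(ITEM_IDS)
    pred = np.array([[p[i] for i in items] for p in predicted], dtype=int)
    ref = np.array([[r[i] for i in items] for r in reference], dtype=int)

    acc = {i: 100.0 * float(np.mean(pred[:, j] == ref[:, j]))
           for j, i in enumerate(items)}
    mae = {i: float(np.mean(np.abs(pred[:, j] - ref[:, j])))
           for j, i in enumerate(items)}

    cm = confusion_matrix(ref.ravel(), pred.ravel(), labels=list(CLASSES))
    kappa = weighted_kappa(ref.ravel(), pred.ravel())
    sys_tot = pred.sum(axis=1)
    ref_tot = ref.sum(axis=1)
    try:
        r, p = pearson_total_correlation(sys_tot, ref_tot)
    except (DegenerateInputError, ValidationError):
        r, p = math.nan, math.nan

    segments = {}
    seg_items = {"rf": [i for i in items if i in RF_ITEM_IDS],
                 "rb": [i for i in items if i not in RF_ITEM_IDS],
                 "all": items}
    for name, ids in seg_items.items():
        cols = [items.index(i) for i in ids]
        seg_cm = confusion_matrix(ref[:, cols].ravel(),
                                  pred[:, cols].ravel(),
                                  labels=list(CLASSES))
        seg = {"accuracy": float(np.mean([acc[i] for i in ids])),
               "mae": float(np.mean([mae[i] for i in ids]))}
        seg.update(_macro_metrics(seg_cm))
        segments[name] = seg

    return CohortEvaluation(
        n_subjects=len(predicted), pearson_r=r, pearson_p=p,
        kappa_linear=kappa, confusion=cm,
        item_accuracy=acc, item_mae=mae, segments=segments)


def sample_size_pearson_two_stage(r_planning: float, ci_width: float,
                                  alpha: float) -> int:
    """Two-stage sample-size approximation for estimating a Pearson
    correlation with a Fisher confidence interval of prescribed width.

    Stage 1 sizes the study from the large-sample Fisher-z width
    formula, ``n0 = 4 (1 - r^2)^2 (z_{1-alpha/2} / w)^2 + 3`` (rounded
    up); stage 2 back-transforms the Fisher-z interval actually achieved
    at ``n0`` to the correlation scale, giving width ``b0``, and
    corrects ``n = (n0 - 3) (b0 / w)^2 + 3`` (rounded to the nearest
    integer).  At (0.9, 0.3, 0.01) this yields 20 subjects.
    """
    if not 0 < abs(r_planning) < 1:
        raise ParameterError("planning correlation must be in (0, 1)")
    if not 0 < ci_width < 2:
        raise ParameterError("confidence-interval width must be in (0, 2)")
    if not 0 < alpha < 1:
        raise ParameterError("alpha must be in (0, 1)")
    z = stats.norm.ppf(1 - alpha / 2)
    n0 = math.ceil(4 * (1 - r_planning ** 2) ** 2 * (z / ci_width) ** 2 + 3)
    n0 = max(n0, 4)
    zr = math.atanh(r_planning)
    half = z / math.sqrt(n0 - 3)
    b0 = math.tanh(zr + half) - math.tanh(zr - half)
    n = (n0 - 3) * (b0 / ci_width) ** 2 + 3
    return max(int(math.floor(n + 0.5)), 4)
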