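"""Segmentation/detection scoring and agreement statistics.

Pixel agreement uses the dice similarity coefficient (DSC).  Object-level
detection matches predicted components to ground-truth instances one-to-one
by descending IoU: matched organoids are true positives, missed organoids
false negatives, spurious predictions false positives, and annotated
negative instances (out-of-focus distractors) with no matching prediction
true negatives.  Agreement between two measurement series is summarized by
Lin's concordance correlation coefficient (authored here, with a Fisher-z
confidence interval), Pearson's r, and ordinary least squares R².
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import stats

from .io import BinaryMask
from .postprocess import LabeledContours

__all__ = [
    "DetectionReport",
    "AgreementStats",
    "dice",
    "match_objects",
    "ccc",
    "pearson",
    "linregress_r2",
    "evaluate_set",
]


@dataclasses.dataclass
class DetectionReport:
    """Detection confusion counts and the derived rates.

    A rate with a zero denominator is ``None`` (flagged undefined) rather
    than NaN so it cannot silently propagate through aggregation.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    iou_threshold: float

    def _rate(self, num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    @property
    def sensitivity(self) -> float | None:
        return self._rate(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float | None:
        return self._rate(self.tn, self.tn + self.fp)

    @property
    def accuracy(self) -> float | None:
        total = self.tp + self.tn + self.fp + self.fn
        return self._rate(self.tp + self.tn, total)

    def __add__(self, other: "DetectionReport") -> "DetectionReport":
        if other.iou_threshold != self.iou_threshold:
            raise ValueError("cannot pool reports at different IoU thresholds")
        return DetectionReport(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn + other.fn,
            self.tn + other.tn,
            self.iou_threshold,
        )


@dataclasses.dataclass
class AgreementStats:
    """Agreement between a measured series and a reference series."""

    ccc: float
    ccc_ci: tuple[float, float]
    pearson_r: float
    pearson_p: float
    slope: float
    intercept: float
    r_squared: float


def _as_bool(mask) -> np.ndarray:
    if isinstance(mask, BinaryMask):
        return mask.pixels
    return np.asarray(mask) != 0


def dice(pred_mask, gt_mask) -> float:
    """Dice similarity coefficient 2|P∩G|/(|P|+|G|); both-empty -> 1."""
    p, g = _as_bool(pred_mask), _as_bool(gt_mask)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    denom = int(p.sum()) + int(g.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((p & g).sum()) / denom


def _iou(a: np.ndarray, b: np.ndarray) -> float:
    union = int((a | b).sum())
    return int((a & b).sum()) / union if union else 0.0


def match_objects(
    pred: LabeledContours | Sequence[np.ndarray],
    gt_positive: Sequence[np.ndarray],
    gt_negative: Sequence[np.ndarray] = (),
    iou_threshold: float = 0.5,
) -> DetectionReport:
    """Greedy one-to-one IoU matching of predictions to annotated instances.

    Parameters
    ----------
    pred
        Predicted objects: a :class:`LabeledContours` or a list of boolean
        instance masks.
    gt_positive
        Boolean masks of the true (in-focus) organoids.
    gt_negative
        Boolean masks of annotated negative instances (out-of-focus
        distractors) that a correct model should NOT detect.
    iou_threshold
        Minimum IoU for a prediction to claim an instance.

    Pairs are claimed in descending IoU, each prediction and each instance
    at most once.  Prediction–organoid pair: TP.  Unclaimed organoid: FN.
    Prediction claiming a distractor, or claiming nothing: FP.  Unclaimed
    distractor: TN.
    """
    if not (0 < iou_threshold <= 1):
        raise ValueError(f"iou_threshold must be in (0, 1], got {iou_threshold}")
    if isinstance(pred, LabeledContours):
        pred_masks = [pred.label_image == i for i in pred.ids]
    else:
        pred_masks = [_as_bool(m) for m in pred]
    instances = [(m, False) for m in gt_positive] + [(m, True) for m in gt_negative]
    pairs = []
    for i, pm in enumerate(pred_masks):
        for j, (gm, _) in enumerate(instances):
            v = _iou(pm, _as_bool(gm))
            if v >= iou_threshold:
                pairs.append((v, i, j))
    pairs.sort(reverse=True)
    used_pred: set[int] = set()
    used_inst: set[int] = set()
    tp = fp_neg = 0
    for v, i, j in pairs:
        if i in used_pred or j in used_inst:
            continue
        used_pred.add(i)
        used_inst.add(j)
        if instances[j][1]:
            fp_neg += 1  # detected a distractor
        else:
            tp += 1
    fp = fp_neg + (len(pred_masks) - len(used_pred))  # + spurious predictions
    fn = sum(
        1 for j, (_, is_neg) in enumerate(instances) if not is_neg and j not in used_inst
    )
    tn = sum(
        1 for j, (_, is_neg) in enumerate(instances) if is_neg and j not in used_inst
    )
    return DetectionReport(tp, fp, fn, tn, iou_threshold)


def ccc(x, y, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Lin's concordance correlation coefficient with a Fisher-z CI.

    rho_c = 2*s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2), with biased
    (1/n) moment estimators.  The confidence interval applies the Fisher z
    transform with Lin's asymptotic standard error and back-transforms.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("length mismatch")
    if n < 3:
        raise ValueError("need n >= 3")
    mx, my = x.mean(), y.mean()
    sx2 = ((x - mx) ** 2).mean()
    sy2 = ((y - my) ** 2).mean()
    sxy = ((x - mx) * (y - my)).mean()
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0:
        raise ValueError("undefined: both series constant with equal means")
    rho_c = 2.0 * sxy / denom
    if sx2 == 0 or sy2 == 0:
        return float(rho_c), (float("nan"), float("nan"))
    r = sxy / np.sqrt(sx2 * sy2)
    # Lin (1989) variance of z = atanh(rho_c)
    u2 = (mx - my) ** 2 / np.sqrt(sx2 * sy2)
    rc2 = rho_c**2
    with np.errstate(divide="ignore", invalid="ignore"):
        var_z = (
            (1 - r**2) * rc2 / ((1 - rc2) * r**2)
            + 2 * rho_c**3 * (1 - rho_c) * u2 / (r * (1 - rc2) ** 2)
            - rho_c**4 * u2**2 / (2 * r**2 * (1 - rc2) ** 2)
        ) / (n - 2)
    z = np.arctanh(np.clip(rho_c, -1 + 1e-15, 1 - 1e-15))
    half = stats.norm.ppf(1 - alpha / 2) * np.sqrt(max(var_z, 0.0))
    lo, hi = np.tanh(z - half), np.tanh(z + half)
    return float(rho_c), (float(lo), float(hi))


def pearson(x, y) -> tuple[float, float]:
    """Pearson's r with its two-sided t-test P-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("undefined: zero variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def linregress_r2(x, y) -> tuple[float, float, float, float]:
    """OLS fit y ~ x: returns (slope, intercept, R², two-sided P)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if x.std() == 0:
        raise ValueError("constant x: regression undefined")
    if y.std() == 0:
        # flat response: the fit is the constant, explaining none of (no) variance
        return 0.0, float(y[0]), 0.0, 1.0
    res = stats.linregress(x, y)
    return (
        float(res.slope),
        float(res.intercept),
        float(res.rvalue**2),
        float(res.pvalue),
    )


def evaluate_set(
    raw_masks: Sequence[BinaryMask | np.ndarray],
    post_masks: Sequence[BinaryMask | np.ndarray] | None,
    gt_masks: Sequence[BinaryMask | np.ndarray],
) -> dict[str, object]:
    """Per-image DSC for raw and post-processed outputs, with means.

    Cleaning can trade away a little pixel overlap for noise-free contours,
    so the two means are reported separately.
    """
    if len(raw_masks) != len(gt_masks):
        raise ValueError("length mismatch between predictions and ground truth")
    if post_masks is not None and len(post_masks) != len(gt_masks):
        raise ValueError("length mismatch between post-processed and ground truth")
    raw = [dice(p, g) for p, g in zip(raw_masks, gt_masks)]
    out: dict[str, object] = {
        "dsc_raw": raw,
        "mean_dsc_raw": float(np.mean(raw)) if raw else float("nan"),
    }
    if post_masks is not None:
        post = [dice(p, g) for p, g in zip(post_masks, gt_masks)]
        out["dsc_post"] = post
        out["mean_dsc_post"] = float(np.mean(post)) if post else float("nan")
    return out
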