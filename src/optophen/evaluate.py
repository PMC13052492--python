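"""Classifier evaluation: one-vs-rest ROC, confusion algebra, and
spatial back-projection of predictions.

AUC is computed by a threshold sweep with trapezoidal integration;
with ties grouped into single threshold steps this equals the
Mann–Whitney rank statistic U / (n+ * n-) with half credit for tied
scores.  Back-projection renders each spot as a two-ring glyph at its
mapped image coordinate — inner disc colored by the predicted class,
outer ring by the true class — so spatial error patterns are visible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import disk as _disk
from sklearn.metrics import (
    confusion_matrix as _sk_confusion,
    precision_recall_fscore_support,
    roc_curve as _sk_roc_curve,
)


@dataclass
class EvalReport:
    classes: np.ndarray
    confusion: np.ndarray                    # true x predicted counts
    per_class: pd.DataFrame                  # precision/recall/f1/support/auc
    weighted: dict
    accuracy: float
    predictions: pd.DataFrame | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.confusion.sum() == self.per_class["support"].sum()
        np.testing.assert_array_equal(
            self.confusion.sum(axis=1), self.per_class["support"].to_numpy()
        )


def ovr_roc(
    scores: np.ndarray, truth: np.ndarray, classes: np.ndarray | None = None
) -> dict:
    """One-vs-rest ROC curve and AUC per class.

    ``scores`` is (n, k) with one column per class; higher means more
    positive.  Classes with no positives or no negatives in ``truth``
    get AUC NaN (reported missing).
    """
    scores = np.asarray(scores, float)
    truth = np.asarray(truth)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if classes is None:
        classes = np.unique(truth)
    out = {}
    for j, c in enumerate(classes):
        pos = truth == c
        if pos.all() or not pos.any():
            out[c] = {"fpr": None, "tpr": None, "auc": np.nan}
            continue
        fpr, tpr, _ = _sk_roc_curve(pos.astype(int), scores[:, j])
        out[c] = {"fpr": fpr, "tpr": tpr, "auc": float(np.trapezoid(tpr, fpr))}
    return out


def confusion_and_report(
    truth: np.ndarray,
    predicted: np.ndarray,
    classes: np.ndarray | None = None,
    scores: np.ndarray | None = None,
) -> EvalReport:
    """k x k confusion counts plus precision/recall/F1 per class and
    support-weighted averages (zero-division -> 0, flagged in
    metadata).  When per-class scores are given, one-vs-rest AUC is
    included."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if len(truth) != len(predicted):
        raise ValueError("truth and predictions must align")
    if classes is None:
        classes = np.unique(np.concatenate([truth, predicted]))
    else:
        classes = np.asarray(classes)
        unknown = set(np.unique(predicted)) - set(classes)
        unknown |= set(np.unique(truth)) - set(classes)
        if unknown:
            raise ValueError(f"labels outside class set: {sorted(unknown)}")
    cm = _sk_confusion(truth, predicted, labels=classes)
    prec, rec, f1, support = precision_recall_fscore_support(
        truth, predicted, labels=classes, zero_division=0
    )
    per_class = pd.DataFrame(
        {
            "class": classes,
            "precision": prec,
            "recall": rec,
            "f1": f1,
            "support": support,
        }
    )
    if scores is not None:
        rocs = ovr_roc(scores, truth, classes)
        per_class["auc"] = [rocs[c]["auc"] for c in classes]
    wsum = support.sum()
    weighted = {
        "precision": float((prec * support).sum() / wsum),
        "recall": float((rec * support).sum() / wsum),
        "f1": float((f1 * support).sum() / wsum),
    }
    accuracy = float(np.trace(cm) / wsum)
    zero_div = bool(((cm.sum(axis=0) == 0) | (cm.sum(axis=1) == 0)).any())
    return EvalReport(
        classes=classes,
        confusion=cm,
        per_class=per_class,
        weighted=weighted,
        accuracy=accuracy,
        predictions=pd.DataFrame({"true": truth, "predicted": predicted}),
        metadata={"zero_division_encountered": zero_div},
    )


# ---------------------------------------------------------------------------
# spatial back-projection
# ---------------------------------------------------------------------------

_PALETTE = np.array(
    [
        [230, 25, 75], [60, 180, 75], [0, 130, 200], [255, 225, 25],
        [245, 130, 48], [70, 240, 240], [240, 50, 230], [128, 128, 128],
    ],
    dtype=np.uint8,
)


def class_colors(classes) -> dict:
    return {c: _PALETTE[i % len(_PALETTE)] for i, c in enumerate(classes)}


def backproject(
    predicted: np.ndarray,
    truth: np.ndarray,
    centers: np.ndarray,
    image: np.ndarray,
    which: str = "all",
    radius: int = 12,
    ring: int = 4,
) -> tuple[np.ndarray, int]:
    """Render prediction glyphs over a grayscale composite.

    ``image`` is a 2-D raster used as the background (scaled to 8-bit
    by its own range).  ``which`` selects ``all``, ``correct`` or
    ``incorrect`` spots.  Out-of-bounds centers are skipped.  Returns
    (RGB overlay, number of glyphs drawn).
    """
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    centers = np.asarray(centers, int)
    img = np.asarray(image, float)
    lo, hi = img.min(), img.max()
    gray = ((img - lo) / (hi - lo if hi > lo else 1) * 255).astype(np.uint8)
    overlay = np.stack([gray] * 3, axis=-1)

    if which == "correct":
        sel = predicted == truth
    elif which == "incorrect":
        sel = predicted != truth
    elif which == "all":
        sel = np.ones(len(predicted), bool)
    else:
        raise ValueError(f"unknown selection {which!r}")

    colors = class_colors(np.unique(np.concatenate([truth, predicted])))
    h, w = gray.shape
    n_drawn = 0
    for (cx, cy), p, t in zip(centers[sel], predicted[sel], truth[sel]):
        if not (0 <= cx < w and 0 <= cy < h):
            continue
        rr, cc = _disk((cy, cx), radius + ring, shape=gray.shape)
        overlay[rr, cc] = colors[t]          # outer ring: true class
        rr, cc = _disk((cy, cx), radius, shape=gray.shape)
        overlay[rr, cc] = colors[p]          # inner disc: predicted class
        n_drawn += 1
    return overlay, n_drawn


def roc_table(rocs: dict) -> pd.DataFrame:
    """Flatten ovr_roc output into a (class, fpr, tpr) frame for CSV export."""
    frames = []
    for c, r in rocs.items():
        if r["fpr"] is None:
            continue
        frames.append(pd.DataFrame({"class": c, "fpr": r["fpr"], "tpr": r["tpr"]}))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
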