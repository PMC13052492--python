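"""The three classifier tiers for phenotype prediction from images.

1. *Abundance SVM* — RBF support vector machine on the 5 abundance
   features;
2. *Texture SVM* — the same machine on 70 features (abundance + 13
   Haralick statistics x 5 channels);
3. *Tile CNN* — a small convolutional network on RGB tiles composed
   from three image channels (R <- channel 1, G <- channel 3,
   B <- channel 5).

SVMs use stratified 5-fold cross-validation with balanced class
weights and a small inner grid search over (C, gamma); features are
standardized to zero mean / unit variance using training-fold
statistics only.  The CNN uses stratified k-fold CV (default 10) with
an inner validation split for early stopping, i.e. roughly an 80/10/10
train/validation/test partition per fold.  All metrics are reported
per fold and aggregated as mean +/- sd.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from . import nn
from .roi_features import VALID_HI, VALID_LO
from .spatial_io import ImageStack

logger = logging.getLogger(__name__)

RGB_CHANNEL_MAP = (0, 2, 4)  # R <- ch1, G <- ch3, B <- ch5 (0-based)


# ---------------------------------------------------------------------------
# split plans and standardization
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    """Stratified fold assignments per spot."""

    n_folds: int
    seed: int
    folds: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    @classmethod
    def stratified(cls, labels: np.ndarray, n_folds: int, seed: int) -> "SplitPlan":
        labels = np.asarray(labels)
        classes, counts = np.unique(labels, return_counts=True)
        if counts.min() < n_folds:
            raise ValueError(
                "stratification failure: a class has fewer spots than folds"
            )
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        folds = [(tr, te) for tr, te in skf.split(np.zeros(len(labels)), labels)]
        # sanity: disjoint and exhaustive test folds
        all_test = np.concatenate([te for _, te in folds])
        assert len(all_test) == len(labels) and len(np.unique(all_test)) == len(labels)
        return cls(n_folds=n_folds, seed=seed, folds=folds)


def standardize(
    x_fit: np.ndarray, *apply_to: np.ndarray
) -> tuple[list[np.ndarray], np.ndarray, np.ndarray]:
    """Center/scale using statistics of ``x_fit`` only.

    Zero-variance features get sd = 1 (so they pass through centred)
    with a warning.  Returns ([standardized x_fit, *standardized
    others], mean, sd).
    """
    x_fit = np.asarray(x_fit, float)
    if len(x_fit) == 0:
        raise ValueError("empty fit set")
    mean = x_fit.mean(axis=0)
    sd = x_fit.std(axis=0)
    n_const = int((sd == 0).sum())
    if n_const:
        logger.warning("%d constant feature(s); sd set to 1", n_const)
    sd = np.where(sd == 0, 1.0, sd)
    out = [(np.asarray(a, float) - mean) / sd for a in (x_fit, *apply_to)]
    return out, mean, sd


# ---------------------------------------------------------------------------
# metrics helpers (per fold)
# ---------------------------------------------------------------------------

def _fold_metrics(y_true, y_pred, classes) -> dict:
    from .evaluate import confusion_and_report

    rep = confusion_and_report(y_true, y_pred, classes=classes)
    return {
        "accuracy": rep.accuracy,
        "weighted_precision": rep.weighted["precision"],
        "weighted_recall": rep.weighted["recall"],
        "weighted_f1": rep.weighted["f1"],
    }


@dataclass
class TrainedModel:
    """Cross-validated classifier results.

    ``fold_metrics`` is one row per fold; ``predictions`` pools the
    held-out predictions of every fold so each spot is predicted
    exactly once.  ``scores`` holds per-class decision scores aligned
    with ``predictions`` rows.
    """

    kind: str
    classes: np.ndarray
    fold_metrics: pd.DataFrame
    predictions: pd.DataFrame  # columns: index, true, predicted
    scores: np.ndarray
    training_log: dict = field(default_factory=dict)

    @property
    def mean_accuracy(self) -> float:
        return float(self.fold_metrics["accuracy"].mean())

    @property
    def sd_accuracy(self) -> float:
        return float(self.fold_metrics["accuracy"].std(ddof=1))

    def summary(self) -> str:
        return (
            f"{self.kind}: weighted accuracy "
            f"{100 * self.mean_accuracy:.1f}% +/- {100 * self.sd_accuracy:.2f}% "
            f"over {len(self.fold_metrics)} folds"
        )


# ---------------------------------------------------------------------------
# SVM tiers
# ---------------------------------------------------------------------------

def train_svm(
    features: pd.DataFrame,
    feature_cols: list[str] | None = None,
    label_col: str = "label",
    n_folds: int = 5,
    seed: int = 0,
    c_grid: tuple[float, ...] = (1.0, 10.0, 100.0),
    gamma_grid: tuple = ("scale", 0.01),
    kind: str = "svm",
) -> TrainedModel:
    """Stratified k-fold CV of an RBF SVM with balanced class weights.

    Standardization and the inner (C, gamma) grid search are fitted on
    each training fold only; held-out metrics are averaged over folds.
    """
    if feature_cols is None:
        feature_cols = [c for c in features.columns if c not in ("spot", label_col)]
    x = features[feature_cols].to_numpy(float)
    y = features[label_col].to_numpy()
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    plan = SplitPlan.stratified(y, n_folds, seed)

    rows, preds, chosen = [], [], []
    score_blocks = []
    for fold, (tr, te) in enumerate(plan.folds):
        (x_tr, x_te), _, _ = standardize(x[tr], x[te])
        grid = GridSearchCV(
            SVC(kernel="rbf", class_weight="balanced", decision_function_shape="ovr"),
            {"C": list(c_grid), "gamma": list(gamma_grid)},
            cv=3,
            n_jobs=1,
        )
        grid.fit(x_tr, y[tr])
        clf = grid.best_estimator_
        y_hat = clf.predict(x_te)
        margin = clf.decision_function(x_te)
        if margin.ndim == 1:  # binary: expand to per-class scores
            margin = np.column_stack([-margin, margin])
        rows.append({"fold": fold, **_fold_metrics(y[te], y_hat, classes)})
        preds.append(pd.DataFrame({"index": te, "true": y[te], "predicted": y_hat}))
        score_blocks.append(margin)
        chosen.append(grid.best_params_)

    predictions = pd.concat(preds, ignore_index=True)
    order = np.argsort(predictions["index"].to_numpy())
    scores = np.concatenate(score_blocks)[order]
    predictions = predictions.iloc[order].reset_index(drop=True)
    return TrainedModel(
        kind=kind,
        classes=classes,
        fold_metrics=pd.DataFrame(rows),
        predictions=predictions,
        scores=scores,
        training_log={"best_params_per_fold": chosen},
    )


# ---------------------------------------------------------------------------
# tiles + CNN tier
# ---------------------------------------------------------------------------

@dataclass
class TileSet:
    """8-bit RGB tiles per spot with class labels."""

    tiles: np.ndarray  # (n, tile_px, tile_px, 3) uint8
    labels: np.ndarray
    spot_ids: np.ndarray
    centers: np.ndarray | None = None  # image-space (x, y) per kept tile
    channel_map: tuple[int, int, int] = RGB_CHANNEL_MAP

    def __post_init__(self) -> None:
        if self.tiles.ndim != 4 or self.tiles.shape[-1] != 3:
            raise ValueError("tiles must be (n, h, w, 3)")
        if not (len(self.tiles) == len(self.labels) == len(self.spot_ids)):
            raise ValueError("tiles, labels and spot ids must align")


def to_8bit(values: np.ndarray, lo: int = VALID_LO, hi: int = VALID_HI) -> np.ndarray:
    """Fixed global 16-bit -> 8-bit window so absolute brightness stays
    informative across tiles: [lo, hi) -> [0, 255]."""
    v = (np.asarray(values, float) - lo) / (hi - lo) * 255.0
    return np.clip(np.round(v), 0, 255).astype(np.uint8)


def make_tiles(
    stack: ImageStack,
    centers: np.ndarray,
    labels: np.ndarray,
    spot_ids: np.ndarray | None = None,
    tile_px: int = 224,
    mode: str = "native",
    crop_px: int = 70,
    channel_map: tuple[int, int, int] = RGB_CHANNEL_MAP,
) -> TileSet:
    """Compose per-spot RGB tiles from three image channels.

    ``native`` mode (default) extracts a tile_px x tile_px window at
    native resolution, so surrounding context is included without
    interpolation; ``crop-resize`` extracts a crop_px window over the
    barcode disc and resizes it to tile_px.  Out-of-bounds spots are
    dropped with a warning.
    """
    centers = np.asarray(centers, int)
    labels = np.asarray(labels)
    if spot_ids is None:
        spot_ids = np.arange(len(centers))
    spot_ids = np.asarray(spot_ids)
    h, w = stack.shape
    window = tile_px if mode == "native" else crop_px
    half = window // 2
    x, y = centers[:, 0], centers[:, 1]
    keep = (
        (x - half >= 0) & (x - half + window <= w)
        & (y - half >= 0) & (y - half + window <= h)
    )
    if (~keep).any():
        logger.warning("%d spot(s) dropped: tile window out of bounds",
                       int((~keep).sum()))
    tiles = []
    for cx, cy in centers[keep]:
        x0, y0 = cx - half, cy - half
        chans = [
            stack.data[c, y0:y0 + window, x0:x0 + window] for c in channel_map
        ]
        rgb = to_8bit(np.stack(chans, axis=-1))
        if mode == "crop-resize" and window != tile_px:
            rgb = (
                _sk_resize(rgb, (tile_px, tile_px, 3), preserve_range=True,
                           anti_aliasing=True)
                .round().astype(np.uint8)
            )
        elif mode not in ("native", "crop-resize"):
            raise ValueError(f"unknown tile mode {mode!r}")
        tiles.append(rgb)
    return TileSet(
        tiles=np.stack(tiles) if tiles else np.empty((0, tile_px, tile_px, 3), np.uint8),
        labels=labels[keep],
        spot_ids=spot_ids[keep],
        centers=centers[keep],
        channel_map=channel_map,
    )


def train_cnn(
    tiles: TileSet,
    n_folds: int = 10,
    seed: int = 0,
    epochs: int = 50,
    batch_size: int = 16,
    val_fraction: float = 1 / 9,
    filters: tuple[int, int] = (16, 32),
    hidden: int = 128,
    dropout: float = 0.25,
    patience: int = 6,
    augment: bool = True,
) -> TrainedModel:
    """Stratified k-fold CV of the tile CNN.

    Within each fold, the non-test spots are split again into training
    and validation sets (default ~80/10/10 overall for 10 folds); the
    validation loss drives early stopping and the LR schedule.  Tiles
    are scaled to [0, 1] and centred with the training fold's mean.
    """
    y_raw = np.asarray(tiles.labels)
    classes = np.unique(y_raw)
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    y = np.searchsorted(classes, y_raw)
    x = tiles.tiles.astype(np.float32).transpose(0, 3, 1, 2) / 255.0
    plan = SplitPlan.stratified(y, n_folds, seed)

    rows, preds, score_blocks = [], [], []
    logs = []
    for fold, (trval, te) in enumerate(plan.folds):
        rng = np.random.default_rng(seed * 1000 + fold)
        # inner stratified validation split
        val_idx = []
        for c in range(len(classes)):
            members = trval[y[trval] == c]
            n_val = max(1, int(round(val_fraction * len(members))))
            val_idx.append(rng.choice(members, size=n_val, replace=False))
        val_idx = np.concatenate(val_idx)
        tr = np.setdiff1d(trval, val_idx)

        mean_img = x[tr].mean(axis=0, keepdims=True)  # training-fold statistic
        model = nn.SmallCNN(
            input_shape=x.shape[1:], n_classes=len(classes),
            filters=filters, hidden=hidden, dropout=dropout,
            seed=seed * 1000 + fold,
        )
        log = nn.train_network(
            model,
            x[tr] - mean_img, y[tr],
            x[val_idx] - mean_img, y[val_idx],
            epochs=epochs, batch_size=batch_size, patience=patience,
            augment=augment, seed=seed * 1000 + fold + 1,
        )
        proba = model.predict_proba(x[te] - mean_img)
        y_hat = classes[np.argmax(proba, axis=1)]
        rows.append({"fold": fold, **_fold_metrics(y_raw[te], y_hat, classes)})
        preds.append(pd.DataFrame({"index": te, "true": y_raw[te], "predicted": y_hat}))
        score_blocks.append(proba)
        logs.append({"fold": fold, "epochs_run": len(log.train_loss),
                     "stopped_epoch": log.stopped_epoch,
                     "final_val_loss": log.val_loss[-1]})

    predictions = pd.concat(preds, ignore_index=True)
    order = np.argsort(predictions["index"].to_numpy())
    scores = np.concatenate(score_blocks)[order]
    predictions = predictions.iloc[order].reset_index(drop=True)
    return TrainedModel(
        kind="cnn",
        classes=classes,
        fold_metrics=pd.DataFrame(rows),
        predictions=predictions,
        scores=scores,
        training_log={"folds": logs},
    )
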