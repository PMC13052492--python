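"""Coordinate spaces, landmark registration, and file I/O.

Visium-style spot coordinates live in three linked spaces:

1. *full-resolution reference* space — the pixel grid of the original
   slide-scanned reference image, where the vendor pipeline reports
   barcode centers;
2. *down-sampled reference* space — the exported reference image whose
   longest side is capped (one global ``downsample_scale``, typically
   0.040–0.044);
3. *registered microscopy* space — the multichannel label-free image,
   registered to the down-sampled reference after the latter is scaled
   up by ``registration_scale`` (default 3).

``map_barcode_to_image`` composes both scalings; landmark-based rigid
(similarity) and affine transforms handle residual misalignment.

Convention: 0-based pixel indices, (x = column, y = row), a spot center
sits at the center of its pixel.  Rounding is half-away-from-zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix
from skimage.transform import SimilarityTransform as _SkSimilarity

logger = logging.getLogger(__name__)

UINT16_MAX = 65535


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ImageStack:
    """Multichannel 16-bit raster: ``data`` has shape (channels, H, W)."""

    data: np.ndarray
    pixel_size_um: float = 1.28
    channel_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("ImageStack.data must be (channels, H, W)")
        if self.data.dtype != np.uint16:
            if self.data.min() < 0 or self.data.max() > UINT16_MAX:
                raise ValueError("pixel values outside [0, 65535]")
            self.data = self.data.astype(np.uint16)
        if self.channel_labels is None:
            self.channel_labels = tuple(
                f"ch{i + 1}" for i in range(self.data.shape[0])
            )
        elif len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length mismatch")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]


@dataclass
class BarcodeTable:
    """Spot ids and centers in full-resolution reference pixels.

    ``df`` columns: ``barcode``, ``x_fullres``, ``y_fullres``.
    """

    df: pd.DataFrame
    downsample_scale: float
    registration_scale: float = 3.0

    def __post_init__(self) -> None:
        required = {"barcode", "x_fullres", "y_fullres"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"barcode table missing columns: {sorted(missing)}")
        if self.df["barcode"].duplicated().any():
            raise ValueError("barcode ids must be unique")
        coords = self.df[["x_fullres", "y_fullres"]].to_numpy(float)
        if not np.isfinite(coords).all() or (coords < 0).any():
            raise ValueError("coordinates must be finite and non-negative")
        if self.downsample_scale <= 0 or self.registration_scale <= 0:
            raise ValueError("scale factors must be positive")

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class CountMatrix:
    """Spots x genes non-negative integer counts."""

    counts: np.ndarray
    barcodes: list[str]
    genes: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (spots x genes)")
        if self.counts.shape != (len(self.barcodes), len(self.genes)):
            raise ValueError("counts shape does not match barcode/gene lists")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.equal(np.mod(self.counts, 1), 0).all():
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass
class LandmarkSet:
    """Paired landmark coordinates, moving -> fixed, each (n, 2)."""

    moving: np.ndarray
    fixed: np.ndarray

    def __post_init__(self) -> None:
        self.moving = np.asarray(self.moving, float)
        self.fixed = np.asarray(self.fixed, float)
        if self.moving.shape != self.fixed.shape or self.moving.ndim != 2 \
                or self.moving.shape[1] != 2:
            raise ValueError("landmarks must be matching (n, 2) arrays")

    def __len__(self) -> int:
        return len(self.moving)


@dataclass
class AffineTransform:
    """2-D affine map y = A @ x + t with residual diagnostics."""

    A: np.ndarray
    t: np.ndarray
    mse: float = field(default=np.nan)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, float).reshape(2, 2)
        self.t = np.asarray(self.t, float).reshape(2)
        if abs(np.linalg.det(self.A)) < 1e-12:
            raise ValueError("linear part is singular")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, float)
        return pts @ self.A.T + self.t

    @property
    def scale(self) -> float:
        """Isotropic scale estimate, sqrt(|det A|)."""
        return float(np.sqrt(abs(np.linalg.det(self.A))))

    @property
    def rotation(self) -> float:
        """Rotation angle in radians (meaningful for similarity maps)."""
        return float(np.arctan2(self.A[1, 0], self.A[0, 0]))


# ---------------------------------------------------------------------------
# coordinate mapping
# ---------------------------------------------------------------------------

def round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (2.5 -> 3, -2.5 -> -3)."""
    x = np.asarray(x, float)
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(np.int64)


def map_barcode_to_image(
    table: BarcodeTable,
    image_shape: tuple[int, int] | None = None,
    roi_size: int | None = None,
) -> pd.DataFrame:
    """Map full-resolution barcode centers into registered-image pixels.

    center = round(fullres * downsample_scale * registration_scale).

    If ``image_shape`` (H, W) is given, spots whose center — or whose
    ``roi_size`` window, when provided — falls outside the image are
    dropped with a warning rather than raising.

    Returns a frame with columns ``barcode``, ``x``, ``y``.
    """
    scale = table.downsample_scale * table.registration_scale
    x = round_half_away(table.df["x_fullres"].to_numpy(float) * scale)
    y = round_half_away(table.df["y_fullres"].to_numpy(float) * scale)
    out = pd.DataFrame({"barcode": table.df["barcode"].to_numpy(), "x": x, "y": y})
    if image_shape is not None:
        h, w = image_shape
        if roi_size is None:
            keep = (x >= 0) & (x < w) & (y >= 0) & (y < h)
        else:
            half = roi_size // 2
            keep = (
                (x - half >= 0) & (x - half + roi_size <= w)
                & (y - half >= 0) & (y - half + roi_size <= h)
            )
        n_drop = int((~keep).sum())
        if n_drop:
            logger.warning(
                "%d spot(s) fall outside the image (or their %s window does); dropped",
                n_drop, roi_size,
            )
        out = out[keep].reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# landmark transform estimation
# ---------------------------------------------------------------------------

def _residual_mse(tf: AffineTransform, lm: LandmarkSet) -> float:
    resid = tf.apply(lm.moving) - lm.fixed
    return float(np.mean(np.sum(resid**2, axis=1)))


def estimate_rigid(landmarks: LandmarkSet) -> AffineTransform:
    """Least-squares similarity transform (translation, rotation,
    isotropic scale) from paired landmarks; closed-form Procrustes fit.
    """
    if len(landmarks) < 2:
        raise ValueError("similarity estimation needs >= 2 landmark pairs")
    if np.allclose(landmarks.moving, landmarks.moving[0]):
        raise ValueError("degenerate landmarks: all moving points coincide")
    sk = _SkSimilarity()
    if not sk.estimate(landmarks.moving, landmarks.fixed):
        raise ValueError("similarity estimation failed (degenerate landmarks)")
    m = np.asarray(sk.params)
    tf = AffineTransform(A=m[:2, :2], t=m[:2, 2])
    tf.mse = _residual_mse(tf, landmarks)
    return tf


def estimate_affine(landmarks: LandmarkSet) -> AffineTransform:
    """Ordinary least-squares 6-parameter affine fit from >= 3
    non-collinear landmark pairs.
    """
    if len(landmarks) < 3:
        raise ValueError("affine estimation needs >= 3 landmark pairs")
    # collinearity check: rank of centred moving points
    centred = landmarks.moving - landmarks.moving.mean(axis=0)
    if np.linalg.matrix_rank(centred, tol=1e-9 * max(1.0, np.abs(centred).max())) < 2:
        raise ValueError("collinear landmarks: affine fit is rank-deficient")
    design = np.column_stack([landmarks.moving, np.ones(len(landmarks))])
    sol, *_ = np.linalg.lstsq(design, landmarks.fixed, rcond=None)  # (3, 2)
    tf = AffineTransform(A=sol[:2].T, t=sol[2])
    tf.mse = _residual_mse(tf, landmarks)
    return tf


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def write_image_stack(stack: ImageStack, path: str | Path) -> None:
    """Write as multi-page 16-bit TIFF, one page per channel."""
    tifffile.imwrite(
        str(path),
        stack.data,
        metadata={
            "pixel_size_um": stack.pixel_size_um,
            "channel_labels": list(stack.channel_labels),
        },
    )


def read_image_stack(path: str | Path) -> ImageStack:
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if data.ndim == 2:
        data = data[None]
    labels = meta.get("channel_labels")
    return ImageStack(
        data=data.astype(np.uint16),
        pixel_size_um=float(meta.get("pixel_size_um", 1.28)),
        channel_labels=tuple(labels) if labels else None,
    )


def write_barcode_table(
    table: BarcodeTable, csv_path: str | Path, sidecar_path: str | Path | None = None
) -> None:
    """CSV of (barcode, x_fullres, y_fullres); scale factors go to a YAML
    sidecar (default: ``<csv stem>.scales.yaml``)."""
    csv_path = Path(csv_path)
    table.df[["barcode", "x_fullres", "y_fullres"]].to_csv(csv_path, index=False)
    sidecar = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".scales.yaml")
    with open(sidecar, "w") as fh:
        yaml.safe_dump(
            {
                "downsample_scale": float(table.downsample_scale),
                "registration_scale": float(table.registration_scale),
            },
            fh,
        )


def read_barcode_table(
    csv_path: str | Path, sidecar_path: str | Path | None = None
) -> BarcodeTable:
    csv_path = Path(csv_path)
    sep = "\t" if csv_path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(csv_path, sep=sep)
    sidecar = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".scales.yaml")
    with open(sidecar) as fh:
        scales = yaml.safe_load(fh)
    return BarcodeTable(
        df=df,
        downsample_scale=float(scales["downsample_scale"]),
        registration_scale=float(scales["registration_scale"]),
    )


def write_landmarks(lm: LandmarkSet, path: str | Path) -> None:
    pd.DataFrame(
        {
            "x_moving": lm.moving[:, 0],
            "y_moving": lm.moving[:, 1],
            "x_fixed": lm.fixed[:, 0],
            "y_fixed": lm.fixed[:, 1],
        }
    ).to_csv(path, index=False)


def read_landmarks(path: str | Path) -> LandmarkSet:
    df = pd.read_csv(path)
    return LandmarkSet(
        moving=df[["x_moving", "y_moving"]].to_numpy(float),
        fixed=df[["x_fixed", "y_fixed"]].to_numpy(float),
    )


def write_count_matrix_mtx(cm: CountMatrix, outdir: str | Path) -> None:
    """MatrixMarket triplet layout: matrix.mtx stored genes x spots with
    barcodes.tsv / features.tsv index files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mmwrite(str(outdir / "matrix.mtx"), coo_matrix(cm.counts.T))
    (outdir / "barcodes.tsv").write_text("\n".join(cm.barcodes) + "\n")
    (outdir / "features.tsv").write_text("\n".join(cm.genes) + "\n")


def read_count_matrix_mtx(outdir: str | Path) -> CountMatrix:
    outdir = Path(outdir)
    mat = mmread(str(outdir / "matrix.mtx"))
    counts = np.asarray(mat.todense() if hasattr(mat, "todense") else mat).T
    if not np.equal(np.mod(counts, 1), 0).all():
        raise ValueError("MTX file contains non-integer counts")
    barcodes = (outdir / "barcodes.tsv").read_text().splitlines()
    genes = (outdir / "features.tsv").read_text().splitlines()
    return CountMatrix(counts=counts.astype(np.int64), barcodes=barcodes, genes=genes)


def write_count_matrix_csv(cm: CountMatrix, path: str | Path) -> None:
    pd.DataFrame(cm.counts, index=cm.barcodes, columns=cm.genes).to_csv(
        path, index_label="barcode"
    )


def read_count_matrix_csv(path: str | Path) -> CountMatrix:
    df = pd.read_csv(path, index_col="barcode")
    counts = df.to_numpy()
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.equal(np.mod(counts, 1), 0).all():
            raise ValueError("CSV count matrix contains non-integer values")
        counts = counts.astype(np.int64)
    return CountMatrix(
        counts=counts, barcodes=list(df.index.astype(str)), genes=list(df.columns)
    )
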