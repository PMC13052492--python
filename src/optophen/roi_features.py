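"""Per-spot ROI extraction, abundance, and Haralick texture features.

Each barcode spot maps to a 70x70 pixel window per channel (slightly
oversampling the 55 µm capture disc at ~1.28 µm/px).  Pixels below the
background threshold (2000) or at the 16-bit saturation ceiling are
masked out of all statistics.  Abundance is the masked mean per
channel; channels 1, 2, 3, 5 are ratio-normalized by channel 4 to
cancel systematic brightness factors (source power, working distance)
that act multiplicatively on every channel at once.

Texture is summarized by the 13 classical Haralick statistics of the
gray-level co-occurrence matrix (GLCM), computed at distance 1 for the
four axial/diagonal directions and averaged over directions: angular
second moment, contrast, correlation, sum of squares (variance),
inverse difference moment, sum average, sum variance, sum entropy,
entropy, difference variance, difference entropy, and the two
information measures of correlation.  13 statistics x 5 channels = 65
texture features; together with 5 abundance features, 70 in total.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from skimage.feature import graycomatrix

logger = logging.getLogger(__name__)

VALID_LO = 2000
VALID_HI = 65535  # exclusive: the 16-bit ceiling is treated as saturation
DEFAULT_ROI = 70
DEFAULT_LEVELS = 64

HARALICK_NAMES = (
    "asm",
    "contrast",
    "correlation",
    "variance",
    "idm",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
)

_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)


def extract_rois(
    stack_data: np.ndarray, centers: np.ndarray, size: int = DEFAULT_ROI
) -> np.ndarray:
    """Cut per-channel windows around each (x, y) center.

    ``stack_data`` is (C, H, W); returns (n_spots, C, size, size).  The
    center pixel sits at window index (size // 2, size // 2) — (35, 35)
    for the default even size.  Centers must already be in bounds
    (see ``spatial_io.map_barcode_to_image`` filtering).
    """
    c, h, w = stack_data.shape
    centers = np.asarray(centers, int)
    half = size // 2
    out = np.empty((len(centers), c, size, size), dtype=stack_data.dtype)
    for i, (x, y) in enumerate(centers):
        y0, x0 = y - half, x - half
        if y0 < 0 or x0 < 0 or y0 + size > h or x0 + size > w:
            raise ValueError(f"ROI for center ({x}, {y}) overruns the image")
        out[i] = stack_data[:, y0:y0 + size, x0:x0 + size]
    return out


def mask_valid(
    roi: np.ndarray, lo: int = VALID_LO, hi: int = VALID_HI
) -> np.ndarray:
    """Boolean mask of analyzable pixels: lo <= value < hi."""
    return (roi >= lo) & (roi < hi)


def abundance(roi: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Masked mean per channel for one spot's (C, h, w) ROI.

    Returns NaN for channels with an empty mask; callers exclude such
    spots.
    """
    roi = np.asarray(roi, float)
    if mask is None:
        mask = mask_valid(roi)
    n = mask.sum(axis=(1, 2))
    total = np.where(mask, roi, 0.0).sum(axis=(1, 2))
    with np.errstate(invalid="ignore"):
        out = np.where(n > 0, total / np.maximum(n, 1), np.nan)
    return out


def normalize_abundance(a: np.ndarray, mode: str = "ratio") -> np.ndarray:
    """Channel-4 ratio normalization of a 5-vector of abundances.

    ``ratio`` (default): entries are (ch1/ch4, ch2/ch4, ch3/ch4,
    ch5/ch4, ch4) — the four ratios plus the raw reference-channel
    abundance, preserving a 5-feature vector.  ``raw`` returns the
    plain means.
    """
    a = np.asarray(a, float)
    if a.shape[-1] != 5:
        raise ValueError("expected 5 channel abundances")
    if mode == "raw":
        return a.copy()
    if mode != "ratio":
        raise ValueError(f"unknown abundance mode {mode!r}")
    ch4 = a[..., 3]
    if np.any(~(ch4 > 0)):
        raise ValueError("channel-4 abundance must be positive for ratio mode")
    return np.stack(
        [a[..., 0] / ch4, a[..., 1] / ch4, a[..., 2] / ch4, a[..., 4] / ch4, ch4],
        axis=-1,
    )


# ---------------------------------------------------------------------------
# Haralick statistics
# ---------------------------------------------------------------------------

def quantize(
    img: np.ndarray,
    mask: np.ndarray | None = None,
    levels: int = DEFAULT_LEVELS,
    lo: int = VALID_LO,
    hi: int = VALID_HI,
) -> np.ndarray:
    """Linear binning of [lo, hi) into ``levels`` gray levels, fixed
    across ROIs so texture features are comparable.  Masked-out pixels
    get the sentinel level ``levels`` (excluded from the GLCM).
    """
    img = np.asarray(img, float)
    q = np.floor((img - lo) / (hi - lo) * levels)
    q = np.clip(q, 0, levels - 1).astype(np.uint16)
    if mask is None:
        mask = mask_valid(img, lo, hi)
    q[~mask] = levels
    return q


def glcm(
    quantized: np.ndarray, levels: int = DEFAULT_LEVELS, distance: int = 1
) -> np.ndarray:
    """Symmetric, direction-resolved normalized co-occurrence matrix.

    Returns (levels, levels, n_angles) with each angle slice summing to
    1 (or all-zero when no valid pair exists at that offset).  Pairs
    touching the sentinel level are discarded.
    """
    full = graycomatrix(
        quantized,
        distances=[distance],
        angles=list(_ANGLES),
        levels=levels + 1,
        symmetric=True,
        normed=False,
    )[:, :, 0, :].astype(float)
    core = full[:levels, :levels, :]
    sums = core.sum(axis=(0, 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        core = np.where(sums > 0, core / np.maximum(sums, 1e-300), 0.0)
    return core


def haralick_from_glcm(p: np.ndarray) -> np.ndarray:
    """The 13 Haralick statistics of one normalized GLCM slice.

    Degenerate denominators (zero marginal variance for correlation,
    zero marginal entropy for the first information measure) yield 0 by
    policy, with a log record left to the caller.  Natural logarithms;
    0 * log 0 = 0.
    """
    g = p.shape[0]
    i = np.arange(g, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = (i * px).sum()
    mu_y = (i * py).sum()
    sd_x = np.sqrt(((i - mu_x) ** 2 * px).sum())
    sd_y = np.sqrt(((i - mu_y) ** 2 * py).sum())

    # p_{x+y}(k), k = 0..2g-2  and  p_{|x-y|}(k), k = 0..g-1
    k_sum = np.arange(2 * g - 1, dtype=float)
    p_sum = np.zeros(2 * g - 1)
    np.add.at(p_sum, (ii + jj).astype(int).ravel(), p.ravel())
    k_diff = np.arange(g, dtype=float)
    p_diff = np.zeros(g)
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), p.ravel())

    def _ent(q: np.ndarray) -> float:
        nz = q > 0
        return float(-(q[nz] * np.log(q[nz])).sum())

    asm = float((p**2).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())
    if sd_x > 0 and sd_y > 0:
        correlation = float(((ii * jj * p).sum() - mu_x * mu_y) / (sd_x * sd_y))
    else:
        correlation = 0.0
    variance = float(((ii - mu_x) ** 2 * p).sum())
    idm = float((p / (1.0 + (ii - jj) ** 2)).sum())
    sum_average = float((k_sum * p_sum).sum())
    sum_variance = float(((k_sum - sum_average) ** 2 * p_sum).sum())
    sum_entropy = _ent(p_sum)
    entropy = _ent(p)
    diff_mean = float((k_diff * p_diff).sum())
    difference_variance = float(((k_diff - diff_mean) ** 2 * p_diff).sum())
    difference_entropy = _ent(p_diff)

    # information measures of correlation
    hx = _ent(px)
    hy = _ent(py)
    outer = np.outer(px, py)
    nz = (p > 0) & (outer > 0)
    hxy1 = float(-(p[nz] * np.log(outer[nz])).sum())
    nz2 = outer > 0
    hxy2 = float(-(outer[nz2] * np.log(outer[nz2])).sum())
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    return np.array(
        [
            asm, contrast, correlation, variance, idm, sum_average,
            sum_variance, sum_entropy, entropy, difference_variance,
            difference_entropy, imc1, imc2,
        ]
    )


def haralick(
    channel_roi: np.ndarray,
    mask: np.ndarray | None = None,
    levels: int = DEFAULT_LEVELS,
    distance: int = 1,
) -> np.ndarray:
    """13 direction-averaged Haralick statistics for one channel ROI."""
    q = quantize(channel_roi, mask=mask, levels=levels)
    mats = glcm(q, levels=levels, distance=distance)
    feats = np.stack(
        [haralick_from_glcm(mats[:, :, a]) for a in range(mats.shape[2])]
    )
    return feats.mean(axis=0)


# ---------------------------------------------------------------------------
# feature table assembly
# ---------------------------------------------------------------------------

def feature_columns(with_texture: bool) -> list[str]:
    cols = [f"abundance_{i + 1}" for i in range(5)]
    if with_texture:
        cols += [
            f"haralick_ch{c + 1}_{name}"
            for c in range(5)
            for name in HARALICK_NAMES
        ]
    return cols


def build_feature_table(
    rois: np.ndarray,
    spot_ids,
    labels,
    with_texture: bool = True,
    abundance_mode: str = "ratio",
    levels: int = DEFAULT_LEVELS,
) -> pd.DataFrame:
    """Assemble the per-spot feature table.

    Columns: ``spot``, ``label``, then 5 abundance features and, when
    ``with_texture``, 65 Haralick features (13 per channel) — 70 in
    total.  Spots with any fully-masked channel (or non-positive
    channel-4 abundance in ratio mode) are excluded with a warning.
    """
    rois = np.asarray(rois)
    spot_ids = np.asarray(spot_ids)
    labels = np.asarray(labels)
    if not (len(rois) == len(spot_ids) == len(labels)):
        raise ValueError("rois, spot_ids and labels must align")
    cols = feature_columns(with_texture)
    rows, kept = [], []
    n_excluded = 0
    for idx in range(len(rois)):
        roi = rois[idx]
        mask = mask_valid(roi)
        a = abundance(roi, mask)
        if np.isnan(a).any() or (abundance_mode == "ratio" and not a[3] > 0):
            n_excluded += 1
            continue
        feats = list(normalize_abundance(a, mode=abundance_mode))
        if with_texture:
            for c in range(roi.shape[0]):
                feats.extend(haralick(roi[c], mask=mask[c], levels=levels))
        rows.append(feats)
        kept.append(idx)
    if n_excluded:
        logger.warning(
            "%d spot(s) excluded (fully masked channel or invalid reference)",
            n_excluded,
        )
    df = pd.DataFrame(rows, columns=cols)
    df.insert(0, "label", labels[kept] if len(kept) else np.array([], dtype=labels.dtype))
    df.insert(0, "spot", spot_ids[kept] if len(kept) else np.array([], dtype=spot_ids.dtype))
    return df
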