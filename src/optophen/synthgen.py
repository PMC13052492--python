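"""Synthetic co-registered datasets with known phenotype structure.

Emulates the geometry and contrast of a spot-barcoded spatial
transcriptomics capture area imaged by five-channel label-free
microscopy:

* a Cartesian grid of circular 55 µm barcode regions spaced 100 µm
  apart at ~1.28 µm/pixel;
* per-spot gene-expression counts drawn from a negative-binomial model
  with cluster-specific "program" genes;
* a 5-channel 16-bit image in which each spot's disc carries a
  cluster-specific mean intensity, a Gaussian-random-field texture with
  cluster/channel-specific correlation length, white detector noise,
  and ONE smooth multiplicative illumination field shared identically
  by all channels (the structure that motivates ratio normalization by
  the reference channel);
* an optional per-tile brightness artifact mimicking mosaic stitching.

Everything is deterministic given the config (including its seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

from .spatial_io import (
    BarcodeTable,
    CountMatrix,
    ImageStack,
    round_half_away,
    write_barcode_table,
    write_count_matrix_mtx,
    write_image_stack,
)

N_CHANNELS = 5
_BACKGROUND = 500  # below the validity threshold, so masked out downstream

# distinct per-cluster channel means used when the config does not set any;
# rows are clusters (cycled if n_clusters > 3), columns the five channels
_DEFAULT_MEANS = np.array(
    [
        [10000, 14000, 22000, 20000, 8000],
        [16000, 20000, 14000, 24000, 12000],
        [22000, 10000, 18000, 16000, 16000],
    ],
    dtype=float,
)


@dataclass
class SynthConfig:
    n_clusters: int = 3
    grid_shape: tuple[int, int] = (20, 20)
    spot_spacing_um: float = 100.0
    spot_diameter_um: float = 55.0
    pixel_size_um: float = 1.28
    n_genes: int = 200
    genes_per_program: int = 20
    nb_mean: float = 5.0
    nb_dispersion: float = 2.0
    program_fold: float = 4.0
    channel_means: np.ndarray | None = None        # (n_clusters, 5)
    texture_corr_lengths: np.ndarray | None = None  # (n_clusters, 5), pixels
    texture_amplitude: float = 0.3
    noise_amplitude: float = 0.1
    illumination_amplitude: float = 0.0
    tile_artifact_amplitude: float = 0.0
    tile_px: int = 256
    margin_px: int = 120
    downsample_scale: float = 0.044
    registration_scale: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.channel_means is None:
            idx = np.arange(self.n_clusters) % len(_DEFAULT_MEANS)
            self.channel_means = _DEFAULT_MEANS[idx].copy()
        self.channel_means = np.atleast_2d(np.asarray(self.channel_means, float))
        if self.texture_corr_lengths is None:
            self.texture_corr_lengths = np.full((self.n_clusters, N_CHANNELS), 3.0)
        self.texture_corr_lengths = np.atleast_2d(
            np.asarray(self.texture_corr_lengths, float)
        )
        self.validate()

    def validate(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.spot_spacing_um <= self.spot_diameter_um:
            raise ValueError("spot spacing must exceed spot diameter")
        if min(self.grid_shape) < 1:
            raise ValueError("grid_shape must be positive")
        if self.nb_mean <= 0 or self.nb_dispersion <= 0:
            raise ValueError("negative-binomial parameters must be positive")
        if self.channel_means.shape != (self.n_clusters, N_CHANNELS):
            raise ValueError("channel_means must be (n_clusters, 5)")
        if (self.channel_means <= 0).any():
            raise ValueError("channel means must be positive")
        if self.texture_corr_lengths.shape != (self.n_clusters, N_CHANNELS):
            raise ValueError("texture_corr_lengths must be (n_clusters, 5)")
        if (self.texture_corr_lengths <= 0).any():
            raise ValueError("texture correlation lengths must be positive")
        if self.illumination_amplitude < 0:
            raise ValueError("illumination_amplitude must be non-negative")
        if self.n_genes < self.n_clusters * self.genes_per_program:
            raise ValueError(
                "n_genes too small for n_clusters disjoint gene programs"
            )

    # -- derived geometry ---------------------------------------------------

    @property
    def spacing_px(self) -> int:
        return int(round_half_away(self.spot_spacing_um / self.pixel_size_um))

    @property
    def spot_radius_px(self) -> float:
        return self.spot_diameter_um / self.pixel_size_um / 2.0

    @property
    def image_shape(self) -> tuple[int, int]:
        rows, cols = self.grid_shape
        h = 2 * self.margin_px + (rows - 1) * self.spacing_px + 1
        w = 2 * self.margin_px + (cols - 1) * self.spacing_px + 1
        return h, w


def texture_coded_config(seed: int = 0, **overrides) -> SynthConfig:
    """Study condition where phenotypes are coded purely by texture.

    All clusters share identical channel means (abundance carries no
    class signal beyond noise); correlation lengths 2/4/8 px separate
    the classes spatially.  Spot-level illumination jitter and detector
    noise give overlapping abundance distributions.
    """
    means = np.tile([15000.0, 18000.0, 21000.0, 24000.0, 12000.0], (3, 1))
    corr = np.array([[2.0] * 5, [4.0] * 5, [8.0] * 5])
    cfg = SynthConfig(
        n_clusters=3,
        channel_means=means,
        texture_corr_lengths=corr,
        texture_amplitude=0.35,
        noise_amplitude=0.15,
        illumination_amplitude=0.2,
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _rng(cfg: SynthConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, stream]))


def true_centers(cfg: SynthConfig) -> np.ndarray:
    """Ground-truth image-space spot centers, shape (n_spots, 2) as (x, y),
    row-major spot order."""
    rows, cols = cfg.grid_shape
    ys, xs = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    x = cfg.margin_px + xs.ravel() * cfg.spacing_px
    y = cfg.margin_px + ys.ravel() * cfg.spacing_px
    return np.column_stack([x, y]).astype(int)


def gen_barcode_grid(cfg: SynthConfig) -> BarcodeTable:
    """Cartesian grid of barcode centers, reported in full-resolution
    reference coordinates so the full mapping chain is exercised."""
    centers = true_centers(cfg)
    scale = cfg.downsample_scale * cfg.registration_scale
    fullres = centers / scale
    n = len(centers)
    df = pd.DataFrame(
        {
            "barcode": [f"SPOT-{i:05d}" for i in range(n)],
            "x_fullres": fullres[:, 0],
            "y_fullres": fullres[:, 1],
        }
    )
    return BarcodeTable(
        df=df,
        downsample_scale=cfg.downsample_scale,
        registration_scale=cfg.registration_scale,
    )


def gen_assignments(cfg: SynthConfig) -> np.ndarray:
    """Balanced random spot -> cluster assignment (labels 0..k-1)."""
    n = cfg.grid_shape[0] * cfg.grid_shape[1]
    labels = np.arange(n) % cfg.n_clusters
    _rng(cfg, 1).shuffle(labels)
    return labels


def gen_counts(cfg: SynthConfig, assignments: np.ndarray) -> CountMatrix:
    """Negative-binomial counts with disjoint cluster gene programs.

    Cluster ``c`` owns genes ``[c * genes_per_program, (c+1) * genes_per_program)``
    whose mean is ``nb_mean * program_fold`` in cluster-``c`` spots; all
    other (gene, spot) means are ``nb_mean``.  Variance follows the
    NB(r, p) law m + m^2 / r with r = ``nb_dispersion``.
    """
    assignments = np.asarray(assignments)
    n_spots = len(assignments)
    if set(np.unique(assignments)) - set(range(cfg.n_clusters)):
        raise ValueError("assignment labels outside 0..n_clusters-1")
    means = np.full((n_spots, cfg.n_genes), cfg.nb_mean)
    for c in range(cfg.n_clusters):
        g0 = c * cfg.genes_per_program
        means[assignments == c, g0:g0 + cfg.genes_per_program] = (
            cfg.nb_mean * cfg.program_fold
        )
    r = cfg.nb_dispersion
    p = r / (r + means)
    counts = _rng(cfg, 2).negative_binomial(r, p)
    return CountMatrix(
        counts=counts.astype(np.int64),
        barcodes=[f"SPOT-{i:05d}" for i in range(n_spots)],
        genes=[f"GENE-{j:04d}" for j in range(cfg.n_genes)],
    )


def _illumination_field_fn(cfg: SynthConfig, rng: np.random.Generator):
    """Smooth multiplicative field exp(a * f(x, y)) with unit-variance f
    built from three random low-frequency plane waves."""
    h, w = cfg.image_shape
    n_waves = 3
    periods = rng.uniform(0.5, 1.5, size=n_waves) * max(h, w)
    angles = rng.uniform(0, np.pi, size=n_waves)
    phases = rng.uniform(0, 2 * np.pi, size=n_waves)
    kx = np.cos(angles) / periods
    ky = np.sin(angles) / periods
    norm = np.sqrt(n_waves / 2.0)  # each sine has variance 1/2

    def field(xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        f = np.zeros(np.broadcast(xs, ys).shape)
        for j in range(n_waves):
            f += np.sin(2 * np.pi * (kx[j] * xs + ky[j] * ys) + phases[j])
        return np.exp(cfg.illumination_amplitude * f / norm)

    return field


def _texture_patch(
    rng: np.random.Generator, size: int, corr_len: float
) -> np.ndarray:
    """Zero-mean, unit-variance Gaussian random field patch: white noise
    smoothed with a Gaussian kernel of the given correlation length."""
    pad = int(np.ceil(3 * corr_len))
    noise = rng.standard_normal((size + 2 * pad, size + 2 * pad))
    smooth = gaussian_filter(noise, sigma=corr_len, mode="reflect")
    patch = smooth[pad:pad + size, pad:pad + size]
    sd = patch.std()
    if sd < 1e-12:
        return np.zeros((size, size))
    return (patch - patch.mean()) / sd


def gen_images(
    cfg: SynthConfig,
    barcodes: BarcodeTable | None = None,
    assignments: np.ndarray | None = None,
) -> ImageStack:
    """Render the 5-channel 16-bit stack.

    Inside each spot's disc, channel ``c`` carries
    ``mean[cluster, c] * (1 + ta * texture + na * noise) * illumination``
    where the texture field is cluster/channel specific, the white noise
    is i.i.d. per pixel, and the illumination field is shared by all
    five channels.  Pixels outside discs sit at a sub-threshold
    background level.  Values are clipped to [0, 65535].
    """
    if assignments is None:
        assignments = gen_assignments(cfg)
    centers = true_centers(cfg)
    if len(assignments) != len(centers):
        raise ValueError("assignments length does not match grid")
    if cfg.channel_means.max() * 2 > 65535 * 4:
        raise ValueError("channel means too close to the representable ceiling")
    h, w = cfg.image_shape
    img = np.full((N_CHANNELS, h, w), _BACKGROUND, dtype=np.float64)

    rng = _rng(cfg, 3)
    illum = _illumination_field_fn(cfg, rng)
    radius = cfg.spot_radius_px
    psize = int(np.ceil(2 * radius)) + 3
    half = psize // 2
    yy, xx = np.mgrid[:psize, :psize]
    disc = (xx - half) ** 2 + (yy - half) ** 2 <= radius**2

    spot_seeds = np.random.SeedSequence([cfg.seed, 4]).spawn(len(centers))
    for i, ((cx, cy), lab) in enumerate(zip(centers, assignments)):
        srng = np.random.default_rng(spot_seeds[i])
        x0, y0 = cx - half, cy - half
        gx = xx + x0
        gy = yy + y0
        ill = illum(gx, gy)
        for c in range(N_CHANNELS):
            tex = _texture_patch(srng, psize, cfg.texture_corr_lengths[lab, c])
            noise = srng.standard_normal((psize, psize))
            vals = (
                cfg.channel_means[lab, c]
                * (1.0 + cfg.texture_amplitude * tex + cfg.noise_amplitude * noise)
                * ill
            )
            block = img[c, y0:y0 + psize, x0:x0 + psize]
            block[disc] = vals[disc]

    if cfg.tile_artifact_amplitude > 0:
        trng = _rng(cfg, 5)
        nty = int(np.ceil(h / cfg.tile_px))
        ntx = int(np.ceil(w / cfg.tile_px))
        factors = 1.0 + cfg.tile_artifact_amplitude * trng.uniform(
            -1, 1, size=(nty, ntx)
        )
        grid = np.repeat(np.repeat(factors, cfg.tile_px, 0), cfg.tile_px, 1)[:h, :w]
        img *= grid[None]

    return ImageStack(
        data=np.clip(img, 0, 65535).astype(np.uint16),
        pixel_size_um=cfg.pixel_size_um,
        channel_labels=("ch1", "ch2", "ch3", "ch4", "ch5"),
    )


# ---------------------------------------------------------------------------
# bundle + disk layout
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    cfg: SynthConfig
    barcodes: BarcodeTable
    assignments: np.ndarray
    counts: CountMatrix
    stack: ImageStack
    centers: np.ndarray = field(default=None)  # ground-truth (x, y) per spot

    def __post_init__(self) -> None:
        if self.centers is None:
            self.centers = true_centers(self.cfg)


def simulate_dataset(cfg: SynthConfig) -> SyntheticDataset:
    """Generate the full co-registered bundle for one config."""
    barcodes = gen_barcode_grid(cfg)
    assignments = gen_assignments(cfg)
    counts = gen_counts(cfg, assignments)
    stack = gen_images(cfg, barcodes, assignments)
    return SyntheticDataset(
        cfg=cfg, barcodes=barcodes, assignments=assignments,
        counts=counts, stack=stack,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> None:
    """Write TIFF stack, barcode CSV (+ scales sidecar), MTX counts, and a
    truth sidecar with the generating config and cluster assignments."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_image_stack(ds.stack, outdir / "stack.tiff")
    write_barcode_table(ds.barcodes, outdir / "barcodes.csv")
    write_count_matrix_mtx(ds.counts, outdir / "counts")
    truth = pd.DataFrame(
        {
            "barcode": ds.barcodes.df["barcode"],
            "cluster": ds.assignments,
            "x_image": ds.centers[:, 0],
            "y_image": ds.centers[:, 1],
        }
    )
    truth.to_csv(outdir / "truth.csv", index=False)
    cfg_dict = {
        k: (v.tolist() if isinstance(v, np.ndarray) else v)
        for k, v in vars(ds.cfg).items()
    }
    cfg_dict["grid_shape"] = list(ds.cfg.grid_shape)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg_dict, fh)
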