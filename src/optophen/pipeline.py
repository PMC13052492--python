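"""End-to-end orchestration: simulate -> phenotype -> features ->
stats -> train -> evaluate, with every artifact written to a run
directory and reproducible from the config snapshot + seed."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import classify, evaluate, phenotyping, roi_features, stats, synthgen
from .config import PipelineConfig
from .spatial_io import map_barcode_to_image

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage


@dataclass
class PipelineResult:
    outdir: Path
    dataset: synthgen.SyntheticDataset
    assignment: phenotyping.PhenotypeAssignment
    features_abundance: pd.DataFrame
    features_texture: pd.DataFrame
    corr_before: np.ndarray
    corr_after: np.ndarray
    models: dict  # kind -> TrainedModel
    reports: dict  # kind -> EvalReport


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            logger.info("stage %s ...", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - tag and re-raise
                raise StageError(name, exc) from exc
        return wrapper
    return deco


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> PipelineResult:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "resolved_config.yaml")

    # -- simulate -----------------------------------------------------------
    scfg = cfg.synth_config()
    ds = _stage("simulate")(synthgen.simulate_dataset)(scfg)
    synthgen.write_dataset(ds, outdir / "data")

    # -- map coordinates ----------------------------------------------------
    centers_df = _stage("map-coords")(map_barcode_to_image)(
        ds.barcodes, image_shape=ds.stack.shape, roi_size=cfg.roi_size
    )
    keep_idx = centers_df.index.to_numpy()
    barcode_to_row = {b: i for i, b in enumerate(ds.barcodes.df["barcode"])}
    row_idx = np.array([barcode_to_row[b] for b in centers_df["barcode"]])
    centers = centers_df[["x", "y"]].to_numpy()

    # -- phenotype ----------------------------------------------------------
    @_stage("phenotype")
    def _phenotype():
        xnorm, keep = phenotyping.normalize_counts(ds.counts)
        if not keep.all():
            raise ValueError("synthetic counts should have no empty spots")
        k = cfg.k or scfg.n_clusters
        pa = phenotyping.kmeans_phenotypes(
            xnorm, k, seed=cfg.seed, barcodes=ds.counts.barcodes
        )
        scan = None
        if cfg.scan_k:
            lo, hi = cfg.scan_k
            scan = phenotyping.silhouette_scan(xnorm, range(lo, hi + 1), seed=cfg.seed)
            scan.to_csv(outdir / "silhouette.csv", index=False)
        deg = phenotyping.deg_zscores(xnorm, pa, genes=ds.counts.genes)
        deg.zscores.to_csv(outdir / "deg_zscores.csv")
        pa.to_frame().to_csv(outdir / "phenotypes.csv", index=False)
        return pa, scan

    assignment, _ = _phenotype()
    labels = assignment.labels[row_idx]

    # -- features -----------------------------------------------------------
    @_stage("features")
    def _features():
        rois = roi_features.extract_rois(ds.stack.data, centers, size=cfg.roi_size)
        spot_ids = centers_df["barcode"].to_numpy()
        ft_ab = roi_features.build_feature_table(
            rois, spot_ids, labels, with_texture=False,
            abundance_mode=cfg.abundance_mode,
        )
        ft_tex = roi_features.build_feature_table(
            rois, spot_ids, labels, with_texture=True,
            abundance_mode=cfg.abundance_mode, levels=cfg.glcm_levels,
        )
        ft_ab.to_csv(outdir / "features_abundance.csv", index=False)
        ft_tex.to_csv(outdir / "features_texture.csv", index=False)
        # raw abundances for the correlation contrast
        raw = roi_features.build_feature_table(
            rois, spot_ids, labels, with_texture=False, abundance_mode="raw"
        )
        return ft_ab, ft_tex, raw

    ft_ab, ft_tex, ft_raw = _features()

    # -- stats --------------------------------------------------------------
    @_stage("stats")
    def _stats():
        ab_cols = [f"abundance_{i + 1}" for i in range(5)]
        corr_before = stats.interchannel_correlation(ft_raw[ab_cols].to_numpy())
        corr_after = stats.interchannel_correlation(ft_ab[ab_cols].to_numpy())
        np.savetxt(outdir / "corr_before.csv", corr_before, delimiter=",")
        np.savetxt(outdir / "corr_after.csv", corr_after, delimiter=",")
        data = ft_ab.rename(columns={"label": "cluster"})
        results = stats.pairwise_mwu_bonferroni(
            data, channels=ab_cols[:4], alpha=cfg.alpha
        )
        stats.comparison_table(results).to_csv(outdir / "comparisons.csv", index=False)
        return corr_before, corr_after

    corr_before, corr_after = _stats()

    # -- train --------------------------------------------------------------
    @_stage("train")
    def _train():
        models = {}
        models["svm_abundance"] = classify.train_svm(
            ft_ab, n_folds=cfg.svm_folds, seed=cfg.seed, kind="svm_abundance"
        )
        models["svm_texture"] = classify.train_svm(
            ft_tex, n_folds=cfg.svm_folds, seed=cfg.seed, kind="svm_texture"
        )
        tiles = classify.make_tiles(
            ds.stack, centers, labels, spot_ids=keep_idx,
            tile_px=cfg.tile_px, mode=cfg.tile_mode,
        )
        models["cnn"] = classify.train_cnn(
            tiles, n_folds=cfg.cnn_folds, seed=cfg.seed, epochs=cfg.cnn_epochs
        )
        return models, tiles

    models, tiles = _train()

    # -- evaluate -----------------------------------------------------------
    @_stage("evaluate")
    def _evaluate():
        reports = {}
        for kind, model in models.items():
            rep = evaluate.confusion_and_report(
                model.predictions["true"].to_numpy(),
                model.predictions["predicted"].to_numpy(),
                classes=model.classes,
                scores=model.scores,
            )
            reports[kind] = rep
            rep.per_class.to_csv(outdir / f"report_{kind}.csv", index=False)
            model.fold_metrics.to_csv(outdir / f"folds_{kind}.csv", index=False)
            summary = {
                "kind": kind,
                "weighted_accuracy_mean": model.mean_accuracy,
                "weighted_accuracy_sd": model.sd_accuracy,
                "weighted": rep.weighted,
            }
            (outdir / f"summary_{kind}.json").write_text(
                json.dumps(summary, indent=2)
            )
        # back-projection of the CNN predictions
        cnn = models["cnn"]
        pred_centers = tiles.centers[cnn.predictions["index"].to_numpy()]
        for which in ("correct", "incorrect"):
            overlay, n = evaluate.backproject(
                cnn.predictions["predicted"].to_numpy(),
                cnn.predictions["true"].to_numpy(),
                pred_centers,
                ds.stack.data[0],
                which=which,
            )
            iio.imwrite(outdir / f"backprojection_{which}.png", overlay)
            logger.info("back-projection %s: %d glyphs", which, n)
        return reports

    reports = _evaluate()

    return PipelineResult(
        outdir=outdir,
        dataset=ds,
        assignment=assignment,
        features_abundance=ft_ab,
        features_texture=ft_tex,
        corr_before=corr_before,
        corr_after=corr_after,
        models=models,
        reports=reports,
    )
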