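"""End-to-end orchestration: simulate → segment → kinetics → texture →
mono-parametric statistics → multi-parametric prediction.

The per-patient feature vector holds the 26 parameters the prediction
stage searches over: the 20 texture features measured on the subtracted
image over the (automatically segmented) lesion, the 3 kinetic
parameters measured on a small ROI placed over the most enhancing part
of the lesion, the BI-RADS mass/non-mass flag, Ki67 > 14 %, and the
HR−/HER2+ flag.
"""
from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import atomic_write_text, write_cohort_table, write_feature_table
from .kinetics import DynamicSeries, kinetic_maps, kinetic_params, roi_curve, subtract
from .masks import RoiMask, dice
from .phantom import CohortConfig, generate_cohort
from .prediction import FeatureTable, KMeansClassifierSpec, ModelEvaluation, loocv
from .segmentation import SegmentationParams, segment_lesion
from .stats import ContingencyTable2x2, fisher_midp, roc
from .texture import TEXTURE_FEATURES, texture_features

__all__ = [
    "RunConfig",
    "KINETIC_FEATURES",
    "BINARY_FEATURES",
    "ALL_MODEL_FEATURES",
    "small_kinetic_roi",
    "extract_patient_features",
    "cohort_feature_table",
    "make_feature_table",
    "monoparametric_roc_table",
    "contingency_table",
    "run_pipeline",
]

log = logging.getLogger("texnac")

KINETIC_FEATURES = ("wash_in", "amplitude", "wash_out")
BINARY_FEATURES = ("mass", "ki67_high", "hr_neg_her2_pos")
#: the 26 parameters submitted to the multi-parametric search
ALL_MODEL_FEATURES = TEXTURE_FEATURES + KINETIC_FEATURES + BINARY_FEATURES

DEFAULT_SUBSET = ("inv_diff_moment", "gln", "lrhge", "wash_in")


def small_kinetic_roi(series: DynamicSeries, lesion, n_pixels: int = 12) -> RoiMask:
    """Small ROI over the most enhancing part of the lesion.

    Takes the ``n_pixels`` lesion pixels with the highest amplitude (the
    whole lesion when it is smaller), emulating the reader's placement
    of the kinetic ROI in the brightest part of the lesion.
    """
    lesion_mask = lesion.pixels if isinstance(lesion, RoiMask) else np.asarray(lesion, dtype=bool)
    amp, _ = kinetic_maps(series, lesion_mask)
    flat = np.where(lesion_mask, amp, -np.inf).ravel()
    k = min(n_pixels, int(lesion_mask.sum()))
    top = np.argpartition(flat, -k)[-k:]
    roi = np.zeros(flat.shape, dtype=bool)
    roi[top] = True
    return RoiMask(roi.reshape(lesion_mask.shape), kind="small_kinetic")


def extract_patient_features(series: DynamicSeries, lesion, bits: int = 5,
                             post_index: int = 2) -> dict[str, float]:
    """Texture (subtracted image over the lesion) + kinetic parameters."""
    lesion_mask = lesion.pixels if isinstance(lesion, RoiMask) else np.asarray(lesion, dtype=bool)
    sub = subtract(series, post_index=post_index)
    out = texture_features(sub, lesion_mask, bits=bits)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tiny lesions are allowed here
        curve = roi_curve(series, small_kinetic_roi(series, lesion_mask))
    kp = kinetic_params(curve)
    out.update({"wash_in": kp.wash_in, "amplitude": kp.amplitude, "wash_out": kp.wash_out})
    return out


def cohort_feature_table(cohort, bits: int = 5,
                         seg_params: SegmentationParams | None = None,
                         segment: bool = False) -> pd.DataFrame:
    """Per-patient feature rows for a generated cohort.

    By default texture is measured over the "manual" lesion ROI — the
    generator's ground-truth mask, standing in for the reader-drawn
    outline the measurements are defined on.  With ``segment`` the
    automatic kinetic-map segmentation replaces it (its Dice against
    the manual mask is recorded either way when available).
    """
    rows = []
    for rec, series, truth in cohort:
        if segment:
            rect = RoiMask(np.ones(series.frame_shape, dtype=bool), kind="rectangle")
            mask = segment_lesion(series, rect, seg_params)
            overlap = dice(mask, truth.lesion_mask)
        else:
            mask, overlap = truth.lesion_mask, np.nan
        feats = extract_patient_features(series, mask, bits=bits)
        rows.append({
            "patient_id": rec.patient_id,
            "response": rec.response,
            **feats,
            "mass": int(rec.mass),
            "ki67_high": int(rec.ki67_high),
            "hr_neg_her2_pos": int(rec.hr_neg_her2_pos),
            "lesion_pixels": mask.n_pixels,
            "dice_vs_truth": overlap,
        })
    return pd.DataFrame(rows)


def make_feature_table(df: pd.DataFrame, log_transform=()) -> FeatureTable:
    """Build the prediction-stage table from a per-patient feature frame."""
    features = df.loc[:, list(ALL_MODEL_FEATURES)]
    outcome = (df["response"] == "NR").to_numpy()
    return FeatureTable(features, outcome, tuple(log_transform))


def monoparametric_roc_table(df: pd.DataFrame) -> pd.DataFrame:
    """Per-feature ROC analysis of NR vs PR+CR for the continuous parameters."""
    y = (df["response"] == "NR").to_numpy()
    rows = []
    for name in TEXTURE_FEATURES + KINETIC_FEATURES:
        r = roc(df[name].to_numpy(dtype=float), y)
        rows.append({
            "feature": name, "auc": r.auc, "p_vs_half": r.p_vs_half,
            "cutoff": r.cutoff, "se": r.se, "sp": r.sp, "direction": r.direction,
        })
    return pd.DataFrame(rows)


def contingency_table(df: pd.DataFrame, flag: str) -> ContingencyTable2x2:
    """2×2 table of a binary feature (rows) against NR / PR+CR (columns)."""
    y = (df["response"] == "NR").to_numpy()
    f = df[flag].to_numpy(dtype=bool)
    return ContingencyTable2x2(
        a=int((f & y).sum()), b=int((f & ~y).sum()),
        c=int((~f & y).sum()), d=int((~f & ~y).sum()),
    )


@dataclass(frozen=True)
class RunConfig:
    """Parameters of one full synthetic-cohort analysis run."""

    out_dir: str
    seed: int = 0
    cohort: CohortConfig | None = None  # default: study-sized cohort at `seed`
    bits: int = 5
    opening_radius: int = 1
    subset: tuple[str, ...] = DEFAULT_SUBSET
    classifier: str = "kmeans"
    n_replicates: int = 30
    write_images: bool = False  # also dump each patient's NIfTI series/mask


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline; write CSV/JSON outputs plus a manifest.

    Returns a results bundle with the feature frame, the per-feature ROC
    table, the biomarker contingency statistics, and the LOOCV model
    evaluation.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_cfg = config.cohort or CohortConfig(seed=config.seed)
    log.info("simulate: %d patients, seed %d",
             cohort_cfg.n_nr + cohort_cfg.n_pr + cohort_cfg.n_cr, cohort_cfg.seed)
    cohort = generate_cohort(cohort_cfg)
    write_cohort_table([rec for rec, _, _ in cohort], out / "cohort.csv")

    if config.write_images:
        from .io import write_mask, write_series  # local import keeps startup light
        img_dir = out / "images"
        img_dir.mkdir(exist_ok=True)
        for rec, series, truth in cohort:
            write_series(series, img_dir / f"{rec.patient_id}.nii")
            write_mask(truth.lesion_mask, img_dir / f"{rec.patient_id}_mask.nii")

    seg = SegmentationParams(opening_radius=config.opening_radius, seed=config.seed)
    log.info("segmentation validation (Dice vs manual masks)")
    seg_rows = []
    for rec, series, truth in cohort:
        rect = RoiMask(np.ones(series.frame_shape, dtype=bool), kind="rectangle")
        try:
            auto = segment_lesion(series, rect, seg)
            seg_rows.append({"patient_id": rec.patient_id, "auto_pixels": auto.n_pixels,
                             "dice": dice(auto, truth.lesion_mask)})
        except ValueError as exc:
            seg_rows.append({"patient_id": rec.patient_id, "auto_pixels": 0,
                             "dice": np.nan})
            log.warning("segmentation failed for %s: %s", rec.patient_id, exc)
    write_feature_table(pd.DataFrame(seg_rows), out / "segmentation.csv")

    log.info("features: bits=%d over the manual lesion ROIs", config.bits)
    df = cohort_feature_table(cohort, bits=config.bits, segment=False)
    write_feature_table(df, out / "features.csv")

    log.info("mono-parametric statistics")
    roc_df = monoparametric_roc_table(df)
    write_feature_table(roc_df, out / "roc.csv")
    fisher_rows = []
    for flag in BINARY_FEATURES:
        t = contingency_table(df, flag)
        res = fisher_midp(t)
        fisher_rows.append({"feature": flag, "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                            "p_value": res.p_value})
    fisher_df = pd.DataFrame(fisher_rows)
    write_feature_table(fisher_df, out / "fisher.csv")

    log.info("prediction: %s on %s", config.classifier, config.subset)
    table = make_feature_table(df)
    spec = KMeansClassifierSpec(n_replicates=config.n_replicates, seed=config.seed)
    evaluation = loocv(table, config.subset, config.classifier, spec)
    model = {
        "subset": list(evaluation.feature_subset),
        "classifier": evaluation.classifier,
        "se": evaluation.se,
        "sp": evaluation.sp,
        "accuracy": evaluation.accuracy,
        "confusion": {"tp": evaluation.tp, "fn": evaluation.fn,
                      "tn": evaluation.tn, "fp": evaluation.fp},
    }
    atomic_write_text(out / "model.json", json.dumps(model, indent=2))

    manifest = {
        "texnac_version": __version__,
        "seed": config.seed,
        "bits": config.bits,
        "opening_radius": config.opening_radius,
        "subset": list(config.subset),
        "classifier": config.classifier,
        "n_patients": len(cohort),
    }
    atomic_write_text(out / "manifest.json", json.dumps(manifest, indent=2))
    return {"features": df, "roc": roc_df, "fisher": fisher_df, "model": evaluation}
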