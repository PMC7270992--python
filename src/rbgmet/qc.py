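"""Feature- and sample-level quality-control filters.

The filters run in pipeline order:

1. feature filter on pooled-QC replicates — drop features with technical
   RSD > 30% or detection rate < 70% across QC injections;
2. sample filter on study samples, evaluated within each assay dataset —
   drop samples with > 50% missing features or a total peak area (TPA) more
   than three SDs above the assay mean;
3. class-missingness filter — drop features missing in > 30% of samples in
   *both* genotype classes (features heavily missing in only one class are
   kept: differential missingness is informative and handled downstream).

RSD is computed on raw peak areas with the sample (n-1) standard deviation,
the metabolomics convention for pooled-QC precision.  Both sample rules are
evaluated on the same input (not sequentially re-estimated), so the removal
log is order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ASSAYS, FeatureTable, qc_samples, study_samples

RSD_MAX_DEFAULT = 30.0
DETECTION_MIN_DEFAULT = 70.0
SAMPLE_MISS_MAX_DEFAULT = 50.0
TPA_SD_DEFAULT = 3.0
CLASS_MISS_MAX_DEFAULT = 30.0


@dataclass
class QCReport:
    """Per-feature and per-sample QC statistics with pass/fail flags.

    ``feature_stats`` is indexed by feature id with columns
    ``rsd_qc`` (%, NaN when undefined), ``detection_qc`` (%), ``qc_pass``
    and ``reason`` (semicolon-joined codes for failures).
    ``sample_stats`` is indexed by (assay, sample id) with columns
    ``missing_pct`` and ``tpa``.
    """

    feature_stats: pd.DataFrame
    sample_stats: pd.DataFrame
    rsd_max: float
    det_min: float


def feature_qc_stats(
    table: FeatureTable,
    meta: pd.DataFrame,
    rsd_max: float = RSD_MAX_DEFAULT,
    det_min: float = DETECTION_MIN_DEFAULT,
) -> QCReport:
    """Technical precision and detection rate of every feature in pooled QC.

    RSD = 100 * sd / mean over the feature's *present* QC values (sample SD,
    denominator n-1); detection = 100 * (#QC injections with a present
    value) / (#QC injections).  A feature absent from all QC injections gets
    detection 0 and undefined RSD, and fails.
    """
    qc = qc_samples(meta, table)
    if len(qc) < 2:
        raise ValueError(
            f"feature QC requires >= 2 pooled-QC samples, found {len(qc)}"
        )
    qc_vals = table.values[qc.index]
    n_qc = len(qc)
    n_present = qc_vals.notna().sum(axis=1)
    detection = 100.0 * n_present / n_qc
    mean = qc_vals.mean(axis=1)
    sd = qc_vals.std(axis=1, ddof=1)
    rsd = 100.0 * sd / mean
    rsd[n_present < 2] = np.nan

    reasons = []
    for fid in table.features:
        r = []
        # undefined RSD (fewer than 2 present QC values) fails any finite cap
        if (np.isnan(rsd[fid]) and np.isfinite(rsd_max)) or rsd[fid] > rsd_max:
            r.append(f"rsd_qc>{rsd_max:g}")
        if detection[fid] < det_min:
            r.append(f"detection_qc<{det_min:g}")
        reasons.append(";".join(r))
    feature_stats = pd.DataFrame(
        {
            "rsd_qc": rsd,
            "detection_qc": detection,
            "qc_pass": [r == "" for r in reasons],
            "reason": reasons,
        },
        index=table.features,
    )

    sample_stats = _sample_stats(table, meta)
    return QCReport(feature_stats, sample_stats, rsd_max, det_min)


def _sample_stats(table: FeatureTable, meta: pd.DataFrame) -> pd.DataFrame:
    """Missing% and TPA of every study sample within each assay dataset."""
    study = study_samples(meta, table)
    rows = []
    for assay in ASSAYS:
        feats = table.feature_meta.index[table.feature_meta["assay"] == assay]
        if len(feats) == 0:
            continue
        block = table.values.loc[feats, study.index]
        missing_pct = 100.0 * block.isna().sum(axis=0) / len(feats)
        tpa = block.sum(axis=0, skipna=True)
        for sid in study.index:
            rows.append(
                {"assay": assay, "sample_id": sid,
                 "missing_pct": float(missing_pct[sid]), "tpa": float(tpa[sid])}
            )
    return pd.DataFrame(rows).set_index(["assay", "sample_id"])


def apply_feature_qc_filter(
    table: FeatureTable,
    report: QCReport,
    rsd_max: float = RSD_MAX_DEFAULT,
    det_min: float = DETECTION_MIN_DEFAULT,
) -> tuple[FeatureTable, pd.DataFrame]:
    """Remove features failing the pooled-QC precision/detection thresholds.

    Returns the filtered table and a removal log (feature id, rsd_qc,
    detection_qc, reason).  Thresholds may be re-specified here; flags are
    re-evaluated from the report's statistics.
    """
    stats = report.feature_stats.loc[table.features]
    fail_rsd = (stats["rsd_qc"].isna() & np.isfinite(rsd_max)) | (stats["rsd_qc"] > rsd_max)
    fail_det = stats["detection_qc"] < det_min
    removed = stats.index[fail_rsd | fail_det]
    reasons = []
    for fid in removed:
        r = []
        if fail_rsd[fid]:
            r.append(f"rsd_qc>{rsd_max:g}")
        if fail_det[fid]:
            r.append(f"detection_qc<{det_min:g}")
        reasons.append(";".join(r))
    log = stats.loc[removed, ["rsd_qc", "detection_qc"]].copy()
    log["reason"] = reasons
    kept = table.features.difference(removed, sort=False)
    return table.subset_features(kept), log


def apply_sample_filters(
    table: FeatureTable,
    meta: pd.DataFrame,
    miss_max: float = SAMPLE_MISS_MAX_DEFAULT,
    tpa_sd: float = TPA_SD_DEFAULT,
) -> tuple[FeatureTable, pd.DataFrame]:
    """Remove study samples with excess missingness or outlying TPA.

    Both rules are evaluated per assay dataset over study samples only
    (pooled QC is exempt): missing% > ``miss_max``, or TPA greater than
    mean + ``tpa_sd`` * SD of that assay's study-sample TPAs.  A sample
    failing in any assay is removed from the table; the log records every
    (sample, assay, rule) violation with the offending value.
    """
    stats = _sample_stats(table, meta)
    log_rows = []
    to_remove: set = set()
    for assay in stats.index.get_level_values("assay").unique():
        block = stats.loc[assay]
        cut = block["tpa"].mean() + tpa_sd * block["tpa"].std(ddof=1)
        for sid, row in block.iterrows():
            if row["missing_pct"] > miss_max:
                log_rows.append(
                    {"sample_id": sid, "assay": assay, "reason": f"missing_pct>{miss_max:g}",
                     "value": row["missing_pct"], "cutoff": miss_max}
                )
                to_remove.add(sid)
            if pd.notna(cut) and row["tpa"] > cut:
                log_rows.append(
                    {"sample_id": sid, "assay": assay, "reason": f"tpa>mean+{tpa_sd:g}sd",
                     "value": row["tpa"], "cutoff": float(cut)}
                )
                to_remove.add(sid)
    log = pd.DataFrame(log_rows, columns=["sample_id", "assay", "reason", "value", "cutoff"])
    kept = [s for s in table.samples if s not in to_remove]
    n_study_kept = len(study_samples(meta).index.intersection(kept))
    if n_study_kept == 0:
        raise ValueError("sample filters removed every study sample (degenerate study)")
    return table.subset_samples(kept), log


def apply_class_missingness_filter(
    table: FeatureTable,
    meta: pd.DataFrame,
    max_miss: float = CLASS_MISS_MAX_DEFAULT,
) -> tuple[FeatureTable, pd.DataFrame]:
    """Remove features missing in more than ``max_miss``% of *both* classes.

    Missing% is computed separately over carrier and non-carrier study
    samples; a feature is excluded only when both exceed the threshold, so
    class-specific absence (the MNAR signal) survives to the Fisher track.
    """
    study = study_samples(meta, table)
    carriers = study.index[study["genotype"] == "carrier"]
    controls = study.index[study["genotype"] == "non-carrier"]
    if len(carriers) == 0 or len(controls) == 0:
        empty = "carrier" if len(carriers) == 0 else "non-carrier"
        raise ValueError(f"genotype class {empty!r} has no study samples")
    miss_c = 100.0 * table.values[carriers].isna().sum(axis=1) / len(carriers)
    miss_n = 100.0 * table.values[controls].isna().sum(axis=1) / len(controls)
    drop = (miss_c > max_miss) & (miss_n > max_miss)
    log = pd.DataFrame(
        {"missing_pct_carrier": miss_c[drop], "missing_pct_noncarrier": miss_n[drop],
         "reason": f"missing>{max_miss:g}% in both classes"}
    )
    return table.subset_features(table.features[~drop]), log
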