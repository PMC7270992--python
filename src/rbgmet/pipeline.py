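"""End-to-end pipeline driver and its configuration.

Stage order: pooled-QC feature filter -> sample filters -> class-missingness
filter -> (optional left-censored imputation) -> PQN -> rank-based
inverse-normal transform -> three-dataset abundance scan -> presence/absence
(Fisher) scan -> annotation dedup -> class summaries and figures.  Every
stage logs in/out counts; the provenance record (versions, seed, thresholds,
stage counts) is written alongside the result tables.  Outputs are
deterministic: two runs with the same inputs and configuration produce
byte-identical tables.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import run_primary_analyses
from .datatypes import FeatureTable, study_samples
from .missingness import overlap_summary, run_missingness_scan
from .normalize import impute_left_censored, pqn_normalize, transform_table
from .postprocess import (
    class_summary,
    cohort_table,
    dedup_annotations,
    plot_effect_by_mz,
    plot_heatmap,
    residualize_table,
)
from .qc import (
    apply_class_missingness_filter,
    apply_feature_qc_filter,
    apply_sample_filters,
    feature_qc_stats,
)


@dataclass
class PipelineConfig:
    """Thresholds, analysis mode and switches for one pipeline run."""

    rsd_max: float = 30.0
    det_min: float = 70.0
    sample_miss_max: float = 50.0
    tpa_sd: float = 3.0
    class_miss_max: float = 30.0
    fdr_alpha: float = 0.05
    mode: str = "primary"  # primary | keep_nonfasting | imputed
    imputation_method: str = "half_min"
    pqn_reference: str = "study_median"
    family_intercept_combined: bool = True
    make_figures: bool = True
    heatmap_exclude_classes: tuple[str, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        for name in ("rsd_max", "det_min", "sample_miss_max", "tpa_sd", "class_miss_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 < self.fdr_alpha < 1.0:
            raise ValueError("fdr_alpha must lie in (0, 1)")
        if self.mode not in ("primary", "keep_nonfasting", "imputed"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "heatmap_exclude_classes" in raw:
            raw["heatmap_exclude_classes"] = tuple(raw["heatmap_exclude_classes"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["heatmap_exclude_classes"] = list(self.heatmap_exclude_classes)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


@dataclass
class PipelineResult:
    """In-memory bundle of everything a pipeline run produced."""

    config: PipelineConfig
    tables: dict = field(default_factory=dict)
    stage_counts: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


def _count(stage: str, kind: str, n_in: int, n_removed: int) -> dict:
    return {
        "stage": stage,
        "kind": kind,
        "n_in": int(n_in),
        "n_removed": int(n_removed),
        "n_out": int(n_in - n_removed),
    }


def run_pipeline(
    table: FeatureTable,
    meta: pd.DataFrame,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    clinical: pd.DataFrame | None = None,
) -> PipelineResult:
    """Run the full analysis on a feature table + sample metadata.

    When ``out_dir`` is given, writes all result tables (TSV), the
    provenance record (JSON) and, unless disabled, the heatmap and
    effect-by-m/z figures (PNG).
    """
    config = config or PipelineConfig()
    config.validate()
    result = PipelineResult(config=config)
    counts = result.stage_counts

    # 1. pooled-QC feature filter
    report = feature_qc_stats(table, meta, config.rsd_max, config.det_min)
    t1, feat_log = apply_feature_qc_filter(table, report, config.rsd_max, config.det_min)
    counts.append(_count("feature_qc", "features", table.n_features, len(feat_log)))

    # 2. sample filters (study samples, per assay)
    n_study_in = len(study_samples(meta, t1))
    t2, sample_log = apply_sample_filters(t1, meta, config.sample_miss_max, config.tpa_sd)
    n_study_out = len(study_samples(meta, t2))
    counts.append(_count("sample_filters", "samples", n_study_in, n_study_in - n_study_out))

    # 3. class-missingness filter
    t3, class_log = apply_class_missingness_filter(t2, meta, config.class_miss_max)
    counts.append(_count("class_missingness", "features", t2.n_features, len(class_log)))

    # presence/absence track uses real (pre-imputation) missingness
    miss_scan = run_missingness_scan(t3, meta, config.fdr_alpha)

    # 4. optional imputation (sensitivity analysis)
    if config.mode == "imputed":
        t4 = impute_left_censored(t3, config.imputation_method)
    else:
        t4 = t3
    counts.append(_count("imputation", "features", t3.n_features, 0))

    # 5. PQN, 6. rank-normal transform (study samples only: pooled QC has
    # served its purpose and must not influence the rank distribution)
    norm = pqn_normalize(t4, meta, config.pqn_reference)
    study_cols = study_samples(meta, norm.normalized).index
    transformed = transform_table(norm.normalized.subset_samples(study_cols))

    # 7. three-dataset abundance scan
    primary = run_primary_analyses(
        transformed,
        norm.normalized,
        meta,
        mode=config.mode,
        alpha=config.fdr_alpha,
        family_intercept_combined=config.family_intercept_combined,
    )

    # 8. dedup + summaries per dataset
    dedup = {}
    summaries = {}
    for ds, res in primary.per_dataset.items():
        assoc = res[res["associated"]]
        dd = dedup_annotations(assoc, t3.feature_meta["annotation"], ds)
        dd = dd.join(t3.feature_meta[["lipid_class", "mz", "assay"]], how="left")
        dedup[ds] = dd
        summaries[ds] = class_summary(dd)

    result.tables = {
        "qc_feature_stats": report.feature_stats,
        "qc_sample_stats": report.sample_stats.reset_index(),
        "feature_filter_log": feat_log,
        "sample_filter_log": sample_log,
        "class_filter_log": class_log,
        "missingness_scan": miss_scan,
        "quotients": result_frame_from_series(norm.quotient),
        "cohort_table": cohort_table(meta, clinical),
        **{f"assoc_{ds}": df for ds, df in primary.per_dataset.items()},
        **{f"metabolites_{ds}": df for ds, df in dedup.items()},
        **{f"class_summary_{ds}": df for ds, df in summaries.items()},
    }
    result.tables["associated_features"] = pd.DataFrame(
        {"feature_id": primary.associated}
    ).set_index("feature_id")

    result.provenance = {
        "rbgmet_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": {**asdict(config),
                   "heatmap_exclude_classes": list(config.heatmap_exclude_classes)},
        "stage_counts": counts,
        "association_summary": primary.summary(),
        "missingness_summary": overlap_summary(miss_scan, primary.associated),
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in result.tables.items():
            df.to_csv(out / f"{name}.tsv", sep="\t", na_rep="")
        with open(out / "provenance.json", "w") as fh:
            json.dump(result.provenance, fh, indent=2, sort_keys=True)
        if config.make_figures and "combined" in primary.per_dataset:
            _figures(result, t3, transformed, meta, primary, dedup, out, config)
    return result


def _figures(result, t3, transformed, meta, primary, dedup, out: Path, config) -> None:
    combined = dedup.get("combined")
    if combined is not None and len(combined) >= 2:
        samples = study_samples(meta, transformed).index
        mat = transformed.subset_features(combined.index).subset_samples(samples)
        resid = residualize_table(mat, meta)
        dense = resid.values.dropna(axis=0, how="any")
        # complete-case rows: the heatmap needs a dense grid
        if dense.shape[0] >= 2 and dense.shape[1] >= 2:
            plot_heatmap(
                dense, meta, t3.feature_meta, str(out / "heatmap_combined.png"),
                exclude_classes=config.heatmap_exclude_classes,
            )
    res = primary.per_dataset.get("combined")
    if res is not None:
        plot_effect_by_mz(
            res[res["associated"]], t3.feature_meta, str(out / "effects_by_mz.png")
        )


def result_frame_from_series(s: pd.Series) -> pd.DataFrame:
    df = s.to_frame()
    df.index.name = "id"
    return df
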