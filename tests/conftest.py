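"""Shared fixtures: tiny hand-built tables and a small simulated study."""

import numpy as np
import pandas as pd
import pytest

from rbgmet.datatypes import FeatureTable
from rbgmet.simulate import SimConfig, simulate_study


def make_feature_meta(feature_ids, assay="HILIC-POS", lipid_class=None, annotation=None):
    n = len(feature_ids)
    return pd.DataFrame(
        {
            "assay": [assay] * n if isinstance(assay, str) else list(assay),
            "mz": np.linspace(100.0, 900.0, n),
            "rt": np.linspace(30.0, 800.0, n),
            "annotation": [annotation] * n if not isinstance(annotation, (list, tuple)) else list(annotation),
            "lipid_class": [lipid_class] * n if not isinstance(lipid_class, (list, tuple)) else list(lipid_class),
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )


def make_meta(sample_ids, genotype, cohort="young", is_qc=None, age=None, sex=None,
              fasting=True, subject=None):
    n = len(sample_ids)
    is_qc = [False] * n if is_qc is None else list(is_qc)
    geno = list(genotype)
    return pd.DataFrame(
        {
            "subject_id": list(subject) if subject is not None else [f"subj-{i}" for i in range(n)],
            "family_id": [f"fam-{i}" for i in range(n)],
            "genotype": [g if not q else np.nan for g, q in zip(geno, is_qc)],
            "age": list(age) if age is not None else [20.0 + i for i in range(n)],
            "sex": list(sex) if sex is not None else ["F", "M"] * (n // 2 + 1),
            "cohort": [cohort] * n if isinstance(cohort, str) else list(cohort),
            "fasting": [fasting] * n if isinstance(fasting, bool) else list(fasting),
            "is_qc": is_qc,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )


@pytest.fixture(scope="session")
def small_study():
    """A small, fully deterministic simulated study with effects and censoring."""
    cfg = SimConfig(
        n_carriers=12,
        controls_per_carrier=2,
        n_mothers_fraction=0.5,
        repeat_measure_prob=0.4,
        n_features_per_class={"TAG": 30, "acyl-alkyl GPL": 15, "other": 30},
        effect_by_class={"TAG": -1.5, "acyl-alkyl GPL": 1.0, "other": 0.0},
        dilution_sd=0.2,
        tech_rsd=10.0,
        biol_sd=0.5,
        lod_quantile=0.1,
        n_qc=6,
        duplicate_rate=0.2,
        seed=11,
    )
    return simulate_study(cfg)


@pytest.fixture()
def qc_fixture():
    """Hand-built 12-feature x 25-sample table with known filter violations.

    Samples: 20 study (8 carrier / 12 non-carrier) + 5 pooled QC.
    Planted violations (all other features/samples clean):

    * F_RSD    — QC values (5, 10, 15, 10, 10): RSD 50% > 30%  -> feature fails
    * F_DET    — present in 3/5 QC injections: detection 60% < 70% -> fails
    * F_BOTH   — QC (5, 10, 15) present in 3/5: fails both rules
    * F_CLASSM — missing in 50% of carriers AND 50% of non-carriers -> class filter
    * F_CARRM  — missing in 75% of carriers, 0% of non-carriers -> retained
    * S_MISS   — study sample missing 7/12 features (58.3% > 50%) -> removed
    * S_TPA    — study sample with TPA far above mean + 3 SD       -> removed
    """
    rng = np.random.default_rng(5)
    feats = [f"F{i:02d}" for i in range(1, 8)] + [
        "F_RSD", "F_DET", "F_BOTH", "F_CLASSM", "F_CARRM"
    ]
    study_ids = [f"S{i:02d}" for i in range(1, 21)]
    qc_ids = [f"QC{i}" for i in range(1, 6)]
    samples = study_ids + qc_ids
    genotype = ["carrier"] * 8 + ["non-carrier"] * 12 + [np.nan] * 5
    meta = make_meta(
        samples, genotype, is_qc=[False] * 20 + [True] * 5,
        sex=["F"] * 25, age=[30.0] * 25,
    )

    # clean baseline: constant-ish values near 100
    vals = pd.DataFrame(
        100.0 + rng.uniform(-1, 1, size=(12, 25)), index=feats, columns=samples
    )
    # QC columns exactly constant for clean features (RSD 0, detection 100)
    vals.loc[:, qc_ids] = 100.0
    vals.loc["F_RSD", qc_ids] = [5.0, 10.0, 15.0, 10.0, 10.0]
    vals.loc["F_DET", qc_ids] = [100.0, 100.0, 100.0, np.nan, np.nan]
    vals.loc["F_BOTH", qc_ids] = [5.0, 10.0, 15.0, np.nan, np.nan]
    # class-missingness: 4/8 carriers and 6/12 non-carriers missing
    vals.loc["F_CLASSM", study_ids[:4]] = np.nan
    vals.loc["F_CLASSM", study_ids[8:14]] = np.nan
    # carrier-only missingness: 6/8 carriers missing
    vals.loc["F_CARRM", study_ids[:6]] = np.nan
    # sample violations
    vals.loc[feats[:7], "S01"] = 100.0  # keep S01 clean; plant on S19/S20
    vals.loc[[f"F{i:02d}" for i in range(1, 8)], "S20"] = 100.0
    vals.loc[feats[:7], "S19"] = np.nan  # 7/12 missing -> 58.3%
    vals.loc[:, "S20"] = 10000.0  # TPA outlier
    table = FeatureTable(vals, make_feature_meta(feats))
    return table, meta
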