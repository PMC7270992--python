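"""QC filters: hand-computed statistics, rule application, bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from rbgmet.datatypes import FeatureTable
from rbgmet.qc import (
    apply_class_missingness_filter,
    apply_feature_qc_filter,
    apply_sample_filters,
    feature_qc_stats,
)

from conftest import make_feature_meta, make_meta


def _table_with_qc(qc_rows: dict, n_qc: int, n_study: int = 6):
    """One table whose QC columns are set per feature from `qc_rows`."""
    feats = list(qc_rows)
    study_ids = [f"S{i}" for i in range(n_study)]
    qc_ids = [f"QC{i}" for i in range(n_qc)]
    meta = make_meta(
        study_ids + qc_ids,
        ["carrier"] * (n_study // 2) + ["non-carrier"] * (n_study - n_study // 2)
        + [np.nan] * n_qc,
        is_qc=[False] * n_study + [True] * n_qc,
        sex=["F"] * (n_study + n_qc),
    )
    vals = pd.DataFrame(50.0, index=feats, columns=study_ids + qc_ids)
    for f, row in qc_rows.items():
        vals.loc[f, qc_ids] = row
    return FeatureTable(vals, make_feature_meta(feats)), meta


def test_rsd_and_detection_hand_computations():
    """QC (8,10,12) -> RSD 20% (pass); (5,10,15) -> 50% (fail); a feature in
    6/10 injections -> detection 60% (fail at the 70% threshold)."""
    table, meta = _table_with_qc(
        {
            "F_pass": [8.0, 10.0, 12.0] + [10.0] * 7,
            "F_rsd": [5.0, 10.0, 15.0] + [10.0] * 7,
            "F_det": [10.0] * 6 + [np.nan] * 4,
        },
        n_qc=10,
    )
    report = feature_qc_stats(table, meta)
    fs = report.feature_stats
    assert fs.loc["F_pass", "rsd_qc"] == pytest.approx(
        100 * np.std([8, 10, 12] + [10] * 7, ddof=1) / 10
    )
    # the classic 3-point example at n=3 QC injections
    t3, m3 = _table_with_qc({"F": [8.0, 10.0, 12.0]}, n_qc=3)
    r3 = feature_qc_stats(t3, m3).feature_stats
    assert r3.loc["F", "rsd_qc"] == pytest.approx(20.0)
    t3b, m3b = _table_with_qc({"F": [5.0, 10.0, 15.0]}, n_qc=3)
    r3b = feature_qc_stats(t3b, m3b).feature_stats
    assert r3b.loc["F", "rsd_qc"] == pytest.approx(50.0)
    assert not r3b.loc["F", "qc_pass"]

    assert fs.loc["F_det", "detection_qc"] == pytest.approx(60.0)
    assert not fs.loc["F_det", "qc_pass"]
    assert "detection" in fs.loc["F_det", "reason"]


def test_feature_absent_from_qc_fails_with_undefined_rsd():
    table, meta = _table_with_qc({"F_none": [np.nan] * 4, "F_ok": [9.0] * 4}, n_qc=4)
    fs = feature_qc_stats(table, meta).feature_stats
    assert fs.loc["F_none", "detection_qc"] == 0.0
    assert np.isnan(fs.loc["F_none", "rsd_qc"])
    assert not fs.loc["F_none", "qc_pass"]


def test_feature_qc_requires_two_qc_samples():
    table, meta = _table_with_qc({"F": [5.0]}, n_qc=1)
    with pytest.raises(ValueError, match="2 pooled-QC"):
        feature_qc_stats(table, meta)


def test_feature_filter_identity_and_removal_log():
    table, meta = _table_with_qc(
        {"A": [10.0] * 4, "B": [10.0] * 4, "C": [10.0] * 4,
         "D": [1.0, 20.0, 10.0, 10.0], "E": [np.nan, np.nan, np.nan, 10.0]},
        n_qc=4,
    )
    report = feature_qc_stats(table, meta)
    filtered, log = apply_feature_qc_filter(table, report)
    assert list(filtered.features) == ["A", "B", "C"]
    assert set(log.index) == {"D", "E"}
    # relaxing both thresholds to no-ops keeps everything
    same, log2 = apply_feature_qc_filter(table, report, rsd_max=np.inf, det_min=0)
    assert list(same.features) == list(table.features)
    assert len(log2) == 0


def test_sample_tpa_cutoff_hand_computation():
    """20 samples with TPA 100 plus one with 200: mean 104.76, sd 21.82,
    cut-off 170.2 -> only the 200 sample is excluded."""
    ids = [f"S{i}" for i in range(21)]
    meta = make_meta(ids + ["QC1", "QC2"],
                     ["carrier"] * 10 + ["non-carrier"] * 11 + [np.nan] * 2,
                     is_qc=[False] * 21 + [True] * 2, sex=["F"] * 23)
    vals = pd.DataFrame(
        [[100.0] * 20 + [200.0] + [100.0, 100.0]], index=["F1"], columns=ids + ["QC1", "QC2"]
    )
    table = FeatureTable(vals, make_feature_meta(["F1"]))
    filtered, log = apply_sample_filters(table, meta)
    assert "S20" not in filtered.samples
    assert len(log) == 1
    assert log.iloc[0]["sample_id"] == "S20"
    assert log.iloc[0]["cutoff"] == pytest.approx(170.2, abs=0.1)
    # QC columns are never dropped
    assert {"QC1", "QC2"} <= set(filtered.samples)


def test_sample_missingness_rule():
    """A sample missing 6 of 10 features (60%) is excluded at the 50% rule."""
    feats = [f"F{i}" for i in range(10)]
    ids = [f"S{i}" for i in range(8)]
    meta = make_meta(ids + ["QC1", "QC2"],
                     ["carrier"] * 4 + ["non-carrier"] * 4 + [np.nan] * 2,
                     is_qc=[False] * 8 + [True] * 2, sex=["F"] * 10)
    vals = pd.DataFrame(100.0, index=feats, columns=ids + ["QC1", "QC2"])
    vals.loc[feats[:6], "S0"] = np.nan
    table = FeatureTable(vals, make_feature_meta(feats))
    filtered, log = apply_sample_filters(table, meta)
    assert "S0" not in filtered.samples
    assert log.iloc[0]["reason"].startswith("missing_pct")
    assert log.iloc[0]["value"] == pytest.approx(60.0)


def test_identical_samples_none_excluded():
    feats = ["F1", "F2"]
    ids = [f"S{i}" for i in range(6)]
    meta = make_meta(ids, ["carrier"] * 3 + ["non-carrier"] * 3, sex=["F"] * 6)
    vals = pd.DataFrame(42.0, index=feats, columns=ids)
    table = FeatureTable(vals, make_feature_meta(feats))
    filtered, log = apply_sample_filters(table, meta)
    assert len(log) == 0
    assert list(filtered.samples) == ids


def test_class_missingness_rule():
    """Excluded iff missing% exceeds the threshold in BOTH classes."""
    feats = ["F_both", "F_one", "F_full"]
    car = [f"C{i}" for i in range(10)]
    con = [f"N{i}" for i in range(10)]
    meta = make_meta(car + con, ["carrier"] * 10 + ["non-carrier"] * 10,
                     sex=["F"] * 20)
    vals = pd.DataFrame(10.0, index=feats, columns=car + con)
    vals.loc["F_both", car[:4]] = np.nan  # 40% carriers
    vals.loc["F_both", con[:4]] = np.nan  # 40% controls
    vals.loc["F_one", car[:4]] = np.nan   # 40% carriers only
    vals.loc["F_one", con[0]] = np.nan    # 10% controls
    table = FeatureTable(vals, make_feature_meta(feats))
    filtered, log = apply_class_missingness_filter(table, meta)
    assert list(filtered.features) == ["F_one", "F_full"]
    assert list(log.index) == ["F_both"]


def test_class_filter_requires_both_classes():
    feats = ["F1"]
    ids = ["S1", "S2"]
    meta = make_meta(ids, ["carrier", "carrier"], sex=["F", "F"],
                     subject=["a", "b"])
    table = FeatureTable(pd.DataFrame(1.0, index=feats, columns=ids),
                         make_feature_meta(feats))
    with pytest.raises(ValueError, match="non-carrier"):
        apply_class_missingness_filter(table, meta)


def test_filters_idempotent_and_threshold_monotone(small_study):
    """Applying a filter twice equals once; relaxing thresholds never
    removes more items."""
    table, meta, _ = small_study
    report = feature_qc_stats(table, meta)
    f1, log1 = apply_feature_qc_filter(table, report)
    f2, log2 = apply_feature_qc_filter(f1, report)
    assert list(f1.features) == list(f2.features) and len(log2) == 0

    s1, slog1 = apply_sample_filters(f1, meta)
    # the missingness rule is idempotent (feature set unchanged); the TPA
    # cut-off is defined single-pass, so only re-estimated TPA removals may
    # appear on a second application
    s2, slog2 = apply_sample_filters(s1, meta)
    assert not any(slog2["reason"].str.startswith("missing_pct"))

    c1, clog1 = apply_class_missingness_filter(s1, meta)
    c2, clog2 = apply_class_missingness_filter(c1, meta)
    assert list(c1.features) == list(c2.features) and len(clog2) == 0

    # monotonicity in thresholds
    strict, _ = apply_feature_qc_filter(table, report, rsd_max=20, det_min=80)
    loose, _ = apply_feature_qc_filter(table, report, rsd_max=40, det_min=60)
    assert set(strict.features) <= set(loose.features)
    cs, _ = apply_class_missingness_filter(s1, meta, max_miss=10)
    cl, _ = apply_class_missingness_filter(s1, meta, max_miss=50)
    assert set(cs.features) <= set(cl.features)

    # bookkeeping: removed + retained = input
    assert table.n_features == f1.n_features + len(log1)
    assert s1.n_features == c1.n_features + len(clog1)


def test_qc_fixture_bookkeeping(qc_fixture):
    """The hand-built fixture's planted violations are each caught with the
    right reason code and nothing else is removed."""
    table, meta = qc_fixture
    report = feature_qc_stats(table, meta)
    t1, feat_log = apply_feature_qc_filter(table, report)
    assert set(feat_log.index) == {"F_RSD", "F_DET", "F_BOTH"}
    assert "rsd" in feat_log.loc["F_RSD", "reason"]
    assert "detection" in feat_log.loc["F_DET", "reason"]
    assert {"rsd", "detection"} <= {
        part.split("_")[0] for part in feat_log.loc["F_BOTH", "reason"].split(";")
    }
    t2, samp_log = apply_sample_filters(t1, meta)
    assert set(samp_log["sample_id"]) == {"S19", "S20"}
    t3, class_log = apply_class_missingness_filter(t2, meta)
    assert list(class_log.index) == ["F_CLASSM"]
    assert "F_CARRM" in t3.features
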