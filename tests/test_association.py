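"""Association models: OLS/mixed paths, BH, fold change, variance explained."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rbgmet.association import (
    ModelSpec,
    associate_dataset,
    bh_adjust,
    fit_feature_association,
    fold_change,
    int_attenuated_effect,
    run_primary_analyses,
    select_dataset_samples,
    variance_explained,
    _design,
)
from rbgmet.datatypes import FeatureTable
from rbgmet.lmm import fit_lmm_ml
from rbgmet.normalize import pqn_normalize, transform_table
from rbgmet.simulate import SimConfig, simulate_study

from conftest import make_feature_meta, make_meta
from oracles import bh_oracle, ols_oracle


def _meta_no_repeats(n=30, seed=0):
    rng = np.random.default_rng(seed)
    ids = [f"S{i}" for i in range(n)]
    geno = ["carrier"] * (n // 3) + ["non-carrier"] * (n - n // 3)
    return make_meta(ids, geno, sex=list(rng.choice(["F", "M"], n)),
                     age=list(rng.uniform(15, 60, n)))


class TestSingleFeatureFits:
    def test_perfect_separation_recovers_unit_beta(self):
        meta = _meta_no_repeats(24)
        y = pd.Series((meta["genotype"] == "carrier").astype(float).to_numpy(),
                      index=meta.index, name="F")
        res = fit_feature_association(y, meta, ModelSpec("combined", False))
        assert res.model_kind == "ols"
        assert res.beta == pytest.approx(1.0, abs=1e-12)
        assert res.p == pytest.approx(0.0, abs=1e-12)

    def test_ols_matches_independent_oracle(self):
        """beta/se/p equal the statsmodels OLS solution to 1e-8 on random
        instances."""
        for seed in range(25):
            rng = np.random.default_rng(seed)
            meta = _meta_no_repeats(rng.integers(12, 60), seed)
            y = pd.Series(rng.normal(size=len(meta)), index=meta.index, name="F")
            res = fit_feature_association(y, meta, ModelSpec("combined", False))
            X, _ = _design(meta)
            b, s, p = ols_oracle(y.to_numpy(), X)
            assert res.beta == pytest.approx(b, abs=1e-8)
            assert res.se == pytest.approx(s, abs=1e-8)
            assert res.p == pytest.approx(p, abs=1e-8)

    def test_mixed_path_matches_statsmodels(self):
        """The profiled-likelihood mixed solver agrees with statsmodels
        MixedLM (ML) on beta and se."""
        import warnings
        from statsmodels.regression.mixed_linear_model import MixedLM

        rng = np.random.default_rng(7)
        n_subj = 25
        subj = np.repeat([f"p{i}" for i in range(n_subj)], 2)
        n = len(subj)
        geno = np.repeat(rng.choice([0.0, 1.0], n_subj, p=[2 / 3, 1 / 3]), 2)
        age = np.repeat(rng.uniform(15, 60, n_subj), 2)
        u = np.repeat(rng.normal(0, 0.7, n_subj), 2)
        y = 0.8 * geno + 0.01 * age + u + rng.normal(0, 1, n)
        X = np.column_stack([np.ones(n), geno, age])
        own = fit_lmm_ml(y, X, subj)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sm_fit = MixedLM(y, X, groups=pd.factorize(subj)[0]).fit(reml=False)
        assert own.beta[1] == pytest.approx(sm_fit.params[1], abs=1e-4)
        assert own.se[1] == pytest.approx(sm_fit.bse[1], rel=1e-2)
        assert own.loglik == pytest.approx(sm_fit.llf, abs=1e-4)

    def test_mixed_with_no_group_variance_converges_to_ols(self):
        """When the generator has zero random-effect variance the mixed fit
        lands on the OLS estimate (within 1e-3)."""
        rng = np.random.default_rng(3)
        n_subj = 40
        subj = np.repeat([f"p{i}" for i in range(n_subj)], 2)
        n = len(subj)
        geno = np.repeat(rng.choice([0.0, 1.0], n_subj), 2)
        y = 0.5 * geno + rng.normal(0, 1, n)  # no subject effect at all
        X = np.column_stack([np.ones(n), geno])
        own = fit_lmm_ml(y, X, subj)
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert own.beta[1] == pytest.approx(beta_ols[1], abs=1e-3)

    def test_too_few_observations_errors(self):
        meta = _meta_no_repeats(10)
        y = pd.Series([1.0, 2.0] + [np.nan] * 8, index=meta.index, name="F")
        with pytest.raises(ValueError, match="informative"):
            fit_feature_association(y, meta, ModelSpec("combined", False))

    def test_sex_dropped_when_constant(self):
        meta = _meta_no_repeats(20)
        meta["sex"] = "F"
        X, names = _design(meta)
        assert "sex" not in names


class TestBH:
    def test_hand_example(self):
        q = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_degenerate_inputs(self):
        assert bh_adjust(np.array([0.3])).tolist() == [0.3]
        assert bh_adjust(np.array([1.0, 1.0, 1.0])).tolist() == [1.0, 1.0, 1.0]
        assert bh_adjust(np.array([])).size == 0
        with pytest.raises(ValueError):
            bh_adjust(np.array([1.5]))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False),
                    min_size=1, max_size=120))
    def test_matches_from_definition_oracle(self, ps):
        p = np.asarray(ps)
        np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)
        # order preservation: q ranks follow p ranks
        q = bh_adjust(p)
        assert ((p[:, None] < p[None, :]) <= (q[:, None] <= q[None, :])).all()


class TestFoldChangeAndR2:
    def test_fold_change_examples(self):
        ids = ["C1", "C2", "N1", "N2"]
        meta = make_meta(ids, ["carrier", "carrier", "non-carrier", "non-carrier"],
                         sex=["F"] * 4)
        vals = pd.DataFrame(
            [[1.0, 3.0, 2.0, 2.0],   # means 2 vs 2 -> 1.0
             [1.0, 1.0, 2.0, 2.0],   # 1 vs 2 -> 0.5
             [5.0, 5.0, 5.0, 5.0]],  # equal -> 1.0
            index=["A", "B", "C"], columns=ids,
        )
        table = FeatureTable(vals, make_feature_meta(["A", "B", "C"]))
        fc = fold_change(table, meta)
        assert fc["A"] == pytest.approx(1.0)
        assert fc["B"] == pytest.approx(0.5)
        assert fc["C"] == pytest.approx(1.0)

    def test_fold_change_undefined_flagged(self):
        ids = ["C1", "N1"]
        meta = make_meta(ids, ["carrier", "non-carrier"], sex=["F", "F"])
        vals = pd.DataFrame([[np.nan, 2.0]], index=["A"], columns=ids)
        table = FeatureTable(vals, make_feature_meta(["A"]))
        assert np.isnan(fold_change(table, meta)["A"])

    def test_variance_explained_pure_genotype(self):
        meta = _meta_no_repeats(40)
        y = pd.Series((meta["genotype"] == "carrier").astype(float).to_numpy(),
                      index=meta.index, name="F")
        out = variance_explained(y, meta)
        assert out["full_pct"] == pytest.approx(100.0)
        assert out["genotype_pct"] > 90.0

    def test_incremental_r2_sums_under_orthogonality(self):
        """With mutually orthogonal balanced predictors the incremental
        R-squareds add up to the full-model R-squared."""
        n = 8
        ids = [f"S{i}" for i in range(n)]
        geno = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        sex = np.array([0, 0, 1, 1, 0, 0, 1, 1])
        age = np.array([0, 1, 0, 1, 0, 1, 0, 1]) * 2.0 + 20
        meta = make_meta(
            ids, ["non-carrier" if g == 0 else "carrier" for g in geno],
            sex=["F" if s == 0 else "M" for s in sex], age=list(age),
        )
        rng = np.random.default_rng(0)
        y = pd.Series(1.0 * geno + 0.5 * sex + 0.25 * (age - 20) + rng.normal(0, 0.3, n),
                      index=ids, name="F")
        out = variance_explained(y, meta)
        total = out["genotype_pct"] + out["sex_pct"] + out["age_pct"]
        assert total == pytest.approx(out["full_pct"], abs=1e-8)

    def test_null_variance_small(self):
        """y independent of all predictors: each share stays below 1% in at
        least 95 of 100 seeds at n=1000."""
        good = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            meta = _meta_no_repeats(1000, seed)
            y = pd.Series(rng.normal(size=1000), index=meta.index, name="F")
            out = variance_explained(y, meta)
            good += max(out["genotype_pct"], out["age_pct"], out["sex_pct"]) < 1.0
        assert good >= 95

    def test_constant_predictor_flagged(self):
        meta = _meta_no_repeats(20)
        meta["sex"] = "F"
        y = pd.Series(np.random.default_rng(0).normal(size=20),
                      index=meta.index, name="F")
        out = variance_explained(y, meta)
        assert "sex" in out["flags"] and out["sex_pct"] == 0.0


@pytest.fixture(scope="module")
def prepared(small_study):
    from rbgmet.qc import (
        apply_class_missingness_filter,
        apply_feature_qc_filter,
        apply_sample_filters,
        feature_qc_stats,
    )

    table, meta, truth = small_study
    t1, _ = apply_feature_qc_filter(table, feature_qc_stats(table, meta))
    t2, _ = apply_sample_filters(t1, meta)
    t3, _ = apply_class_missingness_filter(t2, meta)
    norm = pqn_normalize(t3, meta)
    from rbgmet.datatypes import study_samples

    study = study_samples(meta, norm.normalized).index
    transformed = transform_table(norm.normalized.subset_samples(study))
    return transformed, norm.normalized, meta, truth


class TestPrimaryAnalyses:

    def test_three_datasets_and_union_rule(self, prepared):
        transformed, normalized, meta, truth = prepared
        res = run_primary_analyses(transformed, normalized, meta)
        assert set(res.per_dataset) == {"combined", "mothers", "young"}
        # union rule: associated iff q < alpha in at least one dataset
        manual = set()
        for df in res.per_dataset.values():
            manual |= set(df.index[df["q"] < 0.05])
        assert set(res.associated) == manual
        # strong simulated effects are detected
        hits = set(res.associated) & truth.affected
        assert len(hits) > 0

    def test_determinism(self, prepared):
        transformed, normalized, meta, _ = prepared
        r1 = run_primary_analyses(transformed, normalized, meta)
        r2 = run_primary_analyses(transformed, normalized, meta)
        for ds in r1.per_dataset:
            pd.testing.assert_frame_equal(r1.per_dataset[ds], r2.per_dataset[ds])

    def test_primary_drops_nonfasting(self, prepared):
        transformed, _, meta, _ = prepared
        prim = select_dataset_samples(meta, transformed, "combined", "primary")
        keep = select_dataset_samples(meta, transformed, "combined", "keep_nonfasting")
        nonfast = meta.index[(~meta["fasting"].astype(bool)) & (~meta["is_qc"])]
        assert len(set(prim) & set(nonfast)) == 0
        assert set(nonfast) & set(transformed.samples) <= set(keep)

    def test_mixed_used_only_with_repeats(self, prepared):
        transformed, normalized, meta, _ = prepared
        res = run_primary_analyses(transformed, normalized, meta)
        for ds, df in res.per_dataset.items():
            samples = select_dataset_samples(meta, transformed, ds)
            reps = meta.loc[samples, "subject_id"].value_counts().max() > 1
            expect = "mixed" if reps else "ols"
            assert (df["model_kind"] == expect).all()


def test_clinical_measures_analyzed_untransformed():
    """Clinical lipids go through the same models on their own scale, so a
    planted 0.5 mmol/L carrier effect is recovered directly; a dataset with
    no genotype contrast is skipped rather than reported as zero."""
    from rbgmet.association import associate_clinical

    rng = np.random.default_rng(1)
    n = 90
    meta = make_meta(
        [f"S{i}" for i in range(n)],
        (["carrier"] * 10 + ["non-carrier"] * 20) * 3,
        cohort=["young"] * 60 + ["mother"] * 30,
        sex=["F"] * n, age=[30.0] * n,
        subject=[f"p{i}" for i in range(n)],
    )
    g = (meta["genotype"] == "carrier").astype(float).to_numpy()
    clin = pd.DataFrame(
        {"HDL": 1.2 + 0.5 * g + rng.normal(0, 0.1, n)}, index=meta.index
    )
    out = associate_clinical(clin, meta)
    comb = out[(out["measure"] == "HDL") & (out["dataset"] == "combined")]
    assert comb["beta"].iloc[0] == pytest.approx(0.5, abs=0.1)
    # no rank transform: effects are on the mmol/L scale
    assert comb["beta"].iloc[0] > 0.3

    # a dataset without both genotype classes yields no row
    meta2 = meta.copy()
    meta2.loc[meta2["cohort"] == "mother", "genotype"] = "non-carrier"
    out2 = associate_clinical(clin, meta2)
    assert "mothers" not in set(out2["dataset"])


def test_int_attenuated_effect_properties():
    assert int_attenuated_effect(0.0, 1 / 3) == pytest.approx(0.0, abs=1e-8)
    vals = [int_attenuated_effect(d, 1 / 3) for d in (0.5, 1.0, 1.5)]
    assert vals[0] < vals[1] < vals[2]
    # the transform compresses: |effect| no larger than the raw delta
    for d, v in zip((0.5, 1.0, 1.5), vals):
        assert 0 < v <= d
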