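"""Per-feature genotype association: simple and mixed linear models,
Benjamini-Hochberg FDR, fold change, variance explained, and the
three-dataset primary analysis.

Each feature's transformed abundance is regressed on carrier status (coded
0/1), age and sex.  Within a given analysis dataset the model is ordinary
least squares when every subject contributes a single sample, and a
maximum-likelihood linear mixed model with a per-subject random intercept
(optionally nested in a family/pedigree intercept) when repeated measures are
present.  Inference on the genotype coefficient is a two-sided Wald test.
The scan is run on three datasets — combined, mothers only, young
participants only — with BH adjustment across all tested features within
each dataset; a feature is declared associated when q < alpha in at least
one of the three.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .lmm import fit_lmm_ml

from .datatypes import FeatureTable, study_samples
from .normalize import NormResult

DATASETS = ("combined", "mothers", "young")
ANALYSIS_MODES = ("primary", "keep_nonfasting", "imputed")


@dataclass
class ModelSpec:
    """How to fit one analysis dataset.

    ``family_intercept`` adds a family (pedigree) random intercept above the
    subject intercept; it is on by default only for the combined dataset,
    where mother-offspring pairs can co-occur.
    """

    dataset: str = "combined"
    family_intercept: bool = False

    def __post_init__(self) -> None:
        if self.dataset not in DATASETS:
            raise ValueError(f"unknown dataset {self.dataset!r}")


@dataclass
class AssocResult:
    """Genotype association result for one feature in one dataset."""

    feature_id: str
    beta: float
    se: float
    p: float
    n_samples: int
    n_subjects: int
    model_kind: str  # "ols" | "mixed"
    converged: bool
    q: float = np.nan
    fold_change: float = np.nan


# ---------------------------------------------------------------------------
# design handling


def _design(meta_rows: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Design matrix [intercept, genotype, age, (sex)] for given samples.

    Sex is dropped automatically when constant (e.g. the mothers-only
    dataset, all female).
    """
    g = (meta_rows["genotype"] == "carrier").to_numpy(dtype=float)
    age = meta_rows["age"].to_numpy(dtype=float)
    cols = [np.ones(len(meta_rows)), g, age]
    names = ["intercept", "genotype", "age"]
    sex = (meta_rows["sex"] == "M").to_numpy(dtype=float)
    if len(np.unique(sex)) > 1:
        cols.append(sex)
        names.append("sex")
    return np.column_stack(cols), names


def _ols_genotype(y: np.ndarray, X: np.ndarray) -> tuple[float, float, float]:
    """Closed-form OLS: genotype beta, its SE, and two-sided t-test p.

    The genotype column is X[:, 1]; SEs come from (X'X)^-1 * sigma^2 with
    sigma^2 = RSS / (n - p).
    """
    n = X.shape[0]
    beta_all, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    xtx_inv = np.linalg.pinv(X.T @ X)
    resid = y - X @ beta_all
    dof = n - int(rank)
    if dof <= 0:
        return float(beta_all[1]), np.nan, np.nan
    sigma2 = float(resid @ resid) / dof
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    if se == 0.0:
        return float(beta_all[1]), 0.0, 0.0
    t = beta_all[1] / se
    p = 2.0 * stats.t.sf(abs(t), dof)
    return float(beta_all[1]), se, float(p)


def _has_repeats(meta_rows: pd.DataFrame) -> bool:
    return bool(meta_rows["subject_id"].value_counts().max() > 1)


def fit_feature_association(
    y: pd.Series, meta: pd.DataFrame, spec: ModelSpec
) -> AssocResult:
    """Fit one feature's genotype association.

    ``y`` is the transformed abundance indexed by sample id (missing rows
    dropped listwise); ``meta`` must cover those samples.  The model is OLS
    when no subject repeats exist among the informative samples' dataset,
    else a mixed model with a subject random intercept fitted by maximum
    likelihood; non-convergence is reported via ``converged=False``, never
    silently dropped.
    """
    rows = meta.loc[y.index]
    mask = y.notna().to_numpy()
    yy = y.to_numpy(dtype=float)[mask]
    rows = rows.loc[y.index[mask]]
    if len(yy) < 3:
        raise ValueError(
            f"feature {y.name!r}: fewer than 3 informative observations ({len(yy)})"
        )
    if rows["genotype"].nunique() < 2:
        raise ValueError(f"feature {y.name!r}: no genotype contrast among informative rows")
    mixed = _has_repeats(meta.loc[y.index])
    X, names = _design(rows)
    n_subjects = rows["subject_id"].nunique()
    fid = str(y.name)
    if not mixed:
        beta, se, p = _ols_genotype(yy, X)
        return AssocResult(fid, beta, se, p, len(yy), n_subjects, "ols", True)
    beta, se, p, converged = _fit_mixed(yy, X, rows, spec)
    return AssocResult(fid, beta, se, p, len(yy), n_subjects, "mixed", converged)


def _fit_mixed(
    y: np.ndarray, X: np.ndarray, rows: pd.DataFrame, spec: ModelSpec
) -> tuple[float, float, float, bool]:
    """ML mixed model; Wald z on the genotype coefficient (X[:, 1])."""
    subject = rows["subject_id"].to_numpy()
    family = rows["family_id"].to_numpy() if spec.family_intercept else None
    try:
        fit = fit_lmm_ml(y, X, subject, family)
    except Exception:
        return np.nan, np.nan, np.nan, False
    return float(fit.beta[1]), float(fit.se[1]), fit.wald_p(1), fit.converged


# ---------------------------------------------------------------------------
# multiple testing, fold change, variance explained


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up adjusted values (monotone, capped at 1)."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        out = arr.copy()
    else:
        if np.any((arr < 0) | (arr > 1)):
            raise ValueError("p-values must lie in [0, 1]")
        out = multipletests(arr, method="fdr_bh")[1]
    if isinstance(p, pd.Series):
        return pd.Series(out, index=p.index, name="q")
    return out


def fold_change(norm: NormResult | FeatureTable, meta: pd.DataFrame) -> pd.Series:
    """Carrier/non-carrier ratio of group means per feature.

    Computed on PQN-normalized values *before* rank transformation, present
    values only; NaN flags features where a class has no present value.
    """
    table = norm.normalized if isinstance(norm, NormResult) else norm
    study = study_samples(meta, table)
    carriers = study.index[study["genotype"] == "carrier"]
    controls = study.index[study["genotype"] == "non-carrier"]
    mean_c = table.values[carriers].mean(axis=1, skipna=True)
    mean_n = table.values[controls].mean(axis=1, skipna=True)
    fc = mean_c / mean_n
    fc.name = "fold_change"
    return fc


def variance_explained(y: pd.Series, meta: pd.DataFrame) -> dict:
    """Percentage of variance explained by age, sex and genotype (OLS).

    A simple linear model across all samples (repeated measures treated as
    independent).  Each predictor's share is its incremental R-squared when
    added last to the model containing the other two, x100; ``full_pct`` is
    the full-model R-squared.  Constant predictors contribute 0% and are
    flagged.
    """
    rows = meta.loc[y.index]
    mask = y.notna().to_numpy()
    yy = y.to_numpy(dtype=float)[mask]
    rows = rows.loc[y.index[mask]]
    preds = {
        "genotype": (rows["genotype"] == "carrier").to_numpy(dtype=float),
        "age": rows["age"].to_numpy(dtype=float),
        "sex": (rows["sex"] == "M").to_numpy(dtype=float),
    }
    flags = [k for k, v in preds.items() if len(np.unique(v)) < 2]

    def r2(cols: list[str]) -> float:
        X = np.column_stack([np.ones(len(yy))] + [preds[c] for c in cols])
        beta, *_ = np.linalg.lstsq(X, yy, rcond=None)
        resid = yy - X @ beta
        tss = float(((yy - yy.mean()) ** 2).sum())
        if tss == 0:
            return 0.0
        return 1.0 - float((resid**2).sum()) / tss

    names = list(preds)
    full = r2(names)
    out = {"full_pct": 100.0 * full, "flags": flags}
    for name in names:
        if name in flags:
            out[f"{name}_pct"] = 0.0
        else:
            others = [c for c in names if c != name]
            out[f"{name}_pct"] = 100.0 * (full - r2(others))
    return out


# ---------------------------------------------------------------------------
# dataset scan


def select_dataset_samples(
    meta: pd.DataFrame, table: FeatureTable, dataset: str, mode: str = "primary"
) -> pd.Index:
    """Study samples entering one analysis dataset.

    The primary analysis (and the imputed sensitivity analysis) keep only
    fasting samples; ``keep_nonfasting`` retains all.
    """
    if dataset not in DATASETS:
        raise ValueError(f"unknown dataset {dataset!r}")
    if mode not in ANALYSIS_MODES:
        raise ValueError(f"unknown analysis mode {mode!r}")
    study = study_samples(meta, table)
    if dataset == "mothers":
        study = study[study["cohort"] == "mother"]
    elif dataset == "young":
        study = study[study["cohort"] == "young"]
    if mode != "keep_nonfasting":
        study = study[study["fasting"].astype(bool)]
    return study.index


def associate_dataset(
    table: FeatureTable, meta: pd.DataFrame, spec: ModelSpec, samples: pd.Index
) -> pd.DataFrame:
    """Scan every feature of ``table`` over the given samples.

    Uses a fast closed-form OLS path (batched over features sharing complete
    data) when the dataset has no repeated measures, and per-feature mixed
    models otherwise.  Features that cannot be tested (fewer than 3
    informative observations) get NaN statistics and ``converged=False``.
    """
    rows = meta.loc[samples]
    mixed = _has_repeats(rows)
    Y = table.values[samples].to_numpy(dtype=float)
    feats = table.features
    out = pd.DataFrame(
        index=feats,
        data={
            "beta": np.nan, "se": np.nan, "p": np.nan,
            "n_samples": 0, "n_subjects": 0,
            "model_kind": "mixed" if mixed else "ols",
            "converged": False,
        },
    )
    subj = rows["subject_id"].to_numpy()
    if not mixed:
        X_full, _ = _design(rows)
        n_feat = len(feats)
        beta = np.full(n_feat, np.nan)
        se = np.full(n_feat, np.nan)
        p = np.full(n_feat, np.nan)
        n_samp = np.zeros(n_feat, dtype=int)
        n_subj = np.zeros(n_feat, dtype=int)
        complete = ~np.isnan(Y).any(axis=1)
        if complete.any():
            beta[complete], se[complete], p[complete] = _ols_scan_complete(
                Y[complete], X_full
            )
            n_samp[complete] = Y.shape[1]
            n_subj[complete] = len(np.unique(subj))
        for i in np.flatnonzero(~complete):
            mask = ~np.isnan(Y[i])
            if mask.sum() < 3:
                continue
            X = X_full[mask]
            if len(np.unique(X[:, 1])) < 2:
                continue
            beta[i], se[i], p[i] = _ols_genotype(Y[i, mask], X)
            n_samp[i] = int(mask.sum())
            n_subj[i] = len(np.unique(subj[mask]))
        out["beta"] = beta
        out["se"] = se
        out["p"] = p
        out["n_samples"] = n_samp
        out["n_subjects"] = n_subj
        out["converged"] = ~np.isnan(p)
        return out

    for i, fid in enumerate(feats):
        y = pd.Series(Y[i], index=samples, name=fid)
        if y.notna().sum() < 3:
            continue
        try:
            res = fit_feature_association(y, meta, spec)
        except ValueError:
            continue
        out.loc[fid, ["beta", "se", "p"]] = res.beta, res.se, res.p
        out.loc[fid, "n_samples"] = res.n_samples
        out.loc[fid, "n_subjects"] = res.n_subjects
        out.loc[fid, "model_kind"] = res.model_kind
        out.loc[fid, "converged"] = res.converged
    return out


def _ols_scan_complete(
    Y: np.ndarray, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised OLS over many features sharing one complete design."""
    n, k = X.shape
    xtx_inv = np.linalg.pinv(X.T @ X)
    B = xtx_inv @ (X.T @ Y.T)  # k x features
    resid = Y.T - X @ B
    dof = n - k
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    beta = B[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return beta, se, p


@dataclass
class PrimaryResults:
    """Bundle of the three-dataset association scan."""

    per_dataset: dict[str, pd.DataFrame]
    associated: pd.Index
    alpha: float
    mode: str
    skipped: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "mode": self.mode,
            "alpha": self.alpha,
            "n_associated_union": int(len(self.associated)),
            **{
                f"n_associated_{ds}": int((df["q"] < self.alpha).sum())
                for ds, df in self.per_dataset.items()
            },
            "skipped": list(self.skipped),
        }


def run_primary_analyses(
    transformed: FeatureTable,
    normalized: FeatureTable,
    meta: pd.DataFrame,
    mode: str = "primary",
    alpha: float = 0.05,
    family_intercept_combined: bool = True,
) -> PrimaryResults:
    """The three-dataset genotype scan with BH-FDR and fold change.

    For each of the combined, mothers-only and young-only datasets the scan
    fits every feature, applies BH across all tested features in that
    dataset (the four assay datasets pooled), and attaches the
    carrier/non-carrier fold change computed from the normalized
    (untransformed) values over the same samples.  A feature is associated
    when q < ``alpha`` in at least one dataset.  Datasets with fewer than
    two carrier subjects are skipped with a warning.
    """
    per_dataset: dict[str, pd.DataFrame] = {}
    skipped: list[str] = []
    for ds in DATASETS:
        samples = select_dataset_samples(meta, transformed, ds, mode)
        rows = meta.loc[samples]
        n_carrier_subj = rows.loc[rows["genotype"] == "carrier", "subject_id"].nunique()
        if n_carrier_subj < 2:
            warnings.warn(f"dataset {ds!r} has <2 carrier subjects; skipped")
            skipped.append(ds)
            continue
        spec = ModelSpec(dataset=ds, family_intercept=(ds == "combined") and family_intercept_combined)
        res = associate_dataset(transformed, meta, spec, samples)
        tested = res.index[res["p"].notna()]
        res["q"] = np.nan
        res.loc[tested, "q"] = bh_adjust(res.loc[tested, "p"])
        res["fold_change"] = fold_change(normalized.subset_samples(samples), meta)
        res["associated"] = res["q"] < alpha
        per_dataset[ds] = res

    union: set = set()
    for df in per_dataset.values():
        union |= set(df.index[df["associated"]])
    associated = pd.Index(sorted(union))
    return PrimaryResults(per_dataset, associated, alpha, mode, skipped)


def associate_clinical(
    clinical: pd.DataFrame,
    meta: pd.DataFrame,
    mode: str = "primary",
    family_intercept_combined: bool = True,
) -> pd.DataFrame:
    """Genotype association of clinical lipid measures (e.g. HDL/LDL/TAG).

    Each measure (column of ``clinical``, indexed by sample id, original
    units such as mmol/L) is run through the same per-dataset model as the
    metabolite features but *untransformed*, so effects stay on the
    measurement scale.  Returns one row per (measure, dataset).
    """
    rows = []
    for ds in DATASETS:
        study = study_samples(meta)
        sub = clinical.reindex(study.index)
        samples = pd.Index(
            [s for s in study.index
             if (ds == "combined")
             or (ds == "mothers" and study.loc[s, "cohort"] == "mother")
             or (ds == "young" and study.loc[s, "cohort"] == "young")]
        )
        if mode != "keep_nonfasting":
            samples = samples[study.loc[samples, "fasting"].astype(bool)]
        spec = ModelSpec(ds, family_intercept=(ds == "combined") and family_intercept_combined)
        for measure in clinical.columns:
            y = sub.loc[samples, measure].astype(float)
            y.name = measure
            try:
                res = fit_feature_association(y, meta, spec)
            except ValueError:
                continue
            rows.append(
                {"measure": measure, "dataset": ds, "beta": res.beta,
                 "se": res.se, "p": res.p, "n_samples": res.n_samples,
                 "model_kind": res.model_kind}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# design utilities


def int_attenuated_effect(
    delta: float,
    carrier_fraction: float,
    n: int | None = None,
    n_mc: int = 40000,
    seed: int = 0,
) -> float:
    """Expected genotype contrast after the rank-based inverse-normal
    transform, under a two-component Gaussian mixture.

    If log-abundance is N(0, 1) in controls and N(delta, 1) in carriers with
    carrier fraction pi, the population transform is
    t(y) = Phi^-1(pi * Phi(y - delta) + (1 - pi) * Phi(y)); the returned
    value is E[t(Y) | carrier] - E[t(Y) | control], the effect a regression
    on transformed data estimates.  Useful when validating effect recovery:
    the transform compresses the raw standardized effect.

    With ``n`` given, the finite-sample expectation at a study of that size
    is computed instead, directly from the definition (rank the n draws, map
    through normal quantiles, contrast the group means) by Monte Carlo over
    ``n_mc`` replicate studies: the finite-n transform compresses extremes a
    little more than its population limit.
    """
    pi = carrier_fraction
    if n is not None:
        rng = np.random.default_rng(seed)
        n_car = int(round(pi * n))
        g = np.r_[np.ones(n_car), np.zeros(n - n_car)]
        y = rng.normal(size=(n_mc, n)) + delta * g[None, :]
        ranks = stats.rankdata(y, axis=1)
        t = stats.norm.ppf((ranks - 0.5) / n)
        contrast = t[:, :n_car].mean(axis=1) - t[:, n_car:].mean(axis=1)
        return float(contrast.mean())
    lo = min(-9.0, delta - 9.0)
    hi = max(9.0, delta + 9.0)
    y = np.linspace(lo, hi, 40001)
    cdf = pi * stats.norm.cdf(y - delta) + (1 - pi) * stats.norm.cdf(y)
    t = stats.norm.ppf(np.clip(cdf, 1e-15, 1 - 1e-15))
    f_carrier = stats.norm.pdf(y - delta)
    f_control = stats.norm.pdf(y)
    e_c = np.trapezoid(t * f_carrier, y)
    e_n = np.trapezoid(t * f_control, y)
    return float(e_c - e_n)
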