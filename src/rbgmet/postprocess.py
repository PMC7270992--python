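"""Post-analysis reporting: annotation deduplication, lipid-class summaries,
residualized Ward-clustered heatmaps, effect-by-m/z plots, and the cohort
characteristics table.

Several features (adducts, isotopes, cross-assay detections) can represent
one metabolite; within each analysis dataset the feature with the smallest
association p-value represents its annotation label.  Class summaries and
figures are then reported at the metabolite level.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage

from .datatypes import FeatureTable, study_samples


def dedup_annotations(
    results: pd.DataFrame, annotation: pd.Series, dataset: str = "combined"
) -> pd.DataFrame:
    """Collapse multiple features annotated as the same metabolite.

    For each annotation label, keep the member feature with the smallest p
    (ties broken by smaller feature id, so output is run-to-run stable);
    unannotated features pass through ungrouped, reported as features rather
    than metabolites.  ``results`` must be indexed by feature id and carry a
    ``p`` column; ``annotation`` maps feature id -> label (NaN = none).

    Returns a frame indexed by the representative feature id with columns
    ``metabolite`` (label, or the feature id itself when unannotated),
    ``dataset``, ``n_member_features`` and ``member_features``, joined with
    the representative's result columns.
    """
    ann = annotation.reindex(results.index)
    rows = []
    annotated = ann.dropna()
    for label, members in annotated.groupby(annotated):
        sub = results.loc[members.index.sort_values()]
        # smallest p wins; NaN p sorts last; index is pre-sorted for ties
        order = sub["p"].to_numpy()
        order = np.where(np.isnan(order), np.inf, order)
        rep = sub.index[int(np.argmin(order))]
        rows.append(
            {"feature_id": rep, "metabolite": label, "dataset": dataset,
             "n_member_features": len(sub), "member_features": ";".join(sub.index)}
        )
    for fid in results.index[ann.isna()]:
        rows.append(
            {"feature_id": fid, "metabolite": fid, "dataset": dataset,
             "n_member_features": 1, "member_features": fid}
        )
    dedup = pd.DataFrame(rows).set_index("feature_id")
    return dedup.join(results, how="left")


def class_summary(metabolite_results: pd.DataFrame) -> pd.DataFrame:
    """Counts, column percentages and effect directions per lipid class.

    ``metabolite_results`` is a dedup output joined with a ``lipid_class``
    column (and optionally ``beta``).  Unknown/missing class labels are
    bucketed as ``"other"``.
    """
    cls = metabolite_results.get("lipid_class")
    cls = cls.fillna("other") if cls is not None else pd.Series("other", index=metabolite_results.index)
    out = pd.DataFrame({"n": cls.value_counts()})
    out["pct"] = 100.0 * out["n"] / out["n"].sum()
    if "beta" in metabolite_results.columns:
        beta = metabolite_results["beta"]
        out["n_up"] = cls[beta > 0].value_counts().reindex(out.index).fillna(0).astype(int)
        out["n_down"] = cls[beta < 0].value_counts().reindex(out.index).fillna(0).astype(int)
    out.index.name = "lipid_class"
    return out.sort_values("n", ascending=False)


def residualize(y: pd.Series, meta: pd.DataFrame) -> pd.Series:
    """OLS residuals of a transformed feature on age and sex.

    Genotype is deliberately excluded so that the heatmap can display the
    genotype structure.  Missing values are preserved.  Sex is dropped from
    the design when constant.
    """
    rows = meta.loc[y.index]
    mask = y.notna().to_numpy()
    yy = y.to_numpy(dtype=float)[mask]
    sub = rows.loc[y.index[mask]]
    cols = [np.ones(len(yy)), sub["age"].to_numpy(dtype=float)]
    sex = (sub["sex"] == "M").to_numpy(dtype=float)
    if len(np.unique(sex)) > 1:
        cols.append(sex)
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, yy, rcond=None)
    out = np.full(len(y), np.nan)
    out[mask] = yy - X @ beta
    return pd.Series(out, index=y.index, name=y.name)


def residualize_table(table: FeatureTable, meta: pd.DataFrame) -> FeatureTable:
    """Residualize every feature on age and sex (missing preserved)."""
    res = pd.DataFrame(
        {s: np.nan for s in table.samples}, index=table.features, dtype=float
    )
    for fid in table.features:
        res.loc[fid] = residualize(table.values.loc[fid], meta).to_numpy()
    return FeatureTable(res, table.feature_meta.copy(), positive=False)


@dataclass
class WardResult:
    """Ward clustering of a dense metabolite x sample matrix."""

    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: np.ndarray
    col_order: np.ndarray

    def cut_rows(self, k: int) -> np.ndarray:
        from scipy.cluster.hierarchy import fcluster

        return fcluster(self.row_linkage, k, criterion="maxclust")

    def cut_cols(self, k: int) -> np.ndarray:
        from scipy.cluster.hierarchy import fcluster

        return fcluster(self.col_linkage, k, criterion="maxclust")


def ward_cluster(matrix: pd.DataFrame) -> WardResult:
    """Agglomerative Ward clustering of both axes on Euclidean distance.

    ``matrix`` must be dense (no missing entries) with at least two rows and
    two columns.  Heights follow the standard Ward update (minimum increase
    in within-cluster variance).
    """
    if matrix.isna().to_numpy().any():
        raise ValueError("ward_cluster requires a dense matrix (no missing entries)")
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least 2 items on each axis to cluster")
    row_link = linkage(matrix.to_numpy(), method="ward")
    col_link = linkage(matrix.to_numpy().T, method="ward")
    return WardResult(
        row_linkage=row_link,
        col_linkage=col_link,
        row_order=leaves_list(row_link),
        col_order=leaves_list(col_link),
    )


def plot_heatmap(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    feature_meta: pd.DataFrame,
    path: str,
    exclude_classes: tuple[str, ...] = (),
) -> WardResult:
    """Ward-clustered heatmap of residualized metabolite levels.

    Rows are metabolites (optionally excluding whole lipid classes, e.g. the
    on-target TAG class to expose secondary structure), columns are samples;
    annotation bars show genotype/cohort and lipid class.  Writes a PNG and
    returns the clustering.
    """
    if exclude_classes:
        keep = ~feature_meta.loc[matrix.index, "lipid_class"].isin(exclude_classes)
        matrix = matrix.loc[keep[keep].index]
    ward = ward_cluster(matrix)
    ordered = matrix.iloc[ward.row_order, ward.col_order]

    fig, ax = plt.subplots(
        figsize=(max(6, 0.08 * matrix.shape[1] + 3), max(5, 0.06 * matrix.shape[0] + 2))
    )
    vmax = float(np.nanpercentile(np.abs(ordered.to_numpy()), 98)) or 1.0
    im = ax.imshow(ordered.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    fig.colorbar(im, ax=ax, shrink=0.6, label="residualized level (SD units)")
    geno = meta.loc[ordered.columns, "genotype"].to_numpy()
    carrier_cols = np.flatnonzero(geno == "carrier")
    for x in carrier_cols:
        ax.plot(x, -1.5, marker="s", color="seagreen", markersize=3, clip_on=False)
    ax.set_xlabel("samples (carriers marked above)")
    ax.set_ylabel("metabolites (Ward order)")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return ward


def plot_effect_by_mz(
    results: pd.DataFrame, feature_meta: pd.DataFrame, path: str
) -> None:
    """Scatter of genotype effect estimates against m/z, coloured by class."""
    df = results.join(feature_meta[["mz", "lipid_class"]], how="left")
    df = df[df["beta"].notna()]
    fig, ax = plt.subplots(figsize=(7, 5))
    classes = sorted(df["lipid_class"].fillna("other").unique())
    cmap = plt.get_cmap("tab10")
    for i, cls in enumerate(classes):
        sub = df[df["lipid_class"].fillna("other") == cls]
        ax.scatter(sub["mz"], sub["beta"], s=14, alpha=0.8, label=cls,
                   color=cmap(i % 10))
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("mass to charge ratio (m/z)")
    ax.set_ylabel("genotype effect (SD units, transformed scale)")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# cohort characteristics


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n"


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided two-sample Wilcoxon rank-sum p.

    Exact when both groups have n <= 20 and no ties; otherwise the normal
    approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    exact = len(x) <= 20 and len(y) <= 20 and len(np.unique(np.r_[x, y])) == len(x) + len(y)
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.pvalue)


def cohort_table(
    meta: pd.DataFrame, clinical: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Sample characteristics by cohort and genotype class.

    Per cohort: sample counts, sex split, and mean (SD) of age plus any
    clinical traits (e.g. HDL/LDL/TAG in mmol/L, indexed by sample id), with
    a two-sided Wilcoxon rank-sum test comparing carriers to non-carriers
    and star coding (* p<0.05, ** p<0.01, *** p<0.001, n = not significant).
    """
    study = study_samples(meta)
    traits: dict[str, pd.Series] = {"age": study["age"].astype(float)}
    if clinical is not None:
        for col in clinical.columns:
            traits[col] = clinical[col].reindex(study.index).astype(float)

    rows = []
    for cohort in ("young", "mother"):
        sub = study[study["cohort"] == cohort]
        if len(sub) == 0:
            continue
        carriers = sub.index[sub["genotype"] == "carrier"]
        controls = sub.index[sub["genotype"] == "non-carrier"]
        rows.append(
            {"cohort": cohort, "trait": "n_samples",
             "carrier_mean": float(len(carriers)), "carrier_sd": np.nan,
             "noncarrier_mean": float(len(controls)), "noncarrier_sd": np.nan,
             "p": np.nan, "stars": ""}
        )
        rows.append(
            {"cohort": cohort, "trait": "pct_female",
             "carrier_mean": 100.0 * (sub.loc[carriers, "sex"] == "F").mean(),
             "carrier_sd": np.nan,
             "noncarrier_mean": 100.0 * (sub.loc[controls, "sex"] == "F").mean(),
             "noncarrier_sd": np.nan, "p": np.nan, "stars": ""}
        )
        for trait, series in traits.items():
            xc = series.loc[carriers].dropna().to_numpy()
            xn = series.loc[controls].dropna().to_numpy()
            if len(xc) == 0 or len(xn) == 0:
                continue
            p = wilcoxon_rank_sum(xc, xn)
            rows.append(
                {"cohort": cohort, "trait": trait,
                 "carrier_mean": float(xc.mean()), "carrier_sd": float(xc.std(ddof=1)) if len(xc) > 1 else np.nan,
                 "noncarrier_mean": float(xn.mean()), "noncarrier_sd": float(xn.std(ddof=1)) if len(xn) > 1 else np.nan,
                 "p": p, "stars": _stars(p)}
            )
    return pd.DataFrame(rows).set_index(["cohort", "trait"])
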