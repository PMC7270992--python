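"""Probabilistic quotient normalization, rank-based inverse-normal transform,
and left-censored imputation.

PQN corrects per-sample multiplicative dilution: each sample is divided by
the median of its feature-wise ratios to a reference spectrum (by default the
feature-wise median of the filtered study samples).  Under a pure dilution
model (sample_i = d_i * profile) the estimated quotients are proportional to
the true dilutions and normalization recovers the common profile exactly.

The rank-based inverse-normal transform maps each feature's present values to
standard-normal quantiles at (rank - 0.5) / n with average ranks for ties,
forcing an approximately standard-normal marginal while preserving order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import FeatureTable, qc_samples, study_samples


@dataclass
class NormResult:
    """Outcome of probabilistic quotient normalization.

    ``quotient`` maps each sample to its median quotient (the dilution
    estimate it was divided by); ``reference`` is the reference spectrum.
    """

    normalized: FeatureTable
    quotient: pd.Series
    reference: pd.Series


def pqn_normalize(
    table: FeatureTable,
    meta: pd.DataFrame,
    reference_mode: str = "study_median",
) -> NormResult:
    """Probabilistic quotient normalization of a QC-filtered table.

    Parameters
    ----------
    reference_mode
        ``"study_median"`` (default) — feature-wise median over study
        samples, present values only; ``"qc_median"`` — median over
        pooled-QC samples instead.

    Every sample (study and QC) is divided by the median of its
    value/reference ratios over features present in both; missing values
    stay missing.
    """
    if reference_mode == "study_median":
        ref_cols = study_samples(meta, table).index
    elif reference_mode == "qc_median":
        ref_cols = qc_samples(meta, table).index
    else:
        raise ValueError(f"unknown reference_mode {reference_mode!r}")
    if len(ref_cols) == 0:
        raise ValueError(f"no samples available for reference mode {reference_mode!r}")

    reference = table.values[ref_cols].median(axis=1, skipna=True)
    reference.name = "reference"

    ratios = table.values.div(reference, axis=0)
    quotient = ratios.median(axis=0, skipna=True)
    quotient.name = "quotient"
    no_overlap = quotient.index[quotient.isna()]
    if len(no_overlap):
        raise ValueError(
            "sample(s) share no present feature with the reference spectrum: "
            + ", ".join(map(str, no_overlap))
        )
    normalized = table.values.div(quotient, axis=1)
    return NormResult(
        FeatureTable(normalized, table.feature_meta.copy()), quotient, reference
    )


def rank_normal_transform(
    values: pd.Series | np.ndarray, allow_constant: bool = False
) -> pd.Series | np.ndarray:
    """Rank-based inverse-normal transform of one feature's values.

    Present values are ranked (average rank for ties) and mapped to
    standard-normal quantiles at (rank - 0.5) / n; missing values are
    preserved.  The transform is strictly monotone wherever ranks are untied.

    Raises if fewer than 3 values are present, or if all present values are
    identical — unless ``allow_constant``, in which case they all map to 0
    (the quantile of the central average rank).
    """
    arr = np.asarray(values, dtype=float)
    mask = ~np.isnan(arr)
    n = int(mask.sum())
    if n < 3:
        raise ValueError(f"rank-normal transform needs >= 3 present values, got {n}")
    present = arr[mask]
    if np.all(present == present[0]):
        if not allow_constant:
            raise ValueError("all present values identical; transform undefined")
        out_present = np.zeros(n)
    else:
        ranks = stats.rankdata(present, method="average")
        out_present = stats.norm.ppf((ranks - 0.5) / n)
    out = np.full(arr.shape, np.nan)
    out[mask] = out_present
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out


def transform_table(table: FeatureTable, on_constant: str = "zero") -> FeatureTable:
    """Apply the rank-based inverse-normal transform feature-wise.

    Vectorised over features.  ``on_constant`` controls features whose
    present values are all identical: ``"zero"`` maps them to 0 (their
    average rank is central), ``"error"`` raises.
    """
    vals = table.values.to_numpy(dtype=float)
    mask = ~np.isnan(vals)
    n_present = mask.sum(axis=1)
    if (n_present < 3).any():
        bad = table.features[n_present < 3][0]
        raise ValueError(f"feature {bad!r} has fewer than 3 present values")
    if on_constant == "error":
        mins = np.nanmin(vals, axis=1)
        maxs = np.nanmax(vals, axis=1)
        if ((maxs == mins)).any():
            bad = table.features[maxs == mins][0]
            raise ValueError(f"feature {bad!r} is constant; transform undefined")
    elif on_constant != "zero":
        raise ValueError(f"unknown on_constant policy {on_constant!r}")
    ranks = stats.rankdata(vals, method="average", axis=1, nan_policy="omit")
    with np.errstate(invalid="ignore"):
        out = stats.norm.ppf((ranks - 0.5) / n_present[:, None])
    out[~mask] = np.nan
    return FeatureTable(
        pd.DataFrame(out, index=table.features, columns=table.samples),
        table.feature_meta.copy(),
        positive=False,
    )


def impute_left_censored(table: FeatureTable, method: str = "half_min") -> FeatureTable:
    """Replace missing values assuming left-censoring at the detection limit.

    ``half_min`` (default) substitutes half the feature's minimum present
    value; ``min`` the minimum itself; ``none`` returns the table unchanged.
    A feature with no present value at all cannot be imputed and raises
    (such features should have been filtered upstream).
    """
    if method == "none":
        return table.copy()
    if method not in ("half_min", "min"):
        raise ValueError(f"unknown imputation method {method!r}")
    vals = table.values.to_numpy(dtype=float)
    n_present = (~np.isnan(vals)).sum(axis=1)
    if (n_present == 0).any():
        bad = table.features[n_present == 0][0]
        raise ValueError(f"feature {bad!r} is entirely missing; cannot impute")
    fill = np.nanmin(vals, axis=1)
    if method == "half_min":
        fill = fill / 2.0
    out = np.where(np.isnan(vals), fill[:, None], vals)
    return FeatureTable(
        pd.DataFrame(out, index=table.features, columns=table.samples),
        table.feature_meta.copy(),
    )
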