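"""Presence/absence association track.

A feature sitting below the limit of detection in one genotype class is
invisible to the abundance models (its values are simply missing), so each
feature's missingness pattern is tested directly: a 2x2 table of
missing/present counts by carrier status, Fisher's exact test (two-sided,
point-probability criterion), and BH adjustment across all tested features.
The scan runs on the post-filter, pre-imputation combined dataset —
missingness must be real, not imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import bh_adjust
from .datatypes import FeatureTable, study_samples


@dataclass
class MissRecord:
    """Missingness test result for one feature.

    ``counts`` is [[missing_carrier, missing_noncarrier],
    [present_carrier, present_noncarrier]]; ``direction`` is the sign of
    (carrier missing rate - non-carrier missing rate).
    """

    feature_id: str
    counts: np.ndarray
    p: float
    direction: int
    degenerate: bool
    q: float = np.nan


def missingness_table(
    feature_id: str, table: FeatureTable, meta: pd.DataFrame
) -> np.ndarray:
    """2x2 missing/present x carrier/non-carrier counts for one feature."""
    if feature_id not in table.features:
        raise KeyError(f"feature {feature_id!r} not in table")
    study = study_samples(meta, table)
    row = table.values.loc[feature_id, study.index]
    is_carrier = (study["genotype"] == "carrier").to_numpy()
    miss = row.isna().to_numpy()
    return np.array(
        [
            [int((miss & is_carrier).sum()), int((miss & ~is_carrier).sum())],
            [int((~miss & is_carrier).sum()), int((~miss & ~is_carrier).sum())],
        ]
    )


def fisher_exact_2x2(counts: np.ndarray) -> tuple[float, bool]:
    """Two-sided Fisher's exact p for a 2x2 table, margins fixed.

    Two-sidedness by the point-probability criterion: sum the
    hypergeometric probabilities of all tables (with the observed margins)
    whose probability does not exceed the observed table's.  A zero margin
    makes the test uninformative; p = 1 is returned with a degenerate flag.
    """
    c = np.asarray(counts)
    if c.shape != (2, 2):
        raise ValueError("counts must be a 2x2 table")
    if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
        if np.any(c != np.floor(c)) or np.any(c < 0):
            raise ValueError("counts must be non-negative integers")
        c = c.astype(int)
    if (c.sum(axis=0) == 0).any() or (c.sum(axis=1) == 0).any():
        return 1.0, True
    _, p = stats.fisher_exact(c, alternative="two-sided")
    return float(min(p, 1.0)), False


def run_missingness_scan(
    table: FeatureTable, meta: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Fisher missingness test for every feature of the combined dataset.

    Returns a frame indexed by feature id with the 2x2 counts, two-sided p,
    BH q, direction of the carrier-vs-control missingness difference, and
    the discovery flag at q < ``alpha``.
    """
    study = study_samples(meta, table)
    is_carrier = (study["genotype"] == "carrier").to_numpy()
    n_c = int(is_carrier.sum())
    n_n = int((~is_carrier).sum())
    if n_c == 0 or n_n == 0:
        raise ValueError("both genotype classes must be represented")
    miss = table.values[study.index].isna().to_numpy()
    miss_c = miss[:, is_carrier].sum(axis=1)
    miss_n = miss[:, ~is_carrier].sum(axis=1)

    ps = np.empty(table.n_features)
    degenerate = np.zeros(table.n_features, dtype=bool)
    cache: dict[tuple[int, int], tuple[float, bool]] = {}
    for i, (mc, mn) in enumerate(zip(miss_c, miss_n)):
        key = (int(mc), int(mn))
        if key not in cache:
            cache[key] = fisher_exact_2x2(
                np.array([[mc, mn], [n_c - mc, n_n - mn]])
            )
        ps[i], degenerate[i] = cache[key]

    out = pd.DataFrame(
        {
            "missing_carrier": miss_c,
            "missing_noncarrier": miss_n,
            "present_carrier": n_c - miss_c,
            "present_noncarrier": n_n - miss_n,
            "p": ps,
            "degenerate": degenerate,
            "direction": np.sign(miss_c / n_c - miss_n / n_n).astype(int),
        },
        index=table.features,
    )
    out["q"] = bh_adjust(out["p"])
    out["differentially_missing"] = out["q"] < alpha
    return out


def overlap_summary(
    missing_scan: pd.DataFrame, associated: pd.Index
) -> dict[str, int]:
    """Counts relating the differentially-missing set to the
    abundance-associated set (inclusion-exclusion consistent)."""
    dm = set(missing_scan.index[missing_scan["differentially_missing"]])
    assoc = set(associated)
    return {
        "n_differentially_missing": len(dm),
        "n_abundance_associated": len(assoc),
        "n_overlap": len(dm & assoc),
        "n_missing_only": len(dm - assoc),
        "n_union": len(dm | assoc),
    }
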