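"""Core data containers shared across the pipeline.

Two tables drive everything:

* :class:`FeatureTable` — positive peak areas on a feature x sample grid, with
  ``NaN`` marking a missing (undetected) value, plus per-feature metadata
  (assay, m/z, retention time, optional annotation and lipid class).
* a sample-metadata :class:`pandas.DataFrame` (indexed by sample id) carrying
  the study design: subject, family, genotype class, age, sex, cohort,
  fasting flag and pooled-QC flag.  Helpers below validate and slice it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: The four UHPLC-MS acquisitions: HILIC (polar metabolites) and C18 reversed
#: phase (lipids), each in positive and negative electrospray ionisation mode.
ASSAYS = ("HILIC-POS", "HILIC-NEG", "LIPIDS-POS", "LIPIDS-NEG")

GENOTYPES = ("carrier", "non-carrier")
COHORTS = ("young", "mother")

FEATURE_META_COLUMNS = ("assay", "mz", "rt", "annotation", "lipid_class")
SAMPLE_META_COLUMNS = (
    "subject_id",
    "family_id",
    "genotype",
    "age",
    "sex",
    "cohort",
    "fasting",
    "is_qc",
)


class SchemaError(ValueError):
    """Raised when a table violates its declared schema."""


@dataclass
class FeatureTable:
    """Feature x sample grid of peak areas with aligned feature metadata.

    Parameters
    ----------
    values
        DataFrame indexed by feature id, columns are sample ids.  Present
        values must be strictly positive; ``NaN`` encodes a missing value
        (feature not detected in that sample).
    feature_meta
        DataFrame indexed by feature id with columns
        ``assay, mz, rt, annotation, lipid_class``.  ``annotation`` and
        ``lipid_class`` may be missing (``NaN``) for unannotated features.
    positive
        Whether present values must be strictly positive.  True for raw and
        normalized peak areas; rank-transformed or residualized grids set it
        to False.
    """

    values: pd.DataFrame
    feature_meta: pd.DataFrame
    positive: bool = True

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if not self.values.index.is_unique:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise SchemaError(f"duplicate feature id {dup!r}")
        if not self.values.columns.is_unique:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise SchemaError(f"duplicate sample id {dup!r}")
        if self.positive:
            vals = self.values.to_numpy(dtype=float)
            if np.any(vals[~np.isnan(vals)] <= 0):
                bad = self.values.le(0).any(axis=1)
                raise SchemaError(
                    f"non-positive peak area in feature {self.values.index[bad][0]!r}"
                )
        missing_meta = self.values.index.difference(self.feature_meta.index)
        if len(missing_meta):
            raise SchemaError(f"feature {missing_meta[0]!r} lacks metadata")
        for col in FEATURE_META_COLUMNS:
            if col not in self.feature_meta.columns:
                raise SchemaError(f"feature metadata lacks column {col!r}")
        # keep metadata aligned and ordered with the value grid
        self.feature_meta = self.feature_meta.loc[self.values.index]
        bad_assay = set(self.feature_meta["assay"].dropna()) - set(ASSAYS)
        if bad_assay:
            raise SchemaError(f"unknown assay label {sorted(bad_assay)[0]!r}")

    # -- conveniences -------------------------------------------------------
    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.values.copy(), self.feature_meta.copy(), self.positive)

    def subset_features(self, feature_ids: Sequence) -> "FeatureTable":
        ids = pd.Index(feature_ids)
        return FeatureTable(self.values.loc[ids], self.feature_meta.loc[ids], self.positive)

    def subset_samples(self, sample_ids: Sequence) -> "FeatureTable":
        ids = pd.Index(sample_ids)
        return FeatureTable(self.values[ids], self.feature_meta.copy(), self.positive)

    def missing_fraction(self) -> float:
        """Overall fraction of missing cells."""
        return float(self.values.isna().to_numpy().mean())


# ---------------------------------------------------------------------------
# sample metadata helpers


def validate_sample_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-metadata frame and return it (index = sample id).

    Checks uniqueness of sample ids, genotype codes, constancy of genotype
    within subject, and that mothers are female and pooled-QC samples carry
    no genotype.
    """
    if not meta.index.is_unique:
        dup = meta.index[meta.index.duplicated()][0]
        raise SchemaError(f"duplicate sample id {dup!r}")
    for col in SAMPLE_META_COLUMNS:
        if col not in meta.columns:
            raise SchemaError(f"sample metadata lacks column {col!r}")
    study = meta[~meta["is_qc"].astype(bool)]
    bad_geno = set(study["genotype"].dropna()) - set(GENOTYPES)
    if bad_geno:
        raise SchemaError(f"unknown genotype code {sorted(bad_geno)[0]!r}")
    if study["genotype"].isna().any():
        bad = study.index[study["genotype"].isna()][0]
        raise SchemaError(f"study sample {bad!r} lacks a genotype")
    qc = meta[meta["is_qc"].astype(bool)]
    if qc["genotype"].notna().any():
        bad = qc.index[qc["genotype"].notna()][0]
        raise SchemaError(f"pooled-QC sample {bad!r} must not carry a genotype")
    per_subject = study.groupby("subject_id")["genotype"].nunique()
    if (per_subject > 1).any():
        subj = per_subject.index[per_subject > 1][0]
        raise SchemaError(f"subject {subj!r} has inconsistent genotype")
    mothers = study[study["cohort"] == "mother"]
    if (mothers["sex"] != "F").any():
        bad = mothers.index[mothers["sex"] != "F"][0]
        raise SchemaError(f"mother sample {bad!r} is not coded female")
    return meta


def study_samples(meta: pd.DataFrame, table: FeatureTable | None = None) -> pd.DataFrame:
    """Study (non-QC) sample rows, optionally restricted to a table's columns."""
    out = meta[~meta["is_qc"].astype(bool)]
    if table is not None:
        out = out.loc[out.index.intersection(table.samples)]
    return out


def qc_samples(meta: pd.DataFrame, table: FeatureTable | None = None) -> pd.DataFrame:
    """Pooled-QC sample rows, optionally restricted to a table's columns."""
    out = meta[meta["is_qc"].astype(bool)]
    if table is not None:
        out = out.loc[out.index.intersection(table.samples)]
    return out


def genotype_mask(meta: pd.DataFrame, samples: Iterable, genotype: str) -> pd.Index:
    """Sample ids among `samples` with the given genotype class."""
    sub = meta.loc[pd.Index(samples)]
    return sub.index[sub["genotype"] == genotype]
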