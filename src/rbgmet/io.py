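"""Delimited-text readers and writers for the pipeline's tables.

The feature table is a TSV whose first column is the feature id, followed by
the reserved metadata columns ``assay, mz, rt, annotation, lipid_class`` and
then one column per sample; an empty cell is a missing value.  Sample
metadata and truth tables are plain TSVs indexed by sample/feature id.
Schema violations are rejected with the offending line number (1-based,
counting the header).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    FEATURE_META_COLUMNS,
    SAMPLE_META_COLUMNS,
    FeatureTable,
    SchemaError,
    validate_sample_meta,
)
from .simulate import SimTruth


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    out = table.feature_meta.join(table.values)
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", na_rep="")


def read_feature_table(path: str | Path) -> FeatureTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing_cols = [c for c in FEATURE_META_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"{path}: missing feature-metadata column {missing_cols[0]!r}")
    meta = df[list(FEATURE_META_COLUMNS)]
    values = df.drop(columns=list(FEATURE_META_COLUMNS)).astype(float)
    if df.index.duplicated().any():
        row = int(np.flatnonzero(df.index.duplicated())[0]) + 2
        raise SchemaError(f"{path}: duplicate feature id at line {row}")
    neg = (values <= 0).any(axis=1)
    if neg.any():
        row = int(np.flatnonzero(neg.to_numpy())[0]) + 2
        raise SchemaError(f"{path}: non-positive peak area at line {row}")
    return FeatureTable(values, meta)


def write_sample_meta(meta: pd.DataFrame, path: str | Path) -> None:
    out = meta.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep="")


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing_cols = [c for c in SAMPLE_META_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"{path}: missing sample-metadata column {missing_cols[0]!r}")
    df["is_qc"] = df["is_qc"].astype(bool)
    df["fasting"] = df["fasting"].astype(bool)
    study = df[~df["is_qc"]]
    bad = ~study["genotype"].isin(("carrier", "non-carrier"))
    if bad.any():
        sid = study.index[bad][0]
        row = int(np.flatnonzero(df.index == sid)[0]) + 2
        raise SchemaError(f"{path}: unknown genotype code at line {row}")
    return validate_sample_meta(df[list(SAMPLE_META_COLUMNS)])


def write_truth(truth: SimTruth, path: str | Path) -> None:
    """Ground-truth tables as one TSV (long format) plus the LOD."""
    rows = [
        {"kind": "lod", "key": "lod", "value": truth.lod, "extra": ""},
    ]
    for fid, eff in truth.effect.items():
        rows.append({"kind": "effect", "key": fid, "value": eff, "extra": ""})
    for sid, d in truth.dilution.items():
        rows.append({"kind": "dilution", "key": sid, "value": d, "extra": ""})
    for label, members in truth.annotation_groups.items():
        rows.append(
            {"kind": "annotation_group", "key": label, "value": np.nan,
             "extra": ";".join(members)}
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep="")


def read_truth(path: str | Path) -> SimTruth:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
    lod = float(df.loc[df["kind"] == "lod", "value"].iloc[0])
    eff = df[df["kind"] == "effect"].set_index("key")["value"].astype(float)
    eff.index.name = None
    eff.name = "effect"
    dil = df[df["kind"] == "dilution"].set_index("key")["value"].astype(float)
    dil.index.name = None
    dil.name = "dilution"
    groups = {
        str(r["key"]): str(r["extra"]).split(";")
        for _, r in df[df["kind"] == "annotation_group"].iterrows()
    }
    return SimTruth(
        effect=eff,
        dilution=dil,
        lod=lod,
        affected=frozenset(eff.index[eff != 0.0]),
        annotation_groups=groups,
    )
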