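"""Synthetic recall-by-genotype UHPLC-MS study generator.

Emulates a matched carrier/non-carrier plasma metabolomics study: carriers of
a rare loss-of-function allele are each matched to a fixed number of
non-carrier controls on cohort, sex and age (within one year); the study spans
two cohorts (adolescent "young" participants and adult "mother" participants)
with repeated measures for a subset of carriers; features from four UHPLC-MS
acquisitions carry class-structured genotype effects on log-abundance;
per-sample multiplicative dilution, pooled-QC technical replicates, redundant
(duplicate) features per metabolite, and limit-of-detection left-censoring
produce the missing-not-at-random structure the downstream presence/absence
track is designed to detect.

The abundance model on the natural-log scale is

    log v[f, s] = b[f] + g[s] * delta[f] * sigma_b
                  + u[subject(s), f] + e[s, f] + log d[s]

with ``b`` a per-metabolite baseline, ``g`` the 0/1 carrier indicator,
``delta`` the standardized class effect, ``sigma_b`` the total biological SD
(split evenly between the subject random intercept ``u`` and the sample-level
residual ``e``), and ``d`` a log-normal per-sample dilution factor.  Pooled-QC
injections are the arithmetic mean profile of all study samples under
multiplicative noise with coefficient of variation ``tech_rsd`` %.  Duplicate
features replicate their parent feature under the same technical noise and
share its annotation label.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .datatypes import FeatureTable, validate_sample_meta, study_samples

#: Default feature counts per metabolite class.  The class mix mirrors a
#: plasma lipidome-heavy untargeted acquisition; the total (~600 base
#: metabolites) is a tractable stand-in for a full multi-assay feature set.
DEFAULT_CLASS_SIZES: dict[str, int] = {
    "TAG": 120,
    "DAG": 60,
    "acyl-acyl GPL": 140,
    "acyl-alkyl GPL": 60,
    "ceramide": 60,
    "sphingolipid": 40,
    "other": 120,
}

#: Default standardized genotype effects on log-abundance by class, in units
#: of the total biological SD.  Signs follow the biology being emulated:
#: loss of apoC-III function lowers triacylglycerides, diacylglycerides and
#: acyl-acyl glycerophospholipids while raising acyl-alkyl GPLs and ceramides.
#: Magnitudes are chosen for testability (the source study reports no
#: per-feature effect distribution).
DEFAULT_CLASS_EFFECTS: dict[str, float] = {
    "TAG": -1.0,
    "DAG": -0.6,
    "acyl-acyl GPL": -0.5,
    "acyl-alkyl GPL": 0.5,
    "ceramide": 0.5,
    "sphingolipid": 0.3,
    "other": 0.0,
}

#: Lipid classes are acquired on the C18 lipids assays; everything else on
#: the HILIC assays.  Probability of the negative ion mode per group.
_LIPID_CLASSES = ("TAG", "DAG", "acyl-acyl GPL", "acyl-alkyl GPL", "ceramide", "sphingolipid")
_MZ_RANGES = {
    "TAG": (750.0, 950.0),
    "DAG": (550.0, 680.0),
    "acyl-acyl GPL": (680.0, 850.0),
    "acyl-alkyl GPL": (680.0, 850.0),
    "ceramide": (500.0, 700.0),
    "sphingolipid": (400.0, 650.0),
    "other": (85.0, 550.0),
}


@dataclass
class SimConfig:
    """Configuration of a synthetic recall-by-genotype study.

    Defaults follow the emulated design: 26 carrier subjects (11 mothers,
    15 adolescents), two matched controls per carrier, repeated measures for
    about half the carriers, four assay datasets and a pooled-QC series.
    """

    n_carriers: int = 26
    controls_per_carrier: int = 2
    n_mothers_fraction: float = 11 / 26
    repeat_measure_prob: float = 0.5
    n_features_per_class: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_SIZES)
    )
    effect_by_class: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_EFFECTS)
    )
    dilution_sd: float = 0.2
    tech_rsd: float = 10.0
    biol_sd: float = 0.5
    lod_quantile: float = 0.10
    n_qc: int = 8
    duplicate_rate: float = 0.15
    annotated_fraction: float = 0.8
    family_link_fraction: float = 0.2
    nonfasting_prob: float = 0.3
    seed: int = 0

    # baseline log-abundance distribution (natural log of peak area)
    baseline_mean: float = 11.5
    baseline_sd: float = 1.5

    def validate(self) -> None:
        if self.n_carriers <= 0:
            raise ValueError("n_carriers must be positive (zero carriers requested)")
        for name in ("controls_per_carrier", "n_qc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in (
            "n_mothers_fraction",
            "repeat_measure_prob",
            "duplicate_rate",
            "annotated_fraction",
            "family_link_fraction",
            "nonfasting_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 <= self.lod_quantile < 1.0:
            raise ValueError(f"lod_quantile must lie in [0, 1), got {self.lod_quantile}")
        for name in ("dilution_sd", "tech_rsd", "biol_sd", "baseline_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        unknown = set(self.effect_by_class) - set(self.n_features_per_class)
        if unknown:
            raise ValueError(
                f"effect_by_class names unknown class(es): {sorted(unknown)}"
            )
        if any(n < 0 for n in self.n_features_per_class.values()):
            raise ValueError("feature counts must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["n_features_per_class"] = dict(self.n_features_per_class)
        d["effect_by_class"] = dict(self.effect_by_class)
        return d


@dataclass
class SimTruth:
    """Ground truth of a simulated study, for validating the analysis.

    Attributes
    ----------
    effect
        Per-feature true standardized genotype effect (SD units on the
        log scale); duplicates inherit their parent's effect.
    dilution
        Per-sample true dilution factor (pooled-QC samples have factor 1).
    lod
        The abundance threshold used for left-censoring.
    affected
        Features with a nonzero true effect.
    annotation_groups
        Metabolite label -> list of feature ids sharing it.
    """

    effect: pd.Series
    dilution: pd.Series
    lod: float
    affected: frozenset
    annotation_groups: dict[str, list[str]]

    def __post_init__(self) -> None:
        assert self.affected == frozenset(self.effect.index[self.effect != 0.0])
        assert (self.dilution > 0).all()


# ---------------------------------------------------------------------------


def _simulate_design(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Subjects, matching and sampling schedule -> sample metadata frame."""
    n_mothers = int(round(config.n_mothers_fraction * config.n_carriers))
    rows: list[dict] = []
    subj_counter = 0

    def new_subject() -> str:
        nonlocal subj_counter
        subj_counter += 1
        return f"subj-{subj_counter:04d}"

    carriers: list[dict] = []
    for i in range(config.n_carriers):
        cohort = "mother" if i < n_mothers else "young"
        sid = new_subject()
        if cohort == "mother":
            age = float(np.round(rng.normal(48.0, 5.5), 1))
            sex = "F"
        else:
            age = float(np.round(rng.normal(16.0, 1.2), 1))
            sex = "F" if rng.random() < 0.5 else "M"
        carriers.append(
            {"subject_id": sid, "family_id": f"fam-{sid}", "genotype": "carrier",
             "age": age, "sex": sex, "cohort": cohort}
        )

    # mother-offspring family links: a fraction of young carriers share a
    # family id with a carrier mother, so the pedigree random effect has
    # something to absorb in the combined analysis
    mother_fams = [c["family_id"] for c in carriers if c["cohort"] == "mother"]
    if mother_fams:
        for c in carriers:
            if c["cohort"] == "young" and rng.random() < config.family_link_fraction:
                c["family_id"] = mother_fams[rng.integers(len(mother_fams))]

    controls: list[dict] = []
    for c in carriers:
        for _ in range(config.controls_per_carrier):
            sid = new_subject()
            controls.append(
                {"subject_id": sid, "family_id": f"fam-{sid}",
                 "genotype": "non-carrier",
                 # matched on cohort and sex, age within +/- 1 year
                 "age": float(np.round(c["age"] + rng.uniform(-1.0, 1.0), 1)),
                 "sex": c["sex"], "cohort": c["cohort"]}
            )

    sample_counter = 0
    for subj in carriers + controls:
        n_rep = 1
        if subj["genotype"] == "carrier" and rng.random() < config.repeat_measure_prob:
            n_rep = 2
        for _ in range(n_rep):
            sample_counter += 1
            fasting = True
            if (
                subj["cohort"] == "mother"
                and subj["genotype"] == "carrier"
                and rng.random() < config.nonfasting_prob
            ):
                fasting = False
            rows.append(
                {"sample_id": f"S{sample_counter:04d}", "fasting": fasting,
                 "is_qc": False, **subj}
            )

    for q in range(config.n_qc):
        rows.append(
            {"sample_id": f"QC{q + 1:02d}", "subject_id": "QC-pool",
             "family_id": np.nan, "genotype": np.nan, "age": np.nan,
             "sex": np.nan, "cohort": np.nan, "fasting": True, "is_qc": True}
        )

    meta = pd.DataFrame(rows).set_index("sample_id")
    return meta[list(("subject_id", "family_id", "genotype", "age", "sex",
                      "cohort", "fasting", "is_qc"))]


def _simulate_features(
    config: SimConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, np.ndarray]:
    """Feature metadata plus parent index, per-feature effect and baseline.

    Returns ``(feature_meta, parent_idx, effect, baseline)`` where
    ``parent_idx[j]`` is the index of feature j's parent metabolite and
    ``effect``/``baseline`` are per *metabolite* arrays.
    """
    met_class: list[str] = []
    for cls, n in config.n_features_per_class.items():
        met_class.extend([cls] * int(n))
    n_met = len(met_class)
    if n_met == 0:
        raise ValueError("no features requested")

    effects = np.array(
        [config.effect_by_class.get(cls, 0.0) for cls in met_class], dtype=float
    )
    baselines = rng.normal(config.baseline_mean, config.baseline_sd, size=n_met)

    rows: list[dict] = []
    parent_idx: list[int] = []
    feat_counter = 0
    for m, cls in enumerate(met_class):
        annotated = rng.random() < config.annotated_fraction
        label = f"{cls} M{m + 1:04d}" if annotated else np.nan
        n_feat = 1
        if rng.random() < config.duplicate_rate:
            n_feat = int(rng.integers(2, 4))  # 2 or 3 redundant features
        if cls in _LIPID_CLASSES:
            modes = ("LIPIDS-NEG", "LIPIDS-POS")
            p_neg = 0.7
        else:
            modes = ("HILIC-NEG", "HILIC-POS")
            p_neg = 0.4
        lo, hi = _MZ_RANGES[cls]
        for _ in range(n_feat):
            feat_counter += 1
            rows.append(
                {
                    "feature_id": f"F{feat_counter:05d}",
                    "assay": modes[0] if rng.random() < p_neg else modes[1],
                    "mz": float(np.round(rng.uniform(lo, hi), 4)),
                    "rt": float(np.round(rng.uniform(30.0, 900.0), 1)),
                    "annotation": label,
                    "lipid_class": cls,
                }
            )
            parent_idx.append(m)

    feature_meta = pd.DataFrame(rows).set_index("feature_id")
    return feature_meta, np.asarray(parent_idx), effects, baselines


def simulate_study(config: SimConfig) -> tuple[FeatureTable, pd.DataFrame, SimTruth]:
    """Generate one synthetic study: feature table, sample metadata, truth.

    The same configuration and seed always produce identical outputs.
    Left-censoring at ``config.lod_quantile`` is applied before returning
    (set it to 0 for a fully observed table).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    meta = _simulate_design(config, rng)
    feature_meta, parent_idx, met_effect, met_baseline = _simulate_features(config, rng)

    study = meta[~meta["is_qc"]]
    subjects = study["subject_id"].unique()
    subj_pos = {s: i for i, s in enumerate(subjects)}
    subj_of_sample = np.array([subj_pos[s] for s in study["subject_id"]])
    g = (study["genotype"] == "carrier").to_numpy(dtype=float)

    n_met = len(met_effect)
    n_study = len(study)
    sigma_half = config.biol_sd / np.sqrt(2.0)

    # subject random intercept and sample-level residual, per metabolite
    u = rng.normal(0.0, sigma_half, size=(n_met, len(subjects)))
    e = rng.normal(0.0, sigma_half, size=(n_met, n_study))
    log_dil = rng.normal(0.0, config.dilution_sd, size=n_study)

    log_v = (
        met_baseline[:, None]
        + config.biol_sd * met_effect[:, None] * g[None, :]
        + u[:, subj_of_sample]
        + e
        + log_dil[None, :]
    )
    parent_vals = np.exp(log_v)  # metabolites x study samples

    # expand metabolites -> features; duplicates carry independent
    # multiplicative technical noise (mean-unbiased log-normal, CV = tech_rsd%)
    cv = config.tech_rsd / 100.0
    sigma_t = float(np.sqrt(np.log1p(cv**2)))
    n_feat = len(parent_idx)
    feat_vals = parent_vals[parent_idx, :].copy()
    is_dup = np.zeros(n_feat, dtype=bool)
    seen: set[int] = set()
    for j, m in enumerate(parent_idx):
        if m in seen:
            is_dup[j] = True
        seen.add(m)
    if is_dup.any() and sigma_t > 0:
        noise = rng.normal(0.0, sigma_t, size=(int(is_dup.sum()), n_study))
        feat_vals[is_dup, :] *= np.exp(noise - sigma_t**2 / 2.0)

    # pooled QC: arithmetic mean profile of all study samples, replicated
    # with mean-unbiased multiplicative technical noise
    pooled = feat_vals.mean(axis=1)
    qc_vals = np.tile(pooled[:, None], (1, config.n_qc))
    if config.n_qc > 0 and sigma_t > 0:
        noise = rng.normal(0.0, sigma_t, size=(n_feat, config.n_qc))
        qc_vals *= np.exp(noise - sigma_t**2 / 2.0)

    qc_ids = meta.index[meta["is_qc"]]
    values = pd.DataFrame(
        np.hstack([feat_vals, qc_vals]),
        index=feature_meta.index,
        columns=list(study.index) + list(qc_ids),
    )

    table = FeatureTable(values, feature_meta)
    validate_sample_meta(meta)

    table, lod = apply_censoring(table, meta, config.lod_quantile)

    feat_effect = pd.Series(met_effect[parent_idx], index=feature_meta.index, name="effect")
    dilution = pd.Series(1.0, index=meta.index, name="dilution")
    dilution.loc[study.index] = np.exp(log_dil)
    groups: dict[str, list[str]] = {}
    for fid, label in feature_meta["annotation"].items():
        if isinstance(label, str):
            groups.setdefault(label, []).append(fid)
    truth = SimTruth(
        effect=feat_effect,
        dilution=dilution,
        lod=lod,
        affected=frozenset(feat_effect.index[feat_effect != 0.0]),
        annotation_groups=groups,
    )
    return table, meta, truth


def apply_censoring(
    table: FeatureTable, meta: pd.DataFrame, lod_quantile: float
) -> tuple[FeatureTable, float]:
    """Left-censor values below a global limit of detection.

    The LOD is the ``lod_quantile`` quantile of all present *study-sample*
    values; every value strictly below it (study and pooled-QC alike) becomes
    missing.  Returns the censored table and the LOD used.  ``lod_quantile=0``
    leaves the table unchanged (the LOD is then the observed minimum).
    """
    if not 0.0 <= lod_quantile < 1.0:
        raise ValueError(f"lod_quantile must lie in [0, 1), got {lod_quantile}")
    study = study_samples(meta, table)
    vals = table.values[study.index].to_numpy(dtype=float)
    present = vals[~np.isnan(vals)]
    if present.size == 0:
        raise ValueError("no present study-sample values to set a LOD from")
    lod = float(np.quantile(present, lod_quantile))
    censored = table.values.where(~(table.values < lod))
    return FeatureTable(censored, table.feature_meta.copy()), lod
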