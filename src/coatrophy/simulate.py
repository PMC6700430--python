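"""Seeded synthetic CN/MCI cohorts with planted co-atrophy modules.

The generator emulates the structure of a two-timepoint morphometry study:

* a CN reference cohort whose regional values are noise around per-feature
  reference means (thickness in mm; volumes as a fraction of a log-normal
  per-subject intracranial volume, so head size is a removable confound);
* an MCI cohort in which each planted module m has a per-subject latent
  atrophy factor f_m ~ N(0,1); module members lose ``loading * f_m``
  reference-SDs of tissue, so lower values = more atrophy and members of a
  module are positively inter-correlated after Z-scoring;
* clinical traits driven by the factors: conversion to dementia is
  Bernoulli(logistic(alpha + sum beta_conv_m * f_m)) and cognitive decline
  speed is a linear combination of the factors plus noise;
* a second timepoint (36 months) at which converters' factors are shifted
  by ``conv_shift`` and every subject gains fresh module-level progression,
  so conversion-linked co-atrophy appears in the *longitudinal change* of a
  module whose baseline factor is independent of conversion — the
  temporal-to-parietal extension pattern the consensus pipeline is meant to
  recover.

Default planted layout: module A = bilateral temporal-lobe thickness, with a
baseline conversion link; module B = bilateral parietal thickness, with a
conversion link only through the 36-month shift.  Both modules carry their
correlation structure at both timepoints — a module absent from one network
cannot survive the elementwise-minimum consensus, so "activation at 36
months" is expressed in the trait link, not the covariance.  A module can
still be given literal one-timepoint loadings via ``timepoint_active``.

Identical seed implies bitwise-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    ClinicalTable,
    CohortMatrix,
    SUBJECT_COLUMN,
    TABLE_FILENAMES,
)
from .schema import FeatureSchema, ICV_COLUMN, default_schema

__all__ = [
    "ModuleSpec",
    "SimConfig",
    "default_modules",
    "reference_profile",
    "generate_cohort",
    "planted_truth",
    "write_fixtures",
]

# Temporal-lobe and parietal-lobe Desikan-Killiany regions used by the
# default planted modules (5 bilateral regions each -> 10 features).
TEMPORAL_REGIONS = (
    "entorhinal",
    "fusiform",
    "middletemporal",
    "inferiortemporal",
    "superiortemporal",
)
PARIETAL_REGIONS = (
    "inferiorparietal",
    "superiorparietal",
    "supramarginal",
    "precuneus",
    "postcentral",
)


@dataclass(frozen=True)
class ModuleSpec:
    """One planted co-atrophy module."""

    name: str
    members: tuple[str, ...]
    loading: float = 0.8  # lambda in (0, 1]: SDs of tissue lost per factor unit
    beta_conv: float = 0.0  # effect of the baseline factor on conversion log-odds
    conv_shift: float = 1.0  # factor increment for converters at 36 months
    progression_sd: float = 1.0  # SD of the fresh 36-month module progression
    adas_coef: float = 0.0  # effect of the baseline factor on decline speed
    timepoint_active: str = "both"  # "baseline" | "m36" | "both"

    def __post_init__(self) -> None:
        if not 0.0 <= self.loading <= 1.0:
            raise ValueError(f"module {self.name}: loading must be in [0, 1]")
        if self.timepoint_active not in ("baseline", "m36", "both"):
            raise ValueError(f"module {self.name}: bad timepoint_active")

    def active_at(self, timepoint: str) -> bool:
        return self.timepoint_active in ("both", timepoint)


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort."""

    n_cn: int = 140
    n_mci: int = 200
    seed: int = 0
    modules: tuple[ModuleSpec, ...] | None = None  # None -> default layout
    noise_sd: float = 0.5  # residual SD in units of the reference SD
    icv_log_mean: float = math.log(1.5e6)  # mm^3
    icv_log_sd: float = 0.08
    conversion_intercept: float = 0.0  # alpha; 0 with beta=1.2 gives ~50% converters
    adas_baseline_mean: float = 20.0
    adas_baseline_sd: float = 4.0
    adas_speed_mean: float = 0.18  # score/month, MCI
    adas_speed_sd: float = 0.08
    mci_followup: float = 1.0  # fraction of MCI retained at 36 months
    cn_followup: float = 1.0
    baseline_means: pd.DataFrame | None = None  # per-feature mean/sd override

    def __post_init__(self) -> None:
        if self.n_cn < 10 or self.n_mci < 10:
            raise ValueError("n_cn and n_mci must be >= 10")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")

    def resolved_modules(self, schema: FeatureSchema) -> tuple[ModuleSpec, ...]:
        mods = self.modules if self.modules is not None else default_modules(schema)
        seen: set[str] = set()
        for mod in mods:
            for fid in mod.members:
                if fid not in schema:
                    raise ValueError(f"module {mod.name}: unknown feature {fid!r}")
                if fid in seen:
                    raise ValueError(f"feature {fid!r} belongs to two modules")
                seen.add(fid)
        return tuple(mods)


def default_modules(schema: FeatureSchema) -> tuple[ModuleSpec, ...]:
    """The default two-module planted layout (temporal + parietal)."""
    return (
        ModuleSpec(
            name="temporal",
            members=tuple(schema.select(TEMPORAL_REGIONS, "thickness")),
            loading=0.8,
            beta_conv=1.2,
            conv_shift=1.0,
            adas_coef=0.12,
        ),
        ModuleSpec(
            name="parietal",
            members=tuple(schema.select(PARIETAL_REGIONS, "thickness")),
            loading=0.8,
            beta_conv=0.0,
            conv_shift=1.0,
            adas_coef=0.0,
        ),
    )


def reference_profile(schema: FeatureSchema, include_excluded: bool = False) -> pd.DataFrame:
    """Per-feature reference mean and SD (seed-independent).

    Thickness in mm; volumes as a *fraction of ICV*.  Scales are plausible
    for adult brain morphometry: cortical thickness ~2.2-2.9 mm, a
    parcellated white-matter region ~0.4-0.8 %ICV, subcortical structures
    ~0.1-0.5 %ICV, ventricles ~0.5-1.5 %ICV.  A fixed RNG (independent of
    the cohort seed) adds per-feature variation so no two features share a
    reference distribution.
    """
    base = {
        # (mean, relative sd) per tissue class; volumes as fraction of ICV
        "cortical_gm": (2.5, 0.06),  # mm, thickness
        "cortical_wm": (0.006, 0.10),
        "subcortical": (0.003, 0.08),
        "ventricle": (0.010, 0.30),
        "other": (0.004, 0.12),
    }
    rng = np.random.default_rng(20190725)  # fixed: profile is part of the design
    entries = schema.entries if include_excluded else schema.active
    rows = []
    for e in entries:
        mean0, rel_sd = base[e.tissue]
        jitter = rng.uniform(0.8, 1.2)
        mean = mean0 * jitter
        rows.append((e.feature_id, mean, rel_sd * mean))
    return pd.DataFrame(rows, columns=["feature_id", "mean", "sd"]).set_index(
        "feature_id"
    )


def planted_truth(config: SimConfig, schema: FeatureSchema | None = None) -> pd.Series:
    """Generating feature -> module labels; non-members are 'grey'.

    Labels depend only on the module layout, never on the seed.
    """
    schema = schema or default_schema()
    labels = pd.Series("grey", index=pd.Index(schema.feature_ids, name="feature_id"))
    for mod in config.resolved_modules(schema):
        labels.loc[list(mod.members)] = mod.name
    labels.name = "module"
    return labels


def _standardized_values(
    rng: np.random.Generator,
    schema: FeatureSchema,
    modules: tuple[ModuleSpec, ...],
    factors: np.ndarray,  # n_subjects x n_modules effective factors
    noise_sd: float,
    timepoint: str,
) -> np.ndarray:
    """Subjects x features values on the standardized (reference-SD) scale."""
    n = factors.shape[0]
    feats = schema.feature_ids
    col = {f: i for i, f in enumerate(feats)}
    x = rng.normal(0.0, noise_sd, size=(n, len(feats)))
    for m, mod in enumerate(modules):
        if not mod.active_at(timepoint):
            continue
        idx = [col[f] for f in mod.members]
        # atrophy: a high factor *lowers* the measured value
        x[:, idx] -= mod.loading * factors[:, m][:, None]
    return x


def _raw_from_standardized(
    x: np.ndarray, schema: FeatureSchema, profile: pd.DataFrame, icv: np.ndarray
) -> pd.DataFrame:
    feats = schema.feature_ids
    mean = profile.loc[feats, "mean"].to_numpy()
    sd = profile.loc[feats, "sd"].to_numpy()
    raw = mean[None, :] + sd[None, :] * x
    is_vol = np.array([f in set(schema.volume_ids) for f in feats])
    raw[:, is_vol] = raw[:, is_vol] * icv[:, None]  # fraction of ICV -> mm^3
    return pd.DataFrame(raw, columns=feats)


def generate_cohort(
    config: SimConfig, schema: FeatureSchema | None = None
) -> tuple[CohortMatrix, CohortMatrix, ClinicalTable]:
    """Generate (baseline matrix, 36-month matrix, clinical table)."""
    schema = schema or default_schema()
    modules = config.resolved_modules(schema)
    profile = (
        config.baseline_means
        if config.baseline_means is not None
        else reference_profile(schema)
    )
    rng = np.random.default_rng(config.seed)

    cn_ids = [f"CN{i:04d}" for i in range(1, config.n_cn + 1)]
    mci_ids = [f"MCI{i:04d}" for i in range(1, config.n_mci + 1)]
    subjects = cn_ids + mci_ids
    cohort = pd.Series(
        ["CN"] * config.n_cn + ["MCI"] * config.n_mci,
        index=pd.Index(subjects, name=SUBJECT_COLUMN),
        name="cohort",
    )

    icv = rng.lognormal(config.icv_log_mean, config.icv_log_sd, size=len(subjects))
    icv_s = pd.Series(icv, index=cohort.index, name="icv")

    n_mod = len(modules)
    # Baseline latent atrophy factors: MCI only; CN carry factor 0.
    f_mci = rng.standard_normal((config.n_mci, n_mod))
    f_base = np.vstack([np.zeros((config.n_cn, n_mod)), f_mci])

    # Conversion from the baseline factors.
    beta = np.array([m.beta_conv for m in modules])
    logit = config.conversion_intercept + f_mci @ beta
    p_conv = 1.0 / (1.0 + np.exp(-logit))
    converted = (rng.uniform(size=config.n_mci) < p_conv).astype(float)

    # Cognitive decline speed (score/month) from the baseline factors.
    adas_coef = np.array([m.adas_coef for m in modules])
    speed_mci = (
        config.adas_speed_mean
        + f_mci @ adas_coef
        + rng.normal(0.0, config.adas_speed_sd, size=config.n_mci)
    )
    speed_cn = rng.normal(-0.02, 0.05, size=config.n_cn)

    adas_base_mci = np.clip(
        rng.normal(config.adas_baseline_mean, config.adas_baseline_sd, config.n_mci),
        0.0,
        85.0,
    )
    adas_base_cn = np.clip(rng.normal(7.5, 3.0, config.n_cn), 0.0, 85.0)
    months = rng.choice([24.0, 36.0], size=len(subjects), p=[0.25, 0.75])

    age = np.concatenate(
        [rng.normal(67.0, 5.0, config.n_cn), rng.normal(74.0, 5.0, config.n_mci)]
    ).round(1)
    sex = rng.choice(["F", "M"], size=len(subjects))

    # 36-month effective factors: converters shift, everyone progresses.
    shift = np.array([m.conv_shift for m in modules])
    prog_sd = np.array([m.progression_sd for m in modules])
    eta = rng.standard_normal((config.n_mci, n_mod)) * prog_sd[None, :]
    f_m36_mci = f_mci + converted[:, None] * shift[None, :] + eta
    f_m36 = np.vstack([np.zeros((config.n_cn, n_mod)), f_m36_mci])

    x_base = _standardized_values(
        rng, schema, modules, f_base, config.noise_sd, "baseline"
    )
    x_m36 = _standardized_values(rng, schema, modules, f_m36, config.noise_sd, "m36")

    vals_base = _raw_from_standardized(x_base, schema, profile, icv)
    vals_m36 = _raw_from_standardized(x_m36, schema, profile, icv)
    vals_base.index = cohort.index
    vals_m36.index = cohort.index

    # Follow-up attrition at 36 months (drawn after everything else so that
    # followup fractions do not change the values generated for retained
    # subjects).
    keep_cn = rng.uniform(size=config.n_cn) < config.cn_followup
    keep_mci = rng.uniform(size=config.n_mci) < config.mci_followup
    keep = np.concatenate([keep_cn, keep_mci])
    m36_subjects = cohort.index[keep]

    baseline = CohortMatrix(
        values=vals_base,
        icv=icv_s,
        cohort=cohort,
        timepoint="baseline",
        schema=schema,
    )
    m36 = CohortMatrix(
        values=vals_m36.loc[m36_subjects],
        icv=icv_s.loc[m36_subjects],
        cohort=cohort.loc[m36_subjects],
        timepoint="m36",
        schema=schema,
    )

    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "subject_id": subjects,
                "cohort": cohort.to_numpy(),
                "age_years": age,
                "sex": sex,
                "adas_baseline": np.round(
                    np.concatenate([adas_base_cn, adas_base_mci]), 2
                ),
                "adas_last_month": months,
                "adas_last": np.round(
                    np.concatenate(
                        [
                            adas_base_cn + speed_cn * months[: config.n_cn],
                            adas_base_mci + speed_mci * months[config.n_cn :],
                        ]
                    ),
                    4,
                ),
                "converted": np.concatenate(
                    [np.full(config.n_cn, np.nan), converted]
                ),
            }
        )
    )
    return baseline, m36, clinical


def write_fixtures(
    config: SimConfig,
    outdir: str | Path,
    schema: FeatureSchema | None = None,
) -> dict[str, dict[str, Path] | Path]:
    """Write the four stats tables per timepoint plus the clinical CSV.

    Produces exactly the fixture layout the loader reads:
    ``<outdir>/baseline/{lh.aparc,rh.aparc,aseg,wmparc}.stats.tsv``,
    the same under ``<outdir>/m36/``, and ``<outdir>/clinical.csv``.
    Cerebellar (excluded) columns are included in the aseg tables as pure
    noise so the parser's exclusion rule is exercised on real input.
    """
    schema = schema or default_schema()
    outdir = Path(outdir)
    baseline, m36, clinical = generate_cohort(config, schema)
    profile_excl = reference_profile(schema, include_excluded=True)
    # Excluded columns get their own derived stream so the main draw order
    # (hence generate_cohort determinism) is untouched.
    rng = np.random.default_rng(np.random.default_rng(config.seed).integers(2**31) + 1)

    paths: dict[str, dict[str, Path] | Path] = {}
    for cm in (baseline, m36):
        tdir = outdir / cm.timepoint
        tdir.mkdir(parents=True, exist_ok=True)
        tpaths: dict[str, Path] = {}
        for table, filename in TABLE_FILENAMES.items():
            cols = schema.by_table(table)
            df = pd.DataFrame(index=cm.values.index)
            for entry in cols:
                if entry.excluded:
                    mean = profile_excl.loc[entry.feature_id, "mean"]
                    sd = profile_excl.loc[entry.feature_id, "sd"]
                    frac = rng.normal(mean, sd, size=len(df))
                    df[entry.feature_id] = frac * cm.icv.to_numpy()
                else:
                    df[entry.feature_id] = cm.values[entry.feature_id]
            if table == "aseg":
                df[ICV_COLUMN] = cm.icv
            p = tdir / filename
            df.to_csv(p, sep="\t", float_format="%.17g")
            tpaths[table] = p
        paths[cm.timepoint] = tpaths

    cpath = outdir / "clinical.csv"
    clinical.data.to_csv(cpath, index=False, float_format="%.17g")
    paths["clinical"] = cpath
    return paths
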