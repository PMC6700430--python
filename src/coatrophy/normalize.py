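"""ICV normalization, robust-Z scoring against a CN reference, and the
cognitive progression-speed trait.

Volumes are expressed as a percentage of each subject's total intracranial
volume; cortical thickness is left in mm.  Every feature is then converted
to a robust Z score against the cognitively-normal (CN) cohort of the *same
timepoint*:

    Z = (raw - median_CN) * 1.3489 / IQR_CN

where 1.3489 is the 25-75% spread of the standard normal distribution
(Phi^-1(0.75) - Phi^-1(0.25) = 1.34897..., printed here to four decimals for
reproducibility of the formula as stated), so that for normally distributed
data the robust Z agrees with the conventional (x - mu)/sigma score while
being insensitive to outliers.  The longitudinal "subtracted" matrix is the
per-subject difference of 36-month and baseline Z scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ClinicalTable, CohortMatrix

log = logging.getLogger("coatrophy.normalize")

__all__ = [
    "ROBUST_Z_CONSTANT",
    "ReferenceStats",
    "ZMatrix",
    "normalize_to_icv",
    "reference_stats",
    "robust_z",
    "subtract_z",
    "adas_progression_speed",
]

#: 25-75% quantile spread of the standard normal, to the precision used in
#: the robust-Z formula.
ROBUST_Z_CONSTANT = 1.3489


@dataclass
class ReferenceStats:
    """Per-feature median and IQR of the CN reference at one timepoint."""

    median: pd.Series
    iqr: pd.Series
    n_ref: pd.Series
    timepoint: str
    degenerate: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.iqr < 0).any():
            raise ValueError("negative IQR in reference stats")
        if (self.n_ref < 2).any():
            bad = list(self.n_ref.index[self.n_ref < 2])
            raise ValueError(f"fewer than 2 reference observations for: {bad}")

    @property
    def features(self) -> list[str]:
        return list(self.median.index)

    @property
    def usable_features(self) -> list[str]:
        degen = set(self.degenerate)
        return [f for f in self.features if f not in degen]


@dataclass
class ZMatrix:
    """Subjects x features robust-Z scores for one analysis dataset."""

    values: pd.DataFrame
    dataset_tag: str  # "baseline" | "m36" | "subtracted"
    constant: float = ROBUST_Z_CONSTANT

    def __post_init__(self) -> None:
        if self.dataset_tag not in ("baseline", "m36", "subtracted"):
            raise ValueError(f"bad dataset_tag {self.dataset_tag!r}")

    @property
    def subjects(self) -> list[str]:
        return list(self.values.index)

    @property
    def features(self) -> list[str]:
        return list(self.values.columns)


def normalize_to_icv(m: CohortMatrix) -> CohortMatrix:
    """Replace every volume feature by 100 * volume / ICV (%ICV).

    Thickness features are left unchanged (mm).
    """
    if (m.icv <= 0).any():
        bad = list(m.icv.index[m.icv <= 0])
        raise ValueError(f"non-positive ICV for subjects: {bad}")
    values = m.values.copy()
    vol = m.schema.volume_ids
    values[vol] = 100.0 * values[vol].div(m.icv, axis=0)
    units = dict(m.units)
    for f in vol:
        units[f] = "%ICV"
    return CohortMatrix(
        values=values,
        icv=m.icv,
        cohort=m.cohort,
        timepoint=m.timepoint,
        schema=m.schema,
        units=units,
    )


def reference_stats(m: CohortMatrix) -> ReferenceStats:
    """Median and IQR per feature over the CN rows of ``m``.

    Quantiles use linear interpolation between order statistics.  Features
    with zero reference IQR are flagged degenerate (a zero-spread reference
    makes the robust Z undefined); features with fewer than two non-missing
    CN values are an error.
    """
    cn = m.values.loc[m.cohort == "CN"]
    if cn.empty:
        raise ValueError("no CN rows to build a reference from")
    n_ref = cn.notna().sum()
    if (n_ref == 0).any():
        bad = list(n_ref.index[n_ref == 0])
        raise ValueError(f"all-missing reference features: {bad}")
    if (n_ref < 2).any():
        bad = list(n_ref.index[n_ref < 2])
        raise ValueError(f"fewer than 2 CN observations for features: {bad}")
    median = cn.median()
    q75 = cn.quantile(0.75, interpolation="linear")
    q25 = cn.quantile(0.25, interpolation="linear")
    iqr = q75 - q25
    degenerate = list(iqr.index[iqr == 0])
    if degenerate:
        log.warning(
            "%d degenerate reference features (zero IQR): %s",
            len(degenerate),
            degenerate,
        )
    return ReferenceStats(
        median=median,
        iqr=iqr,
        n_ref=n_ref,
        timepoint=m.timepoint,
        degenerate=degenerate,
    )


def robust_z(
    m: CohortMatrix,
    ref: ReferenceStats,
    cohort: str = "MCI",
    max_missing_fraction: float = 0.2,
) -> ZMatrix:
    """Robust-Z score the ``cohort`` rows of ``m`` against ``ref``.

    Z = (raw - median_ref) * 1.3489 / IQR_ref, elementwise.  Degenerate
    reference features are dropped (logged).  Subjects missing more than
    ``max_missing_fraction`` of features are dropped with a warning; the
    remaining missing cells propagate as NaN.
    """
    if m.timepoint != ref.timepoint:
        raise ValueError(
            f"reference is for timepoint {ref.timepoint!r}, matrix is {m.timepoint!r}"
        )
    if set(m.values.columns) != set(ref.features):
        raise ValueError("feature mismatch between matrix and reference stats")
    rows = m.values.loc[m.cohort == cohort]
    keep = ref.usable_features
    if len(keep) < len(ref.features):
        log.warning(
            "dropping %d degenerate features from %s dataset",
            len(ref.features) - len(keep),
            m.timepoint,
        )
    rows = rows[keep]
    missing_frac = rows.isna().mean(axis=1)
    dropped = list(rows.index[missing_frac > max_missing_fraction])
    if dropped:
        log.warning(
            "dropping %d subjects missing > %.0f%% of features: %s",
            len(dropped),
            100 * max_missing_fraction,
            dropped,
        )
        rows = rows.drop(index=dropped)
    z = (rows - ref.median[keep]) * ROBUST_Z_CONSTANT / ref.iqr[keep]
    return ZMatrix(values=z, dataset_tag=m.timepoint)


def subtract_z(z36: ZMatrix, zbase: ZMatrix) -> ZMatrix:
    """Longitudinal change matrix: 36-month Z minus baseline Z.

    Rows are the subjects present in both matrices; columns the shared
    features.
    """
    common_features = [f for f in zbase.features if f in set(z36.features)]
    if not common_features:
        raise ValueError("no shared features between the two Z matrices")
    common_subjects = [s for s in zbase.subjects if s in set(z36.subjects)]
    if not common_subjects:
        raise ValueError("no subjects present at both timepoints")
    diff = (
        z36.values.loc[common_subjects, common_features]
        - zbase.values.loc[common_subjects, common_features]
    )
    return ZMatrix(values=diff, dataset_tag="subtracted")


def adas_progression_speed(clinical: ClinicalTable) -> pd.Series:
    """Cognitive decline speed: (last score - baseline score) / months.

    Missing inputs yield a missing speed (subject retained, logged); a
    zero-month interval with differing scores is an error.
    """
    df = clinical.data
    for col in ("adas_baseline", "adas_last", "adas_last_month"):
        if col not in df.columns:
            raise ValueError(f"clinical table lacks {col!r}")
    base = df["adas_baseline"]
    last = df["adas_last"]
    months = df["adas_last_month"]
    complete = base.notna() & last.notna() & months.notna()
    zero_month = complete & (months == 0)
    if (zero_month & (last != base)).any():
        bad = list(df.index[zero_month & (last != base)])
        raise ValueError(f"zero-month ADAS interval with differing scores: {bad}")
    speed = pd.Series(np.nan, index=df.index, name="adas_speed")
    ok = complete & (months > 0)
    speed[ok] = (last[ok] - base[ok]) / months[ok]
    speed[zero_month & (last == base)] = 0.0
    n_missing = int((~complete).sum())
    if n_missing:
        log.info("ADAS speed missing for %d subjects (incomplete inputs)", n_missing)
    return speed
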