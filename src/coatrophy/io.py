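"""Reading FreeSurfer-style stats tables and clinical tables; writing results.

Input convention: four tab-separated tables per timepoint in the flat
"one row per subject, one column per region" export layout (as produced by
FreeSurfer's ``aparcstats2table``/``asegstats2table``), named after the
canonical exports ``lh.aparc.stats.tsv``, ``rh.aparc.stats.tsv``,
``aseg.stats.tsv`` and ``wmparc.stats.tsv``.  The aseg table must carry the
total intracranial volume column.  Clinical data arrive as one
comma-separated table.

Outputs are comma-separated tables (assignment, eigengenes, module-trait
correlations, run parameters) plus a JSON run manifest; floats are written
with 17 significant digits so a write/read round trip is lossless.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .schema import FeatureSchema, ICV_COLUMN, TABLE_NAMES, default_schema

log = logging.getLogger("coatrophy.io")

__all__ = [
    "CohortMatrix",
    "ClinicalTable",
    "load_freesurfer_tables",
    "load_clinical",
    "write_results",
    "read_results",
    "FLOAT_FORMAT",
]

FLOAT_FORMAT = "%.17g"

#: Canonical on-disk filenames for the four stats tables.
TABLE_FILENAMES: dict[str, str] = {
    "lh_aparc": "lh.aparc.stats.tsv",
    "rh_aparc": "rh.aparc.stats.tsv",
    "aseg": "aseg.stats.tsv",
    "wmparc": "wmparc.stats.tsv",
}

SUBJECT_COLUMN = "subject"
VALID_COHORTS = ("CN", "MCI")


@dataclass
class CohortMatrix:
    """Subjects x features raw morphometry for one timepoint.

    ``values`` is indexed by subject id with one column per non-excluded
    schema feature (mm for thickness, mm^3 for volume until ICV
    normalization).  ``icv`` is the per-subject total intracranial volume in
    mm^3, ``cohort`` the per-subject CN/MCI label.
    """

    values: pd.DataFrame
    icv: pd.Series
    cohort: pd.Series
    timepoint: str  # "baseline" | "m36"
    schema: FeatureSchema
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.icv.index) or not self.values.index.equals(
            self.cohort.index
        ):
            raise ValueError("values, icv and cohort must share the subject index")
        expected = self.schema.feature_ids
        if list(self.values.columns) != expected:
            missing = set(expected) - set(self.values.columns)
            extra = set(self.values.columns) - set(expected)
            raise ValueError(
                f"feature columns do not match schema (missing={sorted(missing)}, "
                f"extra={sorted(extra)})"
            )
        if (self.icv <= 0).any():
            bad = list(self.icv.index[self.icv <= 0])
            raise ValueError(f"non-positive ICV for subjects: {bad}")
        all_missing = [c for c in self.values.columns if self.values[c].isna().all()]
        if all_missing:
            raise ValueError(f"feature columns entirely missing: {all_missing}")
        bad_cohort = sorted(set(self.cohort) - set(VALID_COHORTS))
        if bad_cohort:
            raise ValueError(f"cohort labels outside {VALID_COHORTS}: {bad_cohort}")
        if not self.units:
            self.units = {
                f: ("mm" if f in self.schema.thickness_ids else "mm^3")
                for f in self.values.columns
            }

    @property
    def subjects(self) -> list[str]:
        return list(self.values.index)

    def restrict(self, cohort: str) -> "CohortMatrix":
        """Rows of a single cohort (CN or MCI)."""
        mask = self.cohort == cohort
        return CohortMatrix(
            values=self.values.loc[mask],
            icv=self.icv.loc[mask],
            cohort=self.cohort.loc[mask],
            timepoint=self.timepoint,
            schema=self.schema,
            units=dict(self.units),
        )


@dataclass
class ClinicalTable:
    """Typed per-subject clinical data.

    Required columns: ``subject_id``, ``cohort``; recognised optional
    columns: ``age_years``, ``sex``, ``adas_baseline``, ``adas_last``,
    ``adas_last_month``, ``converted``.  Any further numeric column is kept
    as a free-form trait.
    """

    data: pd.DataFrame

    NUMERIC = ("age_years", "adas_baseline", "adas_last", "adas_last_month")

    def __post_init__(self) -> None:
        df = self.data
        for col in ("subject_id", "cohort"):
            if col not in df.columns:
                raise ValueError(f"clinical table lacks required column {col!r}")
        if df["subject_id"].duplicated().any():
            dup = sorted(df.loc[df["subject_id"].duplicated(), "subject_id"])
            raise ValueError(f"duplicate subject ids in clinical table: {dup}")
        bad = sorted(set(df["cohort"]) - set(VALID_COHORTS))
        if bad:
            raise ValueError(f"cohort values outside {VALID_COHORTS}: {bad}")
        if "adas_last_month" in df.columns:
            months = pd.to_numeric(df["adas_last_month"], errors="coerce")
            if (months.dropna() < 0).any():
                raise ValueError("adas_last_month must be >= 0")
        if "converted" in df.columns:
            cn_conv = df.loc[df["cohort"] == "CN", "converted"]
            if cn_conv.notna().any():
                raise ValueError("converted must be defined only for MCI rows")
        self.data = df.set_index("subject_id", drop=False)

    @property
    def subjects(self) -> list[str]:
        return list(self.data.index)

    def trait_columns(self) -> list[str]:
        """Numeric columns usable as traits (everything but the ids)."""
        skip = {"subject_id", "cohort", "sex"}
        return [
            c
            for c in self.data.columns
            if c not in skip and pd.api.types.is_numeric_dtype(self.data[c])
        ]


def _read_table(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={SUBJECT_COLUMN: str})
    if SUBJECT_COLUMN not in df.columns:
        raise ValueError(f"{path}: no {SUBJECT_COLUMN!r} column")
    if df[SUBJECT_COLUMN].duplicated().any():
        dup = sorted(df.loc[df[SUBJECT_COLUMN].duplicated(), SUBJECT_COLUMN])
        raise ValueError(f"{path}: duplicate subject ids {dup}")
    return df.set_index(SUBJECT_COLUMN).sort_index()


def load_freesurfer_tables(
    paths: Mapping[str, str | Path],
    schema: FeatureSchema | None = None,
    cohort: Mapping[str, str] | pd.Series | None = None,
    timepoint: str = "baseline",
) -> CohortMatrix:
    """Merge the four stats tables into one :class:`CohortMatrix`.

    Parameters
    ----------
    paths
        Mapping from logical table name (``lh_aparc``, ``rh_aparc``,
        ``aseg``, ``wmparc``) to file path.
    schema
        Feature catalog; defaults to the 164-feature default schema.
    cohort
        Per-subject CN/MCI labels (e.g. from the clinical table).  Subjects
        without a label raise an error.

    Raises
    ------
    ValueError
        If the aseg table lacks the ICV column, or a subject is present in
        only some of the four files (strict intersection: partial rows would
        silently corrupt the correlation structure downstream).
    """
    schema = schema or default_schema()
    missing_tables = [t for t in TABLE_NAMES if t not in paths]
    if missing_tables:
        raise ValueError(f"missing stats tables: {missing_tables}")

    tables = {name: _read_table(Path(paths[name])) for name in TABLE_NAMES}

    if ICV_COLUMN not in tables["aseg"].columns:
        raise ValueError(
            f"aseg table {paths['aseg']} lacks required ICV column {ICV_COLUMN!r}"
        )

    # Strict subject agreement across the four files.
    subject_sets = {name: set(t.index) for name, t in tables.items()}
    union = set.union(*subject_sets.values())
    inter = set.intersection(*subject_sets.values())
    partial = sorted(union - inter)
    if partial:
        raise ValueError(
            f"subjects present in only some stats tables: {partial}"
        )
    subjects = sorted(inter)

    columns: dict[str, pd.Series] = {}
    for name, table in tables.items():
        table = table.loc[subjects]
        wanted = {e.feature_id: e for e in schema.by_table(name)}
        unknown = [
            c for c in table.columns if c not in wanted and c != ICV_COLUMN
        ]
        if unknown:
            log.warning("%s: ignoring unknown columns %s", paths[name], unknown)
        for col, entry in wanted.items():
            if col not in table.columns:
                if entry.excluded:
                    continue
                raise ValueError(f"{paths[name]}: missing feature column {col!r}")
            if entry.excluded:
                continue  # cerebellar / flagged columns are dropped here
            columns[col] = pd.to_numeric(table[col], errors="coerce")

    values = pd.DataFrame(columns).reindex(columns=schema.feature_ids)
    values.index = pd.Index(subjects, name=SUBJECT_COLUMN)
    icv = pd.to_numeric(tables["aseg"].loc[subjects, ICV_COLUMN], errors="coerce")
    icv.name = "icv"

    if cohort is None:
        raise ValueError("per-subject cohort labels are required")
    cohort = pd.Series(dict(cohort) if not isinstance(cohort, pd.Series) else cohort)
    unlabeled = sorted(set(subjects) - set(cohort.index))
    if unlabeled:
        raise ValueError(f"subjects without cohort label: {unlabeled}")
    cohort = cohort.loc[subjects]
    cohort.name = "cohort"

    return CohortMatrix(
        values=values, icv=icv, cohort=cohort, timepoint=timepoint, schema=schema
    )


def load_clinical(path: str | Path) -> ClinicalTable:
    """Read the comma-separated clinical table.

    Unparseable numeric cells become missing values and are counted in the
    log; rows are never dropped here.
    """
    df = pd.read_csv(Path(path), dtype={"subject_id": str, "cohort": str, "sex": str})
    n_coerced = 0
    for col in df.columns:
        if col in ("subject_id", "cohort", "sex"):
            continue
        if col == "converted":
            coerced = pd.to_numeric(df[col], errors="coerce")
            n_coerced += int((coerced.isna() & df[col].notna()).sum())
            df[col] = coerced
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        n_coerced += int((coerced.isna() & df[col].notna()).sum())
        df[col] = coerced
    if n_coerced:
        log.warning("%s: %d unparseable numeric cells set to missing", path, n_coerced)
    return ClinicalTable(df)


# ---------------------------------------------------------------------------
# Result writing


def write_results(moduleset, outdir: str | Path, manifest=None) -> dict[str, Path]:
    """Write the pipeline outputs as comma-separated tables + JSON manifest.

    Files written: ``module_assignment.csv`` (one row per feature, module
    color, grey = unclassified), ``eigengenes_<dataset>.csv`` (subjects x
    modules), ``module_trait_<dataset>.csv`` (long-format rho/p per
    module x trait), ``run_parameters.csv`` and ``run_manifest.json``.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        probe = outdir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise ValueError(f"output directory {outdir} is not writable: {exc}") from exc

    written: dict[str, Path] = {}

    assignment = moduleset.assignment_frame()
    p = outdir / "module_assignment.csv"
    assignment.to_csv(p, index=False, float_format=FLOAT_FORMAT)
    written["assignment"] = p

    for tag, eig in moduleset.eigengenes.items():
        p = outdir / f"eigengenes_{tag}.csv"
        eig.to_csv(p, float_format=FLOAT_FORMAT)
        written[f"eigengenes_{tag}"] = p

    for tag, table in moduleset.trait_tables.items():
        p = outdir / f"module_trait_{tag}.csv"
        table.to_csv(p, index=False, float_format=FLOAT_FORMAT)
        written[f"module_trait_{tag}"] = p

    params = moduleset.parameters()
    if manifest is not None:
        params = {**params, **_manifest_dict(manifest)}
    p = outdir / "run_parameters.csv"
    pd.DataFrame(
        {"parameter": list(params), "value": [json.dumps(v) for v in params.values()]}
    ).to_csv(p, index=False)
    written["parameters"] = p

    p = outdir / "run_manifest.json"
    p.write_text(json.dumps(_manifest_dict(manifest) if manifest is not None else params,
                            indent=2, default=str))
    written["manifest"] = p
    return written


def _manifest_dict(manifest) -> dict:
    if dataclasses.is_dataclass(manifest) and not isinstance(manifest, type):
        return dataclasses.asdict(manifest)
    return dict(manifest)


def read_results(outdir: str | Path) -> dict[str, pd.DataFrame | dict]:
    """Load back the tables written by :func:`write_results`."""
    outdir = Path(outdir)
    out: dict[str, pd.DataFrame | dict] = {
        "assignment": pd.read_csv(outdir / "module_assignment.csv")
    }
    for p in sorted(outdir.glob("eigengenes_*.csv")):
        out[p.stem] = pd.read_csv(p, index_col=0, float_precision="round_trip")
    for p in sorted(outdir.glob("module_trait_*.csv")):
        out[p.stem] = pd.read_csv(p, float_precision="round_trip")
    mpath = outdir / "run_manifest.json"
    if mpath.exists():
        out["manifest"] = json.loads(mpath.read_text())
    return out
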