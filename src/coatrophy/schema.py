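"""Catalog of the regional/structural morphometry features.

The default schema describes the 164 features analysed per subject: mean
cortical thickness (mm) of the 34 Desikan-Killiany regions on each hemisphere
(68 features), the volume (mm^3) of the corresponding parcellated cortical
white matter (68 features), the two unsegmented white-matter volumes, and 26
further subcortical structures/parcellations.  Total intracranial volume
(ICV) is carried separately and is never a feature.  Cerebellar volumes are
present in the catalog but flagged ``excluded`` — cerebellar atrophy is not
expected in Alzheimer-type degeneration — and are dropped at parse time.

Feature identifiers double as the column names used in the tab-separated
stats tables (the flat one-row-per-subject export convention), so the schema
fully determines parsing: each entry knows which of the four tables it lives
in and under which column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

__all__ = [
    "FeatureEntry",
    "FeatureSchema",
    "default_schema",
    "DK_REGIONS",
    "APARC_TABLES",
    "ICV_COLUMN",
]

#: The 34 cortical regions of the Desikan-Killiany atlas, in atlas order.
DK_REGIONS: tuple[str, ...] = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "parahippocampal",
    "paracentral",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "frontalpole",
    "temporalpole",
    "transversetemporal",
    "insula",
)

# Bilateral subcortical structures measured in the aseg table.
_ASEG_BILATERAL: tuple[tuple[str, str], ...] = (
    ("Lateral-Ventricle", "ventricle"),
    ("Thalamus-Proper", "subcortical"),
    ("Caudate", "subcortical"),
    ("Putamen", "subcortical"),
    ("Pallidum", "subcortical"),
    ("Hippocampus", "subcortical"),
    ("Amygdala", "subcortical"),
    ("Accumbens-area", "subcortical"),
    ("VentralDC", "subcortical"),
)

# Midline / unpaired structures in the aseg table.
_ASEG_MIDLINE: tuple[tuple[str, str], ...] = (
    ("3rd-Ventricle", "ventricle"),
    ("WM-hypointensities", "other"),
    ("non-WM-hypointensities", "other"),
    ("CC_Anterior", "other"),
    ("CC_Mid_Anterior", "other"),
    ("CC_Central", "other"),
    ("CC_Mid_Posterior", "other"),
    ("CC_Posterior", "other"),
)

ICV_COLUMN = "EstimatedTotalIntraCranialVol"

APARC_TABLES = ("lh_aparc", "rh_aparc")
#: Logical table names; callers map these onto file paths.
TABLE_NAMES = ("lh_aparc", "rh_aparc", "aseg", "wmparc")


@dataclass(frozen=True)
class FeatureEntry:
    """One measured region/structure.

    ``feature_id`` equals the column name in the source table, so it is
    unique across the four tables by construction of the naming scheme.
    """

    feature_id: str
    region: str
    hemisphere: str  # "left" | "right" | "none"
    measure: str  # "thickness" | "volume"
    tissue: str  # "cortical_gm" | "cortical_wm" | "subcortical" | "ventricle" | "other"
    table: str  # one of TABLE_NAMES
    excluded: bool = False


@dataclass
class FeatureSchema:
    """Ordered catalog of feature entries, including excluded ones."""

    entries: list[FeatureEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.feature_id for e in self.entries]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate feature ids in schema: {dupes}")
        for e in self.entries:
            if e.measure == "thickness" and e.tissue != "cortical_gm":
                raise ValueError(
                    f"{e.feature_id}: thickness features must be cortical gray matter"
                )
            if e.hemisphere not in ("left", "right", "none"):
                raise ValueError(f"{e.feature_id}: bad hemisphere {e.hemisphere!r}")
            if "erebellum" in e.region and not e.excluded:
                raise ValueError(f"{e.feature_id}: cerebellar entries must be excluded")

    # -- views -------------------------------------------------------------

    @property
    def active(self) -> list[FeatureEntry]:
        """Entries that participate in the analysis (excluded=False)."""
        return [e for e in self.entries if not e.excluded]

    @property
    def feature_ids(self) -> list[str]:
        """Ordered ids of the non-excluded features."""
        return [e.feature_id for e in self.active]

    @property
    def thickness_ids(self) -> list[str]:
        return [e.feature_id for e in self.active if e.measure == "thickness"]

    @property
    def volume_ids(self) -> list[str]:
        return [e.feature_id for e in self.active if e.measure == "volume"]

    @property
    def excluded_ids(self) -> list[str]:
        return [e.feature_id for e in self.entries if e.excluded]

    def by_table(self, table: str, include_excluded: bool = True) -> list[FeatureEntry]:
        pool = self.entries if include_excluded else self.active
        return [e for e in pool if e.table == table]

    def entry(self, feature_id: str) -> FeatureEntry:
        for e in self.entries:
            if e.feature_id == feature_id:
                return e
        raise KeyError(feature_id)

    def __len__(self) -> int:
        return len(self.active)

    def __contains__(self, feature_id: str) -> bool:
        return any(e.feature_id == feature_id for e in self.entries)

    def select(self, regions: Iterable[str], measure: str) -> list[str]:
        """Bilateral feature ids for the given region names and measure."""
        wanted = set(regions)
        return [
            e.feature_id
            for e in self.active
            if e.region in wanted and e.measure == measure
        ]


def default_schema() -> FeatureSchema:
    """Build the default 164-feature catalog.

    68 bilateral cortical thickness + 68 bilateral cortical white-matter
    volumes + 2 unsegmented white-matter volumes + 26 subcortical
    structures; cerebellar cortex and white matter are present but excluded.
    """
    entries: list[FeatureEntry] = []

    # Bilateral cortical thickness from lh/rh aparc tables.
    for hemi, prefix, table in (("left", "lh", "lh_aparc"), ("right", "rh", "rh_aparc")):
        for region in DK_REGIONS:
            entries.append(
                FeatureEntry(
                    feature_id=f"{prefix}_{region}_thickness",
                    region=region,
                    hemisphere=hemi,
                    measure="thickness",
                    tissue="cortical_gm",
                    table=table,
                )
            )

    # Bilateral parcellated cortical white-matter volumes (wmparc).
    for hemi, prefix in (("left", "lh"), ("right", "rh")):
        for region in DK_REGIONS:
            entries.append(
                FeatureEntry(
                    feature_id=f"wm-{prefix}-{region}",
                    region=region,
                    hemisphere=hemi,
                    measure="volume",
                    tissue="cortical_wm",
                    table="wmparc",
                )
            )

    # Unsegmented white matter, one per hemisphere (wmparc).
    for hemi, side in (("left", "Left"), ("right", "Right")):
        entries.append(
            FeatureEntry(
                feature_id=f"{side}-UnsegmentedWhiteMatter",
                region="UnsegmentedWhiteMatter",
                hemisphere=hemi,
                measure="volume",
                tissue="other",
                table="wmparc",
            )
        )

    # Subcortical structures (aseg).
    for name, tissue in _ASEG_BILATERAL:
        for hemi, side in (("left", "Left"), ("right", "Right")):
            entries.append(
                FeatureEntry(
                    feature_id=f"{side}-{name}",
                    region=name,
                    hemisphere=hemi,
                    measure="volume",
                    tissue=tissue,
                    table="aseg",
                )
            )
    for name, tissue in _ASEG_MIDLINE:
        entries.append(
            FeatureEntry(
                feature_id=name,
                region=name,
                hemisphere="none",
                measure="volume",
                tissue=tissue,
                table="aseg",
            )
        )

    # Cerebellum: measured by FreeSurfer, excluded from the analysis.
    for part, tissue in (("Cerebellum-Cortex", "subcortical"), ("Cerebellum-White-Matter", "other")):
        for hemi, side in (("left", "Left"), ("right", "Right")):
            entries.append(
                FeatureEntry(
                    feature_id=f"{side}-{part}",
                    region=part,
                    hemisphere=hemi,
                    measure="volume",
                    tissue=tissue,
                    table="aseg",
                    excluded=True,
                )
            )

    schema = FeatureSchema(entries)
    assert len(schema) == 164, f"default schema has {len(schema)} active features"
    return schema
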