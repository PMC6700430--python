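"""One-call orchestration of the full consensus co-atrophy analysis.

Stages: input (synthetic fixtures or real stats tables) -> ICV + robust-Z
normalization (baseline, 36-month, subtracted) -> univariate tables ->
soft-power selection on {baseline, subtracted} -> adjacency / TOM / scaling
/ consensus -> clustering / cut / merge / colors -> eigengenes and
module-trait tables for both datasets -> result files + run manifest.

The consensus is computed between the *baseline* and *subtracted* datasets:
the question is which co-atrophy patterns present at baseline are preserved
in the longitudinal change.  Any stage failure aborts with the stage name.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import (
    ClinicalTable,
    CohortMatrix,
    load_clinical,
    load_freesurfer_tables,
    write_results,
    FLOAT_FORMAT,
)
from .modules import (
    GREY,
    ModuleSet,
    assign_colors,
    cluster_features,
    cut_tree,
    dendrogram_to_newick,
    merge_modules,
    module_eigengene,
    module_trait_correlation,
    recovery_score,
)
from .network import (
    NetworkConfig,
    compute_tom,
    consensus_tom,
    correlation_matrix,
    pick_soft_power,
    scale_toms,
    signed_adjacency,
)
from .normalize import (
    adas_progression_speed,
    normalize_to_icv,
    reference_stats,
    robust_z,
    subtract_z,
)
from .schema import default_schema
from .simulate import ModuleSpec, SimConfig, generate_cohort, planted_truth, write_fixtures
from .univariate import importance_agreement, spearman_trait_correlations, variable_importance

log = logging.getLogger("coatrophy.pipeline")

__all__ = ["RunManifest", "StageError", "run_consensus_analysis", "load_config"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-for-bit."""

    config_hash: str
    seed: int | None
    soft_power: int | None = None
    sft_satisfied: bool | None = None
    sft_threshold: float = 0.80
    scale_quantile: float = 0.95
    scaling_exponents: dict = field(default_factory=dict)
    h_cut: float | None = None
    min_module_size: int = 2
    merge_cut: float = 0.2
    quantile_convention: str = "linear interpolation"
    robust_z_constant: float = 1.3489
    n_subjects: dict = field(default_factory=dict)
    dropped_features: list = field(default_factory=list)
    n_modules: int | None = None
    n_assigned: int | None = None
    planted_ari: float | None = None
    version: str = __version__


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _sim_config_from_dict(d: dict, schema) -> SimConfig:
    d = dict(d)
    mods = d.pop("modules", None)
    if mods is not None:
        mods = tuple(
            ModuleSpec(**{**m, "members": tuple(m["members"])}) for m in mods
        )
    return SimConfig(modules=mods, **d)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, str(exc)) from exc

        return wrapper

    return deco


@_stage("fs_io")
def _load_inputs(
    config: dict, outdir: Path, seed: int | None
) -> tuple[CohortMatrix, CohortMatrix, ClinicalTable, pd.Series | None, dict]:
    schema = default_schema()
    if "simulate" in config:
        sim = _sim_config_from_dict(config["simulate"], schema)
        if seed is not None:
            sim = dataclasses.replace(sim, seed=seed)
        fixture_dir = outdir / "fixtures"
        paths = write_fixtures(sim, fixture_dir, schema)
        clinical = load_clinical(paths["clinical"])
        cohort = clinical.data["cohort"]
        baseline = load_freesurfer_tables(
            paths["baseline"], schema, cohort=cohort, timepoint="baseline"
        )
        m36 = load_freesurfer_tables(
            paths["m36"], schema, cohort=cohort, timepoint="m36"
        )
        truth = planted_truth(sim, schema)
        return baseline, m36, clinical, truth, {"seed": sim.seed}
    if "data" not in config:
        raise ValueError("config needs either a 'simulate' or a 'data' section")
    data = config["data"]
    clinical = load_clinical(data["clinical"])
    cohort = clinical.data["cohort"]
    baseline = load_freesurfer_tables(
        data["baseline"], schema, cohort=cohort, timepoint="baseline"
    )
    m36 = load_freesurfer_tables(data["m36"], schema, cohort=cohort, timepoint="m36")
    return baseline, m36, clinical, None, {"seed": seed}


@_stage("normalization")
def _normalize(baseline: CohortMatrix, m36: CohortMatrix):
    base_pct = normalize_to_icv(baseline)
    m36_pct = normalize_to_icv(m36)
    ref_base = reference_stats(base_pct)
    ref_m36 = reference_stats(m36_pct)
    z_base = robust_z(base_pct, ref_base)
    z_m36 = robust_z(m36_pct, ref_m36)
    z_sub = subtract_z(z_m36, z_base)
    dropped = sorted(set(ref_base.degenerate) | set(ref_m36.degenerate))
    return z_base, z_m36, z_sub, dropped


def _trait_frame(clinical: ClinicalTable, subjects) -> pd.DataFrame:
    speed = adas_progression_speed(clinical)
    df = clinical.data
    traits = pd.DataFrame(index=df.index)
    if "age_years" in df.columns:
        traits["age_years"] = df["age_years"]
    if "converted" in df.columns:
        traits["converted"] = df["converted"]
    traits["adas_speed"] = speed
    known = {
        "subject_id", "cohort", "sex", "age_years", "converted",
        "adas_baseline", "adas_last", "adas_last_month",
    }
    for col in df.columns:
        if col not in known and pd.api.types.is_numeric_dtype(df[col]):
            traits[col] = df[col]
    return traits.reindex([s for s in subjects if s in traits.index])


def run_consensus_analysis(
    config: dict | str | Path,
    outdir: str | Path = "coatrophy_results",
    seed: int | None = None,
) -> tuple[ModuleSet, RunManifest]:
    """Run the full consensus analysis; returns (ModuleSet, RunManifest).

    ``config`` is a dict or path to a YAML file with either a ``simulate:``
    section (synthetic cohort) or a ``data:`` section (paths to the four
    stats tables per timepoint and the clinical CSV), plus optional
    ``network:`` and ``modules:`` parameter sections.  All outputs are
    written under ``outdir``.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    baseline, m36, clinical, truth, meta = _load_inputs(config, outdir, seed)
    log.info("stage=fs_io baseline n=%d, m36 n=%d", len(baseline.subjects), len(m36.subjects))

    z_base, z_m36, z_sub, dropped = _normalize(baseline, m36)
    log.info(
        "stage=normalization baseline=%d x %d, subtracted=%d x %d, dropped=%d",
        *z_base.values.shape, *z_sub.values.shape, len(dropped),
    )

    net_cfg = NetworkConfig(**config.get("network", {}))
    mod_cfg = config.get("modules", {})
    min_size = int(mod_cfg.get("min_module_size", 2))
    merge_cut = float(mod_cfg.get("merge_cut", 0.2))
    h_cut_cfg = mod_cfg.get("h_cut")

    # -- univariate --------------------------------------------------------
    try:
        traits_base = _trait_frame(clinical, z_base.subjects)
        traits_sub = _trait_frame(clinical, z_sub.subjects)
        univariate_tables = {
            "baseline": spearman_trait_correlations(z_base, traits_base),
            "subtracted": spearman_trait_correlations(z_sub, traits_sub),
        }
        importance = {}
        for tag, z, traits in (
            ("baseline", z_base, traits_base),
            ("subtracted", z_sub, traits_sub),
        ):
            imp_conv = variable_importance(z, traits["converted"], kind="binary")
            imp_adas = variable_importance(z, traits["adas_speed"], kind="continuous")
            rho, p = importance_agreement(imp_conv, imp_adas)
            importance[tag] = {
                "conversion": imp_conv,
                "adas_speed": imp_adas,
                "agreement_rho": rho,
                "agreement_p": p,
            }
    except Exception as exc:
        raise StageError("univariate", str(exc)) from exc
    log.info("stage=univariate importance agreement rho=%.3f (baseline)",
             importance["baseline"]["agreement_rho"])

    # -- network -----------------------------------------------------------
    try:
        power = pick_soft_power(
            [z_base, z_sub], net_cfg, tags=["baseline", "subtracted"]
        )
        toms = []
        for tag, z in (("baseline", z_base), ("subtracted", z_sub)):
            corr = correlation_matrix(z)
            adj = signed_adjacency(corr, power.beta, dataset_tag=tag)
            toms.append(compute_tom(adj))
        scaled = scale_toms(toms, q=net_cfg.scale_quantile)
        consensus = consensus_tom(scaled)
    except Exception as exc:
        raise StageError("network_core", str(exc)) from exc
    log.info("stage=network_core beta=%d (criterion %s)",
             power.beta, "met" if power.satisfied else "NOT met, fallback")

    # -- module detection --------------------------------------------------
    try:
        linkage = cluster_features(consensus)
        h_cut = float(h_cut_cfg) if h_cut_cfg is not None else 0.99 * float(
            linkage[:, 2].max()
        )
        provisional = cut_tree(
            linkage, consensus.features, h_cut=h_cut, min_size=min_size
        )
        merged = merge_modules(provisional, [z_base, z_sub], merge_cut=merge_cut)
        colored = assign_colors(merged)

        eigengenes: dict[str, pd.DataFrame] = {}
        var_explained: dict[str, pd.Series] = {}
        trait_tables: dict[str, pd.DataFrame] = {}
        for tag, z, traits in (
            ("baseline", z_base, traits_base),
            ("subtracted", z_sub, traits_sub),
        ):
            cols, ve = {}, {}
            labels = [l for l in pd.unique(colored) if l != GREY] + (
                [GREY] if (colored == GREY).any() else []
            )
            for label in labels:
                members = list(colored.index[colored == label])
                cols[label], ve[label] = module_eigengene(z, members)
            eigengenes[tag] = pd.DataFrame(cols)
            var_explained[tag] = pd.Series(ve, name="var_explained")
            trait_tables[tag] = module_trait_correlation(
                eigengenes[tag], traits, dataset_tag=tag
            )
    except Exception as exc:
        raise StageError("module_detection", str(exc)) from exc

    n_modules = int((colored != GREY).sum() and colored[colored != GREY].nunique())
    n_assigned = int((colored != GREY).sum())
    log.info("stage=module_detection %d modules, %d/%d features assigned",
             n_modules, n_assigned, len(colored))

    ari = float(recovery_score(colored, truth)) if truth is not None else None

    moduleset = ModuleSet(
        assignment=colored,
        linkage=linkage,
        eigengenes=eigengenes,
        var_explained=var_explained,
        trait_tables=trait_tables,
        params={
            "soft_power": power.beta,
            "h_cut": h_cut,
            "min_module_size": min_size,
            "merge_cut": merge_cut,
            "scale_quantile": net_cfg.scale_quantile,
            "seed": meta.get("seed"),
        },
    )
    manifest = RunManifest(
        config_hash=_config_hash(config),
        seed=meta.get("seed"),
        soft_power=power.beta,
        sft_satisfied=power.satisfied,
        sft_threshold=net_cfg.sft_threshold,
        scale_quantile=net_cfg.scale_quantile,
        scaling_exponents={
            t.dataset_tag: t.scaling_exponent for t in scaled
        },
        h_cut=h_cut,
        min_module_size=min_size,
        merge_cut=merge_cut,
        n_subjects={
            "baseline": len(z_base.subjects),
            "m36": len(z_m36.subjects),
            "subtracted": len(z_sub.subjects),
        },
        dropped_features=dropped,
        n_modules=n_modules,
        n_assigned=n_assigned,
        planted_ari=ari,
    )

    # -- outputs -----------------------------------------------------------
    try:
        write_results(moduleset, outdir, manifest)
        for tag, table in univariate_tables.items():
            table.to_csv(
                outdir / f"univariate_{tag}.csv", index=False, float_format=FLOAT_FORMAT
            )
        for tag, imp in importance.items():
            imp["conversion"].to_csv(
                outdir / f"importance_conversion_{tag}.csv", float_format=FLOAT_FORMAT
            )
            imp["adas_speed"].to_csv(
                outdir / f"importance_adas_{tag}.csv", float_format=FLOAT_FORMAT
            )
        power.fits.to_csv(outdir / "soft_power_fits.csv", float_format=FLOAT_FORMAT)
        (outdir / "consensus_dendrogram.nwk").write_text(
            dendrogram_to_newick(linkage, consensus.features)
        )
        for tag, ve in var_explained.items():
            ve.to_csv(outdir / f"var_explained_{tag}.csv", float_format=FLOAT_FORMAT)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("fs_io", f"writing results: {exc}") from exc

    return moduleset, manifest
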