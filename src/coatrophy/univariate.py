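"""Per-feature statistics: Spearman trait correlations with BH correction,
and per-feature variable importance.

Importance for a binary trait (conversion) is the per-feature ROC AUC,
computed by the rank / Mann-Whitney U identity with midrank tie handling and
folded to be direction-agnostic (max of AUC and 1-AUC); for a continuous
trait (decline speed) it is the per-feature R^2, taken as the squared
Pearson correlation (a model-free stand-in for a tuned per-feature
regressor; a custom per-feature predictor can be supplied).  Raw importances
are min-max rescaled across features to [0, 100].
"""

from __future__ import annotations

import logging
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .normalize import ZMatrix

log = logging.getLogger("coatrophy.univariate")

__all__ = [
    "bh_adjust",
    "spearman_trait_correlations",
    "variable_importance",
    "importance_agreement",
]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR).

    Sorted ascending, adj_i = min_{j >= i} p_(j) * m / j, clipped at 1,
    returned in the input order.  NaN entries are passed through and do not
    count toward m.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if ((pv <= 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    result = np.empty(m)
    result[order] = adj
    out[mask] = result
    return out


def _spearman_cell(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 3:
        return np.nan, np.nan
    xv, yv = x[ok], y[ok]
    if np.all(xv == xv[0]) or np.all(yv == yv[0]):
        return np.nan, np.nan
    rho, p = stats.spearmanr(xv, yv)
    return float(rho), float(p)


def spearman_trait_correlations(
    z: ZMatrix | pd.DataFrame, traits: pd.DataFrame
) -> pd.DataFrame:
    """Long-format feature x trait Spearman correlations.

    One BH correction family per trait column (across features), matching
    the per-heatmap-column adjustment of the correlation heatmaps.  Returns
    columns feature, trait, rho, p, fdr.  Constant columns or cells with
    fewer than 3 paired observations yield missing rho/p (logged).
    """
    values = z.values if isinstance(z, ZMatrix) else z
    common = [s for s in values.index if s in set(traits.index)]
    if len(common) < 3:
        raise ValueError("fewer than 3 subjects shared between Z matrix and traits")
    values = values.loc[common]
    traits = traits.loc[common]

    records = []
    n_undefined = 0
    for trait in traits.columns:
        y = traits[trait].to_numpy(dtype=float)
        rhos, ps = [], []
        for feat in values.columns:
            rho, p = _spearman_cell(values[feat].to_numpy(dtype=float), y)
            rhos.append(rho)
            ps.append(p)
            if np.isnan(rho):
                n_undefined += 1
        # a perfect correlation yields p = 0 exactly; clamp to the smallest
        # positive double for the adjustment (reported raw p is unchanged)
        tiny = np.nextafter(0.0, 1.0)
        fdr = bh_adjust([max(p, tiny) if not np.isnan(p) else p for p in ps])
        for feat, rho, p, q in zip(values.columns, rhos, ps, fdr):
            records.append((feat, trait, rho, p, q))
    if n_undefined:
        log.warning("%d undefined correlation cells (constant or sparse)", n_undefined)
    return pd.DataFrame(records, columns=["feature", "trait", "rho", "p", "fdr"])


def _auc_rank(x: np.ndarray, y: np.ndarray) -> float:
    """ROC AUC of score x for binary label y via the rank/U identity."""
    pos = x[y == 1]
    neg = x[y == 0]
    n1, n0 = pos.size, neg.size
    ranks = stats.rankdata(np.concatenate([pos, neg]))  # midranks for ties
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def variable_importance(
    z: ZMatrix | pd.DataFrame,
    trait: pd.Series,
    kind: str = "auto",
    predictor: Callable[[np.ndarray, np.ndarray], float] | None = None,
) -> pd.DataFrame:
    """Per-feature importance for one trait, min-max scaled to [0, 100].

    ``kind='binary'``: raw importance = direction-agnostic ROC AUC
    (max(AUC, 1-AUC), so a protective and a deleterious feature of equal
    strength score equally).  ``kind='continuous'``: raw importance = R^2.
    ``predictor(feature_values, trait_values) -> raw_importance`` overrides
    the per-feature statistic.
    """
    values = z.values if isinstance(z, ZMatrix) else z
    common = [s for s in values.index if s in set(trait.index)]
    values = values.loc[common]
    y_all = trait.loc[common].to_numpy(dtype=float)

    if kind == "auto":
        uniq = np.unique(y_all[~np.isnan(y_all)])
        kind = "binary" if uniq.size <= 2 else "continuous"
    if kind == "binary":
        classes = np.unique(y_all[~np.isnan(y_all)])
        if classes.size < 2:
            raise ValueError("binary trait has a single class")

    raws = []
    for feat in values.columns:
        x = values[feat].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y_all))
        xv, yv = x[ok], y_all[ok]
        if predictor is not None:
            raw = float(predictor(xv, yv))
        elif kind == "binary":
            yb = (yv == np.max(yv)).astype(int)
            if yb.min() == yb.max():
                raise ValueError(f"feature {feat}: trait has a single class")
            auc = _auc_rank(xv, yb)
            raw = max(auc, 1.0 - auc)
        else:
            if np.all(xv == xv[0]):
                raw = 0.0
            else:
                r = np.corrcoef(xv, yv)[0, 1]
                raw = float(r * r)
        raws.append(raw)

    raw_arr = np.asarray(raws, dtype=float)
    span = raw_arr.max() - raw_arr.min()
    scaled = (
        np.clip(100.0 * (raw_arr - raw_arr.min()) / span, 0.0, 100.0)
        if span > 0
        else np.zeros_like(raw_arr)
    )
    col = "raw_auc" if kind == "binary" else "raw_r2"
    return pd.DataFrame(
        {col: raw_arr, "scaled": scaled},
        index=pd.Index(values.columns, name="feature"),
    )


def importance_agreement(
    imp_a: pd.DataFrame, imp_b: pd.DataFrame
) -> tuple[float, float]:
    """Spearman correlation across features between two importance tables.

    Measures whether the features important for one endpoint (e.g.
    conversion) are also important for another (e.g. decline speed).
    """
    if list(imp_a.index) != list(imp_b.index):
        raise ValueError("importance tables cover different feature sets")
    rho, p = stats.spearmanr(imp_a["scaled"], imp_b["scaled"])
    return float(rho), float(p)
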