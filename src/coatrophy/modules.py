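"""Consensus module detection: hierarchical clustering of the consensus
TOM, static branch cut, eigengene computation, eigengene-based merging,
color labelling, and module-trait correlation.

The dissimilarity between features is 1 - consensus TOM.  Average-linkage
clustering gives the dendrogram; a static height cut (default 0.99 of the
maximum merge height) yields provisional branches, branches smaller than
``min_module_size`` (default 2) go to the catch-all "grey" label, and
modules whose eigengenes are similar in *both* datasets are merged
iteratively until no pair is closer than ``merge_cut`` (default 0.2,
i.e. eigengene correlation >= 0.8 in every dataset).

A module eigengene is the first principal component of the
column-standardized member submatrix, signed so it correlates positively
with the members' mean profile; its explained-variance share is reported.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from .network import TOMatrix
from .normalize import ZMatrix
from .univariate import bh_adjust
from scipy import stats

log = logging.getLogger("coatrophy.modules")

__all__ = [
    "GREY",
    "MODULE_COLORS",
    "ModuleSet",
    "cluster_features",
    "cut_tree",
    "module_eigengene",
    "merge_modules",
    "assign_colors",
    "module_trait_correlation",
    "recovery_score",
    "dendrogram_to_newick",
]

GREY = "grey"

#: Standard module color sequence, assigned by descending module size.
MODULE_COLORS: tuple[str, ...] = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta", "sienna3",
    "yellowgreen", "skyblue3", "plum1", "orangered4", "mediumpurple3",
)


@dataclass
class ModuleSet:
    """Final feature -> module assignment with eigengenes and trait tables."""

    assignment: pd.Series  # feature -> color label; GREY = unclassified
    linkage: np.ndarray  # scipy linkage matrix of the consensus dendrogram
    eigengenes: dict[str, pd.DataFrame] = field(default_factory=dict)
    var_explained: dict[str, pd.Series] = field(default_factory=dict)
    trait_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def modules(self, include_grey: bool = False) -> list[str]:
        labels = [l for l in self.assignment.unique() if l != GREY]
        # stable order: by descending size then first member position
        order = {
            l: (-int((self.assignment == l).sum()),
                int(np.argmax((self.assignment == l).to_numpy())))
            for l in labels
        }
        labels = sorted(labels, key=order.get)
        return labels + [GREY] if include_grey else labels

    def members(self, label: str) -> list[str]:
        return list(self.assignment.index[self.assignment == label])

    def assignment_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.assignment.index,
                "module": self.assignment.to_numpy(),
                "is_classified": (self.assignment != GREY).to_numpy(),
            }
        )

    def parameters(self) -> dict:
        return dict(self.params)


def cluster_features(consensus: TOMatrix | pd.DataFrame) -> np.ndarray:
    """Average-linkage dendrogram on the dissimilarity 1 - TOM.

    Returns a scipy linkage matrix; leaf order follows the TOM's feature
    order, which fixes tie-breaking deterministically.
    """
    values = consensus.values if isinstance(consensus, TOMatrix) else consensus
    if values.shape[0] < 2:
        raise ValueError("need at least 2 features to cluster")
    d = 1.0 - values.to_numpy(dtype=float)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, None)
    return hierarchy.linkage(squareform(d, checks=False), method="average")


def cut_tree(
    linkage: np.ndarray,
    features: list[str],
    h_cut: float | None = None,
    min_size: int = 2,
) -> pd.Series:
    """Static height cut; small branches become grey.

    ``h_cut`` defaults to 0.99 x the maximum merge height.  Branches with
    at least ``min_size`` members become provisional modules labelled
    ``M1, M2, ...`` in feature order; everything else is grey.
    """
    max_h = float(linkage[:, 2].max())
    if max_h == 0.0:
        # all features identical: one branch containing everything
        if h_cut is not None and h_cut <= 0:
            raise ValueError(f"h_cut {h_cut} must be positive")
        flat = np.ones(len(features), dtype=int)
    else:
        if h_cut is None:
            h_cut = 0.99 * max_h
        if not 0 < h_cut <= max_h:
            raise ValueError(f"h_cut {h_cut} outside (0, {max_h}]")
        flat = hierarchy.fcluster(linkage, t=h_cut, criterion="distance")
    labels = pd.Series(GREY, index=pd.Index(features, name="feature_id"), dtype=object)
    counts = pd.Series(flat).value_counts()
    next_id = 1
    seen: dict[int, str] = {}
    for i, c in enumerate(flat):
        if counts[c] < min_size:
            continue
        if c not in seen:
            seen[c] = f"M{next_id}"
            next_id += 1
        labels.iloc[i] = seen[c]
    return labels


def module_eigengene(
    z: ZMatrix | pd.DataFrame, members: list[str]
) -> tuple[pd.Series, float]:
    """First principal component of the standardized member submatrix.

    Missing cells are imputed with the member's mean (logged).  The sign is
    chosen so the eigengene correlates non-negatively with the members'
    mean standardized profile; returns (per-subject eigengene,
    explained-variance share of the first component).
    """
    values = z.values if isinstance(z, ZMatrix) else z
    if not members:
        raise ValueError("module has no members")
    x = values[list(members)].copy()
    n_imputed = int(x.isna().sum().sum())
    if n_imputed:
        log.info("imputing %d missing cells with member means", n_imputed)
        x = x.fillna(x.mean())
    sd = x.std(ddof=1)
    dead = list(sd.index[(sd == 0) | sd.isna()])
    if dead:
        warnings.warn(f"dropping zero-variance module members: {dead}")
        x = x.drop(columns=dead)
        if x.shape[1] == 0:
            raise ValueError("all module members have zero variance")
        sd = sd.drop(index=dead)
    xs = (x - x.mean()) / sd
    u, s, _ = np.linalg.svd(xs.to_numpy(), full_matrices=False)
    eig = u[:, 0]
    var_explained = float(s[0] ** 2 / np.sum(s**2))
    mean_profile = xs.mean(axis=1).to_numpy()
    if np.corrcoef(eig, mean_profile)[0, 1] < 0:
        eig = -eig
    return pd.Series(eig, index=values.index, name="eigengene"), var_explained


def _consensus_dissimilarity(
    labels: pd.Series, z_list: list[ZMatrix | pd.DataFrame]
) -> pd.DataFrame:
    """Pairwise module dissimilarity: max over datasets of 1 - cor(eigengenes)."""
    mods = [l for l in pd.unique(labels) if l != GREY]
    diss = pd.DataFrame(np.inf, index=mods, columns=mods, dtype=float)
    per_ds = []
    for z in z_list:
        eig = {
            m: module_eigengene(z, list(labels.index[labels == m]))[0] for m in mods
        }
        per_ds.append(pd.DataFrame(eig).corr(method="pearson"))
    for i, a in enumerate(mods):
        for b in mods[i + 1 :]:
            d = max(1.0 - c.loc[a, b] for c in per_ds)
            diss.loc[a, b] = diss.loc[b, a] = d
    return diss


def merge_modules(
    assignment: pd.Series,
    z_list: list[ZMatrix | pd.DataFrame],
    merge_cut: float = 0.2,
) -> pd.Series:
    """Iteratively merge the closest eigengene-similar module pair.

    Dissimilarity of a pair is the *maximum* over datasets of
    1 - Pearson correlation of their eigengenes (consensus sense: modules
    merge only if similar in every dataset).  Merging recomputes the joint
    eigengene; the loop ends when no pair is closer than ``merge_cut``.
    Terminates in at most (initial module count - 1) iterations.
    """
    labels = assignment.copy()
    while True:
        mods = [l for l in pd.unique(labels) if l != GREY]
        if len(mods) < 2:
            return labels
        diss = _consensus_dissimilarity(labels, z_list)
        arr = diss.to_numpy()
        i, j = np.unravel_index(np.argmin(arr), arr.shape)
        if arr[i, j] >= merge_cut:
            return labels
        a, b = diss.index[i], diss.columns[j]
        log.info("merging modules %s and %s (dissimilarity %.3f)", b, a, arr[i, j])
        labels[labels == b] = a


def assign_colors(assignment: pd.Series) -> pd.Series:
    """Relabel modules with the standard color sequence by descending size.

    Ties in size break by first-member position in feature order; grey is
    preserved for unclassified features.
    """
    labels = [l for l in pd.unique(assignment) if l != GREY]
    order = sorted(
        labels,
        key=lambda l: (
            -int((assignment == l).sum()),
            int(np.argmax((assignment == l).to_numpy())),
        ),
    )
    mapping = {}
    for i, l in enumerate(order):
        mapping[l] = MODULE_COLORS[i] if i < len(MODULE_COLORS) else f"module{i + 1}"
    out = assignment.map(lambda l: GREY if l == GREY else mapping[l])
    out.name = "module"
    return out


def module_trait_correlation(
    eigengenes: pd.DataFrame,
    traits: pd.DataFrame,
    dataset_tag: str = "",
    with_fdr: bool = False,
) -> pd.DataFrame:
    """Long-format Spearman correlation of module eigengenes with traits.

    The grey pseudo-module is included but flagged ``is_module=False``.
    Raw two-sided p-values are reported; BH-adjusted values are added per
    trait column when ``with_fdr`` is set.
    """
    common = [s for s in eigengenes.index if s in set(traits.index)]
    if len(common) < 3:
        raise ValueError("fewer than 3 subjects shared with the trait table")
    eig = eigengenes.loc[common]
    tr = traits.loc[common]
    records = []
    for trait in tr.columns:
        y = tr[trait].to_numpy(dtype=float)
        if np.isnan(y).all():
            warnings.warn(f"trait {trait!r} all-missing; skipped")
            continue
        ps = []
        row = []
        for mod in eig.columns:
            x = eig[mod].to_numpy(dtype=float)
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() < 3 or np.all(y[ok] == y[ok][0]):
                rho, p = np.nan, np.nan
            else:
                rho, p = stats.spearmanr(x[ok], y[ok])
            row.append((mod, trait, float(rho), float(p), mod != GREY))
            ps.append(p)
        fdr = bh_adjust(ps) if with_fdr else [np.nan] * len(ps)
        for (mod, trait_, rho, p, is_mod), q in zip(row, fdr):
            rec = {
                "module": mod,
                "trait": trait_,
                "rho": rho,
                "p": p,
                "is_module": is_mod,
            }
            if with_fdr:
                rec["fdr"] = q
            if dataset_tag:
                rec["dataset"] = dataset_tag
            records.append(rec)
    return pd.DataFrame(records)


def recovery_score(assignment: pd.Series, truth: pd.Series) -> float:
    """Adjusted Rand index between detected and planted labels.

    Grey (unclassified) counts as its own cluster on both sides; labels are
    compared as partitions, so color names need not match planted names.
    """
    if set(assignment.index) != set(truth.index):
        raise ValueError("assignment and truth cover different features")
    truth = truth.loc[assignment.index]
    return float(adjusted_rand_score(truth.to_numpy(), assignment.to_numpy()))


def dendrogram_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy dendrogram as a Newick tree (heights as branch lengths)."""
    tree = hierarchy.to_tree(linkage)

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.get_left(), node.dist)
        right = walk(node.get_right(), node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"
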