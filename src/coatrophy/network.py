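"""Signed weighted co-atrophy networks, soft-threshold selection, topological
overlap, cross-dataset TOM scaling, and the consensus TOM.

The similarity between two regional features is the pairwise Spearman
correlation of their robust-Z scores across subjects.  The *signed*
adjacency maps s in [-1, 1] onto [0, 1] and soft-thresholds it:

    a_ij = ((1 + s_ij) / 2) ** beta

so anti-correlated regions get near-zero adjacency rather than a large one.
The power beta is the smallest candidate whose network meets the scale-free
topology criterion (log-log linear fit of the connectivity distribution,
R^2 >= 0.80) in *both* datasets; if no candidate qualifies, the power
maximising the worse of the two fits is used with a prominent warning.

Topological overlap of a pair combines their direct adjacency with the
adjacency they share through common neighbours:

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij = sum_u a_iu * a_uj,   k_i = sum_u a_iu   (u != i, j)

Before the consensus, per-dataset TOMs are made comparable by a quantile-
matching power transform (each non-reference TOM is raised to
log q_ref / log q_s so all TOMs share the reference's 95th percentile); the
consensus TOM is the elementwise minimum, so only overlap preserved in
every dataset survives.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .normalize import ZMatrix

log = logging.getLogger("coatrophy.network")

__all__ = [
    "NetworkConfig",
    "AdjacencyMatrix",
    "TOMatrix",
    "SoftPowerResult",
    "correlation_matrix",
    "signed_adjacency",
    "scale_free_fit",
    "pick_soft_power",
    "compute_tom",
    "scale_toms",
    "consensus_tom",
]


@dataclass
class NetworkConfig:
    """Parameters of the network construction."""

    power_grid: tuple[int, ...] = tuple(range(1, 21))
    sft_threshold: float = 0.80  # scale-free fit index required of both datasets
    scale_quantile: float = 0.95  # quantile matched across TOMs
    n_bins: int = 10  # equal-width connectivity bins for the scale-free fit

    def __post_init__(self) -> None:
        if not 0 < self.sft_threshold < 1:
            raise ValueError("sft_threshold must be in (0, 1)")
        if list(self.power_grid) != sorted(self.power_grid):
            raise ValueError("power_grid must be sorted ascending")
        if not self.power_grid:
            raise ValueError("power_grid is empty")


@dataclass
class AdjacencyMatrix:
    """Features x features signed soft-thresholded adjacency."""

    values: pd.DataFrame
    beta: int
    dataset_tag: str = ""

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("adjacency must be symmetric")
        if (v < -1e-12).any() or (v > 1 + 1e-12).any():
            raise ValueError("adjacency entries must lie in [0, 1]")


@dataclass
class TOMatrix:
    """Features x features topological overlap."""

    values: pd.DataFrame
    dataset_tag: str = ""
    scaled: bool = False
    scaling_exponent: float = 1.0

    @property
    def features(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class SoftPowerResult:
    """Chosen soft power plus the per-power fit table."""

    beta: int
    fits: pd.DataFrame  # index power, one fit-index column per dataset
    satisfied: bool  # True if the threshold was met in both datasets


def correlation_matrix(z: ZMatrix | pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman correlation between features (symmetric, diag 1).

    Pairwise-complete observations; a constant feature has no rank
    correlation and is an error (constants should have been dropped during
    normalization).
    """
    values = z.values if isinstance(z, ZMatrix) else z
    if values.shape[0] < 3:
        raise ValueError("need at least 3 subjects for a correlation matrix")
    constant = [c for c in values.columns if values[c].nunique(dropna=True) <= 1]
    if constant:
        raise ValueError(f"constant features have undefined correlations: {constant}")
    if values.isna().any().any():
        corr = values.corr(method="spearman", min_periods=3)
    else:
        # rank-then-Pearson, vectorized (identical to spearman, much faster)
        ranks = values.rank(axis=0)
        corr = pd.DataFrame(
            np.corrcoef(ranks.to_numpy(), rowvar=False),
            index=values.columns,
            columns=values.columns,
        )
    arr = corr.to_numpy()
    np.fill_diagonal(arr, 1.0)
    arr = np.clip((arr + arr.T) / 2.0, -1.0, 1.0)
    return pd.DataFrame(arr, index=corr.index, columns=corr.columns)


def signed_adjacency(s: pd.DataFrame, beta: int, dataset_tag: str = "") -> AdjacencyMatrix:
    """Signed soft-thresholded adjacency a = ((1 + s)/2) ** beta, diag 1."""
    if beta < 1:
        raise ValueError("soft power beta must be >= 1")
    arr = s.to_numpy(dtype=float)
    if (np.abs(arr) > 1 + 1e-9).any():
        raise ValueError("correlations must lie in [-1, 1]")
    a = ((1.0 + np.clip(arr, -1.0, 1.0)) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    return AdjacencyMatrix(
        values=pd.DataFrame(a, index=s.index, columns=s.columns),
        beta=int(beta),
        dataset_tag=dataset_tag,
    )


def scale_free_fit(a: AdjacencyMatrix | pd.DataFrame, n_bins: int = 10) -> float:
    """Scale-free topology fit index of a network, in [-1, 1].

    Connectivities k_i = sum_{j != i} a_ij are binned into ``n_bins``
    equal-width bins; log10(bin frequency) is regressed on log10(bin mean
    k) over non-empty bins; the index is R^2 times the negated sign of the
    slope, so only decaying connectivity distributions score positively.
    """
    values = a.values if isinstance(a, AdjacencyMatrix) else a
    arr = values.to_numpy(dtype=float)
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 features")
    k = arr.sum(axis=1) - np.diag(arr)
    if np.allclose(k, k[0]):
        warnings.warn("all connectivities identical; scale-free fit undefined")
        return 0.0
    counts, edges = np.histogram(k, bins=n_bins)
    # bin index per node, consistent with histogram's closed last bin
    idx = np.clip(np.digitize(k, edges[1:-1], right=False), 0, n_bins - 1)
    sums = np.bincount(idx, weights=k, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        binned_mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    ok = (counts > 0) & (binned_mean > 0)
    if ok.sum() < 2:
        warnings.warn("fewer than 2 usable connectivity bins; returning 0")
        return 0.0
    x = np.log10(binned_mean[ok])
    y = np.log10(counts[ok].astype(float))
    if np.allclose(x, x[0]):
        warnings.warn("degenerate connectivity binning; returning 0")
        return 0.0
    res = stats.linregress(x, y)
    r2 = res.rvalue**2
    return float(r2 * (-np.sign(res.slope))) if res.slope != 0 else 0.0


def pick_soft_power(
    z_list: list[ZMatrix | pd.DataFrame],
    cfg: NetworkConfig | None = None,
    tags: list[str] | None = None,
) -> SoftPowerResult:
    """Smallest power meeting the scale-free criterion in every dataset.

    Falls back to the power maximising the minimum fit index across
    datasets (with a prominent warning) if no candidate reaches the
    threshold everywhere.
    """
    cfg = cfg or NetworkConfig()
    tags = tags or [f"dataset{i}" for i in range(len(z_list))]
    corrs = [correlation_matrix(z) for z in z_list]
    table = {}
    for beta in cfg.power_grid:
        fits = [
            scale_free_fit(signed_adjacency(c, beta), cfg.n_bins) for c in corrs
        ]
        table[beta] = fits
    fits_df = pd.DataFrame.from_dict(table, orient="index", columns=tags)
    fits_df.index.name = "power"

    qualifying = fits_df.index[(fits_df >= cfg.sft_threshold).all(axis=1)]
    if len(qualifying):
        beta = int(qualifying[0])
        return SoftPowerResult(beta=beta, fits=fits_df, satisfied=True)
    beta = int(fits_df.min(axis=1).idxmax())
    warnings.warn(
        f"no soft power reached a scale-free fit of {cfg.sft_threshold} in all "
        f"datasets; falling back to beta={beta} "
        f"(min-across-datasets fit {fits_df.min(axis=1).max():.3f})",
        stacklevel=2,
    )
    return SoftPowerResult(beta=beta, fits=fits_df, satisfied=False)


def compute_tom(a: AdjacencyMatrix) -> TOMatrix:
    """Topological overlap matrix of a soft-thresholded adjacency."""
    arr = a.values.to_numpy(dtype=float).copy()
    np.fill_diagonal(arr, 0.0)
    l = arr @ arr  # l_ij = sum_u a_iu a_uj, u != i,j since diag(arr)=0
    k = arr.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - arr
    if (denom <= 0).any():
        raise FloatingPointError("non-positive TOM denominator")
    tom = (l + arr) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    return TOMatrix(
        values=pd.DataFrame(tom, index=a.values.index, columns=a.values.columns),
        dataset_tag=a.dataset_tag,
    )


def _upper_quantile(values: pd.DataFrame, q: float) -> float:
    arr = values.to_numpy()
    iu = np.triu_indices_from(arr, k=1)
    return float(np.quantile(arr[iu], q))


def scale_toms(toms: list[TOMatrix], q: float = 0.95) -> list[TOMatrix]:
    """Quantile-match TOMs across datasets via an elementwise power.

    The first TOM is the reference; every other TOM is raised to
    log(q_ref)/log(q_s) where q_ref and q_s are the q-th quantiles of the
    off-diagonal entries.  A power transform keeps values in [0, 1] and
    preserves ranks.
    """
    if len(toms) < 2:
        raise ValueError("need at least 2 TOMs to scale")
    shapes = {t.values.shape for t in toms}
    if len(shapes) != 1:
        raise ValueError("TOMs have mismatched dimensions")
    q_ref = _upper_quantile(toms[0].values, q)
    if q_ref <= 0 or q_ref >= 1:
        raise ValueError(f"degenerate reference TOM quantile {q_ref}")
    out = [
        TOMatrix(
            values=toms[0].values.copy(),
            dataset_tag=toms[0].dataset_tag,
            scaled=True,
            scaling_exponent=1.0,
        )
    ]
    for t in toms[1:]:
        q_s = _upper_quantile(t.values, q)
        if q_s <= 0 or q_s >= 1:
            raise ValueError(f"degenerate TOM quantile {q_s} in {t.dataset_tag!r}")
        exponent = np.log(q_ref) / np.log(q_s)
        scaled = t.values.to_numpy() ** exponent
        np.fill_diagonal(scaled, 1.0)
        out.append(
            TOMatrix(
                values=pd.DataFrame(
                    scaled, index=t.values.index, columns=t.values.columns
                ),
                dataset_tag=t.dataset_tag,
                scaled=True,
                scaling_exponent=float(exponent),
            )
        )
    return out


def consensus_tom(scaled: list[TOMatrix]) -> TOMatrix:
    """Elementwise minimum of the scaled TOMs (diag 1).

    Only overlap present in every dataset survives, so the modules cut from
    this matrix are preserved across datasets.
    """
    if not scaled:
        raise ValueError("no TOMs given")
    shapes = {t.values.shape for t in scaled}
    if len(shapes) != 1:
        raise ValueError("TOM dimension mismatch")
    ref = scaled[0].values
    for t in scaled[1:]:
        if list(t.values.columns) != list(ref.columns):
            raise ValueError("TOM feature order mismatch")
    arr = np.minimum.reduce([t.values.to_numpy() for t in scaled])
    np.fill_diagonal(arr, 1.0)
    return TOMatrix(
        values=pd.DataFrame(arr, index=ref.index, columns=ref.columns),
        dataset_tag="consensus",
        scaled=True,
    )
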