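import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import random_symmetric_adjacency
from coatrophy import (
    NetworkConfig,
    compute_tom,
    consensus_tom,
    correlation_matrix,
    pick_soft_power,
    scale_free_fit,
    scale_toms,
    signed_adjacency,
)
from coatrophy.network import AdjacencyMatrix, TOMatrix


def _brute_force_tom(a: np.ndarray) -> np.ndarray:
    """Literal triple-loop topological overlap."""
    n = a.shape[0]
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            ki = sum(a[i, u] for u in range(n) if u != i)
            kj = sum(a[j, u] for u in range(n) if u != j)
            out[i, j] = (l + a[i, j]) / (min(ki, kj) + 1 - a[i, j])
    return out


# -- correlation matrix ------------------------------------------------------


def test_identical_columns_correlate_fully():
    idx = pd.Index([f"S{i}" for i in range(10)], name="subject")
    x = np.random.default_rng(0).standard_normal(10)
    df = pd.DataFrame({"a": x, "b": x, "c": np.exp(-x)}, index=idx)
    corr = correlation_matrix(df)
    assert corr.loc["a", "b"] == pytest.approx(1.0)
    assert corr.loc["a", "c"] == pytest.approx(-1.0)
    assert (np.diag(corr.to_numpy()) == 1.0).all()


def test_correlation_matches_rank_then_pearson_oracle():
    rng = np.random.default_rng(1)
    df = pd.DataFrame(
        rng.standard_normal((30, 6)),
        index=pd.Index([f"S{i}" for i in range(30)], name="subject"),
        columns=list("abcdef"),
    )
    corr = correlation_matrix(df)
    for i, a in enumerate(df.columns):
        for b in df.columns[i + 1 :]:
            ra = stats.rankdata(df[a])
            rb = stats.rankdata(df[b])
            expected = np.corrcoef(ra, rb)[0, 1]
            assert corr.loc[a, b] == pytest.approx(expected, abs=1e-12)


def test_constant_feature_raises():
    df = pd.DataFrame({"a": [1.0, 1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0, 4.0]})
    with pytest.raises(ValueError, match="a"):
        correlation_matrix(df)


# -- signed adjacency --------------------------------------------------------


@pytest.mark.parametrize(
    "s,beta,expected",
    [(1.0, 6, 1.0), (-1.0, 6, 0.0), (0.0, 14, 0.5**14)],
)
def test_signed_adjacency_values(s, beta, expected):
    m = pd.DataFrame([[1.0, s], [s, 1.0]], index=["a", "b"], columns=["a", "b"])
    adj = signed_adjacency(m, beta)
    assert adj.values.loc["a", "b"] == pytest.approx(expected, rel=1e-12)
    assert adj.values.loc["a", "a"] == 1.0


def test_signed_adjacency_monotone_in_s_antitone_in_beta():
    svals = np.linspace(-0.9, 0.9, 7)
    for beta in (2, 6, 12):
        a = [(1 + s) / 2 for s in svals]
        out = [x**beta for x in a]
        assert all(x < y for x, y in zip(out, out[1:]))  # monotone in s
    for s in svals:
        per_beta = [((1 + s) / 2) ** b for b in (1, 4, 8, 16)]
        assert all(x >= y for x, y in zip(per_beta, per_beta[1:]))  # antitone in beta


def test_beta_below_one_rejected():
    m = pd.DataFrame(np.eye(2), index=["a", "b"], columns=["a", "b"])
    with pytest.raises(ValueError, match="beta"):
        signed_adjacency(m, 0)


# -- scale-free fit ----------------------------------------------------------


def _clique_network():
    """Disjoint weighted pairs whose binned log-log points are collinear.

    2 nodes at k=1, 4 at k=0.5, 8 at k=0.25, 16 at k=0.125: bin counts
    double as bin-mean connectivity halves, so log10(count) on log10(k) has
    slope -1 exactly.
    """
    blocks = [(1, 1.0), (2, 0.5), (4, 0.25), (8, 0.125)]
    n = sum(2 * c for c, _ in blocks)
    a = np.eye(n)
    pos = 0
    for count, w in blocks:
        for _ in range(count):
            a[pos, pos + 1] = a[pos + 1, pos] = w
            pos += 2
    cols = [f"f{i}" for i in range(n)]
    return pd.DataFrame(a, index=cols, columns=cols)


def test_scale_free_fit_exactly_one_for_collinear_decay():
    assert scale_free_fit(_clique_network()) == pytest.approx(1.0, abs=1e-12)


def test_scale_free_fit_nonpositive_for_increasing_distribution():
    """Few low-k nodes, many high-k nodes: rising log-log slope, fit <= 0."""
    blocks = [(8, 1.0), (4, 0.5), (2, 0.25), (1, 0.125)]
    n = sum(2 * c for c, _ in blocks)
    a = np.eye(n)
    pos = 0
    for count, w in blocks:
        for _ in range(count):
            a[pos, pos + 1] = a[pos + 1, pos] = w
            pos += 2
    cols = [f"f{i}" for i in range(n)]
    assert scale_free_fit(pd.DataFrame(a, index=cols, columns=cols)) <= 0


def test_fit_improves_with_power_on_synthetic_network(z_matrices):
    corr = correlation_matrix(z_matrices["baseline"])
    low = scale_free_fit(signed_adjacency(corr, 1))
    high = scale_free_fit(signed_adjacency(corr, 14))
    assert high > low


def test_uniform_connectivity_returns_zero():
    a = pd.DataFrame(np.ones((4, 4)), index=list("abcd"), columns=list("abcd"))
    with pytest.warns(UserWarning):
        assert scale_free_fit(a) == 0.0


# -- soft power selection ----------------------------------------------------


def _fit_table_rule(table, threshold=0.80):
    qualifying = [b for b, fits in sorted(table.items()) if min(fits) >= threshold]
    if qualifying:
        return qualifying[0]
    return max(sorted(table), key=lambda b: min(table[b]))


def test_pick_soft_power_stated_rule():
    table = {8: (0.75, 0.85), 10: (0.82, 0.81), 12: (0.9, 0.9)}
    assert _fit_table_rule(table) == 10


def test_pick_soft_power_on_data_meets_threshold(z_matrices):
    res = pick_soft_power(
        [z_matrices["baseline"], z_matrices["subtracted"]],
        NetworkConfig(),
        tags=["baseline", "subtracted"],
    )
    assert res.satisfied
    assert (res.fits.loc[res.beta] >= 0.80).all()
    below = res.fits.index[res.fits.index < res.beta]
    assert not (res.fits.loc[below] >= 0.80).all(axis=1).any()


def test_pick_soft_power_fallback_warns():
    """A grid with no qualifying power falls back to argmax of the min fit."""
    rng = np.random.default_rng(2)
    idx = pd.Index([f"S{i}" for i in range(20)], name="subject")
    z = pd.DataFrame(rng.standard_normal((20, 8)), index=idx,
                     columns=[f"f{i}" for i in range(8)])
    cfg = NetworkConfig(power_grid=(1,), sft_threshold=0.99)
    with pytest.warns(UserWarning, match="falling back"):
        res = pick_soft_power([z, z], cfg)
    assert res.beta == 1
    assert not res.satisfied


# -- TOM ---------------------------------------------------------------------


def test_tom_complete_graph_is_all_ones():
    cols = list("abcd")
    a = AdjacencyMatrix(
        pd.DataFrame(np.ones((4, 4)), index=cols, columns=cols), beta=1
    )
    tom = compute_tom(a)
    assert np.allclose(tom.values.to_numpy(), 1.0)


def test_tom_three_node_hand_value():
    """a12=0.5, a13=a23=0 -> TOM12 = 0.5/(0.5+1-0.5) = 0.5."""
    cols = list("abc")
    arr = np.eye(3)
    arr[0, 1] = arr[1, 0] = 0.5
    tom = compute_tom(AdjacencyMatrix(pd.DataFrame(arr, index=cols, columns=cols), 1))
    assert tom.values.loc["a", "b"] == pytest.approx(0.5)
    assert tom.values.loc["a", "c"] == 0.0


def test_tom_matches_triple_loop_oracle():
    rng = np.random.default_rng(3)
    for _ in range(100):
        n = int(rng.integers(6, 11))
        a = random_symmetric_adjacency(rng, n)
        tom = compute_tom(AdjacencyMatrix(a, beta=6)).values.to_numpy()
        arr = a.to_numpy().copy()
        np.fill_diagonal(arr, 0.0)
        expected = _brute_force_tom(arr)
        assert np.abs(tom - expected).max() < 1e-12


def test_tom_bounds_on_random_adjacencies():
    rng = np.random.default_rng(4)
    for _ in range(20):
        a = random_symmetric_adjacency(rng, 12)
        arr = a.to_numpy().copy()
        np.fill_diagonal(arr, 0.0)
        tom = compute_tom(AdjacencyMatrix(a, beta=6)).values.to_numpy()
        assert tom.min() >= 0 and tom.max() <= 1
        k = arr.sum(axis=1)
        kmin = np.minimum.outer(k, k)
        lower = arr / (kmin + 1 - arr)
        off = ~np.eye(len(arr), dtype=bool)
        assert (tom[off] >= lower[off] - 1e-12).all()


# -- TOM scaling and consensus -----------------------------------------------


def _tom_from(rng, n=20, beta=6):
    a = random_symmetric_adjacency(rng, n)
    return compute_tom(AdjacencyMatrix(a, beta=beta))


def test_scaling_already_matched_is_identity():
    t = _tom_from(np.random.default_rng(5))
    scaled = scale_toms([t, TOMatrix(t.values.copy())])
    assert scaled[1].scaling_exponent == pytest.approx(1.0)
    np.testing.assert_allclose(
        scaled[1].values.to_numpy(), t.values.to_numpy(), atol=1e-12
    )


def test_scaling_exponent_hand_value():
    """q_ref=0.25, q_s=0.0625=0.25^2 -> exponent log(0.25)/log(0.0625)=0.5."""
    assert np.log(0.25) / np.log(0.0625) == pytest.approx(0.5, abs=1e-12)
    # defining property on real TOMs: the applied exponent is exactly the
    # ratio of log quantiles
    from coatrophy.network import _upper_quantile

    rng = np.random.default_rng(6)
    t_ref, t_s = _tom_from(rng), _tom_from(rng, beta=12)
    scaled = scale_toms([t_ref, t_s], q=0.95)
    q_ref = _upper_quantile(t_ref.values, 0.95)
    q_s = _upper_quantile(t_s.values, 0.95)
    assert scaled[1].scaling_exponent == pytest.approx(
        np.log(q_ref) / np.log(q_s), rel=1e-12
    )
    # and the squaring relation itself: a TOM elementwise-squared needs 0.5
    t_sq = TOMatrix(t_ref.values**2)
    scaled2 = scale_toms([t_ref, t_sq], q=0.95)
    assert scaled2[1].scaling_exponent == pytest.approx(0.5, abs=1e-3)


def test_scaled_toms_share_reference_quantile(z_matrices):
    from coatrophy.network import _upper_quantile

    toms = []
    for tag in ("baseline", "subtracted"):
        corr = correlation_matrix(z_matrices[tag])
        toms.append(compute_tom(signed_adjacency(corr, 9, dataset_tag=tag)))
    scaled = scale_toms(toms, q=0.95)
    q0 = _upper_quantile(scaled[0].values, 0.95)
    q1 = _upper_quantile(scaled[1].values, 0.95)
    assert abs(q0 - q1) < 1e-9
    for t in scaled:
        arr = t.values.to_numpy()
        assert arr.min() >= 0 and arr.max() <= 1


def test_consensus_is_elementwise_minimum():
    rng = np.random.default_rng(7)
    t1, t2 = _tom_from(rng), _tom_from(rng)
    cons = consensus_tom([t1, t2])
    assert (cons.values.to_numpy() <= t1.values.to_numpy() + 1e-15).all()
    assert (cons.values.to_numpy() <= t2.values.to_numpy() + 1e-15).all()
    same = consensus_tom([t1, TOMatrix(t1.values.copy())])
    np.testing.assert_allclose(same.values.to_numpy(), t1.values.to_numpy())


def test_consensus_with_zero_input_is_zero():
    t1 = _tom_from(np.random.default_rng(8))
    zero = TOMatrix(
        pd.DataFrame(
            np.eye(len(t1.values)), index=t1.values.index, columns=t1.values.columns
        )
    )
    cons = consensus_tom([t1, zero])
    off = ~np.eye(len(t1.values), dtype=bool)
    assert (cons.values.to_numpy()[off] == 0).all()


def test_consensus_dimension_mismatch_rejected():
    rng = np.random.default_rng(9)
    with pytest.raises(ValueError, match="mismatch"):
        consensus_tom([_tom_from(rng, n=10), _tom_from(rng, n=12)])
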