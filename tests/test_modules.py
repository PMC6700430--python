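import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.cluster import hierarchy

from coatrophy import (
    GREY,
    assign_colors,
    cluster_features,
    cut_tree,
    merge_modules,
    module_eigengene,
    module_trait_correlation,
    recovery_score,
)
from coatrophy.modules import MODULE_COLORS, dendrogram_to_newick
from coatrophy.network import TOMatrix


def _block_tom(n_a=5, n_b=5, within=0.9, between=0.1):
    n = n_a + n_b
    arr = np.full((n, n), between)
    arr[:n_a, :n_a] = within
    arr[n_a:, n_a:] = within
    np.fill_diagonal(arr, 1.0)
    cols = [f"f{i}" for i in range(n)]
    return TOMatrix(pd.DataFrame(arr, index=cols, columns=cols))


def _subjects_frame(arr, prefix="S"):
    idx = pd.Index([f"{prefix}{i}" for i in range(arr.shape[0])], name="subject")
    return pd.DataFrame(arr, index=idx, columns=[f"f{j}" for j in range(arr.shape[1])])


# -- clustering and cutting --------------------------------------------------


def test_identical_features_merge_at_height_zero():
    tom = _block_tom(within=1.0, between=0.0, n_a=2, n_b=2)
    Z = cluster_features(tom)
    assert Z[0, 2] == pytest.approx(0.0)


def test_block_diagonal_tom_gives_complete_subtrees():
    tom = _block_tom()
    Z = cluster_features(tom)
    flat = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    assert len(set(flat[:5])) == 1
    assert len(set(flat[5:])) == 1
    assert flat[0] != flat[5]


def test_feature_permutation_gives_isomorphic_tree():
    tom = _block_tom()
    labels1 = cut_tree(cluster_features(tom), list(tom.values.columns))
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(tom.values))
    cols = [tom.values.columns[i] for i in perm]
    shuffled = TOMatrix(tom.values.loc[cols, cols])
    labels2 = cut_tree(cluster_features(shuffled), cols)
    assert recovery_score(labels2.loc[labels1.index], labels1) == pytest.approx(1.0)


def test_cut_assigns_blocks_and_greys_singletons():
    tom = _block_tom()
    # make one feature an isolated singleton
    arr = tom.values.to_numpy().copy()
    arr[0, 1:] = arr[1:, 0] = 0.0
    cols = list(tom.values.columns)
    tom2 = TOMatrix(pd.DataFrame(arr, index=cols, columns=cols))
    labels = cut_tree(cluster_features(tom2), cols, min_size=2)
    assert labels.iloc[0] == GREY
    assert labels.iloc[1:5].nunique() == 1 and labels.iloc[1] != GREY
    assert labels.iloc[5:].nunique() == 1 and labels.iloc[5] != GREY


def test_all_identical_features_form_one_module():
    tom = _block_tom(within=1.0, between=1.0)
    labels = cut_tree(cluster_features(tom), list(tom.values.columns), h_cut=0.5)
    assert labels.nunique() == 1
    assert (labels != GREY).all()


def test_cut_height_out_of_range_rejected():
    Z = cluster_features(_block_tom())
    with pytest.raises(ValueError, match="h_cut"):
        cut_tree(Z, [f"f{i}" for i in range(10)], h_cut=5.0)


def test_newick_export_contains_all_leaves():
    tom = _block_tom()
    nwk = dendrogram_to_newick(cluster_features(tom), list(tom.values.columns))
    assert nwk.endswith(";")
    assert all(f"f{i}" in nwk for i in range(10))


# -- eigengenes --------------------------------------------------------------


def test_eigengene_of_identical_columns():
    rng = np.random.default_rng(1)
    x = rng.standard_normal(30)
    df = _subjects_frame(np.column_stack([x, x, x]))
    eig, ve = module_eigengene(df, ["f0", "f1", "f2"])
    assert ve == pytest.approx(1.0)
    xs = (x - x.mean()) / x.std(ddof=1)
    r = np.corrcoef(eig, xs)[0, 1]
    assert abs(r) == pytest.approx(1.0)
    assert r > 0  # sign follows the member-mean profile


def test_eigengene_sign_convention():
    rng = np.random.default_rng(2)
    for seed in range(5):
        df = _subjects_frame(np.random.default_rng(seed).standard_normal((25, 4)))
        eig, _ = module_eigengene(df, list(df.columns))
        mean_profile = ((df - df.mean()) / df.std(ddof=1)).mean(axis=1)
        assert np.corrcoef(eig, mean_profile)[0, 1] >= 0


def test_var_explained_matches_eigendecomposition_oracle():
    rng = np.random.default_rng(3)
    df = _subjects_frame(rng.standard_normal((40, 5)))
    _, ve = module_eigengene(df, list(df.columns))
    corr = np.corrcoef(df.to_numpy(), rowvar=False)
    eigvals = np.linalg.eigvalsh(corr)
    assert ve == pytest.approx(eigvals.max() / eigvals.sum(), abs=1e-10)


def test_zero_variance_member_dropped_with_warning():
    rng = np.random.default_rng(4)
    arr = rng.standard_normal((20, 3))
    arr[:, 1] = 7.0
    df = _subjects_frame(arr)
    with pytest.warns(UserWarning, match="zero-variance"):
        eig, ve = module_eigengene(df, list(df.columns))
    assert np.isfinite(eig).all()


# -- merging -----------------------------------------------------------------


def _two_module_setup(corr_target):
    """Two 4-feature modules whose eigengenes correlate ~corr_target in both datasets."""
    rng = np.random.default_rng(5)
    n = 200
    f1 = rng.standard_normal(n)
    f2 = corr_target * f1 + np.sqrt(1 - corr_target**2) * rng.standard_normal(n)
    cols = {}
    for j in range(4):
        cols[f"a{j}"] = f1 + 0.05 * rng.standard_normal(n)
    for j in range(4):
        cols[f"b{j}"] = f2 + 0.05 * rng.standard_normal(n)
    df = pd.DataFrame(cols, index=pd.Index([f"S{i}" for i in range(n)], name="subject"))
    labels = pd.Series(
        ["A"] * 4 + ["B"] * 4,
        index=pd.Index(list(cols), name="feature_id"),
    )
    return labels, df


def test_similar_modules_merge():
    labels, df = _two_module_setup(0.95)
    merged = merge_modules(labels, [df, df.iloc[::-1]], merge_cut=0.2)
    assert merged.nunique() == 1


def test_dissimilar_modules_stay_separate():
    labels, df = _two_module_setup(0.5)
    merged = merge_modules(labels, [df, df.iloc[::-1]], merge_cut=0.2)
    assert merged.nunique() == 2


def test_merge_requires_similarity_in_every_dataset():
    """Consensus merging: a pair similar in one dataset only is not merged."""
    labels, df_similar = _two_module_setup(0.95)
    _, df_dissimilar = _two_module_setup(0.0)
    merged = merge_modules(labels, [df_similar, df_dissimilar], merge_cut=0.2)
    assert merged.nunique() == 2


def test_no_final_pair_below_merge_cut(default_run):
    """Post-merge audit: every final pair is dissimilar in at least one dataset."""
    moduleset, _, _ = default_run
    mods = moduleset.modules()
    if len(mods) >= 2:
        corr_b = moduleset.eigengenes["baseline"][mods].corr()
        corr_s = moduleset.eigengenes["subtracted"][mods].corr()
        for i, a in enumerate(mods):
            for b in mods[i + 1 :]:
                diss = max(1 - corr_b.loc[a, b], 1 - corr_s.loc[a, b])
                assert diss >= 0.2


# -- colors ------------------------------------------------------------------


def test_largest_module_is_turquoise():
    labels = pd.Series(
        ["x"] * 5 + ["y"] * 3 + [GREY] * 2,
        index=pd.Index([f"f{i}" for i in range(10)], name="feature_id"),
    )
    colored = assign_colors(labels)
    assert (colored[:5] == "turquoise").all()
    assert (colored[5:8] == "blue").all()
    assert (colored[8:] == GREY).all()


def test_color_relabelling_is_bijective():
    rng = np.random.default_rng(6)
    labels = pd.Series(
        rng.choice(["a", "b", "c", GREY], size=30),
        index=pd.Index([f"f{i}" for i in range(30)], name="feature_id"),
    )
    colored = assign_colors(labels)
    non_grey = labels[labels != GREY]
    mapping = pd.DataFrame({"old": non_grey, "new": colored[non_grey.index]})
    per_old = mapping.groupby("old")["new"].nunique()
    per_new = mapping.groupby("new")["old"].nunique()
    assert (per_old == 1).all() and (per_new == 1).all()
    assert (colored[labels == GREY] == GREY).all()
    assert set(colored[labels != GREY]) <= set(MODULE_COLORS)


# -- module-trait correlation ------------------------------------------------


def test_eigengene_equal_to_trait_gives_rho_one():
    rng = np.random.default_rng(7)
    eig = pd.DataFrame(
        {"turquoise": rng.standard_normal(30)},
        index=pd.Index([f"S{i}" for i in range(30)], name="subject"),
    )
    traits = pd.DataFrame({"t": eig["turquoise"]}, index=eig.index)
    out = module_trait_correlation(eig, traits)
    assert out.loc[0, "rho"] == pytest.approx(1.0)
    assert out.loc[0, "is_module"]


def test_grey_module_flagged_not_module():
    rng = np.random.default_rng(8)
    eig = pd.DataFrame(
        {"turquoise": rng.standard_normal(20), GREY: rng.standard_normal(20)},
        index=pd.Index([f"S{i}" for i in range(20)], name="subject"),
    )
    traits = pd.DataFrame({"t": rng.standard_normal(20)}, index=eig.index)
    out = module_trait_correlation(eig, traits).set_index("module")
    assert not out.loc[GREY, "is_module"]
    assert out.loc["turquoise", "is_module"]


def test_null_trait_rejection_rate():
    """Independent trait: ~5% of module-trait p-values below .05."""
    rng = np.random.default_rng(9)
    n = 50
    eig = rng.standard_normal(n)
    hits = 0
    reps = 1000
    for _ in range(reps):
        y = rng.standard_normal(n)
        _, p = stats.spearmanr(eig, y)
        hits += p < 0.05
    assert abs(hits / reps - 0.05) < 0.02


# -- recovery ----------------------------------------------------------------


def test_ari_identity():
    labels = pd.Series(
        ["a"] * 5 + ["b"] * 5 + [GREY] * 5,
        index=pd.Index([f"f{i}" for i in range(15)], name="feature_id"),
    )
    assert recovery_score(labels, labels) == pytest.approx(1.0)


def test_ari_random_labelling_near_zero():
    rng = np.random.default_rng(10)
    truth = pd.Series(
        ["a"] * 10 + ["b"] * 10 + [GREY] * 30,
        index=pd.Index([f"f{i}" for i in range(50)], name="feature_id"),
    )
    scores = []
    for _ in range(100):
        shuffled = pd.Series(
            rng.permutation(truth.to_numpy()), index=truth.index
        )
        scores.append(recovery_score(shuffled, truth))
    assert abs(np.mean(scores)) < 0.05


def test_ari_mismatched_universe_rejected():
    a = pd.Series(["x"], index=["f0"])
    b = pd.Series(["x"], index=["f1"])
    with pytest.raises(ValueError, match="different features"):
        recovery_score(a, b)
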