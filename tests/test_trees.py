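"""Correlation divergence, NJ expression trees, bootstrap and Duncan's MRT."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from skbio import DistanceMatrix

from polyas.config import AnalysisConfig
from polyas.trees import (
    bootstrap_tree_lengths,
    conserved_ge_divergent_as,
    duncan_any_significant,
    duncan_mrt,
    leaf_psi_matrix,
    neighbor_joining,
    pca_scores,
    subgenome_distance_matrix,
    total_tree_length,
    tree_distance,
    triad_correlations,
)


# ------------------------------------------------------------- correlations

def _stage_frame(values_by_member: dict[str, list[float]], stages):
    """Build (variety, stage) MultiIndex frames for one variety 'AC'."""
    cols = pd.MultiIndex.from_product([["AC"], stages], names=["variety", "stage_tissue"])
    return pd.DataFrame(
        np.array(list(values_by_member.values())),
        index=list(values_by_member), columns=cols,
    )


def test_triad_correlations_flags(analysis):
    stages = tuple(f"E{i:02d}" for i in range(1, 8))
    up = list(range(7))
    gene_means = _stage_frame({"gA": up, "gB": up, "gD": up}, stages)
    psi_means = _stage_frame(
        {"eA": up, "eB": up[::-1], "eD": up}, stages
    )
    triads = pd.DataFrame(
        [{"event_A": "eA", "event_B": "eB", "event_D": "eD",
          "gene_A": "gA", "gene_B": "gB", "gene_D": "gD"}],
        index=pd.Index(["t1"], name="triad_id"),
    )
    out = triad_correlations(triads, gene_means, psi_means, "AC", stages, analysis)
    assert bool(out.loc["t1", "ge_conserved"])       # identical TPM trajectories
    assert bool(out.loc["t1", "as_divergent"])       # one pair has rho = -1
    assert out.loc["t1", "rho_AB"] == pytest.approx(-1.0)
    assert list(conserved_ge_divergent_as(out)) == ["t1"]


def test_ge_conservation_requires_all_three_pairs(analysis):
    stages = tuple(f"E{i:02d}" for i in range(1, 8))
    up = np.arange(7.0)
    weak = np.array([0, 5, 1, 6, 2, 3, 4.0])  # r ~ 0.5 vs up
    gene_means = _stage_frame({"gA": up, "gB": up, "gD": weak}, stages)
    psi_means = _stage_frame({"eA": up, "eB": up, "eD": up}, stages)
    triads = pd.DataFrame(
        [{"event_A": "eA", "event_B": "eB", "event_D": "eD",
          "gene_A": "gA", "gene_B": "gB", "gene_D": "gD"}],
        index=pd.Index(["t1"], name="triad_id"),
    )
    out = triad_correlations(triads, gene_means, psi_means, "AC", stages, analysis)
    assert not bool(out.loc["t1", "ge_conserved"])


def test_spearman_ties_match_rank_oracle(analysis):
    stages = tuple(f"E{i:02d}" for i in range(1, 8))
    a = [1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 5.0]
    b = [2.0, 1.0, 3.0, 3.0, 5.0, 4.0, 6.0]
    gene_means = _stage_frame({"gA": a, "gB": b, "gD": a}, stages)
    psi_means = _stage_frame({"eA": a, "eB": b, "eD": a}, stages)
    triads = pd.DataFrame(
        [{"event_A": "eA", "event_B": "eB", "event_D": "eD",
          "gene_A": "gA", "gene_B": "gB", "gene_D": "gD"}],
        index=pd.Index(["t1"], name="triad_id"),
    )
    out = triad_correlations(triads, gene_means, psi_means, "AC", stages, analysis)
    # average-rank oracle via Pearson on rankdata
    ra, rb = stats.rankdata(a), stats.rankdata(b)
    expected = np.corrcoef(ra, rb)[0, 1]
    assert out.loc["t1", "rho_AB"] == pytest.approx(expected, abs=1e-12)


def test_planted_conserved_ge_divergent_as_recovered(ds0, derived0, analysis):
    """All planted conserved-GE/divergent-AS triads are found; extra calls are
    limited to plain triads whose independently drawn GE trajectories happen
    to correlate above the conservation threshold (a chance-level event)."""
    truth = ds0.truth.triads
    out = triad_correlations(
        truth, derived0["gene_means"], derived0["stage_means"], "AC", config=analysis
    )
    called = set(conserved_ge_divergent_as(out))
    planted = set(truth.index[truth["role"] == "conserved_ge"])
    assert planted <= called
    extras = called - planted
    assert len(extras) <= 0.02 * len(truth)
    # any extra genuinely satisfies the definition on its realized data
    assert all(out.loc[t, "ge_conserved"] and out.loc[t, "as_divergent"] for t in extras)


# ------------------------------------------------------------------ distances

def test_distance_examples():
    m = pd.DataFrame(
        {"x": np.linspace(10, 60, 25), "y": np.linspace(10, 60, 25),
         "z": np.linspace(60, 10, 25)}
    ).T
    dm = subgenome_distance_matrix(m)
    assert dm["x", "y"] == pytest.approx(0.0)     # identical -> d = 0
    assert dm["x", "z"] == pytest.approx(2.0)     # anti-correlated -> d = 2


def test_euclidean_corr_alternative_matches_oracle():
    rng = np.random.default_rng(0)
    m = pd.DataFrame(rng.uniform(0, 100, (4, 30)), index=list("wxyz"))
    dm = subgenome_distance_matrix(m, method="euclidean_corr")
    corr = np.corrcoef(m.values)
    for i, j in itertools.combinations(range(4), 2):
        expected = np.sqrt(((corr[i] - corr[j]) ** 2).sum())
        assert dm[m.index[i], m.index[j]] == pytest.approx(expected, abs=1e-9)


def test_constant_leaf_vector_raises():
    m = pd.DataFrame({"x": np.full(25, 5.0), "y": np.linspace(0, 10, 25)}).T
    m = pd.concat([m, m.iloc[[1]].rename(index={"y": "z"})])
    with pytest.raises(ValueError, match="constant"):
        subgenome_distance_matrix(m)


# ------------------------------------------------------------------------- NJ

def test_three_leaf_closed_form():
    dm = DistanceMatrix(np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float), list("ABC"))
    tree = neighbor_joining(dm)
    assert total_tree_length(tree) == pytest.approx(5.0)
    assert tree_distance(tree, "A", "B") == pytest.approx(2.0)
    assert tree_distance(tree, "A", "C") == pytest.approx(4.0)
    assert tree_distance(tree, "B", "C") == pytest.approx(4.0)


def test_zero_matrix_gives_zero_tree():
    dm = DistanceMatrix(np.zeros((4, 4)), list("ABCD"))
    assert total_tree_length(neighbor_joining(dm)) == pytest.approx(0.0)


def _random_additive_matrix(rng, n=5):
    """Random additive distances from a random binary tree with positive branches."""
    import skbio
    ids = [f"L{i}" for i in range(n)]
    nodes = [skbio.TreeNode(name=i, length=float(rng.uniform(0.1, 2))) for i in ids]
    while len(nodes) > 1:
        a = nodes.pop(int(rng.integers(len(nodes))))
        b = nodes.pop(int(rng.integers(len(nodes))))
        parent = skbio.TreeNode(length=float(rng.uniform(0.1, 2)), children=[a, b])
        nodes.append(parent)
    tree = nodes[0]
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = tree.find(ids[i]).distance(tree.find(ids[j]))
    return DistanceMatrix(d, ids)


def test_additive_matrices_reproduced_as_tree_metrics():
    rng = np.random.default_rng(11)
    for _ in range(10):
        dm = _random_additive_matrix(rng)
        tree = neighbor_joining(dm)
        for a, b in itertools.combinations(dm.ids, 2):
            assert tree_distance(tree, a, b) == pytest.approx(dm[a, b], abs=1e-9)


def test_total_length_invariant_under_leaf_permutation():
    rng = np.random.default_rng(12)
    dm = _random_additive_matrix(rng)
    perm = list(rng.permutation(dm.ids))
    dm2 = DistanceMatrix(dm.filter(perm).data, perm)
    assert total_tree_length(neighbor_joining(dm)) == pytest.approx(
        total_tree_length(neighbor_joining(dm2)), abs=1e-9
    )


# ------------------------------------------------------------------ bootstrap

def test_bootstrap_identical_leaves_zero_length(analysis):
    rng = np.random.default_rng(0)
    row = rng.uniform(20, 80, 40)
    m = pd.DataFrame([row, row, row], index=["a", "b", "c"])
    lengths = bootstrap_tree_lengths(m, analysis, rng=1)
    assert np.allclose(lengths, 0.0, atol=1e-9)


def test_bootstrap_deterministic_given_seed(analysis, ds5, derived5):
    truth = ds5.truth.triads
    leaves = [(v, s) for v in ("AC", "CS") for s in "ABD"]
    m = leaf_psi_matrix(derived5["stage_means"], truth, leaves, "E01")
    a = bootstrap_tree_lengths(m, analysis, rng=77)
    b = bootstrap_tree_lengths(m, analysis, rng=77)
    assert np.array_equal(a, b)
    assert len(a) == analysis.n_bootstrap


def test_early_embryo_divergence_exceeds_late(ds5, derived5, analysis):
    """Planted wider homoeolog spread in E01-E03 yields longer trees."""
    truth = ds5.truth.triads
    leaves = [(v, s) for v in ("AC", "CS") for s in "ABD"]
    early, late = [], []
    for t, stage in enumerate(("E01", "E02", "E03", "E04", "E05", "E06", "E07")):
        m = leaf_psi_matrix(derived5["stage_means"], truth, leaves, stage)
        lens = bootstrap_tree_lengths(m, analysis, rng=500 + t)
        (early if t < 3 else late).append(lens)
    early, late = np.concatenate(early), np.concatenate(late)
    _, p = stats.mannwhitneyu(early, late, alternative="greater")
    assert np.nanmean(early) > np.nanmean(late)
    assert p < 0.01


# -------------------------------------------------------------------- Duncan

def test_duncan_separated_means_get_distinct_letters():
    rng = np.random.default_rng(1)
    groups = {"lo": rng.normal(0, 0.01, 10), "hi": rng.normal(100, 0.01, 10)}
    out = duncan_mrt(groups, 0.05)
    assert duncan_any_significant(out)
    assert set(out.loc["hi", "letters"]) != set(out.loc["lo", "letters"])


def test_duncan_identical_groups_share_a_letter():
    rng = np.random.default_rng(2)
    groups = {k: rng.normal(0, 1, 12) for k in "abc"}
    out = duncan_mrt(groups, 0.05)
    letters = out["letters"].tolist()
    assert any(set(a) & set(b) for a, b in itertools.combinations(letters, 2))


def test_duncan_worked_example_matches_independent_stepdown():
    """Five-group example checked against an explicit step-down computation
    with studentized-range quantiles at Duncan's protection levels."""
    data = {
        "A": np.array([9.8, 10.2, 10.0, 9.9]),
        "B": np.array([15.1, 14.8, 15.3, 15.0]),
        "C": np.array([15.4, 15.0, 15.2, 15.1]),
        "D": np.array([20.1, 19.8, 20.0, 20.2]),
        "E": np.array([25.2, 24.9, 25.1, 25.0]),
    }
    out = duncan_mrt(data, 0.05)
    # independent computation
    means = {k: v.mean() for k, v in data.items()}
    k, n = 5, 4
    df = k * (n - 1)
    mse = np.mean([np.var(v, ddof=1) for v in data.values()])
    se = np.sqrt(mse / n)
    order = sorted(means, key=means.get, reverse=True)

    def sig(i, j):
        p = j - i + 1
        alpha_p = 1 - 0.95 ** (p - 1)
        crit = stats.studentized_range.ppf(1 - alpha_p, p, df) * se
        return means[order[i]] - means[order[j]] > crit

    # B and C are indistinguishable; all other pairs differ
    for i, j in itertools.combinations(range(k), 2):
        shares = bool(set(out.loc[order[i], "letters"]) & set(out.loc[order[j], "letters"]))
        assert shares == (not sig(i, j))


def test_duncan_zero_variance_unequal_means_all_significant():
    groups = {"a": np.array([1.0, 1.0]), "b": np.array([2.0, 2.0]),
              "c": np.array([3.0, 3.0])}
    out = duncan_mrt(groups, 0.05)
    letters = out["letters"].tolist()
    assert all(not set(x) & set(y) for x, y in itertools.combinations(letters, 2))


# ------------------------------------------------------------------------ PCA

def test_pca_rank_one_matrix():
    rng = np.random.default_rng(3)
    u = rng.normal(size=30)
    v = rng.normal(size=12)
    m = pd.DataFrame(np.outer(u, v))
    scores, var = pca_scores(m, n_components=3)
    assert var[0] == pytest.approx(1.0)


def test_pca_scores_permutation_invariant_variance():
    rng = np.random.default_rng(4)
    m = pd.DataFrame(rng.normal(size=(40, 10)))
    _, v1 = pca_scores(m, 3)
    _, v2 = pca_scores(m.sample(frac=1, random_state=0), 3)
    assert np.allclose(v1, v2, atol=1e-9)
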