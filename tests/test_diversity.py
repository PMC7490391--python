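import io as _io

import numpy as np
import pytest
from skbio import TreeNode

from muskin import DNA, DistanceMatrix, FeatureTable
from muskin.diversity import (
    BranchIndex,
    beta_distance,
    chao1,
    distance_matrix,
    faith_pd,
    pcoa,
    permanova,
    shannon,
)


def _tree(newick: str) -> TreeNode:
    return TreeNode.read(_io.StringIO(newick))


# ---------------------------------------------------------------------------
# alpha
# ---------------------------------------------------------------------------

def test_shannon_uniform_four_taxa():
    assert shannon([10, 10, 10, 10]) == pytest.approx(np.log(4), abs=1e-12)


def test_shannon_single_taxon_zero():
    assert shannon([0, 42, 0]) == 0.0


def test_shannon_direct_summation_oracle():
    counts = np.array([1, 2, 3, 4])
    p = counts / counts.sum()
    expected = -sum(pi * np.log(pi) for pi in p)
    assert shannon(counts) == pytest.approx(expected, abs=1e-12)


def test_shannon_all_zero_flagged():
    with pytest.raises(ValueError):
        shannon([0, 0])


def test_chao1_no_singletons_is_sobs():
    assert chao1([5, 3, 2, 0]) == 3.0


def test_chao1_formula():
    # S_obs=3, F1=2, F2=1 -> 3 + 2*1/(2*2) = 3.5
    assert chao1([1, 1, 2]) == pytest.approx(3.5)


def test_chao1_at_least_sobs():
    rng = np.random.default_rng(0)
    for _ in range(50):
        counts = rng.integers(0, 5, size=20)
        if counts.sum() == 0:
            continue
        assert chao1(counts) >= (counts > 0).sum()


# ---------------------------------------------------------------------------
# Faith PD
# ---------------------------------------------------------------------------

def test_pd_all_tips_total_length():
    tree = _tree("((a:1,b:2):0.5,(c:3,d:4):0.25):0;")
    features = ["a", "b", "c", "d"]
    total = 1 + 2 + 0.5 + 3 + 4 + 0.25
    assert faith_pd([1, 1, 1, 1], tree, features) == pytest.approx(total)


def test_pd_single_tip_path_to_root():
    tree = _tree("((a:1,b:2):0.5,(c:3,d:4):0.25):0;")
    features = ["a", "b", "c", "d"]
    assert faith_pd([1, 0, 0, 0], tree, features) == pytest.approx(1.5)


def test_pd_hand_drawn_three_tips():
    tree = _tree("((a:1.0,b:2.0):0.5,c:3.0):0;")
    features = ["a", "b", "c"]
    # tips a and c: branches a(1.0), internal(0.5), c(3.0)
    assert faith_pd([1, 0, 1], tree, features) == pytest.approx(4.5)


def test_pd_missing_tip_is_input_error():
    tree = _tree("(a:1,b:1):0;")
    with pytest.raises(ValueError, match="zzz"):
        faith_pd([1, 1], tree, ["a", "zzz"])


# ---------------------------------------------------------------------------
# beta distances: brute-force branch oracle
# ---------------------------------------------------------------------------

TOY_NEWICK = "((a:1.0,b:2.0):0.5,(c:0.7,d:1.3):0.9):0;"
TOY_FEATURES = ["a", "b", "c", "d"]
# explicit branch decomposition of the toy tree: (length, tips below)
TOY_BRANCHES = [
    (1.0, {"a"}), (2.0, {"b"}), (0.5, {"a", "b"}),
    (0.7, {"c"}), (1.3, {"d"}), (0.9, {"c", "d"}),
]


def _oracle_unweighted(x, y):
    in_x = {f for f, v in zip(TOY_FEATURES, x) if v > 0}
    in_y = {f for f, v in zip(TOY_FEATURES, y) if v > 0}
    unique = sum(l for l, tips in TOY_BRANCHES
                 if bool(tips & in_x) != bool(tips & in_y))
    either = sum(l for l, tips in TOY_BRANCHES
                 if (tips & in_x) or (tips & in_y))
    return unique / either


def _oracle_weighted(x, y):
    px = np.asarray(x, float) / sum(x)
    py = np.asarray(y, float) / sum(y)
    num = den = 0.0
    for l, tips in TOY_BRANCHES:
        pa = sum(px[TOY_FEATURES.index(f)] for f in tips)
        pb = sum(py[TOY_FEATURES.index(f)] for f in tips)
        num += l * abs(pa - pb)
        den += l * (pa + pb)
    return num / den


@pytest.mark.parametrize("x,y", [
    ([5, 0, 3, 1], [0, 2, 3, 0]),
    ([1, 1, 1, 1], [4, 3, 2, 1]),
    ([10, 0, 0, 0], [0, 0, 0, 7]),
])
def test_all_four_distances_match_oracles(x, y):
    tree = _tree(TOY_NEWICK)
    bray = sum(abs(a - b) for a, b in zip(x, y)) / sum(a + b for a, b in zip(x, y))
    ax = {f for f, v in zip(TOY_FEATURES, x) if v > 0}
    ay = {f for f, v in zip(TOY_FEATURES, y) if v > 0}
    jac = 1 - len(ax & ay) / len(ax | ay)
    assert beta_distance(x, y, "bray_curtis") == pytest.approx(bray, abs=1e-8)
    assert beta_distance(x, y, "jaccard") == pytest.approx(jac, abs=1e-8)
    assert beta_distance(x, y, "unweighted_unifrac", tree, TOY_FEATURES) == \
        pytest.approx(_oracle_unweighted(x, y), abs=1e-8)
    assert beta_distance(x, y, "weighted_unifrac", tree, TOY_FEATURES) == \
        pytest.approx(_oracle_weighted(x, y), abs=1e-8)


@pytest.mark.parametrize("kind", ["bray_curtis", "jaccard",
                                  "unweighted_unifrac", "weighted_unifrac"])
def test_identical_columns_distance_zero(kind):
    tree = _tree(TOY_NEWICK)
    x = [3, 1, 0, 5]
    assert beta_distance(x, x, kind, tree, TOY_FEATURES) == 0.0


def test_disjoint_presence_star_tree_distance_one():
    star = _tree("(a:1,b:1,c:1,d:1):0;")
    x, y = [1, 1, 0, 0], [0, 0, 1, 1]
    assert beta_distance(x, y, "jaccard") == 1.0
    assert beta_distance(x, y, "unweighted_unifrac", star, TOY_FEATURES) == 1.0


def test_weighted_unifrac_scale_invariant():
    tree = _tree(TOY_NEWICK)
    x, y = [5, 1, 3, 1], [2, 2, 0, 4]
    d1 = beta_distance(x, y, "weighted_unifrac", tree, TOY_FEATURES)
    d2 = beta_distance([17 * v for v in x], y, "weighted_unifrac", tree,
                       TOY_FEATURES)
    assert d1 == pytest.approx(d2, abs=1e-12)


def test_both_empty_flagged():
    with pytest.raises(ValueError, match="empty"):
        beta_distance([0, 0], [0, 0], "bray_curtis")


def test_distance_matrix_valid_on_random_tables():
    rng = np.random.default_rng(1)
    table = FeatureTable([f"f{i}" for i in range(8)],
                         [f"s{j}" for j in range(6)],
                         rng.integers(0, 30, size=(8, 6)) + 1, DNA)
    for kind in ("bray_curtis", "jaccard"):
        dm = distance_matrix(table, kind)
        assert dm.violations() == []


def test_jaccard_triangle_inequality_random():
    rng = np.random.default_rng(2)
    for _ in range(30):
        cols = (rng.random((10, 3)) < 0.5).astype(int)
        cols[0] = 1  # avoid empty samples
        d01 = beta_distance(cols[:, 0], cols[:, 1], "jaccard")
        d12 = beta_distance(cols[:, 1], cols[:, 2], "jaccard")
        d02 = beta_distance(cols[:, 0], cols[:, 2], "jaccard")
        assert d02 <= d01 + d12 + 1e-12


def test_unweighted_unifrac_triangle_inequality_random():
    rng = np.random.default_rng(3)
    tree = _tree(TOY_NEWICK)
    bi = BranchIndex.build(tree, TOY_FEATURES)
    for _ in range(30):
        cols = (rng.random((4, 3)) < 0.6).astype(int)
        cols[0] = 1
        d = [beta_distance(cols[:, i], cols[:, j], "unweighted_unifrac",
                           feature_ids=TOY_FEATURES, branch_index=bi)
             for i, j in ((0, 1), (1, 2), (0, 2))]
        assert d[2] <= d[0] + d[1] + 1e-12


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

def test_pcoa_reproduces_euclidean_distances():
    rng = np.random.default_rng(4)
    points = rng.normal(size=(7, 2))
    diff = points[:, None, :] - points[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=2))
    result = pcoa(DistanceMatrix([f"s{i}" for i in range(7)], d))
    coords = result.coordinates[:, :2]
    diff2 = coords[:, None, :] - coords[None, :, :]
    d2 = np.sqrt((diff2 ** 2).sum(axis=2))
    assert np.abs(d - d2).max() < 1e-8


def test_pcoa_two_samples_closed_form():
    result = pcoa(DistanceMatrix(["a", "b"], np.array([[0.0, 2.0], [2.0, 0.0]])))
    assert result.coordinates.shape == (2, 1)
    assert sorted(result.coordinates[:, 0]) == pytest.approx([-1.0, 1.0])


def test_pcoa_eigenvalues_non_increasing(default_bundle):
    bundle, _ = default_bundle
    samples = bundle.metadata.group_samples("HL-Lab")
    dm = distance_matrix(bundle.table_dna.subset_samples(samples),
                         "bray_curtis")
    result = pcoa(dm)
    assert (np.diff(result.eigenvalues) <= 1e-9).all()
    assert result.coordinates.shape[1] == (result.eigenvalues > 1e-10).sum()


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def test_permanova_one_sample_per_group_r2_one():
    rng = np.random.default_rng(5)
    pts = rng.normal(size=(4, 2))
    d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
    dm = DistanceMatrix(["a", "b", "c", "d"], d)
    res = permanova(dm, {"g": ["w", "x", "y", "z"]}, nperm=49, seed=0)
    assert res.terms[0].r_squared == pytest.approx(1.0, abs=1e-10)
    assert res.residual_ss == pytest.approx(0.0, abs=1e-10)


def test_permanova_single_factor_matches_bruteforce_ss():
    # SS_total = sum d^2 / N; SS_within = sum_g sum_{i<j in g} d^2 / n_g
    rng = np.random.default_rng(6)
    pts = rng.normal(size=(6, 3))
    d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
    labels = np.array(["A", "A", "A", "B", "B", "B"])
    dm = DistanceMatrix([f"s{i}" for i in range(6)], d)
    res = permanova(dm, {"group": labels}, nperm=49, seed=0)

    d2 = d ** 2
    n = 6
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in ("A", "B"):
        idx = np.where(labels == g)[0]
        ss_within += d2[np.ix_(idx, idx)][np.triu_indices(len(idx), 1)].sum() \
            / len(idx)
    ss_between = ss_total - ss_within
    assert res.total_ss == pytest.approx(ss_total, abs=1e-10)
    assert res.terms[0].sum_of_squares == pytest.approx(ss_between, abs=1e-10)
    assert res.residual_ss == pytest.approx(ss_within, abs=1e-10)


def test_permanova_r2_sums_to_one():
    rng = np.random.default_rng(7)
    pts = rng.normal(size=(12, 3))
    d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
    dm = DistanceMatrix([f"s{i}" for i in range(12)], d)
    terms = {"f1": list("AABBABABABAB"), "f2": list("XYXYXXYYXYXY")}
    res = permanova(dm, terms, nperm=49, seed=1)
    total_r2 = sum(t.r_squared for t in res.terms) + res.residual_ss / res.total_ss
    assert total_r2 == pytest.approx(1.0, abs=1e-10)


def test_permanova_detects_planted_group_effect(default_bundle):
    bundle, _ = default_bundle
    samples = (bundle.metadata.group_samples("wild")[:15]
               + bundle.metadata.group_samples("HL-Lab")[:15])
    dm = distance_matrix(bundle.table_dna.subset_samples(samples),
                         "bray_curtis")
    labels = bundle.metadata.frame.loc[samples, "group"].to_numpy()
    res = permanova(dm, {"group": labels}, nperm=199, seed=2)
    assert res.terms[0].p_value < 0.05


def test_permanova_invalid_nperm():
    dm = DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]))
    with pytest.raises(ValueError, match="nperm"):
        permanova(dm, {"g": ["x", "y"]}, nperm=0, seed=0)
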