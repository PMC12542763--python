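"""Diversity statistics against closed forms and independent implementations."""

import io

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity
from skbio.stats.distance import permanova as skbio_permanova
from skbio.stats.distance import permdisp as skbio_permdisp

from holomics import diversity
from holomics.simulate import SimulationConfig, TaxaSpec, simulate_taxa_counts, _random_rooted_tree


def frame(arr, samples=None):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"t{i}" for i in range(arr.shape[0])],
        columns=samples or [f"s{j}" for j in range(arr.shape[1])],
    )


# ------------------------------------------------------------- normalization

def test_normalize_min_depth_examples():
    counts = frame([[60, 120], [40, 80]])
    norm = diversity.normalize_min_depth(counts)
    assert norm.sum(axis=0).tolist() == [100.0, 100.0]
    assert (norm["s1"] == counts["s1"] / 2).all()
    equal = frame([[10, 10], [5, 5]])
    pd.testing.assert_frame_equal(diversity.normalize_min_depth(equal), equal.astype(float))


def test_normalize_min_depth_conserves_min_depth(rng):
    counts = frame(rng.integers(0, 500, (30, 6)) + 1)
    norm = diversity.normalize_min_depth(counts)
    assert np.allclose(norm.sum(axis=0), counts.sum(axis=0).min(), atol=1e-9)


def test_rarefy_exact_depth_and_composition():
    counts = frame([[10], [0]])
    out = diversity.rarefy(counts, 5, seed=1)
    assert out["s0"].tolist() == [5, 0]
    same = diversity.rarefy(counts, 10, seed=1)
    assert same["s0"].tolist() == [10, 0]


def test_rarefy_mean_matches_hypergeometric(rng):
    col = frame([[60], [30], [10]])
    depth = 50
    sims = np.stack([
        diversity.rarefy(col, depth, seed=s)["s0"].to_numpy() for s in range(400)
    ])
    expected = depth * np.array([0.6, 0.3, 0.1])
    assert np.allclose(sims.mean(axis=0), expected, atol=0.5)


def test_rarefy_drops_shallow_samples():
    counts = frame([[10, 3], [5, 1]])
    with pytest.warns(UserWarning, match="dropped"):
        out = diversity.rarefy(counts, 10, seed=0)
    assert list(out.columns) == ["s0"]


# ------------------------------------------------------------- alpha

def test_alpha_closed_forms():
    uniform = frame([[25], [25], [25], [25]])
    alpha = diversity.alpha_diversity(uniform)
    assert alpha.loc["s0", "observed"] == 4
    assert alpha.loc["s0", "shannon"] == pytest.approx(np.log(4), abs=1e-9)
    assert alpha.loc["s0", "inv_simpson"] == pytest.approx(4.0, abs=1e-9)

    skew = frame([[50], [25], [25]])  # p = (0.5, 0.25, 0.25)
    alpha = diversity.alpha_diversity(skew)
    assert alpha.loc["s0", "shannon"] == pytest.approx(1.0397208, abs=1e-6)
    assert alpha.loc["s0", "inv_simpson"] == pytest.approx(8 / 3, abs=1e-9)

    single = frame([[100], [0]])
    alpha = diversity.alpha_diversity(single)
    assert alpha.loc["s0", "shannon"] == 0.0
    assert alpha.loc["s0", "inv_simpson"] == 1.0


# ------------------------------------------------------------- bray-curtis

def test_bray_curtis_examples():
    # u=(1,2,0), v=(2,1,0), w=(0,0,7): BC(u,v) = 2/6, disjoint supports give 1
    counts = frame([[1, 2, 0], [2, 1, 0], [0, 0, 7]], samples=["u", "v", "w"])
    d = diversity.bray_curtis(counts)
    assert d.loc["u", "v"] == pytest.approx(2 / 6, abs=1e-12)
    assert d.loc["u", "w"] == 1.0  # disjoint supports
    assert d.loc["u", "u"] == 0.0
    assert (d.to_numpy() <= 1).all() and (d.to_numpy() >= 0).all()


def test_bray_curtis_identical_columns_zero():
    counts = frame([[3, 3], [7, 7]])
    assert diversity.bray_curtis(counts).loc["s0", "s1"] == 0.0


# ------------------------------------------------------------- weighted unifrac

def test_weighted_unifrac_star_tree_by_hand():
    nwk = "(t0:1,t1:1,t2:1);"
    counts = frame([[10, 0], [0, 5], [0, 0]])
    d = diversity.weighted_unifrac(counts, nwk)
    # all mass moves from leaf t0 (branch 1) to leaf t1 (branch 1): 1*1 + 1*1 = 2
    assert d.loc["s0", "s1"] == pytest.approx(2.0, abs=1e-12)
    assert d.loc["s0", "s0"] == 0.0


def test_weighted_unifrac_matches_skbio_on_random_trees(rng):
    for trial in range(20):
        taxa = [f"t{i}" for i in range(8)]
        nwk = _random_rooted_tree(taxa, rng)
        counts = frame(rng.integers(0, 50, (8, 4)) + (rng.random((8, 4)) < 0.2), )
        counts.index = taxa
        counts = counts.astype(int)
        counts.iloc[0] += 1  # avoid all-zero samples
        mine = diversity.weighted_unifrac(counts, nwk)
        ref = beta_diversity(
            "weighted_unifrac",
            counts.T.to_numpy(),
            ids=list(counts.columns),
            tree=TreeNode.read(io.StringIO(nwk)),
            taxa=taxa,
        )
        assert np.allclose(mine.to_numpy(), ref.data, atol=1e-9)
        mine_norm = diversity.weighted_unifrac(counts, nwk, normalized=True)
        ref_norm = beta_diversity(
            "weighted_unifrac", counts.T.to_numpy(), ids=list(counts.columns),
            tree=TreeNode.read(io.StringIO(nwk)), taxa=taxa, normalized=True,
        )
        assert np.allclose(mine_norm.to_numpy(), ref_norm.data, atol=1e-9)


def test_weighted_unifrac_missing_taxon_error():
    with pytest.raises(ValueError, match="missing"):
        diversity.weighted_unifrac(frame([[1], [1]]), "(t0:1,x:1);")


def test_distance_matrix_invariants(rng):
    cfg = SimulationConfig(taxa_spec=TaxaSpec(n_taxa=20), seed=31)
    taxa, nwk = simulate_taxa_counts(cfg)
    for d in (diversity.bray_curtis(taxa.counts),
              diversity.weighted_unifrac(taxa.counts, nwk)):
        x = d.to_numpy()
        assert np.allclose(x, x.T)
        assert np.allclose(np.diag(x), 0)
        assert (x >= 0).all()
    # BC on min-depth-normalized counts equals BC on relative abundances
    rel = taxa.counts / taxa.counts.sum(axis=0)
    norm = diversity.normalize_min_depth(taxa.counts)
    assert np.allclose(
        diversity.bray_curtis(norm).to_numpy(),
        diversity.bray_curtis(rel).to_numpy(),
        atol=1e-12,
    )


# ------------------------------------------------------------- permanova

def test_permanova_statistic_matches_skbio():
    cfg = SimulationConfig(seed=41)
    taxa, _ = simulate_taxa_counts(cfg)
    bc = diversity.bray_curtis(diversity.normalize_min_depth(taxa.counts))
    mine = diversity.permanova(bc, taxa.groups, 99, seed=1)
    ref = skbio_permanova(
        DistanceMatrix(bc.to_numpy(), ids=list(bc.index)),
        grouping=list(taxa.groups),
        permutations=99,
    )
    assert mine.statistic == pytest.approx(ref["test statistic"], rel=1e-12)


def test_permanova_separated_clusters_minimal_p():
    rng = np.random.default_rng(2)
    a = rng.normal(0, 0.1, (10, 3))
    b = rng.normal(10, 0.1, (10, 3))
    pts = np.vstack([a, b])
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    ids = [f"s{i}" for i in range(20)]
    dist = pd.DataFrame(d, index=ids, columns=ids)
    groups = ["A"] * 10 + ["B"] * 10
    res = diversity.permanova(dist, groups, 999, seed=3)
    assert res.p == pytest.approx(1 / 1000)


def test_permanova_equidistant_points_p_near_one():
    n = 8
    d = np.ones((n, n)) - np.eye(n)
    dist = pd.DataFrame(d, index=[f"s{i}" for i in range(n)], columns=[f"s{i}" for i in range(n)])
    res = diversity.permanova(dist, ["A"] * 4 + ["B"] * 4, 499, seed=1)
    assert res.p > 0.95


def test_permanova_requires_two_groups():
    d = pd.DataFrame(np.zeros((3, 3)), index=list("abc"), columns=list("abc"))
    with pytest.raises(ValueError):
        diversity.permanova(d, ["A", "A", "A"], 99, seed=0)


# ------------------------------------------------------------- permdisp

def test_permdisp_statistic_close_to_skbio():
    cfg = SimulationConfig(seed=43)
    taxa, _ = simulate_taxa_counts(cfg)
    bc = diversity.bray_curtis(diversity.normalize_min_depth(taxa.counts))
    mine = diversity.permdisp(bc, taxa.groups, 99, seed=1)
    ref = skbio_permdisp(
        DistanceMatrix(bc.to_numpy(), ids=list(bc.index)),
        grouping=list(taxa.groups),
        permutations=99,
        test="centroid",
    )
    assert mine.statistic == pytest.approx(ref["test statistic"], rel=1e-6)


def test_permdisp_detects_unequal_dispersion():
    rng = np.random.default_rng(8)
    tight = rng.normal(0, 0.01, (10, 2))
    wide = rng.normal(0, 5.0, (10, 2))
    pts = np.vstack([tight, wide])
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    ids = [f"s{i}" for i in range(20)]
    dist = pd.DataFrame(d, index=ids, columns=ids)
    res = diversity.permdisp(dist, ["A"] * 10 + ["B"] * 10, 999, seed=2)
    assert res.p < 0.01


def test_permdisp_duplicate_group_f_near_zero():
    rng = np.random.default_rng(9)
    pts = rng.normal(0, 1, (6, 2))
    both = np.vstack([pts, pts + 100])  # same shape, translated: equal dispersion
    d = np.linalg.norm(both[:, None] - both[None, :], axis=2)
    ids = [f"s{i}" for i in range(12)]
    dist = pd.DataFrame(d, index=ids, columns=ids)
    res = diversity.permdisp(dist, ["A"] * 6 + ["B"] * 6, 499, seed=4)
    assert res.statistic == pytest.approx(0.0, abs=1e-18)
    assert res.p > 0.9
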