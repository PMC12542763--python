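"""Block scalings, cross-omics Spearman, network thresholds, percolation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from holomics import integration
from holomics.integration import OmicsBlock


def block(arr, kind, samples=None, features=None):
    arr = np.asarray(arr, dtype=float)
    return OmicsBlock(
        pd.DataFrame(
            arr,
            index=features or [f"{kind[:3]}{i}" for i in range(arr.shape[0])],
            columns=samples or [f"s{j}" for j in range(arr.shape[1])],
        ),
        kind,
    )


# ------------------------------------------------------------- scalings

def test_scale_metals_minmax_rows():
    b = scale = integration.scale_metals(block([[2, 6, 10]], "metallome"))
    assert scale.data.iloc[0].tolist() == [0.0, 0.5, 1.0]
    already = integration.scale_metals(block([[0, 0.5, 1]], "metallome"))
    assert already.data.iloc[0].tolist() == [0.0, 0.5, 1.0]


def test_scale_metabolites_sqrt_then_pareto():
    out = integration.scale_metabolites(block([[0, 4]], "metabolome"))
    # sqrt -> (0, 2); mean 1, sd sqrt(2); Pareto divides by sd**0.5
    expected = (np.array([0.0, 2.0]) - 1.0) / np.sqrt(np.sqrt(2))
    assert np.allclose(out.data.iloc[0], expected)
    assert np.allclose(expected, [-0.8409, 0.8409], atol=1e-4)


def test_scale_metabolites_centers_rows(rng):
    b = block(rng.uniform(0, 100, (10, 6)), "metabolome")
    out = integration.scale_metabolites(b)
    assert np.allclose(out.data.mean(axis=1), 0.0, atol=1e-9)


def test_clr_identities(rng):
    uniform = integration.clr_transform(block([[5], [5], [5]], "microbiome"))
    assert np.allclose(uniform.data.to_numpy(), 0.0)
    b = block(rng.integers(0, 200, (12, 5)), "microbiome")
    out = integration.clr_transform(b)
    assert np.allclose(out.data.sum(axis=0), 0.0, atol=1e-9)
    # exact scale invariance when the pseudocount is scaled with the column
    c = 7.0
    scaled = integration.clr_transform(
        block(b.data.to_numpy() * c, "microbiome"), pseudocount=c
    )
    assert np.allclose(out.data.to_numpy(), scaled.data.to_numpy(), atol=1e-12)


def test_drop_zero_sd_matches_variance_scan(rng):
    x = rng.normal(0, 1, (15, 6))
    x[3] = 2.5
    x[9] = 0.0
    b = block(x, "metabolome")
    (out,) = integration.drop_zero_sd([b])
    expected = [i for i in range(15) if np.std(x[i]) > 0]
    assert list(out.data.index) == [f"met{i}" for i in expected]


def test_scaling_permutation_equivariance(rng):
    x = rng.uniform(1, 50, (6, 8))
    cols = [f"s{j}" for j in range(8)]
    perm = rng.permutation(8)
    for fn in (integration.scale_metals,
               integration.scale_metabolites,
               integration.clr_transform):
        kind = "metallome" if fn is integration.scale_metals else (
            "metabolome" if fn is integration.scale_metabolites else "microbiome")
        out = fn(block(x, kind, samples=cols))
        out_perm = fn(block(x[:, perm], kind, samples=[cols[p] for p in perm]))
        assert np.allclose(out.data.to_numpy()[:, perm], out_perm.data.to_numpy())


# ------------------------------------------------------------- spearman

def test_cross_block_spearman_matches_scipy_with_ties(rng):
    a = block(np.round(rng.uniform(0, 10, (4, 9))), "metallome")
    b = block(np.round(rng.uniform(0, 10, (5, 9))), "metabolome")
    edges = integration.cross_block_spearman([a, b])
    assert len(edges) == 20
    for row in edges.itertuples(index=False):
        ref = spearmanr(
            a.data.loc[row.feature_a], b.data.loc[row.feature_b]
        ).statistic
        assert row.rho == pytest.approx(ref, abs=1e-12)


def test_spearman_monotone_transform_invariance():
    x = np.array([[1.0, 5.0, 2.0, 9.0, 4.0]])
    a = block(x, "metallome")
    b = block(np.exp(x), "metabolome")  # strictly monotone transform
    edges = integration.cross_block_spearman([a, b])
    assert edges["rho"].iloc[0] == pytest.approx(1.0)


def test_constant_feature_pairs_skipped():
    a = block([[1, 1, 1, 1]], "metallome")
    b = block([[1, 2, 3, 4]], "metabolome")
    edges = integration.cross_block_spearman([a, b])
    assert edges.empty


def test_mismatched_samples_rejected():
    a = block([[1, 2, 3]], "metallome")
    b = block([[1, 2, 3]], "metabolome", samples=["x", "y", "z"])
    with pytest.raises(ValueError, match="share one identical"):
        integration.cross_block_spearman([a, b])


# ------------------------------------------------------------- network

def edge_frame(rows):
    return pd.DataFrame(
        rows, columns=["block_a", "feature_a", "block_b", "feature_b", "rho"]
    )


def test_build_network_threshold_boundaries():
    edges = edge_frame([
        ("metallome", "Mn", "metabolome", "m1", 0.996),
        ("metallome", "Mn", "metabolome", "m2", 0.9949),
        ("metallome", "Ni", "metabolome", "m3", -0.985),
        ("metallome", "Ni", "metabolome", "m4", -0.992),
    ])
    g = integration.build_network(edges, 0.995, 0.990)
    kept = {(u[1], v[1]) for u, v in g.edges}
    assert kept == {("Mn", "m1"), ("Ni", "m4")}
    assert g.edges[("metallome", "Ni"), ("metabolome", "m4")]["sign"] == -1


def test_build_network_retained_equals_linear_scan(rng):
    rhos = rng.uniform(-1, 1, 400)
    edges = edge_frame([
        ("metallome", f"a{i}", "metabolome", f"b{i}", r) for i, r in enumerate(rhos)
    ])
    g = integration.build_network(edges, 0.9, 0.8)
    expected = {i for i, r in enumerate(rhos) if r >= 0.9 or r <= -0.8}
    assert {int(u[1][1:]) for u, v in g.edges} == expected


def test_empty_network_not_an_error():
    g = integration.build_network(edge_frame([]), 0.995, 0.99)
    assert g.number_of_edges() == 0


# ------------------------------------------------------------- percolation

def union_find_components(edges):
    parent = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    comps = {}
    for node in parent:
        comps.setdefault(find(node), set()).add(node)
    return sorted((len(c) for c in comps.values()), reverse=True)


def two_clique_edges():
    """Two disjoint high-|rho| cliques over weak background: a planted gap."""
    rng = np.random.default_rng(12)
    rows = []
    cliq1 = [("metallome", f"A{i}") for i in range(4)]
    cliq2 = [("microbiome", f"B{i}") for i in range(4)]
    for group in (cliq1, cliq2):
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                rows.append((*group[i], *group[j], rng.uniform(0.93, 0.99)))
    nodes = cliq1 + cliq2
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            u, v = nodes[i], nodes[j]
            if (u in cliq1) == (v in cliq1):
                continue
            rows.append((*u, *v, rng.uniform(0.05, 0.6)))  # weak background
    return edge_frame(rows)


def test_percolation_suggestion_brackets_planted_gap():
    edges = two_clique_edges()
    grid = [round(0.05 * k, 2) for k in range(1, 20)]
    scan = integration.percolation_scan(edges, grid)
    within = edges[edges["block_a"] == edges["block_b"]]["rho"]   # clique edges
    across = edges[edges["block_a"] != edges["block_b"]]["rho"]   # background
    assert across.max() < scan.suggested_positive <= within.min()


def test_percolation_component_sizes_match_union_find():
    edges = two_clique_edges()
    grid = [0.3, 0.7, 0.95]
    scan = integration.percolation_scan(edges, grid)
    for t in grid:
        sub = edges[(edges["rho"] > 0) & (edges["rho"].abs() >= t)]
        expected = union_find_components(
            [((r.block_a, r.feature_a), (r.block_b, r.feature_b))
             for r in sub.itertuples(index=False)]
        )
        row = scan.table[(scan.table.threshold == t) & (scan.table.sign == "positive")]
        got = [int(s) for s in row["sizes"].iloc[0].split(",")] if row["sizes"].iloc[0] else []
        assert got == expected


def test_percolation_all_perfect_edges_warns():
    edges = edge_frame([
        ("metallome", "a", "metabolome", "b", 1.0),
        ("metallome", "a", "metabolome", "c", 1.0),
    ])
    scan = integration.percolation_scan(edges, [0.5, 0.9, 1.0])
    assert scan.suggested_positive == 1.0
    assert any("positive" in w for w in scan.warnings)
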