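"""Comparative metabolomics on the filtered feature table.

Replicate averaging, per-feature min-max normalization for heatmaps, UPGMA
hierarchical clustering, nonmetric multidimensional scaling (Kruskal stress-1
via SMACOF with monotone regression, multiple random restarts), volcano
statistics (homoscedastic t-tests on log2(x+1) intensities by default), and
Benjamini-Hochberg FDR adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.manifold import MDS
from statsmodels.stats.multitest import multipletests

from .tables import FeatureTable


def average_replicates(table: FeatureTable) -> FeatureTable:
    """Collapse technical replicates: one column per biological sample (mean).

    Blank columns are averaged into a single ``blank`` column when present.
    """
    rep_map = table.replicate_map()
    if not rep_map and not len(table.blank_columns):
        raise ValueError("no replicate mapping available")
    cols = {}
    meta_rows = {}
    for s, reps in rep_map.items():
        cols[s] = table.intensities[reps].mean(axis=1)
        meta_rows[s] = {
            "sample": s,
            "group": table.samples.loc[reps[0], "group"],
            "replicate": 1,
        }
    blanks = table.blank_columns
    if len(blanks):
        cols["blank"] = table.intensities[blanks].mean(axis=1)
        meta_rows["blank"] = {"sample": "blank", "group": "blank", "replicate": 1}
    avg = pd.DataFrame(cols, index=table.feature_ids)
    meta = pd.DataFrame(meta_rows).T
    meta.index.name = "column"
    return FeatureTable(avg, table.mz, table.rt, meta)


def minmax_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-feature row scaling to [0, 1]; constant rows map to all-zero."""
    x = matrix.to_numpy(dtype=float)
    lo = x.min(axis=1, keepdims=True)
    hi = x.max(axis=1, keepdims=True)
    span = hi - lo
    out = np.where(span > 0, (x - lo) / np.where(span > 0, span, 1.0), 0.0)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def hierarchical_cluster(dist: pd.DataFrame) -> np.ndarray:
    """UPGMA (average linkage) merge tree on a distance matrix.

    Returns a scipy linkage matrix; leaf order follows ``dist.index``.
    """
    condensed = squareform(dist.to_numpy(dtype=float), checks=True)
    return linkage(condensed, method="average")


def linkage_to_newick(link: np.ndarray, labels) -> str:
    """Render a scipy linkage matrix as a rooted newick string with heights."""
    labels = list(labels)
    n = len(labels)
    nodes = {i: (labels[i], 0.0) for i in range(n)}
    for i, (a, b, height, _) in enumerate(link):
        (na, ha), (nb, hb) = nodes.pop(int(a)), nodes.pop(int(b))
        h = height / 2.0  # ultrametric heights
        nodes[n + i] = (f"({na}:{h - ha:.6g},{nb}:{h - hb:.6g})", h)
    (tree, _), = nodes.values()
    return tree + ";"


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x k, centered at the origin
    stress: float              # Kruskal stress-1
    seed: int
    n_restarts: int


def nmds(
    dist: pd.DataFrame, k: int = 2, seed: int = 0, n_restarts: int = 20,
    max_iter: int = 300,
) -> OrdinationResult:
    """Nonmetric MDS minimizing Kruskal stress-1, best of ``n_restarts``."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if dist.shape[0] < k + 1:
        raise ValueError("need at least k+1 samples")
    model = MDS(
        n_components=k,
        metric_mds=False,
        metric="precomputed",
        init="random",
        n_init=n_restarts,
        max_iter=max_iter,
        random_state=seed,
        normalized_stress=True,
        eps=1e-9,
    )
    coords = model.fit_transform(dist.to_numpy(dtype=float))
    coords = coords - coords.mean(axis=0, keepdims=True)
    frame = pd.DataFrame(coords, index=dist.index, columns=[f"dim{i+1}" for i in range(k)])
    return OrdinationResult(frame, float(model.stress_), seed, n_restarts)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in original order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def volcano(
    table: FeatureTable, group_a: str = "host", group_b: str = "water",
    log_transform: bool = True,
) -> pd.DataFrame:
    """Per-feature differential statistics between two sample groups.

    Technical replicates are averaged first; intensities are log2(x+1)
    transformed by default before a two-tailed homoscedastic t-test.  Returns
    a DataFrame with log2 fold change (group_a over group_b, +1 offset on the
    linear scale), t statistic, raw p, BH-adjusted q, and a degenerate flag
    for zero-variance features.
    """
    avg = average_replicates(table)
    groups = avg.sample_groups()
    cols_a = [s for s, g in groups.items() if g == group_a]
    cols_b = [s for s, g in groups.items() if g == group_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need >= 2 samples per group")
    a_lin = avg.intensities[cols_a].to_numpy(dtype=float)
    b_lin = avg.intensities[cols_b].to_numpy(dtype=float)
    a = np.log2(a_lin + 1) if log_transform else a_lin
    b = np.log2(b_lin + 1) if log_transform else b_lin

    log2fc = np.log2((a_lin.mean(axis=1) + 1) / (b_lin.mean(axis=1) + 1))
    t = np.full(len(a), np.nan)
    p = np.ones(len(a))
    degenerate = np.zeros(len(a), dtype=bool)
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    zero_var = (var_a == 0) & (var_b == 0)
    testable = ~zero_var
    if testable.any():
        res = stats.ttest_ind(a[testable], b[testable], axis=1, equal_var=True)
        t[testable] = res.statistic
        p[testable] = res.pvalue
    equal_means = zero_var & np.isclose(a.mean(axis=1), b.mean(axis=1))
    p[zero_var] = np.where(equal_means[zero_var], 1.0, 0.0)
    degenerate[zero_var & ~equal_means] = True

    q = bh_adjust(p)
    return pd.DataFrame(
        {"log2fc": log2fc, "t": t, "p": p, "q": q, "degenerate": degenerate},
        index=avg.feature_ids,
    )
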