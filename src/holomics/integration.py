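"""Cross-omics correlation networks on shared-sample blocks.

Each omics block (metallome, microbiome, metabolome) is scaled on its own
terms — metals min-max per feature, metabolites square-root then Pareto
(mean-centered, divided by the square root of the standard deviation), taxa
counts by centered log-ratio per sample — zero-variance features are pruned,
all cross-block feature pairs are Spearman-correlated, and edges surviving
sign-specific thresholds (defaults 0.995 positive / 0.990 negative) form the
network.  A percolation scan over a threshold grid records component-size
distributions and suggests the fragmentation point of the giant component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

BLOCK_KINDS = ("metallome", "microbiome", "metabolome")


@dataclass
class OmicsBlock:
    """One omics data matrix (features x shared samples)."""

    data: pd.DataFrame
    kind: str
    groups: pd.Series | None = None  # sample -> group label

    def __post_init__(self) -> None:
        if self.kind not in BLOCK_KINDS:
            raise ValueError(f"kind must be one of {BLOCK_KINDS}")

    @property
    def samples(self) -> pd.Index:
        return self.data.columns


def _check_shared_samples(blocks: list[OmicsBlock]) -> None:
    ref = blocks[0].samples
    for b in blocks[1:]:
        if not b.samples.equals(ref):
            raise ValueError("all blocks must share one identical ordered sample set")


# ----------------------------------------------------------------------
# block scalings
# ----------------------------------------------------------------------

def scale_metals(block: OmicsBlock) -> OmicsBlock:
    """Min-max scale each metal across its own maximum and minimum."""
    x = block.data.to_numpy(dtype=float)
    lo = x.min(axis=1, keepdims=True)
    hi = x.max(axis=1, keepdims=True)
    span = hi - lo
    out = np.where(span > 0, (x - lo) / np.where(span > 0, span, 1.0), 0.0)
    return OmicsBlock(pd.DataFrame(out, block.data.index, block.data.columns),
                      block.kind, block.groups)


def scale_metabolites(block: OmicsBlock) -> OmicsBlock:
    """Square-root transform then Pareto scale each feature row.

    Pareto scaling mean-centers and divides by the square root of the sample
    standard deviation (ddof=1).  Constant rows yield NaN and are removed by
    :func:`drop_zero_sd` downstream.
    """
    x = block.data.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("metabolite intensities must be >= 0")
    r = np.sqrt(x)
    sd = r.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (r - r.mean(axis=1, keepdims=True)) / np.sqrt(sd)
    return OmicsBlock(pd.DataFrame(out, block.data.index, block.data.columns),
                      block.kind, block.groups)


def clr_transform(block: OmicsBlock, pseudocount: float = 1.0) -> OmicsBlock:
    """Centered log-ratio per sample column: ln(x + pc) minus the column mean log."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    x = block.data.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be >= 0")
    logs = np.log(x + pseudocount)
    out = logs - logs.mean(axis=0, keepdims=True)
    return OmicsBlock(pd.DataFrame(out, block.data.index, block.data.columns),
                      block.kind, block.groups)


def drop_zero_sd(blocks: list[OmicsBlock]) -> list[OmicsBlock]:
    """Remove features with zero variance (or NaN scale) across shared samples."""
    out = []
    for b in blocks:
        x = b.data.to_numpy(dtype=float)
        sd = np.nanstd(x, axis=1)
        bad = (sd == 0) | np.isnan(x).any(axis=1)
        if bad.any():
            logger.info("%s: removed %d zero-variance features", b.kind, int(bad.sum()))
        out.append(OmicsBlock(b.data.loc[~bad], b.kind, b.groups))
    return out


def scale_blocks(
    metals: OmicsBlock, taxa: OmicsBlock, metabolites: OmicsBlock,
    pseudocount: float = 1.0,
) -> list[OmicsBlock]:
    """Apply each block's scaling and prune zero-variance features."""
    _check_shared_samples([metals, taxa, metabolites])
    return drop_zero_sd(
        [scale_metals(metals), clr_transform(taxa, pseudocount), scale_metabolites(metabolites)]
    )


# ----------------------------------------------------------------------
# correlation and network
# ----------------------------------------------------------------------

def cross_block_spearman(blocks: list[OmicsBlock]) -> pd.DataFrame:
    """Spearman rho for every cross-block feature pair (average ranks for ties).

    Returns a DataFrame with columns block_a, feature_a, block_b, feature_b,
    rho.  Constant vectors have undefined rank correlation; their pairs are
    skipped and logged.
    """
    _check_shared_samples(blocks)
    n = blocks[0].data.shape[1]
    if n < 3:
        raise ValueError("Spearman needs >= 3 shared samples")
    ranked = []
    for b in blocks:
        x = b.data.to_numpy(dtype=float)
        r = np.apply_along_axis(rankdata, 1, x) if x.size else x
        sd = r.std(axis=1) if x.size else np.array([])
        if (sd == 0).any():
            logger.info("%s: %d constant features skipped", b.kind, int((sd == 0).sum()))
        z = np.where(
            sd[:, None] > 0,
            (r - r.mean(axis=1, keepdims=True)) / np.where(sd[:, None] > 0, sd[:, None], 1.0),
            np.nan,
        )
        ranked.append(z)
    rows = []
    for i in range(len(blocks)):
        for j in range(i + 1, len(blocks)):
            rho = ranked[i] @ ranked[j].T / n
            ai = blocks[i].data.index
            aj = blocks[j].data.index
            ii, jj = np.nonzero(~np.isnan(rho))
            for a, b_ in zip(ii, jj):
                rows.append(
                    (blocks[i].kind, ai[a], blocks[j].kind, aj[b_], float(rho[a, b_]))
                )
    return pd.DataFrame(rows, columns=["block_a", "feature_a", "block_b", "feature_b", "rho"])


def build_network(
    edges: pd.DataFrame,
    pos_threshold: float = 0.995,
    neg_threshold: float = 0.990,
    node_shares: dict | None = None,
) -> nx.Graph:
    """Keep edges with rho >= pos_threshold or rho <= -neg_threshold.

    ``node_shares`` optionally maps (block, feature) -> per-group mean
    abundance share, stored as a node attribute (pie fractions).
    """
    if not 0 < pos_threshold <= 1 or not 0 < neg_threshold <= 1:
        raise ValueError("thresholds must lie in (0, 1]")
    g = nx.Graph()
    keep = edges[(edges["rho"] >= pos_threshold) | (edges["rho"] <= -neg_threshold)]
    for row in keep.itertuples(index=False):
        u = (row.block_a, row.feature_a)
        v = (row.block_b, row.feature_b)
        g.add_node(u, block=row.block_a)
        g.add_node(v, block=row.block_b)
        g.add_edge(u, v, rho=row.rho, sign=1 if row.rho > 0 else -1)
    if node_shares:
        for node in g.nodes:
            if node in node_shares:
                g.nodes[node]["group_share"] = node_shares[node]
    return g


def group_abundance_shares(blocks: list[OmicsBlock]) -> dict:
    """(block, feature) -> {group: share of the feature's total abundance}."""
    shares = {}
    for b in blocks:
        if b.groups is None:
            continue
        g = b.groups.loc[b.data.columns]
        totals = b.data.sum(axis=1)
        for grp in pd.unique(g):
            cols = b.data.columns[(g == grp).to_numpy()]
            part = b.data[cols].sum(axis=1)
            for fid in b.data.index:
                key = (b.kind, fid)
                denom = totals[fid]
                shares.setdefault(key, {})[grp] = (
                    float(part[fid] / denom) if denom else 0.0
                )
    return shares


@dataclass
class PercolationScan:
    table: pd.DataFrame          # threshold, sign, n_nodes, n_components, largest, sizes
    suggested_positive: float
    suggested_negative: float
    warnings: list = field(default_factory=list)


def percolation_scan(edges: pd.DataFrame, threshold_grid) -> PercolationScan:
    """Component-size scan over |rho| thresholds, per edge sign.

    The suggested threshold (per sign) is the smallest grid value at which the
    largest connected component holds at most half of the participating nodes
    (the fragmentation point of the giant component; at-most-half so that a
    split into two equal clusters counts as fragmented); if no grid value
    fragments the network, the top of the grid is suggested with a warning.
    """
    grid = sorted(float(t) for t in threshold_grid)
    if not grid or grid[0] <= 0 or grid[-1] > 1:
        raise ValueError("threshold grid must lie in (0, 1]")
    rows = []
    suggestions = {}
    warn = []
    for sign, sub in (("positive", edges[edges["rho"] > 0]),
                      ("negative", edges[edges["rho"] < 0])):
        suggestion = None
        for t in grid:
            keep = sub[sub["rho"].abs() >= t]
            g = nx.Graph()
            for row in keep.itertuples(index=False):
                g.add_edge((row.block_a, row.feature_a), (row.block_b, row.feature_b))
            sizes = sorted((len(c) for c in nx.connected_components(g)), reverse=True)
            n_nodes = g.number_of_nodes()
            largest = sizes[0] if sizes else 0
            rows.append(
                {"threshold": t, "sign": sign, "n_nodes": n_nodes,
                 "n_components": len(sizes), "largest": largest,
                 "sizes": ",".join(map(str, sizes))}
            )
            if suggestion is None and n_nodes and largest <= 0.5 * n_nodes:
                suggestion = t
        if suggestion is None:
            suggestion = grid[-1]
            warn.append(f"{sign}: no fragmentation on the grid; suggesting its top")
        suggestions[sign] = suggestion
    return PercolationScan(pd.DataFrame(rows), suggestions["positive"],
                           suggestions["negative"], warn)
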