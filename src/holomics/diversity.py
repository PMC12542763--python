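"""Microbial community diversity: depth normalization, alpha diversity,
Bray-Curtis and weighted UniFrac distances, PERMANOVA and PERMDISP.

All statistics are computed from first principles on a taxa x samples count
table.  Shannon entropy uses the natural logarithm.  Weighted UniFrac is the
raw (non-normalized) form by default,

    d(u, v) = sum over branches b of  l_b * |P_b(u) - P_b(v)|,

where P_b is the fraction of a sample's reads descending from branch b; the
normalized variant divides by sum_b l_b (P_b(u) + P_b(v)).  PERMANOVA uses
the pseudo-F from among/within partitioning of squared distances with free
label permutation; PERMDISP embeds the distances by principal coordinates and
permutes a one-way F on distances to group centroids.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode


@dataclass
class PermutationTestResult:
    statistic: float
    p: float
    n_permutations: int
    seed: int

    def __post_init__(self) -> None:
        lo = 1.0 / (self.n_permutations + 1)
        assert lo - 1e-12 <= self.p <= 1.0


# ----------------------------------------------------------------------
# normalization
# ----------------------------------------------------------------------

def normalize_min_depth(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample column to the minimum library size (fractional)."""
    sizes = counts.sum(axis=0)
    if (sizes <= 0).any():
        raise ValueError("all library sizes must be > 0")
    return counts * (sizes.min() / sizes)


def rarefy(counts: pd.DataFrame, depth: int, seed: int = 0) -> pd.DataFrame:
    """Subsample each column without replacement to exactly ``depth`` reads.

    Samples shallower than ``depth`` are dropped with a warning.
    """
    rng = np.random.default_rng(seed)
    keep = {}
    for s in counts.columns:
        col = counts[s].to_numpy(dtype=np.int64)
        total = int(col.sum())
        if total < depth:
            warnings.warn(f"sample {s} has {total} < {depth} reads; dropped", stacklevel=2)
            continue
        keep[s] = rng.multivariate_hypergeometric(col, depth)
    return pd.DataFrame(keep, index=counts.index)


# ----------------------------------------------------------------------
# alpha diversity
# ----------------------------------------------------------------------

def alpha_diversity(counts: pd.DataFrame) -> pd.DataFrame:
    """Observed richness, Shannon H (natural log), inverse Simpson, per sample."""
    out = {}
    for s in counts.columns:
        x = counts[s].to_numpy(dtype=float)
        total = x.sum()
        if total <= 0:
            raise ValueError(f"sample {s} has zero total count")
        p = x[x > 0] / total
        out[s] = {
            "observed": int((x > 0).sum()),
            "shannon": float(-(p * np.log(p)).sum()),
            "inv_simpson": float(1.0 / (p**2).sum()),
        }
    return pd.DataFrame(out).T[["observed", "shannon", "inv_simpson"]]


# ----------------------------------------------------------------------
# beta diversity
# ----------------------------------------------------------------------

def bray_curtis(counts: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity sum|u-v| / sum(u+v), samples x samples."""
    if counts.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    x = counts.to_numpy(dtype=float).T  # samples x taxa
    num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    den = (x[:, None, :] + x[None, :, :]).sum(axis=2)
    off = ~np.eye(len(x), dtype=bool)
    if (den[off] == 0).any():
        raise ValueError("Bray-Curtis undefined for a pair of all-zero samples")
    with np.errstate(invalid="ignore"):
        d = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=counts.columns, columns=counts.columns)


def _branch_matrix(tree: TreeNode, taxa: pd.Index) -> tuple[np.ndarray, np.ndarray]:
    """(branch lengths, branch x taxon descent indicator) for all non-root nodes."""
    tree = tree.copy()
    leaves = {leaf.name for leaf in tree.tips()}
    missing = [t for t in taxa if t not in leaves]
    if missing:
        raise ValueError(f"taxa missing from tree: {missing}")
    taxon_pos = {t: i for i, t in enumerate(taxa)}
    lengths = []
    desc_rows = []
    for node in tree.postorder(include_self=False):
        node._mask = np.zeros(len(taxa), dtype=bool)
        if node.is_tip():
            if node.name in taxon_pos:
                node._mask[taxon_pos[node.name]] = True
        else:
            for child in node.children:
                node._mask |= child._mask
        length = node.length if node.length is not None else 0.0
        if length < 0:
            raise ValueError("branch lengths must be >= 0")
        lengths.append(length)
        desc_rows.append(node._mask)
    return np.asarray(lengths, dtype=float), np.asarray(desc_rows, dtype=bool)


def weighted_unifrac(
    counts: pd.DataFrame, tree: TreeNode | str, normalized: bool = False
) -> pd.DataFrame:
    """Weighted UniFrac distance matrix over samples.

    ``tree`` may be a scikit-bio TreeNode or a newick string; every taxon in
    ``counts`` must be a leaf.  Raw form by default; set ``normalized=True``
    for the variant bounded by 1.
    """
    if isinstance(tree, str):
        tree = TreeNode.read(io.StringIO(tree))
    lengths, desc = _branch_matrix(tree, counts.index)
    x = counts.to_numpy(dtype=float)
    totals = x.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("all samples need positive total counts")
    props = x / totals  # taxa x samples
    branch_p = desc.astype(float) @ props  # branches x samples
    diff = np.abs(branch_p[:, :, None] - branch_p[:, None, :])
    d = np.einsum("b,bij->ij", lengths, diff)
    if normalized:
        both = branch_p[:, :, None] + branch_p[:, None, :]
        den = np.einsum("b,bij->ij", lengths, both)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(den > 0, d / np.where(den > 0, den, 1.0), 0.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=counts.columns, columns=counts.columns)


# ----------------------------------------------------------------------
# permutation tests
# ----------------------------------------------------------------------

def _group_indices(groups: pd.Series | list, ids) -> list[np.ndarray]:
    g = pd.Series(list(groups), index=ids) if not isinstance(groups, pd.Series) else groups
    g = g.loc[ids]
    return [np.flatnonzero((g == lvl).to_numpy()) for lvl in pd.unique(g)]


def _pseudo_f(d2: np.ndarray, idx_groups: list[np.ndarray]) -> float:
    n = d2.shape[0]
    k = len(idx_groups)
    ss_total = d2.sum() / (2 * n)
    ss_within = 0.0
    for idx in idx_groups:
        ss_within += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    ss_among = ss_total - ss_within
    return (ss_among / (k - 1)) / (ss_within / (n - k))


def permanova(
    dist: pd.DataFrame, groups, n_permutations: int = 999, seed: int = 0
) -> PermutationTestResult:
    """Permutational multivariate ANOVA on a distance matrix (pseudo-F).

    p = (1 + #{permuted F >= observed}) / (1 + n_permutations), with free
    permutation of sample labels.
    """
    ids = dist.index
    idx_groups = _group_indices(groups, ids)
    if len(idx_groups) < 2:
        raise ValueError("PERMANOVA needs >= 2 groups")
    if any(len(i) < 2 for i in idx_groups):
        raise ValueError("each group needs >= 2 samples")
    d2 = dist.to_numpy(dtype=float) ** 2
    n = d2.shape[0]
    sizes = [len(i) for i in idx_groups]
    f_obs = _pseudo_f(d2, idx_groups)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        start = 0
        perm_groups = []
        for size in sizes:
            perm_groups.append(perm[start : start + size])
            start += size
        if _pseudo_f(d2, perm_groups) >= f_obs:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return PermutationTestResult(float(f_obs), float(p), n_permutations, seed)


def pcoa_coordinates(dist: pd.DataFrame, warn_negative: float = 0.5) -> pd.DataFrame:
    """Classical principal-coordinates embedding (positive eigenvalues kept)."""
    d2 = dist.to_numpy(dtype=float) ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    neg_mass = -evals[evals < 0].sum()
    pos_mass = evals[evals > 0].sum()
    if pos_mass > 0 and neg_mass / (pos_mass + neg_mass) > warn_negative:
        warnings.warn("more than half the eigenvalue mass is negative", stacklevel=2)
    keep = evals > max(1e-12, 1e-9 * abs(evals).max())
    coords = evecs[:, keep] * np.sqrt(evals[keep])
    return pd.DataFrame(coords, index=dist.index)


def permdisp(
    dist: pd.DataFrame, groups, n_permutations: int = 999, seed: int = 0
) -> PermutationTestResult:
    """Homogeneity of multivariate dispersions (distance to group centroid).

    Embeds the distance matrix by PCoA, computes each sample's Euclidean
    distance to its own group centroid, and permutes the one-way ANOVA F on
    those distances.
    """
    ids = dist.index
    idx_groups = _group_indices(groups, ids)
    if len(idx_groups) < 2:
        raise ValueError("PERMDISP needs >= 2 groups")
    if any(len(i) < 2 for i in idx_groups):
        raise ValueError("each group needs >= 2 samples")
    coords = pcoa_coordinates(dist).to_numpy()
    n = coords.shape[0]
    sizes = [len(i) for i in idx_groups]

    # distances to own-group centroid, computed once from the observed groups;
    # the permutation scheme reassigns these values to groups
    z = np.empty(n)
    for idx in idx_groups:
        centroid = coords[idx].mean(axis=0)
        z[idx] = np.linalg.norm(coords[idx] - centroid, axis=1)

    def one_way_f(idx_list) -> float:
        k = len(idx_list)
        grand = z.mean()
        ss_between = sum(len(i) * (z[i].mean() - grand) ** 2 for i in idx_list)
        ss_within = sum(((z[i] - z[i].mean()) ** 2).sum() for i in idx_list)
        if ss_within == 0:
            return np.inf if ss_between > 0 else 0.0
        return (ss_between / (k - 1)) / (ss_within / (n - k))

    f_obs = one_way_f(idx_groups)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        start = 0
        perm_groups = []
        for size in sizes:
            perm_groups.append(perm[start : start + size])
            start += size
        if one_way_f(perm_groups) >= f_obs:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return PermutationTestResult(float(f_obs), float(p), n_permutations, seed)
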