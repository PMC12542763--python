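"""Pan-metabolome calculus: presence calls, core/flexible/unique partition,
UpSet-style intersections, origin annotation, and group overlap.

By analogy with the pan-genome, the *core* metabolome is the set of features
present in every biological sample of a group under the group-parsing
presence rule, the *flexible* metabolome the set present in at least one but
not all samples.  Presence is a ratio rule on replicate-averaged counts: a
feature is present in a sample iff its count is nonzero and the maximum count
across the group divided by the sample's count stays below a threshold
(default 100); it is absent if the count is zero or the ratio reaches the
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .comparative import average_replicates
from .tables import FeatureTable

ORIGIN_CLASSES = ("microbial", "invertebrate", "mixed", "unannotated")


@dataclass
class PresenceMatrix:
    """Boolean occupancy of features across biological samples."""

    values: pd.DataFrame  # bool, features x samples
    ratio_threshold: float = 100.0
    provenance: str = "replicate-mean"

    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


@dataclass
class PanPartition:
    core: set = field(default_factory=set)
    flexible: set = field(default_factory=set)
    unique_by_sample: dict = field(default_factory=dict)
    intersections: dict = field(default_factory=dict)   # frozenset(samples) -> count
    subset_by_feature: dict = field(default_factory=dict)  # feature -> frozenset(samples)

    @property
    def present_features(self) -> set:
        return self.core | self.flexible

    def to_json_dict(self) -> dict:
        return {
            "core": sorted(self.core),
            "flexible": sorted(self.flexible),
            "unique_by_sample": {s: sorted(v) for s, v in self.unique_by_sample.items()},
            "intersections": {
                "&".join(sorted(k)): v for k, v in self.intersections.items()
            },
        }


def presence_call(
    table: FeatureTable,
    group_samples: list[str] | None = None,
    ratio_threshold: float = 100.0,
    averaged: bool = True,
) -> PresenceMatrix:
    """Group-parsing presence rule on (replicate-averaged) counts.

    For each feature, with M the maximum count across the group's samples,
    sample ``s`` is present iff ``count(s) > 0`` and ``M / count(s) <
    ratio_threshold``.
    """
    if ratio_threshold <= 1:
        raise ValueError("ratio_threshold must be > 1")
    counts = average_replicates(table).intensities if averaged else table.intensities
    if group_samples is not None:
        counts = counts[list(group_samples)]
    m = counts.max(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = counts.rdiv(m, axis=0)
    present = (counts > 0) & (ratio < ratio_threshold)
    return PresenceMatrix(present.fillna(False), ratio_threshold)


def partition_pan(presence: PresenceMatrix) -> PanPartition:
    """Decompose presence into core/flexible/unique sets and UpSet counts.

    Each present feature contributes to exactly one intersection: the subset
    of samples where it is present (UpSet semantics).
    """
    if presence.values.shape[1] < 1:
        raise ValueError("need at least one sample")
    part = PanPartition()
    n = presence.values.shape[1]
    samples = list(presence.samples)
    part.unique_by_sample = {s: set() for s in samples}
    for fid, row in presence.values.iterrows():
        where = frozenset(row.index[row])
        if not where:
            continue
        part.subset_by_feature[fid] = where
        part.intersections[where] = part.intersections.get(where, 0) + 1
        if len(where) == n:
            part.core.add(fid)
        else:
            part.flexible.add(fid)
        if len(where) == 1:
            part.unique_by_sample[next(iter(where))].add(fid)
    return part


def group_overlap(
    presence_a: PresenceMatrix, presence_b: PresenceMatrix
) -> tuple[set, set, set, dict]:
    """Unique-to-A / unique-to-B / shared feature sets and their percentages.

    A feature belongs to a group iff it is present in at least one of that
    group's samples; percentages are relative to the union of both groups'
    features (full precision; display rounding is the caller's concern).
    """
    if not presence_a.features.equals(presence_b.features):
        raise ValueError("presence matrices must share one feature universe")
    in_a = set(presence_a.features[presence_a.values.any(axis=1)])
    in_b = set(presence_b.features[presence_b.values.any(axis=1)])
    shared = in_a & in_b
    only_a = in_a - in_b
    only_b = in_b - in_a
    union = len(in_a | in_b)
    pct = {
        "unique_a": 100.0 * len(only_a) / union if union else 0.0,
        "unique_b": 100.0 * len(only_b) / union if union else 0.0,
        "shared": 100.0 * len(shared) / union if union else 0.0,
    }
    return only_a, only_b, shared, pct


def annotate_origin(
    partition: PanPartition, annotation: pd.Series | None = None
) -> pd.DataFrame:
    """Stacked origin-class counts per intersection subset.

    ``annotation`` maps feature id -> origin class; missing features default
    to ``unannotated``.  Column sums equal the subset sizes.
    """
    subsets = sorted(partition.intersections, key=lambda k: (-len(k), sorted(k)))
    cols = ["&".join(sorted(k)) for k in subsets]
    out = pd.DataFrame(0, index=pd.Index(ORIGIN_CLASSES, name="origin"), columns=cols)
    for fid, subset in partition.subset_by_feature.items():
        origin = "unannotated"
        if annotation is not None and fid in annotation.index:
            val = annotation.loc[fid]
            if pd.notna(val):
                if val not in ORIGIN_CLASSES:
                    raise ValueError(f"unknown origin class {val!r} for {fid}")
                origin = val
        out.loc[origin, "&".join(sorted(subset))] += 1
    assert (out.sum(axis=0).to_numpy() == [partition.intersections[s] for s in subsets]).all()
    return out
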