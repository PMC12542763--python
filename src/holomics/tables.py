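"""Core data containers shared across the pipeline.

The central object is :class:`FeatureTable`, an aligned LC-MS feature table
(features x sample-replicate columns) with per-feature m/z and retention time
and per-column sample metadata.  Metal panels and taxa count tables are thin
wrappers around pandas objects with the extra fields the statistics need
(limits of detection, censoring flags, group labels).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

BLANK_GROUP = "blank"


@dataclass
class FeatureTable:
    """LC-MS feature intensities with feature coordinates and column metadata.

    Parameters
    ----------
    intensities : DataFrame
        Non-negative intensities, one row per feature (index = feature id),
        one column per injected sample-replicate.
    mz : Series
        Mass-to-charge per feature, same index as ``intensities``.
    rt : Series
        Retention time (minutes) per feature.
    samples : DataFrame
        Column metadata indexed by the intensity column names, with columns
        ``sample`` (biological sample id), ``group`` (e.g. ``host``, ``water``
        or ``blank``) and ``replicate`` (technical replicate index).
    """

    intensities: pd.DataFrame
    mz: pd.Series
    rt: pd.Series
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.intensities.index.equals(self.mz.index) or not self.intensities.index.equals(
            self.rt.index
        ):
            raise ValueError("mz/rt index must match the intensity feature index")
        missing = self.intensities.columns.difference(self.samples.index)
        if len(missing):
            raise ValueError(f"columns without sample metadata: {list(missing)}")
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("intensities must be non-negative")
        if len(self.mz) and ((self.mz <= 0).any() or (self.rt < 0).any()):
            raise ValueError("require mz > 0 and rt >= 0")

    # -- column helpers -------------------------------------------------
    @property
    def feature_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def blank_columns(self) -> pd.Index:
        meta = self.samples.loc[self.intensities.columns]
        return self.intensities.columns[(meta["group"] == BLANK_GROUP).to_numpy()]

    @property
    def sample_columns(self) -> pd.Index:
        meta = self.samples.loc[self.intensities.columns]
        return self.intensities.columns[(meta["group"] != BLANK_GROUP).to_numpy()]

    def replicate_map(self) -> dict[str, list[str]]:
        """Biological sample id -> list of its (non-blank) replicate columns."""
        meta = self.samples.loc[self.sample_columns]
        return {s: list(cols.index) for s, cols in meta.groupby("sample", sort=False)}

    def sample_groups(self) -> pd.Series:
        """Biological sample id -> group label, for non-blank samples."""
        meta = self.samples.loc[self.sample_columns]
        return meta.drop_duplicates("sample").set_index("sample")["group"]

    def subset(self, feature_ids) -> "FeatureTable":
        return FeatureTable(
            self.intensities.loc[feature_ids],
            self.mz.loc[feature_ids],
            self.rt.loc[feature_ids],
            self.samples,
        )

    # -- IO --------------------------------------------------------------
    def to_tsv(self, table_path, meta_path) -> None:
        out = pd.concat([self.mz.rename("mz"), self.rt.rename("rt"), self.intensities], axis=1)
        out.to_csv(table_path, sep="\t", index_label="feature_id")
        self.samples.to_csv(meta_path, sep="\t", index_label="column")

    @classmethod
    def from_tsv(cls, table_path, meta_path) -> "FeatureTable":
        raw = pd.read_csv(table_path, sep="\t", index_col="feature_id")
        samples = pd.read_csv(meta_path, sep="\t", index_col="column")
        intensities = raw.drop(columns=["mz", "rt"])
        return cls(intensities, raw["mz"], raw["rt"], samples)


@dataclass
class MetalPanel:
    """Metal concentrations (ppm) per sample with LOD censoring.

    ``concentrations`` is metals x samples; ``lod`` is the per-metal limit of
    detection; ``censored`` marks cells whose value fell below the LOD and
    must not enter means.
    """

    concentrations: pd.DataFrame
    lod: pd.Series
    censored: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.censored is None:
            self.censored = self.concentrations.lt(
                self.lod.reindex(self.concentrations.index), axis=0
            )
        if not self.lod.index.equals(self.concentrations.index):
            self.lod = self.lod.reindex(self.concentrations.index)

    @property
    def metals(self) -> pd.Index:
        return self.concentrations.index

    def uncensored_values(self, metal: str) -> np.ndarray:
        mask = ~self.censored.loc[metal].to_numpy()
        return self.concentrations.loc[metal].to_numpy()[mask]

    def to_tsv(self, path) -> None:
        long = self.concentrations.stack().rename("concentration_ppm").reset_index()
        long.columns = ["metal", "sample", "concentration_ppm"]
        long["censored"] = self.censored.stack().to_numpy()
        long["lod"] = self.lod.loc[long["metal"]].to_numpy()
        long.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "MetalPanel":
        long = pd.read_csv(path, sep="\t")
        conc = long.pivot(index="metal", columns="sample", values="concentration_ppm")
        lod = long.drop_duplicates("metal").set_index("metal")["lod"]
        censored = None
        if "censored" in long.columns:
            censored = long.pivot(index="metal", columns="sample", values="censored").astype(bool)
        return cls(conc, lod, censored)


@dataclass
class TaxaCountTable:
    """Taxon counts (taxa x samples) with taxonomy strings and group labels."""

    counts: pd.DataFrame
    taxonomy: pd.Series | None = None
    groups: pd.Series | None = None  # sample -> group label

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        if self.taxonomy is not None:
            out.insert(0, "taxonomy", self.taxonomy)
        out.to_csv(path, sep="\t", index_label="taxon")

    @classmethod
    def from_tsv(cls, path, groups: pd.Series | None = None) -> "TaxaCountTable":
        raw = pd.read_csv(path, sep="\t", index_col="taxon")
        taxonomy = None
        if "taxonomy" in raw.columns:
            taxonomy = raw.pop("taxonomy")
        return cls(raw, taxonomy, groups)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify))


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, (set, frozenset, tuple, pd.Index, np.ndarray)):
        return list(x)
    raise TypeError(f"not JSON serialisable: {type(x)}")
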