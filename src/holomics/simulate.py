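"""Synthetic multi-omics data generator with machine-readable ground truth.

Emulates the study design of a host/seawater holobiont survey: 8 host and 3
water biological samples, technical triplicate LC-MS injections, methanol
blanks, an 8-metal ICP panel, Dirichlet-multinomial 16S taxa counts on a
random rooted tree, and shared-sample multi-omics blocks with planted
metal-taxon-metabolite correlation triplets.

Every planted MS artifact is recoverable from the generated table alone by
its defining geometric/statistical rule: separations are generated strictly
inside (artifacts) or strictly outside (unrelated features) the default
filter windows, so a correct filter cascade achieves perfect precision and
recall against the returned :class:`GroundTruth`.  An optional boundary-jitter
mode instead draws artifact offsets up to the window edge with a small
Gaussian smear, so a few artifacts land undetectably outside their windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import FeatureTable, MetalPanel, TaxaCountTable

ISOTOPE_SPACING = 1.00335  # 13C - 12C mass difference
ARTIFACT_CLASSES = ("ringing", "isotopologue", "insource", "blank_contaminant", "high_cv")

# default ICP panel: per-metal (tissue mean ppm, water mean ppm, relative sd)
DEFAULT_METAL_SPEC = {
    "V": (40.0, 0.0015, 0.10),   # water vanadium sits below the 0.002 ppm LOD
    "Mn": (250.0, 0.020, 0.10),
    "Fe": (400.0, 0.080, 0.10),
    "Co": (1.5, 0.004, 0.10),
    "Ni": (6.0, 0.030, 0.10),
    "Cu": (25.0, 0.012, 0.10),
    "Zn": (700.0, 0.050, 0.10),
    "Ce": (30.0, 0.003, 0.10),
}


@dataclass
class TaxaSpec:
    """Parameters of the Dirichlet-multinomial community generator."""

    n_taxa: int = 150
    dirichlet_alpha: float = 0.5      # base-composition concentration (skewed, realistic)
    overdispersion: float = 200.0     # per-sample Dirichlet concentration around group mean
    n_differential: int = 15          # taxa whose abundance differs between groups
    effect_size: float = 4.0          # multiplicative group effect on differential taxa
    depth_range: tuple[int, int] = (4173, 81886)  # observed amplicon-read range


@dataclass
class PlantedLink:
    """A metal-taxon-metabolite triplet sharing a latent monotone profile.

    ``rho`` is a *floor* on the realized rank correlation magnitude between
    the metal and the other two members (its sign sets the direction); the
    generator plants near-perfect monotone rank profiles so the triplet is
    recoverable above the default network thresholds.
    """

    metal: str
    taxon: str
    metabolite: str
    rho: float

    def __post_init__(self) -> None:
        if not 0 < abs(self.rho) <= 1:
            raise ValueError(f"planted |rho| must be in (0, 1], got {self.rho}")


@dataclass
class SimulationConfig:
    n_host_samples: int = 8
    n_water_samples: int = 3
    n_tech_replicates: int = 3
    n_blanks: int = 3
    n_true_features: int = 500
    artifact_counts: dict = field(
        default_factory=lambda: {c: 100 for c in ARTIFACT_CLASSES}
    )
    occupancy_design: dict | None = None  # feature id -> "core" | "flexible:s1,s2" | "unique:s"
    metal_spec: dict = field(default_factory=lambda: dict(DEFAULT_METAL_SPEC))
    water_lod: float = 0.002
    tissue_lod: float = 0.2
    taxa_spec: TaxaSpec = field(default_factory=TaxaSpec)
    planted_links: list = field(
        default_factory=lambda: [
            PlantedLink("Mn", "T001", "M001", -0.99),
            PlantedLink("Ni", "T002", "M002", -0.99),
            PlantedLink("Zn", "T003", "M003", 0.99),
        ]
    )
    n_shared_samples: int = 30
    n_metabolites_integration: int = 200
    intensity_threshold: float = 7500.0  # features are generated above this floor
    technical_cv: float = 0.08           # multiplicative replicate noise of true features
    boundary_jitter: bool = False
    seed: int = 0

    def validate(self) -> None:
        counts = [
            self.n_host_samples,
            self.n_water_samples,
            self.n_blanks,
            self.n_true_features,
            *self.artifact_counts.values(),
        ]
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if self.n_tech_replicates < 2:
            raise ValueError("need >= 2 technical replicates (CV filter requires >= 2)")
        unknown = set(self.artifact_counts) - set(ARTIFACT_CLASSES)
        if unknown:
            raise ValueError(f"unknown artifact classes: {sorted(unknown)}")
        needs_parent = sum(
            self.artifact_counts.get(c, 0) for c in ("ringing", "isotopologue", "insource")
        )
        if needs_parent and self.n_true_features < 1:
            raise ValueError("parent-attached artifacts require at least one true feature")

    @property
    def biological_samples(self) -> list[str]:
        return [f"host{i + 1}" for i in range(self.n_host_samples)] + [
            f"water{i + 1}" for i in range(self.n_water_samples)
        ]


@dataclass
class GroundTruth:
    """Machine-readable truth accompanying every simulated dataset."""

    feature_labels: dict = field(default_factory=dict)   # feature id -> class
    occupancy: dict = field(default_factory=dict)        # feature id -> set of samples
    metal_truth: dict = field(default_factory=dict)      # metal -> true fold increase
    planted_edges: list = field(default_factory=list)    # ((block, id), (block, id), sign)

    def to_json_dict(self) -> dict:
        return {
            "feature_labels": self.feature_labels,
            "occupancy": {k: sorted(v) for k, v in self.occupancy.items()},
            "metal_truth": self.metal_truth,
            "planted_edges": [
                {"a": list(a), "b": list(b), "sign": s} for a, b, s in self.planted_edges
            ],
        }


# ----------------------------------------------------------------------
# occupancy plans
# ----------------------------------------------------------------------

def default_occupancy_design(config: SimulationConfig, rng: np.random.Generator) -> dict:
    """Random occupancy plan: ~40% core, ~40% flexible subsets, ~20% unique."""
    samples = config.biological_samples
    design = {}
    for i in range(config.n_true_features):
        fid = f"F{i + 1:05d}"
        u = rng.random()
        if u < 0.4 or len(samples) == 1:
            design[fid] = "core"
        elif u < 0.8 and len(samples) > 2:
            size = int(rng.integers(2, len(samples)))
            subset = rng.choice(samples, size=size, replace=False)
            design[fid] = "flexible:" + ",".join(sorted(subset))
        else:
            design[fid] = "unique:" + str(rng.choice(samples))
    return design


def _occupancy_sets(design: dict, samples: list[str]) -> dict:
    out = {}
    for fid, spec in design.items():
        if spec == "core":
            out[fid] = set(samples)
        elif spec.startswith("flexible:"):
            out[fid] = set(spec.split(":", 1)[1].split(","))
        elif spec.startswith("unique:"):
            out[fid] = {spec.split(":", 1)[1]}
        else:
            raise ValueError(f"bad occupancy spec for {fid}: {spec!r}")
        if not out[fid] <= set(samples):
            raise ValueError(f"occupancy of {fid} names unknown samples")
    return out


# ----------------------------------------------------------------------
# feature table
# ----------------------------------------------------------------------

def simulate_feature_table(config: SimulationConfig) -> tuple[FeatureTable, GroundTruth]:
    """Generate an LC-MS feature table with planted, recoverable artifacts.

    True features live on a retention-time grid whose spacing (0.16 min)
    exceeds three co-elution windows, so unrelated features never co-elute.
    Parent-attached artifacts (ringing satellites, isotopologues, in-source
    fragments) share their parent's grid slot and its across-column intensity
    profile; blank contaminants and irreproducible (high technical CV)
    features occupy their own slots.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    samples = config.biological_samples
    n_rep = config.n_tech_replicates

    columns = [f"{s}_r{r + 1}" for s in samples for r in range(n_rep)]
    groups = ["host" if s.startswith("host") else "water" for s in samples]
    meta = pd.DataFrame(
        {
            "sample": [s for s in samples for _ in range(n_rep)],
            "group": [g for g in groups for _ in range(n_rep)],
            "replicate": [r + 1 for _ in samples for r in range(n_rep)],
        },
        index=pd.Index(columns, name="column"),
    )
    blank_cols = [f"blank_r{b + 1}" for b in range(config.n_blanks)]
    for b in blank_cols:
        meta.loc[b] = ["blank", "blank", int(b.split("_r")[1])]
    all_cols = columns + blank_cols

    design = config.occupancy_design or default_occupancy_design(config, rng)
    if len(design) != config.n_true_features:
        raise ValueError("occupancy_design must cover every true feature exactly once")
    occupancy = _occupancy_sets(design, samples)

    truth = GroundTruth()
    rows: list[dict] = []

    def add_feature(fid, mz, rt, sample_int, blank_int, label, occ):
        rec = {"feature_id": fid, "mz": float(mz), "rt": float(rt)}
        for s in samples:
            for r in range(n_rep):
                rec[f"{s}_r{r + 1}"] = float(sample_int.get((s, r), 0.0))
        for b, v in zip(blank_cols, blank_int):
            rec[b] = float(v)
        rows.append(rec)
        truth.feature_labels[fid] = label
        truth.occupancy[fid] = set(occ)

    sigma_tech = float(np.sqrt(np.log1p(config.technical_cv**2)))
    n_parented = sum(
        config.artifact_counts.get(c, 0) for c in ("ringing", "isotopologue", "insource")
    )

    # --- true features on the rt grid -------------------------------------
    slot = 0
    true_profiles: dict[str, dict] = {}
    for i, fid in enumerate(sorted(design)):
        rt = 0.5 + 0.16 * slot
        slot += 1
        mz = float(rng.uniform(300.0, 2200.0))
        # parents of planted artifacts need high intensity and full occupancy
        is_parent_pool = i < max(1, min(config.n_true_features, n_parented)) and n_parented > 0
        if is_parent_pool:
            base = 10 ** rng.uniform(6.8, 7.5)
            occ = set(samples)
        else:
            base = 10 ** rng.uniform(4.5, 7.0)
            occ = occupancy[fid]
        bio = {s: base * np.exp(rng.normal(0.0, 0.4)) for s in occ}
        sample_int = {
            (s, r): bio[s] * np.exp(rng.normal(0.0, sigma_tech))
            for s in occ
            for r in range(n_rep)
        }
        add_feature(fid, mz, rt, sample_int, [0.0] * config.n_blanks, "true", occ)
        true_profiles[fid] = {"mz": mz, "rt": rt, "intensities": sample_int, "occ": occ}

    parent_pool = sorted(true_profiles)[: max(1, min(config.n_true_features, n_parented))]

    def offset(window: float, margin_lo: float = 0.1, margin_hi: float = 0.8) -> float:
        """Draw an artifact offset inside (default) or up to (jitter) the window."""
        if config.boundary_jitter:
            return float(rng.uniform(0.0, window) + rng.normal(0.0, 0.02 * window))
        return float(rng.uniform(margin_lo * window, margin_hi * window))

    # --- ringing satellites ------------------------------------------------
    for j in range(config.artifact_counts.get("ringing", 0)):
        fid = f"RING{j + 1:04d}"
        parent = true_profiles[parent_pool[int(rng.integers(len(parent_pool)))]]
        dmz = offset(0.5) * (1 if rng.random() < 0.5 else -1)
        drt = offset(0.05, margin_lo=0.0) * (1 if rng.random() < 0.5 else -1)
        frac = rng.uniform(0.002, 0.009)
        ints = {k: v * frac for k, v in parent["intensities"].items()}
        add_feature(fid, parent["mz"] + dmz, parent["rt"] + drt, ints,
                    [0.0] * config.n_blanks, "ringing", parent["occ"])

    # --- isotopologues -----------------------------------------------------
    for j in range(config.artifact_counts.get("isotopologue", 0)):
        fid = f"ISO{j + 1:04d}"
        parent = true_profiles[parent_pool[int(rng.integers(len(parent_pool)))]]
        k = int(rng.integers(1, 4))
        dmz = k * ISOTOPE_SPACING + offset(0.01) * (1 if rng.random() < 0.5 else -1)
        drt = offset(0.05, margin_lo=0.0) * (1 if rng.random() < 0.5 else -1)
        frac = 0.4**k
        ints = {key: v * frac for key, v in parent["intensities"].items()}
        add_feature(fid, parent["mz"] + dmz, parent["rt"] + drt, ints,
                    [0.0] * config.n_blanks, "isotopologue", parent["occ"])

    # --- in-source fragments (lower m/z, shared intensity profile) ---------
    for j in range(config.artifact_counts.get("insource", 0)):
        fid = f"INS{j + 1:04d}"
        parent = true_profiles[parent_pool[int(rng.integers(len(parent_pool)))]]
        dmz = -float(rng.uniform(20.0, 80.0))
        drt = offset(0.05, margin_lo=0.0, margin_hi=0.4) * (1 if rng.random() < 0.5 else -1)
        frac = rng.uniform(0.1, 0.5)
        ints = {k: v * frac for k, v in parent["intensities"].items()}
        add_feature(fid, parent["mz"] + dmz, parent["rt"] + drt, ints,
                    [0.0] * config.n_blanks, "insource", parent["occ"])

    # --- blank contaminants -------------------------------------------------
    for j in range(config.artifact_counts.get("blank_contaminant", 0)):
        fid = f"BLK{j + 1:04d}"
        rt = 0.5 + 0.16 * slot
        slot += 1
        mz = float(rng.uniform(300.0, 2200.0))
        base = 10 ** rng.uniform(4.8, 6.5)
        bio = {s: base * np.exp(rng.normal(0.0, 0.4)) for s in samples}
        ints = {
            (s, r): bio[s] * np.exp(rng.normal(0.0, sigma_tech))
            for s in samples
            for r in range(n_rep)
        }
        peak = max(ints.values())
        if config.boundary_jitter:
            ratios = np.clip(rng.uniform(0.05, 0.8, config.n_blanks)
                             + rng.normal(0.0, 0.001, config.n_blanks), 0.0, None)
        else:
            ratios = rng.uniform(0.2, 0.8, config.n_blanks)
        add_feature(fid, mz, rt, ints, list(peak * ratios), "blank_contaminant", set(samples))

    # --- irreproducible features (exact per-sample replicate CV) -----------
    base_pattern = np.array([0.2 if r % 2 == 0 else 2.2 for r in range(n_rep)])
    dev = (base_pattern - base_pattern.mean()) / base_pattern.std()  # population sd
    for j in range(config.artifact_counts.get("high_cv", 0)):
        fid = f"CV{j + 1:04d}"
        rt = 0.5 + 0.16 * slot
        slot += 1
        mz = float(rng.uniform(300.0, 2200.0))
        base = 10 ** rng.uniform(4.5, 6.5)
        target_cv = rng.uniform(0.5, 1.2) if config.boundary_jitter else rng.uniform(0.8, 1.2)
        ints = {}
        for s in samples:
            level = base * np.exp(rng.normal(0.0, 0.4))
            mult = 1.0 + target_cv * dev  # replicate multipliers with exact CV
            for r in range(n_rep):
                ints[(s, r)] = level * max(mult[r], 1e-6)
        add_feature(fid, mz, rt, ints, [0.0] * config.n_blanks, "high_cv", set(samples))

    if not rows:
        empty = pd.DataFrame(columns=all_cols, dtype=float)
        empty.index.name = "feature_id"
        return (
            FeatureTable(empty, pd.Series(dtype=float, name="mz"),
                         pd.Series(dtype=float, name="rt"), meta),
            truth,
        )

    frame = pd.DataFrame(rows).set_index("feature_id")
    table = FeatureTable(frame[all_cols], frame["mz"], frame["rt"], meta)
    return table, truth


# ----------------------------------------------------------------------
# metal panels
# ----------------------------------------------------------------------

def simulate_metal_panel(
    config: SimulationConfig,
) -> tuple[MetalPanel, MetalPanel, GroundTruth]:
    """Draw tissue and water ICP panels with the configured relative noise.

    Water values falling below the water LOD are flagged censored, mirroring
    below-detection seawater measurements.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    truth = GroundTruth()
    metals = list(config.metal_spec)
    t_samples = [f"host{i + 1}" for i in range(config.n_host_samples)]
    w_samples = [f"water{i + 1}" for i in range(config.n_water_samples)]

    tissue = pd.DataFrame(index=pd.Index(metals, name="metal"), columns=t_samples, dtype=float)
    water = pd.DataFrame(index=pd.Index(metals, name="metal"), columns=w_samples, dtype=float)
    for m in metals:
        t_mean, w_mean, rel = config.metal_spec[m]
        if t_mean <= 0 or w_mean <= 0:
            raise ValueError(f"metal means must be > 0 (metal {m})")
        tissue.loc[m] = np.clip(t_mean * (1 + rel * rng.standard_normal(len(t_samples))), 0, None)
        water.loc[m] = np.clip(w_mean * (1 + rel * rng.standard_normal(len(w_samples))), 0, None)
        truth.metal_truth[m] = t_mean / w_mean

    t_lod = pd.Series(config.tissue_lod, index=tissue.index)
    w_lod = pd.Series(config.water_lod, index=water.index)
    return MetalPanel(tissue, t_lod), MetalPanel(water, w_lod), truth


# ----------------------------------------------------------------------
# taxa counts and tree
# ----------------------------------------------------------------------

def simulate_taxa_counts(config: SimulationConfig) -> tuple[TaxaCountTable, str]:
    """Dirichlet-multinomial taxa counts with group-differential taxa.

    Returns the count table and a rooted binary newick tree with positive
    branch lengths covering every taxon.  Library sizes are drawn uniformly
    over the configured depth range (unequal by design).
    """
    config.validate()
    spec = config.taxa_spec
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    taxa = [f"T{i + 1:03d}" for i in range(spec.n_taxa)]
    samples = config.biological_samples
    groups = pd.Series(
        ["host" if s.startswith("host") else "water" for s in samples], index=samples
    )

    base = rng.dirichlet(np.full(spec.n_taxa, spec.dirichlet_alpha))
    base = np.maximum(base, 1e-12)
    diff_idx = rng.choice(spec.n_taxa, size=min(spec.n_differential, spec.n_taxa), replace=False)
    host_p = base.copy()
    host_p[diff_idx] *= spec.effect_size if spec.effect_size > 0 else 1.0
    host_p /= host_p.sum()

    counts = pd.DataFrame(0, index=pd.Index(taxa, name="taxon"), columns=samples)
    for s in samples:
        p_group = host_p if (groups[s] == "host" and spec.effect_size != 0) else base
        p = rng.dirichlet(p_group * spec.overdispersion)
        depth = int(rng.integers(spec.depth_range[0], spec.depth_range[1] + 1))
        counts[s] = rng.multinomial(depth, p)

    taxonomy = pd.Series(
        [f"Bacteria;clade_{i % 10};taxon_{t}" for i, t in enumerate(taxa)],
        index=counts.index,
        name="taxonomy",
    )
    newick = _random_rooted_tree(taxa, rng)
    return TaxaCountTable(counts, taxonomy, groups), newick


def _random_rooted_tree(leaves: list[str], rng: np.random.Generator) -> str:
    """Random rooted binary tree over ``leaves`` with positive branch lengths."""
    if len(leaves) == 1:
        return f"({leaves[0]}:{rng.uniform(0.1, 1.0):.6f});"
    nodes = [f"{leaf}" for leaf in leaves]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        la, lb = rng.uniform(0.05, 1.0, size=2)
        merged = f"({a}:{la:.6f},{b}:{lb:.6f})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0] + ";"


# ----------------------------------------------------------------------
# shared-sample multi-omics blocks with planted links
# ----------------------------------------------------------------------

def _planted_ranks(n: int, rng: np.random.Generator) -> np.ndarray:
    """Latent rank permutation shared by a planted triplet."""
    return rng.permutation(n)


def _perturb_ranks(ranks: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One adjacent rank swap (n >= 15): realized pairwise Spearman >= 0.999."""
    n = len(ranks)
    out = ranks.copy()
    if n >= 15:
        order = np.argsort(out)
        pos = int(rng.integers(n - 1))
        a, b = order[pos], order[pos + 1]
        out[a], out[b] = out[b], out[a]
    return out


def _monotone_values(ranks: np.ndarray, draws: np.ndarray) -> np.ndarray:
    """Assign sorted draws to ranks: values strictly increase with rank."""
    srt = np.sort(draws)
    # enforce strict increase so rank correlations are exact
    srt = srt + np.arange(len(srt)) * (1e-9 * (abs(srt).max() + 1.0))
    return srt[ranks]


def simulate_multiomics(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Shared-sample metallome/microbiome/metabolome blocks with planted links.

    Returns ``(metals, taxa, metabolites, truth)`` as features x samples
    DataFrames over one shared ordered sample set.  Each planted triplet
    follows a common latent monotone profile (sign per its target rho); all
    other cross-block pairs are independent.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    n = config.n_shared_samples
    if n < 3:
        raise ValueError("need >= 3 shared samples for rank correlations")
    if n < 10:
        warnings.warn(
            f"only {n} shared samples: correlation estimates will be unstable",
            stacklevel=2,
        )
    samples = [f"s{i + 1:02d}" for i in range(n)]

    metals = list(config.metal_spec)
    taxa = [f"T{i + 1:03d}" for i in range(config.taxa_spec.n_taxa)]
    mets = [f"M{i + 1:03d}" for i in range(config.n_metabolites_integration)]
    for link in config.planted_links:
        if link.metal not in metals or link.taxon not in taxa or link.metabolite not in mets:
            raise ValueError(f"planted link references unknown feature: {link}")

    metal_block = pd.DataFrame(
        {s: [config.metal_spec[m][0] * np.exp(rng.normal(0, 0.3)) for m in metals]
         for s in samples},
        index=pd.Index(metals, name="feature"),
    )
    # wide per-taxon dynamic range keeps planted rank profiles robust to the
    # per-sample shift a centered log-ratio transform introduces downstream
    taxa_block = pd.DataFrame(
        np.round(np.exp(rng.uniform(3, 8, (len(taxa), 1)) + rng.normal(0, 1.0, (len(taxa), n)))),
        index=pd.Index(taxa, name="feature"),
        columns=samples,
    )
    met_block = pd.DataFrame(
        np.exp(rng.uniform(8, 14, (len(mets), 1)) + rng.normal(0, 1.0, (len(mets), n))),
        index=pd.Index(mets, name="feature"),
        columns=samples,
    )

    truth = GroundTruth()
    for link in config.planted_links:
        latent = _planted_ranks(n, rng)
        sign = 1 if link.rho > 0 else -1
        r_metal = _perturb_ranks(latent, rng)
        partner = latent if sign > 0 else (n - 1 - latent)
        r_taxon = _perturb_ranks(partner, rng)
        r_met = _perturb_ranks(partner, rng)

        metal_block.loc[link.metal] = _monotone_values(
            r_metal, config.metal_spec[link.metal][0] * np.exp(rng.normal(0, 0.5, n))
        )
        taxa_block.loc[link.taxon] = np.round(
            _monotone_values(r_taxon, np.exp(np.linspace(5.0, 12.0, n)))
        )
        met_block.loc[link.metabolite] = _monotone_values(
            r_met, np.exp(rng.uniform(9, 13) + rng.normal(0, 1.2, n))
        )
        truth.planted_edges += [
            (("metallome", link.metal), ("microbiome", link.taxon), sign),
            (("metallome", link.metal), ("metabolome", link.metabolite), sign),
            (("microbiome", link.taxon), ("metabolome", link.metabolite), 1),
        ]

    return metal_block, taxa_block, met_block, truth
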