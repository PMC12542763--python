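# Methods

This note records the models, conventions, and numerical choices behind each
stage of the pipeline, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Filter cascade

The cascade applies five filters in a fixed order — absolute intensity
threshold, mispicked-peak correction, in-source ion filtering, technical-CV
filtering, blank filtering — and assigns each input feature exactly one
status (the first flag it triggers). The order matters: ringing satellites
and isotopologues are proportional to their parent and would otherwise also
be caught by the in-source correlation rule; running mispicked correction
first keeps the provenance informative.

Boundary conventions are chosen so that each quoted parameter is the last
*passing* value: a feature whose maximum intensity equals the threshold is
retained, a median CV equal to 0.5 is retained, a blank ratio equal to 0.05
is retained, and a Spearman correlation equal to 0.95 is flagged.

Parameter defaults (all configurable through `FilterConfig`):

| parameter | default | units | role |
|---|---|---|---|
| `intensity_threshold` | 7 500 | counts | max over non-blank columns must reach it |
| `ringing_mass_window` | 0.5 | mass units | satellite window around a stronger parent |
| `isotope_mass_window` | 0.01 | mass units | tolerance around *k*·1.00335 (¹³C–¹²C), *k* ≤ 3 |
| `rt_window` | 0.05 | min | co-elution window (transitive closure) |
| `insource_rho` | 0.95 | — | Spearman clustering threshold |
| `cv_max` | 0.5 | — | median per-sample replicate CV |
| `blank_ratio` | 0.05 | — | mean blank / max sample intensity |

Design choices where a convention was needed: in-source clusters keep their
highest-m/z member (fragments are lighter than the parent ion); mispicked
parents are visited in descending maximum intensity and a flagged feature
cannot act as a parent; satellite intensities are dropped, not summed; the
blank statistic is the mean over blank columns divided by the maximum over
sample columns; the CV uses the population standard deviation (n
denominator), which is deterministic and well-behaved at triplicate scale —
configurable via `cv_ddof`. The CV of a feature is computed only in samples
where it is present, and a feature absent everywhere is retained and logged
rather than flagged (its CV is undefined). Spearman correlation against a
constant intensity vector is undefined; such pairs are treated as
uncorrelated and logged.

## Pan-metabolome

Presence follows a group-parsing ratio rule on replicate-averaged counts: a
feature is present in a sample iff its count is nonzero and (max count
across the group) / (count in the sample) stays **below** 100; zero counts
or ratios of 100 and above are absences. Averaging replicates before the
call is a choice (raw-replicate calls are available via `averaged=False`).
The partition is plain set algebra: the core is the set of features present
in every sample, the flexible set those present in some but not all, and
each present feature contributes to exactly one intersection subset (UpSet
semantics). Group membership for the host/water overlap is presence in at
least one sample of the group; percentages are reported at full precision
relative to the union.

## Metal bioaccumulation

Fold increase per metal is z = ȳ/x̄ over uncensored measurements, with

Δz = z·√((Δx/x̄)² + (Δy/ȳ)²),

the first-order quadrature propagation for an independent quotient; Δx and
Δy are sample standard deviations (n−1). Cells below the limit of detection
are excluded from means rather than substituted; when a metal's water panel
is entirely censored, z is reported as a lower bound against the LOD with a
`bound_flag`. Significance is a two-tailed pooled-variance t-test, with the
degenerate conventions p = 1 for identical constant groups and p = 0 for
distinct constant groups.

The quadrature formula is validated against a Monte-Carlo oracle that
resamples ȳ* ~ N(ȳ, Δy) and x̄* ~ N(x̄, Δx) and measures the spread of
ȳ*/x̄*. A subtlety dictates the spread measure: a ratio of Gaussians has no
finite variance (the denominator can approach zero), so a raw sample sd is
tail-dominated and depends on an arbitrary truncation — under a 3σ
truncation it sits 13–15% above the quadrature value once Δx/x̄ reaches 0.2,
and it diverges without one. The oracle therefore reports the half-width of
the central 68.27% interval, the standard one-sigma-equivalent scale for a
skewed quotient and the quantity a reported ±Δz describes. Against that
measure the quadrature agrees within ~4% across the whole Δ/mean ≤ 0.2 grid.

## Community diversity

Counts are depth-normalized by scaling every sample to the minimum library
size (fractional counts allowed); rarefaction without replacement
(multivariate hypergeometric) is available for comparison. Shannon entropy
uses the natural logarithm. Weighted UniFrac is the raw form,
d(u,v) = Σ_b l_b·|P_b(u) − P_b(v)| over all non-root branches, where P_b is
the fraction of a sample's reads descending from branch b; the normalized
variant divides by Σ_b l_b·(P_b(u) + P_b(v)). PERMANOVA partitions squared
distances among/within groups and permutes labels freely (no strata), with
p = (1 + #{F* ≥ F}) / (1 + n_permutations); 999 permutations and an explicit
seed are the defaults. PERMDISP embeds the distance matrix by classical
principal coordinates (positive eigenvalues only; a warning fires if more
than half of the eigenvalue mass is negative), measures each sample's
distance to its own group centroid once, and permutes the one-way ANOVA F on
those distances — the standard scheme, which keeps the test calibrated.

## Comparative metabolomics

Volcano statistics use log2(x+1)-transformed replicate-averaged intensities
by default (configurable off); the reported fold change is
log2((mean_A+1)/(mean_B+1)) on the linear scale. Multiple testing uses
Benjamini-Hochberg step-up adjustment. Note that BH is *not* idempotent —
re-adjusting adjusted values inflates them — so only the step-up definition,
rank monotonicity, q ≥ p, and empirical FDR control are asserted as
invariants. Sample clustering is UPGMA (average linkage), which reproduces
ultrametric inputs exactly. NMDS minimizes Kruskal stress-1 by SMACOF with
monotone regression, 2 dimensions and 20 random restarts by default, seeded;
coordinates are centered at the origin and are identifiable only up to
rotation and reflection.

## Multi-omics integration

Blocks must share one identical ordered sample set. Scalings: metals are
min-max scaled per feature; metabolite intensities are square-root
transformed then Pareto scaled ((v − mean)/√sd, sample sd); taxa counts get
a centered log-ratio transform per sample with pseudocount 1 (the CLR is
exactly scale-invariant only when the pseudocount scales with the column;
the property is asserted in that regime). Features with zero variance across
the shared samples are removed before correlation. All cross-block feature
pairs are Spearman-correlated with average ranks for ties; pairs involving a
constant vector are skipped and logged. The network keeps edges with
ρ ≥ 0.995 or ρ ≤ −0.990 by default. The latent-variable multiblock
discriminant model that originally motivated these thresholds is not
re-implemented; correlations are computed directly on the scaled blocks, and
the thresholds remain user-configurable.

The percolation scan rebuilds the network on a grid of |ρ| thresholds
(positive and negative edges separately) and suggests the smallest grid
value at which the largest connected component holds **at most** half of the
participating nodes. At-most rather than strictly-less is deliberate: the
canonical planted structure — two equally sized correlation cliques over a
weak background — fragments into two components of exactly half the nodes,
and a strict rule could never identify that point.

## Synthetic-data generator

The generator emulates the study design: 8 host and 3 water biological
samples, technical triplicates, 3 solvent blanks, 500 genuine features plus
100 planted artifacts per class by default, an 8-metal panel (V, Mn, Fe, Co,
Ni, Cu, Zn, Ce) with strong tissue-over-water enrichment at 10% relative
noise and water vanadium below the 0.002 ppm LOD, Dirichlet-multinomial
taxa counts with library sizes spanning 4 173–81 886 reads and a random
rooted binary tree, and shared-sample omics blocks with planted
metal–taxon–metabolite triplets.

Key conventions:

- Absent features are exact zeros; occupancy ground truth equals the zero
  pattern.
- Technical noise is multiplicative log-normal (MS intensity noise is
  scale-dependent), CV 8% for genuine features. Intensity magnitudes are
  drawn log-uniform above the detection threshold — the true intensity
  distribution of real features is unknown, so this is a convention, not a
  reconstruction.
- Genuine features sit on a retention-time grid spaced at more than three
  co-elution windows, so unrelated features never co-elute; each artifact
  shares its parent's slot. Artifact offsets are drawn strictly inside their
  windows (at most 80% of the window) and parent-proportional intensities
  make the correlation and intensity-order rules exact, so a correct cascade
  attains precision and recall of 1 by construction. The optional
  boundary-jitter mode instead draws offsets up to the window edge with a 2%
  Gaussian smear, letting a small fraction of artifacts escape detection.
- Irreproducible features receive replicate multipliers constructed to give
  an exact per-sample CV (0.8–1.2 by default), so the median-CV rule
  separates them from genuine features with margin.
- Planted correlation triplets follow a shared latent rank profile through
  strictly monotone value maps; the requested |ρ| is a floor, and the
  realized rank correlation is pushed near 1 (one adjacent rank swap per
  member at n ≥ 15, none below) so that recovery through the scaling
  transforms — including the per-sample shift the CLR introduces — stays
  above the default network thresholds. Planted taxa are given a wide,
  evenly spaced log-abundance range for the same reason. This mirrors the
  artifact-window convention: planted structure is separated from the
  decision boundary so that a correct pipeline recovers it exactly, and the
  test measures the pipeline rather than sampling noise.

What the generator does **not** emulate, and hence what passing tests do not
show about real data: chromatographic drift and alignment error, correlated
(matrix-dependent) blank contamination, compositional coupling between
metabolite features, taxa-taxa phylogenetic correlation in abundances,
instrument batch effects, and censoring in the tissue metal panel. Results
on real studies depend on vendor peak picking and alignment upstream of this
pipeline.

## Problem sizes

Default test and validation sizes were chosen to exercise each property at
comfortable statistical resolution on a single CPU: 1 000-feature tables for
filter recovery, 200 random presence matrices (up to 12 samples × 300
features) against exhaustive subset enumeration, 500 null community
simulations at 999 permutations for PERMANOVA calibration, 1 000 random
p-vectors against the step-up oracle, 50 random 8-leaf trees for the
weighted-UniFrac comparison, and 30 shared samples for planted-link
recovery.

## Known limitations

- The in-source filter clusters by transitive closure, so long co-elution
  chains can merge features a pairwise rule would keep apart.
- PERMDISP uses centroids in principal-coordinate space, not spatial
  medians, and drops negative-eigenvalue axes.
- The percolation suggestion is a heuristic fragmentation rule, not a model
  selection procedure; final thresholds remain the user's choice.
- The pan-metabolome presence rule is sensitive to its ratio threshold for
  features near the dynamic-range floor; 100 is a convention inherited from
  group-parsing practice.
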