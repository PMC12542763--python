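"""Metal bioaccumulation statistics.

Fold increase z = ȳ/x̄ (mean tissue over mean water concentration, ppm) with
uncertainty propagated in quadrature,

    Δz = z * sqrt((Δx/x̄)² + (Δy/ȳ)²),

the standard quotient-rule propagation for independent errors; x̄ ± Δx and
ȳ ± Δy are means ± sample standard deviations over uncensored measurements.
Per-metal significance is a two-tailed homoscedastic (pooled-variance)
two-sample t-test.  Values censored at the limit of detection are excluded
from means; when a metal's water measurements are entirely censored, the fold
increase is reported as a lower bound against the LOD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables import MetalPanel


@dataclass
class FoldIncrease:
    metal: str
    z: float                 # fold increase (tissue/water); lower bound if bound_flag
    dz: float                # propagated uncertainty; nan on the bound path
    x_mean: float            # water mean (ppm)
    x_sd: float
    y_mean: float            # tissue mean (ppm)
    y_sd: float
    p: float                 # two-tailed homoscedastic t-test p-value (nan if untestable)
    bound_flag: bool = False
    degenerate: bool = False


def metal_ttest(tissue_values, water_values) -> float:
    """Two-tailed pooled-variance two-sample t-test p-value.

    Degenerate inputs follow explicit conventions: zero pooled variance with
    equal means gives p = 1, with unequal means p = 0.
    """
    a = np.asarray(tissue_values, dtype=float)
    b = np.asarray(water_values, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("t-test requires >= 2 values per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)


def fold_increase(tissue: MetalPanel, water: MetalPanel) -> pd.DataFrame:
    """Per-metal fold increase with propagated uncertainty and t-test p-value.

    Returns a DataFrame indexed by metal with columns z, dz, x_mean, x_sd,
    y_mean, y_sd, p, bound_flag, degenerate.
    """
    results = []
    for metal in tissue.metals:
        y = tissue.uncensored_values(metal)
        if metal not in water.metals:
            raise KeyError(f"metal {metal} missing from water panel")
        x = water.uncensored_values(metal)
        if len(y) == 0:
            raise ValueError(f"metal {metal}: no uncensored tissue values")
        y_mean, y_sd = float(y.mean()), float(y.std(ddof=1)) if len(y) > 1 else 0.0

        if len(x) == 0:
            # fully censored water: report a lower bound against the LOD
            lod = float(water.lod[metal])
            results.append(
                FoldIncrease(metal, y_mean / lod, math.nan, math.nan, math.nan,
                             y_mean, y_sd, math.nan, bound_flag=True)
            )
            continue

        x_mean, x_sd = float(x.mean()), float(x.std(ddof=1)) if len(x) > 1 else 0.0
        if x_mean == 0:
            results.append(
                FoldIncrease(metal, math.nan, math.nan, x_mean, x_sd, y_mean, y_sd,
                             math.nan, degenerate=True)
            )
            continue
        z = y_mean / x_mean
        dz = z * math.sqrt((x_sd / x_mean) ** 2 + (y_sd / y_mean) ** 2) if y_mean else 0.0
        p = metal_ttest(y, x) if len(y) >= 2 and len(x) >= 2 else math.nan
        degen = len(y) >= 2 and len(x) >= 2 and (p == 0.0)
        results.append(FoldIncrease(metal, z, dz, x_mean, x_sd, y_mean, y_sd, p,
                                    degenerate=degen))
    frame = pd.DataFrame([vars(r) for r in results]).set_index("metal")
    return frame


def propagate_quotient(y_mean, y_sd, x_mean, x_sd) -> tuple[float, float]:
    """Quadrature propagation for z = y/x; exposed for direct use."""
    z = y_mean / x_mean
    dz = abs(z) * math.sqrt((x_sd / x_mean) ** 2 + (y_sd / y_mean) ** 2)
    return z, dz


def monte_carlo_dz(
    y_mean, y_sd, x_mean, x_sd, n_draws: int = 200_000, seed: int = 0
) -> float:
    """Monte-Carlo uncertainty of z = y/x from resampled Gaussian means.

    Draws ȳ* ~ N(ȳ, Δy) and x̄* ~ N(x̄, Δx) and returns the half-width of the
    central 68.27% interval of ȳ*/x̄* (the one-sigma-equivalent spread).  The
    ratio of two Gaussians has no finite variance — the denominator can come
    arbitrarily close to zero — so a raw sample sd is tail-dominated and
    depends on an arbitrary truncation; the central spread is the standard
    well-defined scale for such a quotient and is what a quoted ±Δz means.
    """
    rng = np.random.default_rng(seed)
    ratio = rng.normal(y_mean, y_sd, n_draws) / rng.normal(x_mean, x_sd, n_draws)
    lo, hi = np.percentile(ratio, [100 * stats.norm.cdf(-1), 100 * stats.norm.cdf(1)])
    return float((hi - lo) / 2)
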