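"""End-to-end assembly of the adaptive-introgression scan.

Ties the stages together on a shared window grid: windowed f4 with the
label-permutation null, per-population Tajima's D against the simulated
sweep null, per-window fixed-difference counts between the two focal
populations, Dxy to each candidate donor, and the intersection-based
category-IV candidate call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .candidates import call_candidates, classify_categories, sweep_windows
from .f4 import F4Config
from .model import PopulationMap, ScaffoldIndex, VariantTable, window_index
from .permutation import (
    NullDistribution,
    PermutationConfig,
    build_null,
    flag_windows,
    observed_window_values,
    window_p_values,
)
from .popgen import fixed_diff_sites, window_statistics


def fixed_diff_window_counts(
    tables: list[VariantTable],
    popmap: PopulationMap,
    pop_a: str,
    pop_b: str,
    grid: pd.DataFrame,
    window_size: int,
) -> pd.Series:
    """Count of reciprocally fixed pop_a/pop_b SNPs per window of *grid*."""
    counts = {
        (r.scaffold, int(r.start)): 0 for r in grid.itertuples(index=False)
    }
    for t in tables:
        sites = fixed_diff_sites(t, popmap, pop_a, pop_b)
        for w in window_index(t.positions[sites], window_size):
            key = (t.scaffold, int(w) * window_size)
            if key in counts:
                counts[key] += 1
    return pd.Series(
        [counts[(r.scaffold, int(r.start))] for r in grid.itertuples(index=False)],
        index=grid.index,
        name="n_fixed",
    )


@dataclass
class ScanResult:
    """Combined window table, the permutation null, and the candidate call."""

    windows: pd.DataFrame
    null: NullDistribution
    category_percentages: dict[str, float]
    candidates: pd.DataFrame


def adaptive_introgression_scan(
    tables: list[VariantTable],
    popmap: PopulationMap,
    scaffold_index: ScaffoldIndex,
    f4_config: F4Config,
    perm_config: PermutationConfig,
    sweep_threshold: float,
    focal_pops: list[str],
    donor_pops: list[str],
    exclude_low_pi: bool = False,
    include_fst: bool = False,
) -> ScanResult:
    """Run the full scan and call category-IV candidate regions.

    *sweep_threshold* is the lower-tail Tajima's D cutoff from the
    simulated null (see :func:`introscan.coalescent.tajd_null_distribution`);
    the sweep flag is set when either focal population falls below it.
    """
    grid, observed = observed_window_values(tables, popmap, f4_config)
    null = build_null(tables, popmap, f4_config, perm_config)
    windows = grid.copy()
    windows["f4"] = observed
    windows["n_usable_sites"] = np.nan  # filled from the stats table below
    windows["p_value"] = window_p_values(observed, null)
    windows["significant"] = flag_windows(observed, null)

    pairs = [(f, d) for f in focal_pops for d in donor_pops]
    stats = window_statistics(
        tables,
        popmap,
        scaffold_index,
        populations=focal_pops + donor_pops,
        pairs=pairs,
        window_size=f4_config.window_size,
        min_sites=1,
        max_missing_frac=f4_config.max_missing_frac,
        include_fst=include_fst,
    )
    windows = windows.drop(columns=["n_usable_sites"]).merge(
        stats, on=["scaffold", "start", "end"], how="left"
    )
    windows["n_fixed"] = fixed_diff_window_counts(
        tables, popmap, focal_pops[0], focal_pops[1], windows, f4_config.window_size
    )

    sweep = pd.Series(False, index=windows.index)
    for p in focal_pops:
        sweep |= sweep_windows(windows, p, sweep_threshold)
    _, percentages = classify_categories(
        windows["significant"], sweep, windows["n_fixed"] > 0
    )
    cands = call_candidates(
        windows,
        significant_f4=windows["significant"],
        sweep=sweep,
        fixed_counts=windows["n_fixed"],
        focal_pops=focal_pops,
        donor_pops=donor_pops,
        exclude_low_pi=exclude_low_pi,
    )
    return ScanResult(
        windows=windows,
        null=null,
        category_percentages=percentages,
        candidates=cands,
    )
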