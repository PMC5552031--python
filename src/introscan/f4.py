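"""Windowed and genome-wide f4 statistics for a four-population tree.

For the tree ((P1, P2), (P3, P4)) the per-site statistic is
``(p1 - p2)(p3 - p4)`` on alt-allele frequencies; its expectation is zero
under incomplete lineage sorting without gene flow, and a positive value
indicates excess sharing between P1 and P3 or between P2 and P4.  Sites
where any population's frequency is undefined under the per-population
missing-data rule are skipped entirely (never imputed or zeroed).

The genome-wide mean gets a standard error from a delete-one block
jackknife over contiguous blocks (scaffolds by default), with the weighted
delete-m_j formula to accommodate unequal block sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import PopulationMap, VariantTable, window_index
from .popgen import DEFAULT_MAX_MISSING, pop_frequencies


@dataclass
class F4Config:
    """Four populations in ((p1, p2), (p3, p4)) topology plus window rules."""

    p1: str
    p2: str
    p3: str
    p4: str
    window_size: int = 10_000
    min_sites: int = 50
    max_missing_frac: float = DEFAULT_MAX_MISSING

    def __post_init__(self) -> None:
        pops = [self.p1, self.p2, self.p3, self.p4]
        if len(set(pops)) != 4:
            raise ValueError("the four populations must be distinct")
        if self.min_sites < 1:
            raise ValueError("min_sites must be at least 1")

    @property
    def populations(self) -> list[str]:
        return [self.p1, self.p2, self.p3, self.p4]


def site_f4(p1: float, p2: float, p3: float, p4: float) -> float:
    """(p1 - p2)(p3 - p4); NaN if any frequency is undefined."""
    if any(math.isnan(p) for p in (p1, p2, p3, p4)):
        return float("nan")
    return (p1 - p2) * (p3 - p4)


def site_f4_array(
    table: VariantTable,
    popmap: PopulationMap,
    config: F4Config,
) -> np.ndarray:
    """Per-site f4 values for one scaffold (NaN where a site is unusable)."""
    freqs = [
        pop_frequencies(
            table.genotypes,
            popmap.indices(table.sample_ids, pop),
            config.max_missing_frac,
        )
        for pop in config.populations
    ]
    return (freqs[0] - freqs[1]) * (freqs[2] - freqs[3])


def window_f4(
    table: VariantTable,
    popmap: PopulationMap,
    config: F4Config,
    site_values: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean site f4 per non-overlapping window of one scaffold.

    Rows: scaffold, start, end, n_usable_sites, f4 (NaN below min_sites).
    Only windows containing at least one variant record appear; the
    genome-wide grid over empty windows is not materialized because such
    windows can never reach the minimum site count.
    """
    if site_values is None:
        site_values = site_f4_array(table, popmap, config)
    widx = window_index(table.positions, config.window_size)
    usable = ~np.isnan(site_values)
    rows = []
    for w in np.unique(widx):
        sel = widx == w
        n_usable = int((usable & sel).sum())
        if n_usable >= config.min_sites:
            value = float(site_values[usable & sel].mean())
        else:
            value = float("nan")
        rows.append(
            {
                "scaffold": table.scaffold,
                "start": int(w) * config.window_size,
                "end": (int(w) + 1) * config.window_size,
                "n_usable_sites": n_usable,
                "f4": value,
            }
        )
    return pd.DataFrame(rows)


def scan_f4(
    tables: list[VariantTable],
    popmap: PopulationMap,
    config: F4Config,
) -> pd.DataFrame:
    """Windowed f4 over a list of scaffold tables."""
    frames = [window_f4(t, popmap, config) for t in tables]
    if not frames:
        return pd.DataFrame(
            columns=["scaffold", "start", "end", "n_usable_sites", "f4"]
        )
    return pd.concat(frames, ignore_index=True)


@dataclass
class GenomeF4:
    """Genome-wide f4 with a block-jackknife standard error."""

    mean: float
    se: float
    z: float
    p: float
    n_sites: int
    n_blocks: int
    degenerate: bool = False  # SE = 0 (all usable sites identical)


def genome_f4(
    tables: list[VariantTable],
    popmap: PopulationMap,
    config: F4Config,
    block_size: int | None = None,
    min_blocks: int = 20,
) -> GenomeF4:
    """Mean site f4 over all usable sites with a delete-one block jackknife.

    Blocks are whole scaffolds unless *block_size* (bp) is given, in which
    case contiguous fixed-size blocks within scaffolds are used.  Requires
    at least *min_blocks* blocks containing usable sites.
    """
    block_sums: list[float] = []
    block_counts: list[int] = []
    for table in tables:
        vals = site_f4_array(table, popmap, config)
        usable = ~np.isnan(vals)
        if block_size is None:
            if usable.any():
                block_sums.append(float(vals[usable].sum()))
                block_counts.append(int(usable.sum()))
        else:
            bidx = window_index(table.positions, block_size)
            for b in np.unique(bidx):
                sel = usable & (bidx == b)
                if sel.any():
                    block_sums.append(float(vals[sel].sum()))
                    block_counts.append(int(sel.sum()))
    g = len(block_sums)
    if g < min_blocks:
        raise ValueError(
            f"only {g} blocks contain usable sites (need >= {min_blocks}); "
            "use a smaller block size"
        )
    sums = np.array(block_sums)
    counts = np.array(block_counts, dtype=np.float64)
    total = float(sums.sum())
    n = float(counts.sum())
    mean = total / n
    # weighted delete-m_j jackknife (Busing et al. 1999)
    loo = (total - sums) / (n - counts)
    h = n / counts
    theta_j = g * mean - float(((1.0 - counts / n) * loo).sum())
    dev = h * mean - (h - 1.0) * loo - theta_j
    # (1/g) sum dev^2/(h-1) is already the variance of the estimate; with
    # equal blocks it reduces to the usual (g-1)/g sum (loo - loo_bar)^2
    var = float((dev**2 / (h - 1.0)).sum()) / g
    se = math.sqrt(var) if var > 0 else 0.0
    if se == 0.0:
        return GenomeF4(
            mean=mean, se=0.0, z=float("nan"), p=float("nan"),
            n_sites=int(n), n_blocks=g, degenerate=True,
        )
    z = mean / se
    p = 2.0 * stats.norm.sf(abs(z))
    return GenomeF4(mean=mean, se=se, z=z, p=float(p), n_sites=int(n), n_blocks=g)


@dataclass
class DiversityDiagnostic:
    """Correlation report between f4 behaviour and nucleotide diversity."""

    r_scaffold_var_vs_pi: float   # per-scaffold f4 variance vs mean scaffold pi
    r_window_f4_vs_pi: float      # window f4 vs window pi
    n_scaffolds: int
    n_windows: int


def f4_diversity_diagnostic(
    windows: pd.DataFrame,
    f4_col: str = "f4",
    pi_col: str = "pi",
) -> DiversityDiagnostic:
    """Report Pearson correlations between f4 and diversity (no test).

    Expects a window table with scaffold, *f4_col* and *pi_col* columns.
    The scaffold-level correlation relates per-scaffold variance in window
    f4 to mean scaffold pi; NaN when variance is undefined (constant f4).
    """
    needed = {"scaffold", f4_col, pi_col}
    if not needed.issubset(windows.columns):
        raise ValueError(f"window table must contain columns {sorted(needed)}")
    ok = windows.dropna(subset=[f4_col, pi_col])
    per_scaffold = ok.groupby("scaffold").agg(
        f4_var=(f4_col, "var"), pi_mean=(pi_col, "mean")
    ).dropna()
    if len(per_scaffold) < 3:
        raise ValueError("need at least 3 scaffolds with data for the diagnostic")
    if per_scaffold["f4_var"].nunique() <= 1 or per_scaffold["pi_mean"].nunique() <= 1:
        r_scaf = float("nan")
    else:
        r_scaf = float(
            stats.pearsonr(per_scaffold["f4_var"], per_scaffold["pi_mean"])[0]
        )
    if ok[f4_col].nunique() <= 1 or ok[pi_col].nunique() <= 1:
        r_win = float("nan")
    else:
        r_win = float(stats.pearsonr(ok[f4_col], ok[pi_col])[0])
    return DiversityDiagnostic(
        r_scaffold_var_vs_pi=r_scaf,
        r_window_f4_vs_pi=r_win,
        n_scaffolds=len(per_scaffold),
        n_windows=len(ok),
    )
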