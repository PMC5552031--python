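"""Intersection-based adaptive-introgression candidate calling and dating.

Windows are classified by three binary signals — a significant windowed f4
value (permutation test), a selective sweep (Tajima's D below the
simulated-null 2% tail in at least one focal population), and at least one
SNP fixed between the two focal populations — into the four categories of
the contribution accounting:

* I   introgression contributing to divergence, no sweep (f4 and fixed),
* II  sweep of non-introgressed variation (sweep and fixed, no f4),
* III adaptive introgression not contributing to divergence (f4 and sweep),
* IV  adaptive introgression involved in divergence (all three) — these are
  the called candidates.

Donor and recipient are assigned per window by the minimum Dxy over focal x
donor population pairs.  An external sweep-statistic column (e.g. a
composite-likelihood-ratio flag computed elsewhere) can be supplied to
further restrict the sweep signal.  Introgression timing is dated from the
per-site divergence d of the introgressed haplotype pair via d = 2 * mu * t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CATEGORY_ORDER = ["I", "II", "III", "IV"]
UNCLASSIFIED = "unclassified"

_KEY = ["scaffold", "start", "end"]


def sweep_windows(
    windows: pd.DataFrame, pop: str, threshold: float
) -> pd.Series:
    """Boolean per window: Tajima's D of *pop* defined and below *threshold*."""
    col = f"tajd_{pop}"
    if col not in windows.columns:
        raise KeyError(f"window table lacks column {col!r}")
    d = windows[col]
    return (d.notna() & (d < threshold)).rename(f"sweep_{pop}")


def classify_categories(
    significant_f4: pd.Series,
    sweep: pd.Series,
    fixed_snp: pd.Series,
) -> tuple[pd.Series, dict[str, float]]:
    """Window category from the three boolean signals, plus percentages.

    Categories partition the windows; percentages (of all windows) for
    I-IV and the unclassified remainder sum to 100.
    """
    sig = significant_f4.fillna(False).astype(bool)
    swp = sweep.fillna(False).astype(bool)
    fix = fixed_snp.fillna(False).astype(bool)
    cat = pd.Series(UNCLASSIFIED, index=sig.index, dtype=object)
    cat[sig & fix & ~swp] = "I"
    cat[swp & fix & ~sig] = "II"
    cat[sig & swp & ~fix] = "III"
    cat[sig & swp & fix] = "IV"
    n = len(cat)
    percentages = {
        c: 100.0 * float((cat == c).sum()) / n
        for c in CATEGORY_ORDER + [UNCLASSIFIED]
    }
    return cat, percentages


def assign_donor(
    windows: pd.DataFrame,
    focal_pops: list[str],
    donor_pops: list[str],
) -> pd.DataFrame:
    """Per-window (donor, recipient) by minimum Dxy over focal x donor pairs.

    Expects columns ``dxy_<focal>_<donor>`` for every pair.  Ties are broken
    by the mean Dxy over the +/-1 flanking windows on the same scaffold,
    then lexicographically by (donor, focal); the ``donor_tie`` flag marks
    windows decided lexicographically.  Windows with any missing pair Dxy
    get no assignment.
    """
    pairs = [(f, d) for f in focal_pops for d in donor_pops]
    cols = {}
    for f, d in pairs:
        col = f"dxy_{f}_{d}"
        if col not in windows.columns:
            raise KeyError(f"window table lacks column {col!r}")
        cols[(f, d)] = col
    mat = np.column_stack([windows[cols[p]].to_numpy(dtype=float) for p in pairs])
    donors = np.full(len(windows), None, dtype=object)
    recipients = np.full(len(windows), None, dtype=object)
    ties = np.zeros(len(windows), dtype=bool)
    scaffolds = windows["scaffold"].to_numpy()
    for i in range(len(windows)):
        row = mat[i]
        if np.isnan(row).any():
            continue
        best = row.min()
        tied = np.flatnonzero(np.isclose(row, best, rtol=0.0, atol=0.0))
        if tied.size > 1:
            # widen to +/-1 window context on the same scaffold
            neighbours = [
                j
                for j in (i - 1, i, i + 1)
                if 0 <= j < len(windows) and scaffolds[j] == scaffolds[i]
            ]
            context = np.nanmean(mat[neighbours][:, tied], axis=0)
            best_ctx = np.nanmin(context)
            tied = tied[np.isclose(context, best_ctx, rtol=0.0, atol=0.0)]
            if tied.size > 1:
                order = sorted(
                    (pairs[k][1], pairs[k][0], k) for k in tied
                )
                tied = np.array([order[0][2]])
                ties[i] = True
        f, d = pairs[int(tied[0])]
        donors[i] = d
        recipients[i] = f
    return pd.DataFrame(
        {"donor": donors, "recipient": recipients, "donor_tie": ties},
        index=windows.index,
    )


def call_candidates(
    windows: pd.DataFrame,
    significant_f4: pd.Series,
    sweep: pd.Series,
    fixed_counts: pd.Series,
    focal_pops: list[str],
    donor_pops: list[str],
    exclude_low_pi: bool = False,
    low_pi_percentile: float = 5.0,
) -> pd.DataFrame:
    """Category-IV windows as candidate adaptive-introgression regions.

    All inputs must share the window table's index (same window grid).
    Candidates carry the window's f4, permutation p-value (if present),
    fixed-SNP count, donor/recipient assignment, and the sweep flag.

    With *exclude_low_pi*, a candidate is dropped as a putative
    low-recombination false positive when pi is below the given percentile
    of all windows in every focal population and its assigned-donor Dxy is
    not itself unusually low (below the same percentile of that pair's
    windows) — low diversity everywhere with no corroborating donor
    similarity.
    """
    for series, name in (
        (significant_f4, "significant_f4"),
        (sweep, "sweep"),
        (fixed_counts, "fixed_counts"),
    ):
        if not series.index.equals(windows.index):
            raise ValueError(f"{name} is not aligned with the window grid")
    has_fixed = fixed_counts.fillna(0) > 0
    category, _ = classify_categories(significant_f4, sweep, has_fixed)
    assignment = assign_donor(windows, focal_pops, donor_pops)
    mask = category == "IV"
    out = windows.loc[mask, _KEY].copy()
    for col in ("f4", "p_value", "n_usable_sites"):
        if col in windows.columns:
            out[col] = windows.loc[mask, col]
    out["n_fixed"] = fixed_counts[mask].astype(int)
    out["donor"] = assignment.loc[mask, "donor"]
    out["recipient"] = assignment.loc[mask, "recipient"]
    out["donor_tie"] = assignment.loc[mask, "donor_tie"]
    out["category"] = "IV"
    if exclude_low_pi and len(out):
        pi_cols = [f"pi_{p}" for p in focal_pops]
        for col in pi_cols:
            if col not in windows.columns:
                raise KeyError(f"window table lacks column {col!r}")
        thresholds = {
            col: np.nanpercentile(windows[col], low_pi_percentile)
            for col in pi_cols
        }
        drop = []
        for idx in out.index:
            all_low = all(
                pd.notna(windows.at[idx, col])
                and windows.at[idx, col] < thresholds[col]
                for col in pi_cols
            )
            if not all_low:
                continue
            donor = out.at[idx, "donor"]
            recipient = out.at[idx, "recipient"]
            corroborated = False
            if donor is not None and recipient is not None:
                dxy_col = f"dxy_{recipient}_{donor}"
                dxy_thr = np.nanpercentile(windows[dxy_col], low_pi_percentile)
                corroborated = windows.at[idx, dxy_col] < dxy_thr
            if not corroborated:
                drop.append(idx)
        out = out.drop(index=drop)
    return out.reset_index(drop=True)


@dataclass
class DatingConfig:
    """Mutation-rate bounds (per site per year) and generation time (years)."""

    mu_low: float = 1.32e-7
    mu_high: float = 5.37e-7
    generation_time: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.mu_low <= self.mu_high):
            raise ValueError("need 0 < mu_low <= mu_high")
        if self.generation_time <= 0:
            raise ValueError("generation time must be positive")


@dataclass
class DatingResult:
    """Introgression age range from pairwise divergence d = 2 * mu * t."""

    d_per_site: float
    t_low_years: float       # from the fast mutation-rate bound
    t_high_years: float      # from the slow mutation-rate bound
    t_low_generations: float
    t_high_generations: float

    def rounded(self, nearest: int = 100) -> tuple[float, float]:
        """Convenience (low, high) years rounded to the nearest *nearest*."""
        return (
            round(self.t_low_years / nearest) * nearest,
            round(self.t_high_years / nearest) * nearest,
        )


def date_introgression(
    d_count: int, window_len: int, config: DatingConfig | None = None
) -> DatingResult:
    """Date an introgressed haplotype from accumulated pairwise differences.

    Under neutrality the per-site divergence between the donor and the
    introgressed recipient haplotype is d = 2 * mu * t, so t = d / (2 * mu)
    for each mutation-rate bound.  Raw (unrounded) values are authoritative.
    """
    if config is None:
        config = DatingConfig()
    if d_count < 0:
        raise ValueError("d_count must be non-negative")
    if window_len <= 0:
        raise ValueError("window_len must be positive")
    d = d_count / window_len
    t_low = d / (2.0 * config.mu_high)
    t_high = d / (2.0 * config.mu_low)
    return DatingResult(
        d_per_site=d,
        t_low_years=t_low,
        t_high_years=t_high,
        t_low_generations=t_low / config.generation_time,
        t_high_generations=t_high / config.generation_time,
    )
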