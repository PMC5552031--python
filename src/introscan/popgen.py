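"""Site- and window-level population genetic estimators.

All estimators work on alt-allele dosage matrices with missing genotypes and
share one frequency rule: a population's frequency at a site is computed
from called genotypes only and is undefined when the missing fraction in
that population exceeds ``max_missing_frac`` (default 10%).

Conventions
-----------
* pi uses the unbiased pairwise estimator ``c_alt*c_ref / C(n,2)`` on called
  allele counts, summed over sites and divided by the full window length in
  bp, so positions without a variant record count as invariant.
* Dxy = sum over sites of ``pA(1-pB) + pB(1-pA)`` divided by the full
  window length (the variants-only VCF correction); pass
  ``per_site_denominator=True`` to divide by the number of contributing
  variant sites instead.
* The Fst window estimate is the Weir & Cockerham (1984) ratio of summed
  variance components (VCFtools "weighted" convention).
* Tajima's D follows Tajima (1989); the window version uses n = 2 x
  (population size in diploids) for the constants and counts a site as
  segregating when called genotypes show both alleles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import MISSING, PopulationMap, VariantTable

DEFAULT_MAX_MISSING = 0.10


# ---------------------------------------------------------------------------
# frequency machinery (shared by the f4 scan and the permutation null)
# ---------------------------------------------------------------------------

def pop_allele_counts(
    genotypes: np.ndarray, pop_idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(alt allele count, called allele count) per site for one population."""
    sub = genotypes[pop_idx, :]
    called = sub != MISSING
    alt = np.where(called, sub, 0).sum(axis=0).astype(np.float64)
    n_called = 2.0 * called.sum(axis=0)
    return alt, n_called


def pop_frequencies(
    genotypes: np.ndarray,
    pop_idx: np.ndarray,
    max_missing_frac: float = DEFAULT_MAX_MISSING,
) -> np.ndarray:
    """Alt-allele frequency per site; NaN where the missing rule fails."""
    if pop_idx.size == 0:
        raise ValueError("empty population")
    alt, n_called = pop_allele_counts(genotypes, pop_idx)
    n_total = pop_idx.size
    missing_frac = 1.0 - n_called / (2.0 * n_total)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_called > 0, alt / np.maximum(n_called, 1), np.nan)
    freq = np.where(missing_frac > max_missing_frac + 1e-12, np.nan, freq)
    return freq


@dataclass
class SiteFrequencies:
    """Per-population alt-allele frequency at one site."""

    freqs: dict[str, float]       # NaN = undefined under the missing rule
    n_called: dict[str, int]      # called diploid individuals
    n_total: dict[str, int]

    def defined(self, pop: str) -> bool:
        return not math.isnan(self.freqs[pop])


def site_frequencies(
    table: VariantTable,
    popmap: PopulationMap,
    site_index: int,
    max_missing_frac: float = DEFAULT_MAX_MISSING,
    populations: list[str] | None = None,
) -> SiteFrequencies:
    """Allele frequencies at one site for each population."""
    pops = populations if populations is not None else popmap.populations
    freqs, n_called, n_total = {}, {}, {}
    col = table.genotypes[:, site_index]
    for pop in pops:
        idx = popmap.indices(table.sample_ids, pop)
        sub = col[idx]
        called = sub != MISSING
        nc = int(called.sum())
        n_called[pop] = nc
        n_total[pop] = idx.size
        missing_frac = 1.0 - nc / idx.size
        if nc == 0 or missing_frac > max_missing_frac + 1e-12:
            freqs[pop] = float("nan")
        else:
            freqs[pop] = float(sub[called].sum() / (2.0 * nc))
    return SiteFrequencies(freqs=freqs, n_called=n_called, n_total=n_total)


# ---------------------------------------------------------------------------
# fixed differences
# ---------------------------------------------------------------------------

def fixed_diff_sites(
    table: VariantTable,
    popmap: PopulationMap,
    pop_a: str,
    pop_b: str,
    max_missing_frac: float = DEFAULT_MAX_MISSING,
) -> np.ndarray:
    """Site indices where the two populations are reciprocally fixed.

    A site qualifies when both frequencies are defined and one is exactly 0
    while the other is exactly 1 (per-site Fst = 1).
    """
    idx_a = popmap.indices(table.sample_ids, pop_a)
    idx_b = popmap.indices(table.sample_ids, pop_b)
    pa = pop_frequencies(table.genotypes, idx_a, max_missing_frac)
    pb = pop_frequencies(table.genotypes, idx_b, max_missing_frac)
    with np.errstate(invalid="ignore"):
        fixed = ((pa == 0.0) & (pb == 1.0)) | ((pa == 1.0) & (pb == 0.0))
    return np.flatnonzero(fixed)


# ---------------------------------------------------------------------------
# Weir & Cockerham Fst
# ---------------------------------------------------------------------------

def _wc_components(
    genotypes: np.ndarray,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    sites: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (a, a+b+c) variance components for two populations.

    Sites with fewer than 2 called genotypes in either population get NaN.
    """
    comps_num = np.full(sites.size, np.nan)
    comps_den = np.full(sites.size, np.nan)
    r = 2.0
    for out_i, j in enumerate(sites):
        stats = []
        ok = True
        for idx in (idx_a, idx_b):
            col = genotypes[idx, j]
            called = col[col != MISSING]
            n_i = called.size  # diploid individuals
            if n_i < 2:
                ok = False
                break
            p_i = called.sum() / (2.0 * n_i)
            h_i = np.mean(called == 1)
            stats.append((float(n_i), float(p_i), float(h_i)))
        if not ok:
            continue
        (n1, p1, h1), (n2, p2, h2) = stats
        n_bar = (n1 + n2) / r
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1.0)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        a = (n_bar / n_c) * (
            s2
            - (1.0 / (n_bar - 1.0))
            * (p_bar * (1.0 - p_bar) - s2 * (r - 1.0) / r - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1.0 - p_bar)
            - s2 * (r - 1.0) / r
            - h_bar * (2.0 * n_bar - 1.0) / (4.0 * n_bar)
        )
        c = h_bar / 2.0
        comps_num[out_i] = a
        comps_den[out_i] = a + b + c
    return comps_num, comps_den


def weir_cockerham_fst(
    table: VariantTable,
    popmap: PopulationMap,
    pop_a: str,
    pop_b: str,
    window: tuple[int, int] | None = None,
) -> tuple[np.ndarray, float]:
    """Weir & Cockerham (1984) theta-hat per site and for the window.

    The window estimate is the ratio of summed variance components across
    usable sites (not a mean of per-site ratios); NaN when no site has a
    nonzero denominator.
    """
    sites = _sites_in_window(table, window)
    idx_a = popmap.indices(table.sample_ids, pop_a)
    idx_b = popmap.indices(table.sample_ids, pop_b)
    num, den = _wc_components(table.genotypes, idx_a, idx_b, sites)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_site = num / den
    usable = np.isfinite(num) & np.isfinite(den) & (np.abs(den) > 0)
    if not usable.any():
        return per_site, float("nan")
    return per_site, float(num[usable].sum() / den[usable].sum())


# ---------------------------------------------------------------------------
# pi and Dxy
# ---------------------------------------------------------------------------

def _sites_in_window(
    table: VariantTable, window: tuple[int, int] | None
) -> np.ndarray:
    if window is None:
        return np.arange(table.n_sites)
    start, end = window
    if end <= start:
        raise ValueError("window end must exceed start")
    # positions are 1-based; window is 0-based half-open
    lo = np.searchsorted(table.positions, start + 1, side="left")
    hi = np.searchsorted(table.positions, end, side="right")
    return np.arange(lo, hi)


def window_pi(
    table: VariantTable,
    popmap: PopulationMap,
    pop: str,
    window: tuple[int, int] | None,
    window_len: float,
    max_missing_frac: float = DEFAULT_MAX_MISSING,
) -> float:
    """Nucleotide diversity per bp over the window.

    pi = sum over usable sites of ``c_alt*c_ref / C(n, 2)`` divided by
    *window_len*; sites whose frequency is undefined under the missing rule
    are skipped.
    """
    if window_len <= 0:
        raise ValueError("window_len must be positive")
    sites = _sites_in_window(table, window)
    idx = popmap.indices(table.sample_ids, pop)
    sub = table.genotypes[np.ix_(idx, sites)]
    called = sub != MISSING
    n_alleles = 2.0 * called.sum(axis=0)
    alt = np.where(called, sub, 0).sum(axis=0).astype(np.float64)
    missing_frac = 1.0 - n_alleles / (2.0 * idx.size)
    usable = (n_alleles >= 2) & (missing_frac <= max_missing_frac + 1e-12)
    pairs = n_alleles * (n_alleles - 1.0) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        per_site = np.where(usable, alt * (n_alleles - alt) / np.maximum(pairs, 1.0), 0.0)
    return float(per_site.sum() / window_len)


def window_dxy(
    table: VariantTable,
    popmap: PopulationMap,
    pop_a: str,
    pop_b: str,
    window: tuple[int, int] | None,
    window_len: float,
    max_missing_frac: float = DEFAULT_MAX_MISSING,
    per_site_denominator: bool = False,
) -> float:
    """Absolute divergence Dxy between two populations over the window.

    By default the denominator is the full window length, so non-genotyped
    positions count as invariant (the variants-only correction); with
    ``per_site_denominator`` the contributing variant-site count is used.
    """
    if window_len <= 0:
        raise ValueError("window_len must be positive")
    sites = _sites_in_window(table, window)
    idx_a = popmap.indices(table.sample_ids, pop_a)
    idx_b = popmap.indices(table.sample_ids, pop_b)
    pa = pop_frequencies(table.genotypes, idx_a, max_missing_frac)[sites]
    pb = pop_frequencies(table.genotypes, idx_b, max_missing_frac)[sites]
    usable = np.isfinite(pa) & np.isfinite(pb)
    per_site = pa[usable] * (1.0 - pb[usable]) + pb[usable] * (1.0 - pa[usable])
    denom = float(usable.sum()) if per_site_denominator else float(window_len)
    if per_site_denominator and denom == 0:
        return float("nan")
    return float(per_site.sum() / denom)


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def tajimas_d(S: int, pi_sum: float, n: int) -> float:
    """Tajima (1989) D from S segregating sites and summed pairwise diversity.

    *pi_sum* is the sum over sites of the per-site mean pairwise difference
    (unnormalized by sequence length); *n* is the number of haplotypes.
    Returns NaN when S = 0 (the statistic is undefined).
    """
    if n < 4:
        raise ValueError("Tajima's D requires at least 4 haplotypes")
    if S < 0:
        raise ValueError("S must be non-negative")
    if S == 0:
        return float("nan")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1.0)
    return float((pi_sum - S / a1) / math.sqrt(var))


def window_tajimas_d(
    table: VariantTable,
    popmap: PopulationMap,
    pop: str,
    window: tuple[int, int] | None = None,
) -> float:
    """Tajima's D for one population over a window.

    S counts sites where called genotypes of the population carry both
    alleles; pi_sum sums the per-site mean pairwise difference over called
    allele counts.  The constants use n = 2 x (population size in diploids),
    ignoring per-site missingness (which biases D slightly on incomplete
    data).  NaN when no site segregates.
    """
    sites = _sites_in_window(table, window)
    idx = popmap.indices(table.sample_ids, pop)
    sub = table.genotypes[np.ix_(idx, sites)]
    called = sub != MISSING
    n_alleles = 2.0 * called.sum(axis=0)
    alt = np.where(called, sub, 0).sum(axis=0).astype(np.float64)
    seg = (alt > 0) & (alt < n_alleles)
    S = int(seg.sum())
    if S == 0:
        return float("nan")
    pairs = n_alleles * (n_alleles - 1.0) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        per_site = np.where(seg, alt * (n_alleles - alt) / np.maximum(pairs, 1.0), 0.0)
    pi_sum = float(per_site.sum())
    return tajimas_d(S, pi_sum, 2 * idx.size)


def window_segregating_sites(
    table: VariantTable,
    popmap: PopulationMap,
    pop: str,
    window: tuple[int, int] | None = None,
) -> int:
    """Count of sites segregating among called genotypes of *pop*."""
    sites = _sites_in_window(table, window)
    idx = popmap.indices(table.sample_ids, pop)
    sub = table.genotypes[np.ix_(idx, sites)]
    called = sub != MISSING
    n_alleles = 2.0 * called.sum(axis=0)
    alt = np.where(called, sub, 0).sum(axis=0).astype(np.float64)
    return int(((alt > 0) & (alt < n_alleles)).sum())


# ---------------------------------------------------------------------------
# combined window table
# ---------------------------------------------------------------------------

def window_statistics(
    tables,
    popmap: PopulationMap,
    scaffold_index,
    populations: list[str],
    pairs: list[tuple[str, str]] | None = None,
    window_size: int = 10_000,
    min_sites: int = 50,
    max_missing_frac: float = DEFAULT_MAX_MISSING,
    include_fst: bool = True,
):
    """Per-window Fst, Dxy, pi, Tajima's D and S over all scaffolds.

    Returns a DataFrame with one row per window (scaffold, start, end,
    n_sites) and columns ``fst_<a>_<b>``, ``dxy_<a>_<b>``, ``pi_<p>``,
    ``tajd_<p>``, ``S_<p>``.  Statistics other than Fst use the full window
    length as denominator; rows with fewer than *min_sites* variant records
    carry NaN for all statistics.
    """
    import pandas as pd

    from .model import window_bounds

    if pairs is None:
        pairs = [
            (populations[i], populations[j])
            for i in range(len(populations))
            for j in range(i + 1, len(populations))
        ]
    rows = []
    for table in tables:
        length = scaffold_index[table.scaffold]
        for start, end in window_bounds(length, window_size):
            sites = _sites_in_window(table, (start, end))
            row: dict = {
                "scaffold": table.scaffold,
                "start": start,
                "end": end,
                "n_sites": int(sites.size),
            }
            enough = sites.size >= min_sites
            wlen = float(end - start)
            for a, b in pairs:
                key = f"{a}_{b}"
                if enough:
                    if include_fst:
                        _, fst = weir_cockerham_fst(
                            table, popmap, a, b, (start, end)
                        )
                        row[f"fst_{key}"] = fst
                    row[f"dxy_{key}"] = window_dxy(
                        table, popmap, a, b, (start, end), wlen, max_missing_frac
                    )
                else:
                    if include_fst:
                        row[f"fst_{key}"] = np.nan
                    row[f"dxy_{key}"] = np.nan
            for p in populations:
                if enough:
                    row[f"pi_{p}"] = window_pi(
                        table, popmap, p, (start, end), wlen, max_missing_frac
                    )
                    # D needs >= 4 haplotypes; single-individual outgroups get NaN
                    if len(popmap.samples(p)) >= 2:
                        row[f"tajd_{p}"] = window_tajimas_d(
                            table, popmap, p, (start, end)
                        )
                    else:
                        row[f"tajd_{p}"] = np.nan
                    row[f"S_{p}"] = window_segregating_sites(
                        table, popmap, p, (start, end)
                    )
                else:
                    row[f"pi_{p}"] = np.nan
                    row[f"tajd_{p}"] = np.nan
                    row[f"S_{p}"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

@dataclass
class LDResult:
    """Pairwise r2 values with distances and a binned decay curve."""

    distances: np.ndarray      # bp between site pairs
    r2: np.ndarray             # squared dosage correlation per pair
    bin_edges: np.ndarray
    bin_mean_r2: np.ndarray    # NaN for empty bins


def pairwise_r2(
    table: VariantTable,
    popmap: PopulationMap,
    pop: str,
    max_pairs: int | None = None,
    max_dist: int | None = None,
    bin_width: int = 10_000,
    rng: np.random.Generator | None = None,
) -> LDResult:
    """Pairwise r2 (squared Pearson correlation of dosages) within *pop*.

    Pairwise-complete genotypes are used for each pair; zero-variance sites
    are skipped.  With *max_pairs* set, pairs are subsampled uniformly.
    """
    idx = popmap.indices(table.sample_ids, pop)
    sub = table.genotypes[idx, :].astype(np.float64)
    sub[sub == MISSING] = np.nan
    n_sites = sub.shape[1]
    pairs = [
        (i, j)
        for i in range(n_sites)
        for j in range(i + 1, n_sites)
        if max_dist is None
        or table.positions[j] - table.positions[i] <= max_dist
    ]
    if max_pairs is not None and len(pairs) > max_pairs:
        rng = rng or np.random.default_rng()
        chosen = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[k] for k in sorted(chosen)]
    dists, r2s = [], []
    for i, j in pairs:
        x, y = sub[:, i], sub[:, j]
        complete = ~(np.isnan(x) | np.isnan(y))
        if complete.sum() < 2:
            continue
        xc, yc = x[complete], y[complete]
        if np.ptp(xc) == 0 or np.ptp(yc) == 0:
            continue  # zero variance
        r = np.corrcoef(xc, yc)[0, 1]
        dists.append(int(table.positions[j] - table.positions[i]))
        r2s.append(float(r * r))
    dists_arr = np.array(dists, dtype=np.int64)
    r2_arr = np.array(r2s, dtype=np.float64)
    top = int(dists_arr.max()) + 1 if dists_arr.size else bin_width
    edges = np.arange(0, top + bin_width, bin_width)
    means = np.full(edges.size - 1, np.nan)
    if dists_arr.size:
        which = np.digitize(dists_arr, edges) - 1
        for b in range(edges.size - 1):
            sel = which == b
            if sel.any():
                means[b] = r2_arr[sel].mean()
    return LDResult(distances=dists_arr, r2=r2_arr, bin_edges=edges, bin_mean_r2=means)
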