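"""Independent brute-force oracles for the window estimators.

Everything here enumerates allele pairs or evaluates textbook formulas with
explicit Python loops, deliberately sharing no code with the package's
vectorized implementations.
"""

from __future__ import annotations

import math

MISSING = -1


def called_alleles(genotypes_col, pop_rows):
    """Expand called diploid dosages of one site into a list of 0/1 alleles."""
    alleles = []
    for r in pop_rows:
        d = int(genotypes_col[r])
        if d == MISSING:
            continue
        alleles.extend([1] * d + [0] * (2 - d))
    return alleles


def freq_or_none(genotypes_col, pop_rows, max_missing_frac=0.10):
    """Alt frequency from called genotypes; None under the missing rule."""
    called = [r for r in pop_rows if int(genotypes_col[r]) != MISSING]
    if not called:
        return None
    if 1.0 - len(called) / len(pop_rows) > max_missing_frac + 1e-12:
        return None
    total = sum(int(genotypes_col[r]) for r in called)
    return total / (2.0 * len(called))


def pi_window(genotypes, pop_rows, site_cols, window_len, max_missing_frac=0.10):
    """Mean pairwise difference per bp by enumerating all allele pairs."""
    total = 0.0
    for j in site_cols:
        if freq_or_none(genotypes[:, j], pop_rows, max_missing_frac) is None:
            continue
        alleles = called_alleles(genotypes[:, j], pop_rows)
        n = len(alleles)
        if n < 2:
            continue
        diff = 0
        pairs = 0
        for a in range(n):
            for b in range(a + 1, n):
                pairs += 1
                if alleles[a] != alleles[b]:
                    diff += 1
        total += diff / pairs
    return total / window_len


def dxy_window(genotypes, rows_a, rows_b, site_cols, window_len,
               max_missing_frac=0.10):
    """Mean between-population difference per bp over all inter-pop pairs."""
    total = 0.0
    for j in site_cols:
        fa = freq_or_none(genotypes[:, j], rows_a, max_missing_frac)
        fb = freq_or_none(genotypes[:, j], rows_b, max_missing_frac)
        if fa is None or fb is None:
            continue
        al_a = called_alleles(genotypes[:, j], rows_a)
        al_b = called_alleles(genotypes[:, j], rows_b)
        diff = 0
        for x in al_a:
            for y in al_b:
                if x != y:
                    diff += 1
        total += diff / (len(al_a) * len(al_b))
    return total / window_len


def wc_fst_window(genotypes, rows_a, rows_b, site_cols):
    """Weir & Cockerham (1984) theta-hat, ratio of summed components."""
    num_sum = 0.0
    den_sum = 0.0
    any_site = False
    r = 2
    for j in site_cols:
        stats = []
        ok = True
        for rows in (rows_a, rows_b):
            ds = [int(genotypes[rr, j]) for rr in rows
                  if int(genotypes[rr, j]) != MISSING]
            if len(ds) < 2:
                ok = False
                break
            n_i = len(ds)
            p_i = sum(ds) / (2.0 * n_i)
            h_i = sum(1 for d in ds if d == 1) / n_i
            stats.append((n_i, p_i, h_i))
        if not ok:
            continue
        (n1, p1, h1), (n2, p2, h2) = stats
        n_bar = (n1 + n2) / 2.0
        n_c = (r * n_bar - (n1 * n1 + n2 * n2) / (r * n_bar)) / (r - 1)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4.0)
            / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - s2 * (r - 1) / r
            - h_bar * (2 * n_bar - 1) / (4 * n_bar)
        )
        c = h_bar / 2.0
        if a + b + c != 0:
            any_site = True
        num_sum += a
        den_sum += a + b + c
    if not any_site or den_sum == 0:
        return None
    return num_sum / den_sum


def tajimas_d_direct(S, pi_sum, n):
    """Tajima (1989) D evaluated straight from the published constants."""
    if S == 0:
        return None
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi_sum - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def tajd_window(genotypes, pop_rows, site_cols):
    """Window Tajima's D with n = 2 x population size, via allele counts."""
    S = 0
    pi_sum = 0.0
    for j in site_cols:
        alleles = called_alleles(genotypes[:, j], pop_rows)
        n = len(alleles)
        if n < 2:
            continue
        c1 = sum(alleles)
        if 0 < c1 < n:
            S += 1
            diff = 0
            pairs = 0
            for a in range(n):
                for b in range(a + 1, n):
                    pairs += 1
                    if alleles[a] != alleles[b]:
                        diff += 1
            pi_sum += diff / pairs
    return tajimas_d_direct(S, pi_sum, 2 * len(pop_rows))


def r2_pair(genotypes, pop_rows, site_i, site_j):
    """Squared Pearson correlation of dosages on pairwise-complete cases."""
    xs, ys = [], []
    for r in pop_rows:
        x = int(genotypes[r, site_i])
        y = int(genotypes[r, site_j])
        if x != MISSING and y != MISSING:
            xs.append(x)
            ys.append(y)
    n = len(xs)
    if n < 2:
        return None
    mx = sum(xs) / n
    my = sum(ys) / n
    sxx = sum((x - mx) ** 2 for x in xs)
    syy = sum((y - my) ** 2 for y in ys)
    if sxx == 0 or syy == 0:
        return None
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    return (sxy * sxy) / (sxx * syy)


def site_f4_direct(genotypes, rows, site, max_missing_frac=0.10):
    """(p1-p2)(p3-p4) from per-population frequencies; None if unusable."""
    freqs = []
    for pop_rows in rows:
        f = freq_or_none(genotypes[:, site], pop_rows, max_missing_frac)
        if f is None:
            return None
        freqs.append(f)
    return (freqs[0] - freqs[1]) * (freqs[2] - freqs[3])
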