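"""Goodness-of-fit tests of hybrid genotype-class expectations.

At SNPs fixed between two parental populations, a putative hybrid's
genotype falls into one of three classes: homozygous for the P1 allele,
heterozygous, or homozygous for the P2 allele.  Mendelian expectations are
F1 (0, 1, 0), F2 (1/4, 1/2, 1/4), and backcrosses (1/2, 1/2, 0) or
(0, 1/2, 1/2).  Counts are pooled over individuals and diagnostic sites by
default, matching a single genome-wide test; note that linkage makes
pooled counts non-independent, so a per-individual mode is also offered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model import MISSING, PopulationMap, VariantTable
from .popgen import DEFAULT_MAX_MISSING, pop_frequencies

HYBRID_CLASSES = ("F1", "F2", "BC_P1", "BC_P2")

#: Numerical floor for reported p-values.
P_FLOOR = 1e-300


def expected_proportions(hybrid_class: str) -> tuple[float, float, float]:
    """(hom P1, het, hom P2) expectations for a hybrid class."""
    table = {
        "F1": (0.0, 1.0, 0.0),
        "F2": (0.25, 0.5, 0.25),
        "BC_P1": (0.5, 0.5, 0.0),
        "BC_P2": (0.0, 0.5, 0.5),
    }
    try:
        return table[hybrid_class]
    except KeyError:
        raise ValueError(
            f"unknown hybrid class {hybrid_class!r}; expected one of "
            f"{HYBRID_CLASSES}"
        ) from None


@dataclass
class GenotypeClassCounts:
    """Pooled genotype-class counts of hybrids at diagnostic sites."""

    n_hom_p1: int
    n_het: int
    n_hom_p2: int
    n_sites: int
    n_individuals: int

    @property
    def total(self) -> int:
        return self.n_hom_p1 + self.n_het + self.n_hom_p2

    def as_array(self) -> np.ndarray:
        return np.array([self.n_hom_p1, self.n_het, self.n_hom_p2], dtype=float)


def genotype_class_counts(
    table: VariantTable,
    popmap: PopulationMap,
    parental_a: str,
    parental_b: str,
    hybrids: list[str],
    diagnostic_sites: np.ndarray,
    max_missing_frac: float = DEFAULT_MAX_MISSING,
    per_individual: bool = False,
):
    """Classify hybrid genotypes at sites fixed between the parents.

    *diagnostic_sites* are site indices (e.g. from
    :func:`introscan.popgen.fixed_diff_sites`).  Each called hybrid
    genotype is classified by which parental allele(s) it carries; missing
    genotypes are excluded.  Returns pooled counts, or a dict of per-sample
    counts with ``per_individual``.
    """
    diagnostic_sites = np.asarray(diagnostic_sites, dtype=np.intp)
    if diagnostic_sites.size == 0:
        raise ValueError("empty diagnostic site set")
    idx_a = popmap.indices(table.sample_ids, parental_a)
    pa = pop_frequencies(table.genotypes, idx_a, max_missing_frac)[diagnostic_sites]
    if np.isnan(pa).any() or not np.isin(pa, (0.0, 1.0)).all():
        raise ValueError(
            "diagnostic sites must be fixed in the parental populations"
        )
    hybrid_rows = [table.sample_index(h) for h in hybrids]
    # dosage of the P1 allele per hybrid genotype: alt dosage if P1 is fixed
    # alt, else 2 - alt dosage
    per_sample: dict[str, GenotypeClassCounts] = {}
    for h, row in zip(hybrids, hybrid_rows):
        geno = table.genotypes[row, diagnostic_sites].astype(np.int64)
        called = geno != MISSING
        p1_dosage = np.where(pa == 1.0, geno, 2 - geno)[called]
        per_sample[h] = GenotypeClassCounts(
            n_hom_p1=int((p1_dosage == 2).sum()),
            n_het=int((p1_dosage == 1).sum()),
            n_hom_p2=int((p1_dosage == 0).sum()),
            n_sites=int(diagnostic_sites.size),
            n_individuals=1,
        )
    if per_individual:
        return per_sample
    return GenotypeClassCounts(
        n_hom_p1=sum(c.n_hom_p1 for c in per_sample.values()),
        n_het=sum(c.n_het for c in per_sample.values()),
        n_hom_p2=sum(c.n_hom_p2 for c in per_sample.values()),
        n_sites=int(diagnostic_sites.size),
        n_individuals=len(hybrids),
    )


@dataclass
class GofResult:
    """Chi-square goodness-of-fit outcome for one hybrid-class hypothesis."""

    chi2: float
    df: int
    p_value: float
    expected_proportions: tuple[float, float, float]
    hybrid_class: str
    floored: bool = False          # p reported at the numerical floor
    impossible_class: bool = False  # observations in a zero-expectation class


def chisq_gof(counts: GenotypeClassCounts, hybrid_class: str) -> GofResult:
    """Chi-square test of observed class counts against a hybrid class.

    Classes with zero expectation are dropped from the statistic and the
    degrees of freedom (df = nonzero classes - 1); a nonzero observation in
    a zero-expectation class makes the hypothesis impossible and is
    reported as a rejection at the numerical p floor with a flag.
    """
    obs = counts.as_array()
    total = obs.sum()
    if total == 0:
        raise ValueError("no called genotypes to test")
    props = np.array(expected_proportions(hybrid_class))
    nonzero = props > 0
    if obs[~nonzero].sum() > 0:
        return GofResult(
            chi2=float("inf"),
            df=int(nonzero.sum()) - 1,
            p_value=P_FLOOR,
            expected_proportions=tuple(props),
            hybrid_class=hybrid_class,
            floored=True,
            impossible_class=True,
        )
    expected = props[nonzero] * total
    chi2 = float(((obs[nonzero] - expected) ** 2 / expected).sum())
    df = int(nonzero.sum()) - 1
    p = float(stats.chi2.sf(chi2, df))
    floored = p < P_FLOOR
    return GofResult(
        chi2=chi2,
        df=df,
        p_value=max(p, P_FLOOR),
        expected_proportions=tuple(props),
        hybrid_class=hybrid_class,
        floored=floored,
    )
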