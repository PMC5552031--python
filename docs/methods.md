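# Methods

This note documents the models behind `introscan`, the defaults and why
they are set where they are, what the synthetic-data generator does and
does not emulate, and the numerical conventions that matter when comparing
output against other tools.

## Data model and conventions

Genotypes are unphased alt-allele dosages (0/1/2) per diploid with a
MISSING sentinel; phase in the GT field is ignored because no statistic
here uses it. VCF positions remain 1-based; all window arithmetic is
0-based half-open, centralized in `introscan.model`. Windows are
non-overlapping, anchored at position 0 of each scaffold, default length
10 kb; the final partial window keeps its true length so per-bp
denominators stay honest. Only biallelic SNPs are retained on input;
records failing FILTER are kept by default on the assumption of a
pre-filtered call set (a flag drops them).

A population's allele frequency at a site uses called genotypes only and
is *undefined* when more than 10% of that population's genotypes are
missing at the site (`max_missing_frac = 0.10`). Undefined sites are
skipped by every estimator — never imputed, never zeroed. With
single-individual populations this rule means one missing genotype
undefines the site for that population, which is the intended, conservative
behaviour.

## Window estimators

* **π** — sum over usable sites of `c_alt * c_ref / C(n, 2)` on called
  allele counts, divided by the window length in bp. This is the unbiased
  pairwise estimator (not `2p(1-p)`), matching the common VCF-toolkit
  convention.
* **Dxy** — sum over sites of `pA(1-pB) + pB(1-pA)` divided by the full
  window length. A variants-only VCF omits invariant positions, so using
  the window length as denominator treats every non-record position as
  invariant; because truly missing (unalignable) regions are also counted
  as invariant, Dxy is a mild underestimate on sparse data. A
  `per_site_denominator` flag computes the uncorrected variant-sites-only
  version for comparison.
* **Fst** — Weir & Cockerham (1984) θ̂ for two populations. The window
  estimate is the ratio of summed variance components Σa / Σ(a+b+c)
  (the "weighted" convention), not a mean of per-site ratios; per-site
  values may be negative, and sites need ≥2 called genotypes in each
  population to contribute.
* **Tajima's D** — Tajima (1989), `D = (π_sum − S/a1) / sqrt(e1·S +
  e2·S(S−1))`. The window version counts a site as segregating when called
  genotypes show both alleles and uses `n = 2 × (population size in
  diploids)` for the constants, ignoring per-site missingness; on
  incomplete data this biases D slightly (the synthetic tests use
  near-complete data). D is undefined (NaN) when S = 0 and requires n ≥ 4
  haplotypes.
* **r²** — squared Pearson correlation of dosage vectors on
  pairwise-complete individuals; zero-variance sites are skipped. The decay
  curve is the mean r² per distance bin (default 10-kb bins).

All five estimators are verified against brute-force enumeration oracles
(explicit allele-pair counting, direct textbook formulas) on 1,000 random
missing-data matrices to 1e-12 in the test suite.

## The f4 scan

Site f4 is `(p1 − p2)(p3 − p4)` on alt-allele frequencies for the tree
((P1, P2), (P3, P4)); by allele-coding invariance (p → 1−p in all four
populations leaves the product unchanged, property-tested) the choice of
alt vs ref is immaterial. A window's value is the mean over usable sites,
reported only when ≥ `min_sites` (default 50) sites are usable. The
genome-wide mean gets a standard error from a **delete-one block
jackknife** (weighted delete-mⱼ form for unequal block sizes), blocks =
scaffolds by default or fixed-size bp blocks when scaffolds are few;
Z = mean/SE with a two-sided normal p. The jackknife was chosen because it
is the standard variance estimator for f-statistics under linkage; at least
20 blocks are required, and an SE of exactly 0 (all usable sites identical)
is reported as a degenerate result rather than an infinite Z.

### Permutation null

Individuals from the four focal populations are reshuffled among them
without replacement, preserving population sizes and leaving all other
samples untouched; all window f4 values are recomputed per permutation
(default B = 1,000; the type-I calibration uses B = 200 to fit its time
budget). Two devices are derived:

* **pooled thresholds** — the 1%/99% quantiles of all permuted window
  values pooled across permutations and windows; observed windows outside
  them are significant at a two-tailed α = 0.02. On exchangeable data the
  flagged fraction is 0.02 within binomial error (verified).
* **per-window p** — directional with add-one correction:
  k counts permutations with a value at least as extreme as the observed
  one in its own direction (ties count as exceeding), p = (k+1)/(B+1), so
  B = 1,000 gives a floor of ≈0.001. Because the count is directional,
  p lives on (0, ½]; on exchangeable data 2p is uniform (verified by KS).
  A `pooled` option compares against the pooled null instead.

The two devices can disagree at genuinely introgressed windows: permuting
labels there keeps the outlier haplotypes in the dataset, so the window's
own permuted values are inflated and the per-window p is conservative,
while the pooled thresholds — dominated by the genome's background windows
— still flag the window. Region flagging therefore uses the pooled
thresholds; the per-window p is reported alongside.

Permutation RNG streams are spawned independently per permutation index
from the seed, so results are reproducible and order-independent.

## Coalescent simulator

A Hudson coalescent with time in units of 4N₀ generations: within a
population of relative size x each lineage pair coalesces at rate 2/x (a
sample of two in a constant-size population has E[TMRCA] = 0.5). Events,
applied in increasing time order (list order at equal times):
`size_change` (-eN/-en), `join` (-ej: all source lineages move to the
destination), and `pulse` (-ev: each source lineage moves independently
with the given probability). Configurations whose sampled populations can
never fully merge are rejected up front. There is no recombination within
loci — consistent with treating 10-kb windows as single loci — and no
continuous migration.

Mutations follow the infinite-sites model: either exactly S per locus on
branches chosen proportionally to length, S drawn uniformly from a
configured range, or Poisson with mean θ × (total tree length in 4N₀
units), which yields the Watterson/ms expectation E[S] = θ·a1(n) at
constant size (calibrated in tests, and cross-validated distributionally
against msprime by KS at α = 0.01).

### Tajima's D sweep null

The null demography is a 100-fold population crash at t = 0.8
(`size_change(0.8, 0.01)`, ≈10 kya for this system) together with an
admixture pulse of fraction 0.1 and a coincident population join at the
same time, with the pulse applied before the join so the join cannot
silently erase it. With all sampled lineages in the focal population and
both events at the same instant, the pulse is distributionally inert and
the strong negative skew of the null comes from the bottleneck — consistent
with the observation that the null is robust to the pulse fraction. S per
locus is drawn uniformly from (50, s_max) — uniform because no distribution
is implied by "variable", documented and configurable; s_max defaults to
300, a realistic ceiling for variant counts in 10-kb windows of this data
type. The sweep threshold is the ⌈tail·m⌉-ranked smallest simulated D
(default tail 2%), excluding undefined loci. Default null size is 10,000
loci, which stabilizes the 2% quantile to ±0.02 while keeping runtime in
seconds; scale up for production scans.

## Synthetic studies

`simulate_study` emulates the motivating sampling design: recipient
specialist (14 diploids), sister specialist (13), and single-individual
donor and far outgroup, on a species tree ((recipient, sister), (donor,
far)) with splits at 0.7 / 2.0 / 4.0 coalescent units. Outgroup populations
run at relative size 0.3, which makes a single sampled individual
reasonably representative and matches the low divergence observed between
introgressed haplotypes and their donor population. Per 10-kb window,
θ = 25 (≈250 segregating sites over the whole sample, π within populations
≈10⁻³ — the right order for a young radiation sequenced at modest depth),
positions uniform within the window, haplotypes paired into diploids, and
2% MCAR missing genotypes.

Window regimes:

* **neutral** — species tree only; windowed f4 averages 0 (verified).
* **introgressed** — donor→recipient pulse at t = 0.6 (just inside the
  radiation's founding) with fraction 0.6.
* **introgressed_swept** — the pulse at fraction 1.0 followed by a hard
  sweep, emulated genealogically: the recipient's size crashes to 10⁻⁴
  during t ∈ [0.05, 0.06], forcing near-complete coalescence of its
  lineages, whose single ancestral lineage then joins the donor population
  at the pulse. This produces the sweep-plus-introgression signature
  package: π and Tajima's D collapse in the recipient, tens to hundreds of
  SNPs fixed against the sister, and Dxy(recipient, donor) ≈ 0.15 × the
  background focal–donor divergence.
* **swept_only** — the crash without the pulse.

What the generator does **not** emulate: recombination within windows and
linkage between windows (every window is an independent locus, so
block-jackknife SEs on synthetic data are optimistic), sequencing error,
non-random missingness, selection simulated forward in time (the
genealogical crash is an approximation to a completed hard sweep), or
reference-bias artefacts. Passing tests on these data therefore demonstrate
the statistical machinery — estimator correctness, null calibration,
signal recovery under the modelled signatures — not robustness to
real-data pathologies.

## Candidate calling and dating

Windows are classified by three booleans (significant f4; Tajima's D below
the sweep-null threshold in ≥1 focal population; ≥1 focal-pair fixed SNP)
into categories I/II/III/IV; the categories are disjoint and, with the
unclassified remainder, partition all windows. Category IV is the candidate
call. An external per-window sweep statistic (e.g. a composite likelihood
ratio computed by another tool) can be supplied to replace or augment the
D-tail flag. Requiring ≥1 fixed SNP implements "contributing to species
divergence" minimally; raise the count for stricter calls.

Donor/recipient assignment is the argmin of window Dxy over focal × donor
pairs; exact ties widen to the mean over ±1 flanking windows, then fall
back to lexicographic order with an explicit tie flag. An optional
low-diversity exclusion drops candidates whose π is below the 5th
percentile in *every* focal population unless corroborated by an
unusually low (below the same percentile) assigned-donor Dxy — an
operationalization of manual screening for f4 outliers caused by low
recombination rather than introgression.

Dating assumes the introgressed haplotype and the donor lineage accumulate
differences neutrally after the transfer: per-site divergence d = 2μt,
so t = d/(2μ) for each mutation-rate bound (defaults 1.32×10⁻⁷ and
5.37×10⁻⁷ site⁻¹yr⁻¹ — a pedigree-derived and a phylogeny-derived rate for
these fishes — and a 6-month generation time). Raw values are
authoritative; a convenience formatter rounds to the nearest 100 years,
and with d = 62/10 kb the bounds are 5,773 and 23,485 years (≈5,800–23,500
rounded).

## Hybrid-ancestry test

Genotype classes at parent-diagnostic SNPs are pooled across individuals
and sites into a single chi-square goodness-of-fit test (df = nonzero
expectation classes − 1: 2 for F1/F2, 1 for backcrosses). Pooling matches
the single genome-wide test design, but linkage makes pooled counts
non-independent, so the p-value is anti-conservative on real data; a
per-individual mode is provided. Observations in a zero-expectation class
(e.g. homozygotes under F1) make the hypothesis impossible and are reported
as a rejection at the numerical floor (10⁻³⁰⁰) with flags rather than as a
computed statistic.

## Problem sizes and numerical notes

Default test/calibration sizes: 10,000 loci for coalescent calibration and
sweep nulls; ≥500–1,000 windows with B = 200 permutations for type-I
calibration; 2,000 windows with 20 planted signals for end-to-end recovery;
1,000 random matrices for oracle equivalence. These sizes put Monte-Carlo
error well inside the asserted tolerances while keeping the full suite in
minutes; production scans should use B = 1,000 and ≥100,000 null loci.

Quantiles use numpy's default (linear interpolation) except the sweep-null
threshold, which is the exact ⌈tail·m⌉ order statistic. Empirical p-values
use add-one correction to avoid zeros. The frequency missing-rule
comparison uses a 1e-12 tolerance so a population with exactly the
threshold missing fraction (e.g. 1 of 10 genotypes) is kept. Jackknife
variance uses the weighted delete-mⱼ formula, which reduces to the standard
delete-one form for equal blocks.

## Known limitations

* No recombination anywhere in the coalescent machinery; LD within windows
  of real data will make window statistics noisier than the simulator
  suggests.
* Dxy's invariant-site correction treats unalignable regions as invariant,
  biasing Dxy downward on low-coverage data.
* Tajima's D with the fixed-n convention is slightly biased under per-site
  missingness.
* The f4 permutation null requires exchangeability of individuals under
  the no-introgression hypothesis; strong within-population structure
  (e.g. family sampling) would inflate the null's width.
* Single-individual donor populations make frequency estimates at those
  tips coarse (0, ½, 1); the scan tolerates this by design but donor
  assignment in short windows is correspondingly noisy.
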