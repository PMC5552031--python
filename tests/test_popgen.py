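import math

import numpy as np
import pytest

import oracles
from conftest import random_variant_table
from introscan import (
    MISSING,
    PopulationMap,
    VariantTable,
    fixed_diff_sites,
    pairwise_r2,
    site_frequencies,
    tajimas_d,
    weir_cockerham_fst,
    window_dxy,
    window_pi,
    window_tajimas_d,
)


def make_table(genotypes, positions=None, sample_prefix="s"):
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n_samples, n_sites = genotypes.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 10
    return VariantTable(
        scaffold="scf1",
        positions=np.asarray(positions),
        ref=np.full(n_sites, "A"),
        alt=np.full(n_sites, "T"),
        genotypes=genotypes,
        sample_ids=[f"{sample_prefix}{i}" for i in range(n_samples)],
    )


def two_pop_map(n_a, n_b):
    return PopulationMap(
        [(f"s{i}", "A") for i in range(n_a)]
        + [(f"s{n_a + i}", "B") for i in range(n_b)]
    )


class TestSiteFrequencies:
    def test_basic_frequency(self):
        t = make_table([[0], [1], [2]])
        pm = PopulationMap([("s0", "A"), ("s1", "A"), ("s2", "A")])
        sf = site_frequencies(t, pm, 0)
        assert sf.freqs["A"] == pytest.approx(0.5)
        assert sf.n_called["A"] == 3

    def test_missing_rule_threshold(self):
        # 10 individuals, 2 missing: 20% > 10% -> undefined
        geno = [[1]] * 8 + [[MISSING]] * 2
        t = make_table(geno)
        pm = PopulationMap([(f"s{i}", "A") for i in range(10)])
        sf = site_frequencies(t, pm, 0)
        assert math.isnan(sf.freqs["A"])
        # 1 of 10 missing (10%) is allowed
        geno = [[2]] * 9 + [[MISSING]]
        sf = site_frequencies(make_table(geno), pm, 0)
        assert sf.freqs["A"] == pytest.approx(1.0)


class TestFixedDiffs:
    def test_reciprocal_fixation_required(self):
        # site0: fixed 2 vs 0; site1: 0.95-ish vs 0; site2: A undefined
        geno_a = [[2, 2, 2], [2, 2, MISSING], [2, 1, MISSING]]
        geno_b = [[0, 0, 0], [0, 0, 0], [0, 0, 0]]
        t = make_table(geno_a + geno_b)
        pm = two_pop_map(3, 3)
        assert list(fixed_diff_sites(t, pm, "A", "B")) == [0]

    def test_symmetric_in_direction(self):
        geno = [[0], [0], [2], [2]]
        t = make_table(geno)
        pm = two_pop_map(2, 2)
        assert list(fixed_diff_sites(t, pm, "A", "B")) == [0]
        assert list(fixed_diff_sites(t, pm, "B", "A")) == [0]


class TestFst:
    def test_reciprocally_fixed_site_is_one(self):
        geno = [[2]] * 20 + [[0]] * 20
        t = make_table(geno)
        pm = two_pop_map(20, 20)
        per_site, window = weir_cockerham_fst(t, pm, "A", "B")
        assert window == pytest.approx(1.0)
        assert per_site[0] == pytest.approx(1.0)

    def test_identical_populations_near_zero(self):
        block = [[0], [1], [2], [1], [0], [2], [1], [1]]
        t = make_table(block + block)
        pm = two_pop_map(8, 8)
        _, window = weir_cockerham_fst(t, pm, "A", "B")
        # identical frequencies and sizes: near zero, slightly negative
        assert -0.1 <= window <= 0.02

    def test_no_usable_sites_gives_missing(self):
        t = make_table([[MISSING], [MISSING], [0], [0]])
        pm = two_pop_map(2, 2)
        _, window = weir_cockerham_fst(t, pm, "A", "B")
        assert math.isnan(window)


class TestPi:
    def test_monomorphic_window_is_zero(self):
        t = make_table([[0, 2], [0, 2], [0, 2]])
        pm = PopulationMap([(f"s{i}", "A") for i in range(3)])
        assert window_pi(t, pm, "A", (0, 100), 100) == 0.0

    def test_hand_counted_single_site(self):
        # 2 diploids, dosages 1 and 1 -> alleles 2 alt / 2 ref of 4:
        # pairs differing = 2*2 = 4 of C(4,2)=6 -> pi = (4/6)/10
        t = make_table([[1], [1]])
        pm = PopulationMap([("s0", "A"), ("s1", "A")])
        assert window_pi(t, pm, "A", (0, 10), 10) == pytest.approx(4 / 6 / 10)

    def test_additive_over_sites(self):
        t = make_table([[1, 1], [1, 1]], positions=[3, 7])
        pm = PopulationMap([("s0", "A"), ("s1", "A")])
        assert window_pi(t, pm, "A", (0, 10), 10) == pytest.approx(2 * 4 / 6 / 10)

    def test_invalid_window_length(self, small_table, small_popmap):
        with pytest.raises(ValueError, match="positive"):
            window_pi(small_table, small_popmap, "A", (0, 10), 0)


class TestDxy:
    def test_reciprocally_fixed_site(self):
        t = make_table([[2], [2], [0], [0]])
        pm = two_pop_map(2, 2)
        assert window_dxy(t, pm, "A", "B", (0, 10), 10) == pytest.approx(0.1)

    def test_shared_intermediate_frequency(self):
        t = make_table([[1], [1], [1], [1]])
        pm = two_pop_map(2, 2)
        # pA = pB = 0.5 -> 2*0.5*0.5/10
        assert window_dxy(t, pm, "A", "B", (0, 10), 10) == pytest.approx(0.05)

    def test_symmetry_in_populations(self, rng):
        t = random_variant_table(rng)
        pm = two_pop_map(3, 3)
        d_ab = window_dxy(t, pm, "A", "B", (0, 10_000), 10_000)
        d_ba = window_dxy(t, pm, "B", "A", (0, 10_000), 10_000)
        assert d_ab == pytest.approx(d_ba, abs=1e-15)


class TestTajimasD:
    def test_no_segregating_sites_is_missing(self):
        assert math.isnan(tajimas_d(0, 0.0, 10))

    def test_known_small_case(self):
        # n=4, S=3, pi_sum=1.5: a1=11/6 -> D = -0.7545 (direct evaluation)
        assert tajimas_d(3, 1.5, 4) == pytest.approx(-0.754451, abs=1e-5)

    def test_zero_when_estimators_agree(self):
        n = 8
        a1 = sum(1.0 / i for i in range(1, n))
        assert tajimas_d(5, 5 / a1, n) == pytest.approx(0.0, abs=1e-12)

    def test_too_few_haplotypes_rejected(self):
        with pytest.raises(ValueError, match="4 haplotypes"):
            tajimas_d(3, 1.0, 3)

    def test_window_version_invariant_to_sample_order(self, rng):
        t = random_variant_table(rng, n_samples=6, missing_rate=0.0)
        pm = PopulationMap([(f"s{i}", "A") for i in range(6)])
        d1 = window_tajimas_d(t, pm, "A")
        order = rng.permutation(6)
        t2 = VariantTable(
            scaffold=t.scaffold,
            positions=t.positions,
            ref=t.ref,
            alt=t.alt,
            genotypes=t.genotypes[order, :],
            sample_ids=[t.sample_ids[i] for i in order],
        )
        assert window_tajimas_d(t2, pm, "A") == pytest.approx(d1, abs=1e-12)

    def test_window_position_does_not_matter(self, rng):
        t = random_variant_table(rng, n_samples=4, missing_rate=0.0)
        pm = PopulationMap([(f"s{i}", "A") for i in range(4)])
        shifted = VariantTable(
            scaffold=t.scaffold,
            positions=t.positions + 50_000,
            ref=t.ref,
            alt=t.alt,
            genotypes=t.genotypes,
            sample_ids=t.sample_ids,
        )
        d1 = window_tajimas_d(t, pm, "A", (0, 20_000))
        d2 = window_tajimas_d(shifted, pm, "A", (50_000, 70_000))
        assert d1 == pytest.approx(d2, abs=1e-12)


class TestFstRangeOnSimulatedData:
    def test_window_fst_within_expected_band(self, planted_study):
        """On coalescent-simulated diploid data the window Fst stays within
        [-0.1, 1]."""
        _, tables, popmap, truth, _ = planted_study
        t = tables[0]
        values = []
        for start in range(0, 100_000, 10_000):
            _, fst = weir_cockerham_fst(
                t, popmap, "recipient", "sister", (start, start + 10_000)
            )
            if not math.isnan(fst):
                values.append(fst)
        assert values
        assert all(-0.1 <= v <= 1.0 for v in values)


class TestPairwiseR2:
    def test_duplicated_site_gives_one(self):
        t = make_table([[0, 0], [1, 1], [2, 2], [1, 1]])
        pm = PopulationMap([(f"s{i}", "A") for i in range(4)])
        res = pairwise_r2(t, pm, "A")
        assert res.r2[0] == pytest.approx(1.0)

    def test_independent_sites_near_zero(self, rng):
        n = 400
        x = rng.integers(0, 3, size=n)
        y = rng.permutation(x)
        geno = np.stack([x, y], axis=1).astype(np.int8)
        t = make_table(geno)
        pm = PopulationMap([(f"s{i}", "A") for i in range(n)])
        res = pairwise_r2(t, pm, "A")
        assert res.r2[0] < 0.05

    def test_zero_variance_site_skipped(self):
        t = make_table([[0, 1], [0, 2], [0, 0]])
        pm = PopulationMap([(f"s{i}", "A") for i in range(3)])
        res = pairwise_r2(t, pm, "A")
        assert res.r2.size == 0

    def test_matches_direct_correlation(self, rng):
        t = random_variant_table(rng, n_samples=8)
        pm = PopulationMap([(f"s{i}", "A") for i in range(8)])
        res = pairwise_r2(t, pm, "A")
        rows = list(range(8))
        # rebuild the kept pair list to compare against the oracle
        kept = 0
        for i in range(t.n_sites):
            for j in range(i + 1, t.n_sites):
                expected = oracles.r2_pair(t.genotypes, rows, i, j)
                if expected is None:
                    continue
                assert res.r2[kept] == pytest.approx(expected, abs=1e-12)
                kept += 1
        assert kept == res.r2.size


class TestOracleAgreement:
    """Vectorized estimators equal explicit enumeration on random data."""

    @pytest.mark.parametrize("trial", range(25))
    def test_all_estimators(self, trial):
        rng = np.random.default_rng(9000 + trial)
        n_a = int(rng.integers(2, 6))
        n_b = int(rng.integers(2, 6))
        t = random_variant_table(rng, n_samples=n_a + n_b, max_sites=30)
        pm = two_pop_map(n_a, n_b)
        rows_a = list(range(n_a))
        rows_b = list(range(n_a, n_a + n_b))
        sites = list(range(t.n_sites))
        L = 10_000.0
        win = (0, 10_000)

        assert window_pi(t, pm, "A", win, L) == pytest.approx(
            oracles.pi_window(t.genotypes, rows_a, sites, L), abs=1e-12
        )
        assert window_dxy(t, pm, "A", "B", win, L) == pytest.approx(
            oracles.dxy_window(t.genotypes, rows_a, rows_b, sites, L), abs=1e-12
        )
        expected_fst = oracles.wc_fst_window(t.genotypes, rows_a, rows_b, sites)
        _, got_fst = weir_cockerham_fst(t, pm, "A", "B", win)
        if expected_fst is None:
            assert math.isnan(got_fst)
        else:
            assert got_fst == pytest.approx(expected_fst, abs=1e-12)
        # range invariants (Fst's soft lower bound is checked on
        # coalescent-simulated data, where genotypes are HWE-like)
        pi_val = window_pi(t, pm, "A", win, L)
        dxy_val = window_dxy(t, pm, "A", "B", win, L)
        assert 0.0 <= pi_val <= 1.0
        assert 0.0 <= dxy_val <= 1.0
        assert got_fst <= 1.0 + 1e-12 or math.isnan(got_fst)
        expected_d = oracles.tajd_window(t.genotypes, rows_a, sites)
        got_d = window_tajimas_d(t, pm, "A", win)
        if expected_d is None:
            assert math.isnan(got_d)
        else:
            assert got_d == pytest.approx(expected_d, abs=1e-12)
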