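import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from introscan import (
    F4Config,
    PopulationMap,
    VariantTable,
    f4_diversity_diagnostic,
    genome_f4,
    site_f4,
    window_f4,
)
from introscan.f4 import site_f4_array


def four_pop_map(sizes=(2, 2, 2, 2)):
    names = ["P1", "P2", "P3", "P4"]
    pairs = []
    k = 0
    for name, n in zip(names, sizes):
        for _ in range(n):
            pairs.append((f"s{k}", name))
            k += 1
    return PopulationMap(pairs)


def table_from_geno(geno, positions=None):
    geno = np.asarray(geno, dtype=np.int8)
    n_samples, n_sites = geno.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1)
    return VariantTable(
        scaffold="scf1",
        positions=np.asarray(positions),
        ref=np.full(n_sites, "A"),
        alt=np.full(n_sites, "T"),
        genotypes=geno,
        sample_ids=[f"s{i}" for i in range(n_samples)],
    )


class TestSiteF4:
    @pytest.mark.parametrize(
        "freqs,expected",
        [
            ((0.5, 0.5, 0.2, 0.9), 0.0),
            ((1.0, 0.0, 1.0, 0.0), 1.0),
            ((0.8, 0.2, 0.1, 0.7), -0.36),
        ],
    )
    def test_arithmetic(self, freqs, expected):
        assert site_f4(*freqs) == pytest.approx(expected)

    def test_undefined_frequency_is_nan(self):
        assert math.isnan(site_f4(float("nan"), 0.5, 0.5, 0.5))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        p=st.tuples(*[st.floats(0, 1) for _ in range(4)]),
    )
    def test_antisymmetry_and_coding_invariance(self, p):
        p1, p2, p3, p4 = p
        v = site_f4(p1, p2, p3, p4)
        assert site_f4(p2, p1, p3, p4) == pytest.approx(-v, abs=1e-12)
        assert site_f4(p1, p2, p4, p3) == pytest.approx(-v, abs=1e-12)
        assert site_f4(p2, p1, p4, p3) == pytest.approx(v, abs=1e-12)
        # ref/alt recoding flips every frequency
        assert site_f4(1 - p1, 1 - p2, 1 - p3, 1 - p4) == pytest.approx(
            v, abs=1e-12
        )


class TestWindowF4:
    def test_min_sites_threshold(self, rng):
        # 49 usable sites with min 50 -> missing; 50 -> defined
        pm = four_pop_map()
        for n_sites, defined in [(49, False), (50, True)]:
            geno = rng.integers(0, 3, size=(8, n_sites)).astype(np.int8)
            t = table_from_geno(geno)
            cfg = F4Config("P1", "P2", "P3", "P4", window_size=1000, min_sites=50)
            out = window_f4(t, pm, cfg)
            assert len(out) == 1
            assert out.n_usable_sites[0] == n_sites
            assert np.isfinite(out.f4[0]) == defined

    def test_equal_p1_p2_gives_zero(self):
        pm = four_pop_map()
        # P1 and P2 identical columns at every site
        geno = np.array(
            [[2, 0], [0, 2], [2, 0], [0, 2], [2, 2], [0, 0], [1, 1], [2, 0]],
            dtype=np.int8,
        )
        t = table_from_geno(geno)
        cfg = F4Config("P1", "P2", "P3", "P4", window_size=1000, min_sites=1)
        out = window_f4(t, pm, cfg)
        assert out.f4[0] == pytest.approx(0.0, abs=1e-12)

    def test_sites_with_undefined_population_skipped(self):
        pm = four_pop_map()
        geno = np.zeros((8, 2), dtype=np.int8)
        geno[:, 1] = 1
        geno[6, 0] = -1  # P4 sample missing -> 50% missing in P4 at site 0
        t = table_from_geno(geno)
        vals = site_f4_array(t, pm, F4Config("P1", "P2", "P3", "P4"))
        assert math.isnan(vals[0]) and np.isfinite(vals[1])


class TestGenomeF4:
    def _tables(self, rng, n_scaffolds=25, n_sites=30):
        tables = []
        for s in range(n_scaffolds):
            geno = rng.integers(0, 3, size=(8, n_sites)).astype(np.int8)
            t = table_from_geno(geno)
            tables.append(
                VariantTable(
                    scaffold=f"scf{s}",
                    positions=t.positions,
                    ref=t.ref,
                    alt=t.alt,
                    genotypes=t.genotypes,
                    sample_ids=t.sample_ids,
                )
            )
        return tables

    def test_sign_flip_negates_z(self, rng):
        tables = self._tables(rng)
        pm = four_pop_map()
        a = genome_f4(tables, pm, F4Config("P1", "P2", "P3", "P4"))
        b = genome_f4(tables, pm, F4Config("P1", "P2", "P4", "P3"))
        assert b.mean == pytest.approx(-a.mean, abs=1e-12)
        assert b.z == pytest.approx(-a.z, abs=1e-9)

    def test_degenerate_constant_f4_flagged(self):
        pm = four_pop_map()
        tables = []
        for s in range(25):
            geno = np.array(
                [[2, 2], [2, 2], [0, 0], [0, 0],
                 [2, 2], [2, 2], [0, 0], [0, 0]],
                dtype=np.int8,
            )
            t = table_from_geno(geno)
            tables.append(
                VariantTable(
                    scaffold=f"scf{s}", positions=t.positions, ref=t.ref,
                    alt=t.alt, genotypes=t.genotypes, sample_ids=t.sample_ids,
                )
            )
        res = genome_f4(tables, pm, F4Config("P1", "P2", "P3", "P4"))
        assert res.degenerate and res.mean == pytest.approx(1.0)

    def test_too_few_blocks_rejected(self, rng):
        tables = self._tables(rng, n_scaffolds=5)
        pm = four_pop_map()
        with pytest.raises(ValueError, match="blocks"):
            genome_f4(tables, pm, F4Config("P1", "P2", "P3", "P4"))


class TestDiversityDiagnostic:
    def _windows(self, f4, pi, scaffolds):
        return pd.DataFrame(
            {"scaffold": scaffolds, "start": 0, "end": 10_000, "f4": f4, "pi": pi}
        )

    def test_constant_f4_reported_missing(self):
        w = self._windows(
            [0.1] * 9, [0.01, 0.02, 0.03] * 3,
            ["a"] * 3 + ["b"] * 3 + ["c"] * 3,
        )
        res = f4_diversity_diagnostic(w)
        assert math.isnan(res.r_scaffold_var_vs_pi)

    def test_independent_pi_gives_small_r(self, rng):
        n = 300
        scafs = [f"s{i % 20}" for i in range(n)]
        f4 = rng.normal(0, 0.05, n)
        pi = rng.permutation(rng.uniform(0.001, 0.01, n))
        res = f4_diversity_diagnostic(self._windows(f4, pi, scafs))
        assert abs(res.r_window_f4_vs_pi) < 0.2

    def test_low_diversity_scaffolds_with_inflated_variance(self, rng):
        # construct scaffolds where low pi comes with high f4 variance
        rows = []
        for s in range(12):
            pi = 0.001 + 0.001 * s
            spread = 0.2 / (1 + s)
            for w in range(20):
                rows.append(
                    {"scaffold": f"scf{s}", "start": w * 10_000,
                     "end": (w + 1) * 10_000,
                     "f4": rng.normal(0, spread), "pi": pi}
                )
        res = f4_diversity_diagnostic(pd.DataFrame(rows))
        assert res.r_scaffold_var_vs_pi < 0

    def test_needs_three_scaffolds(self):
        w = self._windows([0.1, 0.2], [0.01, 0.02], ["a", "b"])
        with pytest.raises(ValueError, match="3 scaffolds"):
            f4_diversity_diagnostic(w)


class TestGenomeZCalibration:
    def test_z_standard_normal_without_gene_flow(self):
        """Across replicate no-gene-flow genomes the jackknife Z is
        approximately standard normal (KS at alpha = 0.01)."""
        from scipy import stats as sps

        from introscan import ScenarioConfig, simulate_study

        zs = []
        for rep in range(200):
            # shallow splits so incomplete lineage sorting makes site f4
            # genuinely variable; no gene flow, so its expectation is 0
            sc = ScenarioConfig(
                pop_sizes={"recipient": 4, "sister": 4, "donor": 2,
                           "far_outgroup": 2},
                n_scaffolds=24, windows_per_scaffold=2,
                theta=20.0, missing_rate=0.0, seed=50_000 + rep,
                t_split_sisters=0.1, t_split_donor=0.2, t_root=0.3,
                t_pulse=0.05, t_sweep_start=0.01, t_sweep_end=0.02,
            )
            tables, pm, _, _ = simulate_study(sc)
            res = genome_f4(
                tables, pm,
                F4Config("recipient", "sister", "donor", "far_outgroup"),
                min_blocks=20,
            )
            if not res.degenerate:
                zs.append(res.z)
        assert len(zs) >= 190
        assert sps.kstest(zs, "norm").pvalue > 0.01

    def test_donor_pulse_gives_positive_z(self):
        """With a genome-wide donor->recipient pulse, Z > 0 in >= 95% of
        replicate genomes (P1<->P3 sharing is the positive sign)."""
        from introscan import ScenarioConfig, simulate_study

        positive = 0
        reps = 100
        for rep in range(reps):
            sc = ScenarioConfig(
                pop_sizes={"recipient": 4, "sister": 4, "donor": 2,
                           "far_outgroup": 2},
                n_scaffolds=24, windows_per_scaffold=1,
                n_introgressed=24,  # every window carries the pulse
                theta=20.0, missing_rate=0.0, seed=60_000 + rep,
                t_split_sisters=0.1, t_split_donor=0.2, t_root=0.3,
                t_pulse=0.05, t_sweep_start=0.01, t_sweep_end=0.02,
                pulse_fraction=0.5,
            )
            tables, pm, _, _ = simulate_study(sc)
            res = genome_f4(
                tables, pm,
                F4Config("recipient", "sister", "donor", "far_outgroup"),
                min_blocks=20,
            )
            positive += (not res.degenerate) and res.z > 0
        assert positive >= 95


class TestNeutralSimulatedF4:
    def test_no_gene_flow_mean_near_zero(self):
        """Windowed f4 averages to ~0 under a four-population tree without
        gene flow (coalescent-simulated windows)."""
        from introscan import ScenarioConfig, observed_window_values, simulate_study

        sc = ScenarioConfig(
            n_scaffolds=10, windows_per_scaffold=25, seed=77, missing_rate=0.0
        )
        tables, pm, truth, _ = simulate_study(sc)
        cfg = F4Config("recipient", "sister", "donor", "far_outgroup")
        _, obs = observed_window_values(tables, pm, cfg)
        obs = obs[np.isfinite(obs)]
        assert obs.size >= 200
        se = obs.std(ddof=1) / math.sqrt(obs.size)
        assert abs(obs.mean()) <= 2 * se + 1e-4
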