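"""Synthetic four-population studies with planted introgression and sweeps.

The generator emulates the sampling design of the pupfish system: a
recipient trophic specialist (14 diploids), its sister specialist (13), and
two single-individual distant outgroups, one of which acts as the
introgression donor.  Windows are simulated independently (no intra-window
recombination) under one of four regimes:

* ``neutral`` — the four-population species tree only,
* ``introgressed`` — a recent donor -> recipient admixture pulse,
* ``introgressed_swept`` — the pulse followed by a hard selective sweep in
  the recipient, emulated genealogically by an extreme transient crash of
  the recipient's population size that forces near-complete coalescence of
  its lineages shortly after the pulse (low pi, strongly negative Tajima's
  D, fixed differences against the sister, low Dxy to the donor),
* ``swept_only`` — the crash without the pulse.

Each window is simulated as one coalescent locus; positions are placed
uniformly within the window, haplotypes are paired into diploids, and
missing genotypes are masked independently (MCAR) at a configurable rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coalescent import DemographyEvent, SimConfig, place_mutations, simulate_genealogy
from .model import MISSING, PopulationMap, ScaffoldIndex, VariantTable

REGIMES = ("neutral", "introgressed", "introgressed_swept", "swept_only")

_NUCS = np.array(list("ACGT"))


@dataclass
class ScenarioConfig:
    """Study layout, species-tree demography, and planted-window regimes.

    Times are coalescent units of 4N0 generations.  The species tree is
    ((recipient, sister), (donor, far_outgroup)) with the recipient/sister
    split at *t_split_sisters*, the donor clade joining at *t_split_donor*,
    and the root at *t_root*.  Introgression is a donor -> recipient pulse
    at *t_pulse*; sweeps crash the recipient's relative size to
    *sweep_size* during [t_sweep_start, t_sweep_end].
    """

    pop_sizes: dict[str, int] = field(
        default_factory=lambda: {
            "recipient": 14, "sister": 13, "donor": 1, "far_outgroup": 1
        }
    )
    n_scaffolds: int = 10
    windows_per_scaffold: int = 20
    window_size: int = 10_000
    n_introgressed: int = 0
    n_introgressed_swept: int = 0
    n_swept_only: int = 0
    theta: float = 25.0
    t_split_sisters: float = 0.7
    t_split_donor: float = 2.0
    t_root: float = 4.0
    t_pulse: float = 0.6
    pulse_fraction: float = 0.6
    t_sweep_start: float = 0.05
    t_sweep_end: float = 0.06
    sweep_size: float = 1e-4
    outgroup_size: float = 0.3
    missing_rate: float = 0.02
    seed: int | None = None

    def __post_init__(self) -> None:
        required = {"recipient", "sister", "donor", "far_outgroup"}
        if set(self.pop_sizes) != required:
            raise ValueError(f"pop_sizes must name exactly {sorted(required)}")
        if any(n <= 0 for n in self.pop_sizes.values()):
            raise ValueError("population sizes must be positive")
        planted = self.n_introgressed + self.n_introgressed_swept + self.n_swept_only
        if planted > self.n_windows:
            raise ValueError("more planted windows than windows in the scenario")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        if not (0.0 < self.t_sweep_start < self.t_sweep_end < self.t_pulse
                < self.t_split_sisters < self.t_split_donor < self.t_root):
            raise ValueError(
                "times must satisfy 0 < sweep start < sweep end < pulse < "
                "sister split < donor split < root"
            )

    @property
    def n_windows(self) -> int:
        return self.n_scaffolds * self.windows_per_scaffold

    @property
    def populations(self) -> list[str]:
        return ["recipient", "sister", "donor", "far_outgroup"]


def _regime_events(config: ScenarioConfig, regime: str) -> list[DemographyEvent]:
    # population indices: 0 recipient, 1 sister, 2 donor, 3 far outgroup
    events = [
        DemographyEvent.size_change(0.0, config.outgroup_size, 2),
        DemographyEvent.size_change(0.0, config.outgroup_size, 3),
        DemographyEvent.join(config.t_split_sisters, 1, 0),
        DemographyEvent.join(config.t_split_donor, 3, 2),
        DemographyEvent.join(config.t_root, 2, 0),
    ]
    if regime in ("introgressed", "introgressed_swept"):
        frac = 1.0 if regime == "introgressed_swept" else config.pulse_fraction
        events.append(DemographyEvent.pulse(config.t_pulse, 0, 2, frac))
    if regime in ("introgressed_swept", "swept_only"):
        events.append(
            DemographyEvent.size_change(config.t_sweep_start, config.sweep_size, 0)
        )
        events.append(DemographyEvent.size_change(config.t_sweep_end, 1.0, 0))
    return sorted(events, key=lambda e: e.time)


def _assign_regimes(config: ScenarioConfig, rng: np.random.Generator) -> list[str]:
    regimes = ["neutral"] * config.n_windows
    planted = (
        ["introgressed"] * config.n_introgressed
        + ["introgressed_swept"] * config.n_introgressed_swept
        + ["swept_only"] * config.n_swept_only
    )
    slots = rng.choice(config.n_windows, size=len(planted), replace=False)
    for slot, regime in zip(slots, planted):
        regimes[int(slot)] = regime
    return regimes


def simulate_study(
    scenario: ScenarioConfig,
) -> tuple[list[VariantTable], PopulationMap, pd.DataFrame, ScaffoldIndex]:
    """Simulate a full study: variant tables, popmap, truth table, lengths.

    The truth table has one row per window with BED-compatible coordinates
    (scaffold, start, end), the planted regime, and the true donor and
    recipient names (NA for windows without introgression).  Identical
    seeds give identical output.
    """
    rng = np.random.default_rng(scenario.seed)
    pops = scenario.populations
    sizes_hap = [2 * scenario.pop_sizes[p] for p in pops]
    sample_ids: list[str] = []
    assignments: list[tuple[str, str]] = []
    for p in pops:
        for k in range(scenario.pop_sizes[p]):
            sid = f"{p}_{k + 1:02d}"
            sample_ids.append(sid)
            assignments.append((sid, p))
    popmap = PopulationMap(assignments)

    regimes = _assign_regimes(scenario, rng)
    event_cache = {r: _regime_events(scenario, r) for r in REGIMES}

    tables: list[VariantTable] = []
    truth_rows = []
    lengths: dict[str, int] = {}
    w_global = 0
    for s in range(scenario.n_scaffolds):
        scaffold = f"scaffold_{s + 1:03d}"
        lengths[scaffold] = scenario.windows_per_scaffold * scenario.window_size
        pos_parts, ref_parts, alt_parts, gt_parts = [], [], [], []
        for w in range(scenario.windows_per_scaffold):
            regime = regimes[w_global]
            start = w * scenario.window_size
            end = start + scenario.window_size
            cfg = SimConfig(
                sample_sizes=sizes_hap,
                events=event_cache[regime],
                theta=scenario.theta,
                n_loci=1,
            )
            tree = simulate_genealogy(cfg, rng)
            haps = place_mutations(tree, rng, theta=scenario.theta)
            S = haps.shape[1]
            if S > scenario.window_size:
                raise ValueError(
                    f"window of {scenario.window_size} bp too small for {S} sites"
                )
            if S:
                offsets = np.sort(
                    rng.choice(scenario.window_size, size=S, replace=False)
                )
                positions = start + 1 + offsets
                ref_idx = rng.integers(0, 4, size=S)
                alt_idx = (ref_idx + rng.integers(1, 4, size=S)) % 4
                geno = (haps[0::2, :] + haps[1::2, :]).astype(np.int8)
                if scenario.missing_rate > 0:
                    mask = rng.random(geno.shape) < scenario.missing_rate
                    geno = np.where(mask, np.int8(MISSING), geno)
                pos_parts.append(positions)
                ref_parts.append(_NUCS[ref_idx])
                alt_parts.append(_NUCS[alt_idx])
                gt_parts.append(geno)
            donor, recipient = (
                ("donor", "recipient")
                if regime in ("introgressed", "introgressed_swept")
                else (pd.NA, pd.NA)
            )
            truth_rows.append(
                {
                    "scaffold": scaffold, "start": start, "end": end,
                    "regime": regime, "donor": donor, "recipient": recipient,
                }
            )
            w_global += 1
        if pos_parts:
            tables.append(
                VariantTable(
                    scaffold=scaffold,
                    positions=np.concatenate(pos_parts),
                    ref=np.concatenate(ref_parts),
                    alt=np.concatenate(alt_parts),
                    genotypes=np.concatenate(gt_parts, axis=1),
                    sample_ids=sample_ids,
                )
            )
    truth = pd.DataFrame(truth_rows)
    return tables, popmap, truth, ScaffoldIndex(lengths)


def simulate_exchangeable_study(
    group_sizes: dict[str, int],
    n_scaffolds: int = 10,
    windows_per_scaffold: int = 50,
    window_size: int = 10_000,
    theta: float = 25.0,
    missing_rate: float = 0.0,
    seed: int | None = None,
) -> tuple[list[VariantTable], PopulationMap, ScaffoldIndex]:
    """One panmictic population split arbitrarily into labelled groups.

    Every window is an independent constant-size coalescent locus over all
    individuals, so the group labels are exchangeable by construction —
    the null scenario for type-I-error checks of label-permutation tests.
    """
    rng = np.random.default_rng(seed)
    groups = list(group_sizes)
    n_dip = sum(group_sizes.values())
    sample_ids: list[str] = []
    assignments: list[tuple[str, str]] = []
    for g in groups:
        for k in range(group_sizes[g]):
            sid = f"{g}_{k + 1:02d}"
            sample_ids.append(sid)
            assignments.append((sid, g))
    popmap = PopulationMap(assignments)
    tables: list[VariantTable] = []
    lengths: dict[str, int] = {}
    for s in range(n_scaffolds):
        scaffold = f"scaffold_{s + 1:03d}"
        lengths[scaffold] = windows_per_scaffold * window_size
        pos_parts, ref_parts, alt_parts, gt_parts = [], [], [], []
        for w in range(windows_per_scaffold):
            cfg = SimConfig(sample_sizes=[2 * n_dip], theta=theta, n_loci=1)
            tree = simulate_genealogy(cfg, rng)
            haps = place_mutations(tree, rng, theta=theta)
            S = haps.shape[1]
            if S == 0:
                continue
            offsets = np.sort(rng.choice(window_size, size=S, replace=False))
            pos_parts.append(w * window_size + 1 + offsets)
            ref_idx = rng.integers(0, 4, size=S)
            alt_idx = (ref_idx + rng.integers(1, 4, size=S)) % 4
            ref_parts.append(_NUCS[ref_idx])
            alt_parts.append(_NUCS[alt_idx])
            geno = (haps[0::2, :] + haps[1::2, :]).astype(np.int8)
            if missing_rate > 0:
                mask = rng.random(geno.shape) < missing_rate
                geno = np.where(mask, np.int8(MISSING), geno)
            gt_parts.append(geno)
        if pos_parts:
            tables.append(
                VariantTable(
                    scaffold=scaffold,
                    positions=np.concatenate(pos_parts),
                    ref=np.concatenate(ref_parts),
                    alt=np.concatenate(alt_parts),
                    genotypes=np.concatenate(gt_parts, axis=1),
                    sample_ids=sample_ids,
                )
            )
    return tables, popmap, ScaffoldIndex(lengths)


def plant_fixed_differences(
    tables: list[VariantTable],
    windows: list[tuple[str, int, int]],
    popmap: PopulationMap,
    pop_a: str,
    pop_b: str,
    count: int,
) -> list[VariantTable]:
    """Inject reciprocally fixed biallelic sites into designated windows.

    Exactly *count* sites per window: *pop_a* homozygous alt, everyone else
    homozygous ref.  Preferred positions step from the window centre; a
    collision with an existing position advances to the next free one.
    Returns new tables; the inputs are not modified.
    """
    if count < 0:
        raise ValueError("count must be non-negative")
    if count == 0:
        return tables
    by_scaffold = {t.scaffold: t for t in tables}
    out: dict[str, VariantTable] = dict(by_scaffold)
    for scaffold, start, end in windows:
        if scaffold not in by_scaffold:
            raise KeyError(f"no variant table for scaffold {scaffold!r}")
        t = out[scaffold]
        existing = set(int(p) for p in t.positions)
        chosen: list[int] = []
        pos = start + (end - start) // 2
        while len(chosen) < count:
            if pos > end:
                raise ValueError(
                    f"window {scaffold}:{start}-{end} has no free positions left"
                )
            if pos not in existing and start < pos <= end:
                chosen.append(pos)
                existing.add(pos)
            pos += 1
        idx_a = popmap.indices(t.sample_ids, pop_a)
        n_samples = t.n_samples
        new_cols = np.zeros((n_samples, count), dtype=np.int8)
        new_cols[idx_a, :] = 2
        positions = np.concatenate([t.positions, np.array(chosen, dtype=np.int64)])
        order = np.argsort(positions, kind="stable")
        ref = np.concatenate([t.ref, np.full(count, "A", dtype="U1")])
        alt = np.concatenate([t.alt, np.full(count, "T", dtype="U1")])
        genotypes = np.concatenate([t.genotypes, new_cols], axis=1)
        out[scaffold] = VariantTable(
            scaffold=scaffold,
            positions=positions[order],
            ref=ref[order],
            alt=alt[order],
            genotypes=genotypes[:, order],
            sample_ids=t.sample_ids,
        )
    return [out[t.scaffold] for t in tables]
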