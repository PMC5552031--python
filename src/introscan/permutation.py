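"""Permutation null for the windowed f4 scan.

Individuals from the four focal populations are reshuffled among those
populations without replacement (population sizes preserved; all other
populations untouched) and all window f4 values are recomputed for each of
B permutations.  Two significance devices are derived, mirroring the
two ways the scan is read:

* pooled 1%/99% quantile thresholds of all permuted window values — the
  genome-wide two-tailed alpha = 0.02 flagging rule, and
* per-window one-sided empirical p-values, counting permutations at least
  as extreme as the observed value in its own direction, with the add-one
  correction p = (k + 1)/(B + 1) so B = 1,000 gives a floor of ~0.001.

Permutation streams are spawned independently per permutation index, so
results are reproducible for a given seed regardless of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .f4 import F4Config
from .model import MISSING, PopulationMap, VariantTable, window_index


@dataclass
class PermutationConfig:
    """Number of permutations, pooled tail quantiles, and the seed."""

    n_permutations: int = 1000
    lower_quantile: float = 0.01
    upper_quantile: float = 0.99
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("need at least one permutation")
        if not (0.0 < self.lower_quantile < self.upper_quantile < 1.0):
            raise ValueError("quantiles must satisfy 0 < lower < upper < 1")


def permute_popmap(
    popmap: PopulationMap,
    four_pops: list[str],
    rng: np.random.Generator,
) -> PopulationMap:
    """Reshuffle individuals of the four focal populations among them.

    Sampling is without replacement and preserves each population's size;
    samples outside the four populations keep their assignment.
    """
    if len(set(four_pops)) != len(four_pops):
        raise ValueError("focal populations overlap")
    pool: list[str] = []
    sizes: list[int] = []
    for pop in four_pops:
        members = popmap.samples(pop)
        pool.extend(members)
        sizes.append(len(members))
    order = rng.permutation(len(pool))
    reassigned: dict[str, str] = {}
    cursor = 0
    for pop, size in zip(four_pops, sizes):
        for k in order[cursor : cursor + size]:
            reassigned[pool[int(k)]] = pop
        cursor += size
    return popmap.replace(reassigned)


@dataclass
class NullDistribution:
    """Permuted window f4 values and the pooled tail thresholds."""

    windows: pd.DataFrame          # scaffold/start/end grid of the scan
    permuted: np.ndarray           # (B, n_windows), NaN below min_sites
    lower: float
    upper: float
    config: PermutationConfig

    @property
    def n_permutations(self) -> int:
        return self.permuted.shape[0]

    def pooled(self) -> np.ndarray:
        vals = self.permuted.ravel()
        return vals[~np.isnan(vals)]


class _ScanWorkspace:
    """Precomputed arrays for fast repeated window-f4 evaluation."""

    def __init__(
        self,
        tables: list[VariantTable],
        popmap: PopulationMap,
        config: F4Config,
    ):
        self.config = config
        self.popmap = popmap
        self.gt: list[np.ndarray] = []
        self.called: list[np.ndarray] = []
        self.alt: list[np.ndarray] = []
        self.widx: list[np.ndarray] = []
        self.window_rows: list[tuple[str, int, int]] = []
        self.window_slices: list[tuple[int, np.ndarray]] = []  # (table i, windows)
        self.sample_ids: list[list[str]] = []
        for ti, t in enumerate(tables):
            gt = t.genotypes
            called = (gt != MISSING)
            self.gt.append(gt)
            self.called.append(called)
            self.alt.append(np.where(called, gt, 0).astype(np.float64))
            widx = window_index(t.positions, config.window_size)
            self.widx.append(widx)
            uniq = np.unique(widx)
            self.window_slices.append((ti, uniq))
            for w in uniq:
                self.window_rows.append(
                    (t.scaffold, int(w) * config.window_size,
                     (int(w) + 1) * config.window_size)
                )
            self.sample_ids.append(t.sample_ids)
        self.n_windows = len(self.window_rows)

    def window_values(self, popmap: PopulationMap) -> np.ndarray:
        """All window f4 values for a (possibly permuted) population map."""
        out = np.full(self.n_windows, np.nan)
        cursor = 0
        cfg = self.config
        for ti, uniq in self.window_slices:
            idx = [
                popmap.indices(self.sample_ids[ti], pop)
                for pop in cfg.populations
            ]
            freqs = []
            for pop_idx in idx:
                called = self.called[ti][pop_idx, :]
                n_called = 2.0 * called.sum(axis=0)
                alt = self.alt[ti][pop_idx, :].sum(axis=0)
                missing_frac = 1.0 - n_called / (2.0 * pop_idx.size)
                with np.errstate(invalid="ignore", divide="ignore"):
                    f = np.where(n_called > 0, alt / np.maximum(n_called, 1), np.nan)
                f = np.where(
                    missing_frac > cfg.max_missing_frac + 1e-12, np.nan, f
                )
                freqs.append(f)
            vals = (freqs[0] - freqs[1]) * (freqs[2] - freqs[3])
            usable = ~np.isnan(vals)
            widx = self.widx[ti]
            for w in uniq:
                sel = usable & (widx == w)
                n_usable = int(sel.sum())
                if n_usable >= cfg.min_sites:
                    out[cursor] = vals[sel].mean()
                cursor += 1
        return out

    def grid(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.window_rows, columns=["scaffold", "start", "end"]
        )


def build_null(
    tables: list[VariantTable],
    popmap: PopulationMap,
    f4_config: F4Config,
    perm_config: PermutationConfig,
) -> NullDistribution:
    """Recompute all window f4 values under B label permutations.

    The pooled thresholds are the configured quantiles of all finite
    permuted window values across permutations and windows.
    """
    ws = _ScanWorkspace(tables, popmap, f4_config)
    if ws.n_windows == 0:
        raise ValueError("no windows contain variant sites")
    four = f4_config.populations
    streams = np.random.SeedSequence(perm_config.seed).spawn(
        perm_config.n_permutations
    )
    permuted = np.full((perm_config.n_permutations, ws.n_windows), np.nan)
    for b, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        pm = permute_popmap(popmap, four, rng)
        permuted[b] = ws.window_values(pm)
    pooled = permuted[~np.isnan(permuted)]
    if pooled.size == 0:
        raise ValueError("no usable windows in any permutation")
    lower = float(np.quantile(pooled, perm_config.lower_quantile))
    upper = float(np.quantile(pooled, perm_config.upper_quantile))
    return NullDistribution(
        windows=ws.grid(), permuted=permuted,
        lower=lower, upper=upper, config=perm_config,
    )


def observed_window_values(
    tables: list[VariantTable],
    popmap: PopulationMap,
    f4_config: F4Config,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Window grid and observed f4 values aligned with a null's columns."""
    ws = _ScanWorkspace(tables, popmap, f4_config)
    return ws.grid(), ws.window_values(popmap)


def window_p_values(
    observed: np.ndarray, null: NullDistribution, pooled: bool = False
) -> np.ndarray:
    """Directional add-one empirical p-value per window.

    For a non-negative observed value, k counts permutations with a value
    >= the observed one (ties count as exceeding); for a negative value,
    <=.  p = (k + 1)/(B + 1); NaN where the observed value is missing.

    By default k counts within the same window's B permuted values; with
    ``pooled`` the comparison set is the pooled null across all windows
    (fractional k, same add-one form), matching the pooled thresholds.
    """
    B = null.n_permutations
    pool = null.pooled() if pooled else None
    out = np.full(observed.size, np.nan)
    for w, obs in enumerate(observed):
        if np.isnan(obs):
            continue
        col = pool if pooled else null.permuted[:, w]
        col = col[~np.isnan(col)]
        if obs >= 0:
            k = (col >= obs).sum()
        else:
            k = (col <= obs).sum()
        if pooled:
            k = k * B / max(col.size, 1)  # rescale pooled count to B trials
        out[w] = (float(k) + 1.0) / (B + 1.0)
    return out


def flag_windows(observed: np.ndarray, null: NullDistribution) -> np.ndarray:
    """Boolean flag per window: observed value outside the pooled thresholds."""
    with np.errstate(invalid="ignore"):
        return (observed < null.lower) | (observed > null.upper)
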