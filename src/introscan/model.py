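"""Core in-memory containers for the genome scan.

Genotypes are stored as unphased alt-allele dosage per diploid individual
(0, 1, 2) with ``MISSING`` (-1) for uncalled genotypes.  VCF positions stay
1-based as in the standard; all window arithmetic is 0-based half-open and
goes through :func:`window_bounds` / :func:`window_index` so the convention
lives in one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

#: Sentinel dosage for a missing diploid genotype.
MISSING: int = -1


@dataclass
class VariantTable:
    """Biallelic SNPs of one scaffold: positions plus a samples x sites dosage matrix."""

    scaffold: str
    positions: np.ndarray          # 1-based, strictly increasing, int64
    ref: np.ndarray                # single-nucleotide reference alleles
    alt: np.ndarray                # single-nucleotide alternate alleles
    genotypes: np.ndarray          # (n_samples, n_sites) int8 dosage, MISSING allowed
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype="U1")
        self.alt = np.asarray(self.alt, dtype="U1")
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.validate()

    @property
    def n_sites(self) -> int:
        return int(self.positions.size)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def validate(self) -> None:
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D samples x sites matrix")
        n_samples, n_sites = self.genotypes.shape
        if n_samples != len(self.sample_ids):
            raise ValueError(
                f"{len(self.sample_ids)} sample ids but genotype matrix has "
                f"{n_samples} rows"
            )
        if n_sites != self.positions.size:
            raise ValueError(
                f"{self.positions.size} positions but genotype matrix has "
                f"{n_sites} columns"
            )
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError(
                f"positions on scaffold {self.scaffold!r} are not strictly increasing"
            )
        valid = (self.genotypes == MISSING) | (
            (self.genotypes >= 0) & (self.genotypes <= 2)
        )
        if not valid.all():
            raise ValueError("dosages must be in {0, 1, 2} or MISSING")

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in table") from None


class PopulationMap:
    """Sample -> population assignment with deterministic population order.

    Populations are ordered by first appearance in the input; samples keep
    their insertion order within a population.
    """

    def __init__(self, assignments: Mapping[str, str] | Iterable[tuple[str, str]]):
        items = assignments.items() if isinstance(assignments, Mapping) else assignments
        self._assignments: dict[str, str] = {}
        self._populations: list[str] = []
        for sample, pop in items:
            if sample in self._assignments:
                raise ValueError(f"sample {sample!r} assigned more than once")
            self._assignments[sample] = pop
            if pop not in self._populations:
                self._populations.append(pop)
        if not self._assignments:
            raise ValueError("population map is empty")

    @property
    def assignments(self) -> dict[str, str]:
        return dict(self._assignments)

    @property
    def populations(self) -> list[str]:
        return list(self._populations)

    def __len__(self) -> int:
        return len(self._assignments)

    def __contains__(self, sample: str) -> bool:
        return sample in self._assignments

    def population_of(self, sample: str) -> str:
        return self._assignments[sample]

    def samples(self, population: str) -> list[str]:
        if population not in self._populations:
            raise KeyError(f"population {population!r} not in map")
        return [s for s, p in self._assignments.items() if p == population]

    def indices(self, sample_ids: Sequence[str], population: str) -> np.ndarray:
        """Row indices of *population*'s samples within *sample_ids*."""
        members = set(self.samples(population))
        idx = np.array(
            [i for i, s in enumerate(sample_ids) if s in members], dtype=np.intp
        )
        if idx.size == 0:
            raise ValueError(
                f"population {population!r} has no samples among the table's "
                "sample ids"
            )
        return idx

    def replace(self, assignments: Mapping[str, str]) -> "PopulationMap":
        """New map with some samples reassigned; population order is preserved."""
        new = {s: assignments.get(s, p) for s, p in self._assignments.items()}
        pm = PopulationMap(new)
        # keep the original ordering for populations that survive
        order = [p for p in self._populations if p in pm._populations]
        order += [p for p in pm._populations if p not in order]
        pm._populations = order
        return pm


@dataclass
class ScaffoldIndex:
    """Scaffold -> length in bp."""

    lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for scaffold, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"scaffold {scaffold!r} has non-positive length")

    def __getitem__(self, scaffold: str) -> int:
        return self.lengths[scaffold]

    def __contains__(self, scaffold: str) -> bool:
        return scaffold in self.lengths

    def __iter__(self) -> Iterator[str]:
        return iter(self.lengths)

    def check_tables(self, tables: Iterable[VariantTable]) -> None:
        for t in tables:
            if t.scaffold not in self.lengths:
                raise KeyError(f"scaffold {t.scaffold!r} missing from index")
            if t.n_sites and int(t.positions[-1]) > self.lengths[t.scaffold]:
                raise ValueError(
                    f"position {int(t.positions[-1])} exceeds length of "
                    f"scaffold {t.scaffold!r}"
                )


def window_bounds(scaffold_length: int, window_size: int) -> list[tuple[int, int]]:
    """Non-overlapping 0-based half-open windows anchored at 0.

    The final partial window is kept with its true length so that per-bp
    denominators (pi, Dxy) stay honest.
    """
    if window_size <= 0:
        raise ValueError("window size must be positive")
    if scaffold_length <= 0:
        raise ValueError("scaffold length must be positive")
    bounds = []
    for start in range(0, scaffold_length, window_size):
        bounds.append((start, min(start + window_size, scaffold_length)))
    return bounds


def window_index(positions: np.ndarray, window_size: int) -> np.ndarray:
    """Window ordinal for each 1-based position."""
    return (np.asarray(positions, dtype=np.int64) - 1) // window_size
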