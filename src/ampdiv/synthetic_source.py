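"""Ground-truth source populations and multinomial library simulation.

A source population is a named set of variants with true proportions — the
quantity diversity inference targets. Sequencing a sample is modeled as a
multinomial draw: each read independently lands on variant i with
probability p_i. The canonical fixture is the 100-tile English Scrabble
bag (26 letters plus blanks, 27 variants), whose source Shannon index is
3.03 nats: small enough to reason about exactly, uneven enough to behave
like real compositional data.

Sampling is with replacement (multinomial), treating the source as
effectively infinite relative to the library; a finite-population
multivariate hypergeometric view is deliberately not offered here.
All samplers take explicit seeds — there is no hidden global RNG.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .asv_io import ASVTable, CountVector
from .diversity_core import Simplex

__all__ = [
    "SourcePopulation",
    "SimulationDesign",
    "scrabble_population",
    "sample_library",
    "simulate_design",
]

# Standard English Scrabble tile counts: 100 tiles over 26 letters + blank.
SCRABBLE_TILE_COUNTS: dict[str, int] = {
    "E": 12,
    "A": 9, "I": 9,
    "O": 8,
    "N": 6, "R": 6, "T": 6,
    "D": 4, "L": 4, "S": 4, "U": 4,
    "G": 3,
    "B": 2, "C": 2, "F": 2, "H": 2, "M": 2, "P": 2,
    "V": 2, "W": 2, "Y": 2, "blank": 2,
    "J": 1, "K": 1, "Q": 1, "X": 1, "Z": 1,
}


@dataclass(frozen=True)
class SourcePopulation:
    """Named variants with true proportions; optional finite tile counts."""

    variant_ids: tuple[str, ...]
    true_proportions: Simplex
    tile_counts: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.variant_ids) != len(self.true_proportions):
            raise ValueError("variant_ids and proportions lengths differ")
        if self.tile_counts is not None:
            tc = np.asarray(self.tile_counts, dtype=np.int64)
            if np.any(tc < 0) or tc.sum() < 1:
                raise ValueError("tile counts must be non-negative with positive total")
            expect = tc / tc.sum()
            if not np.allclose(expect, self.true_proportions.proportions, atol=1e-12):
                raise ValueError("tile counts do not reproduce the stated proportions")

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)


@dataclass(frozen=True)
class SimulationDesign:
    """Library sizes x replicates grid for a simulation run."""

    library_sizes: tuple[int, ...]
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.library_sizes or any(n < 1 for n in self.library_sizes):
            raise ValueError("library sizes must all be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def scrabble_population() -> SourcePopulation:
    """The 27-variant, 100-tile English Scrabble source population."""
    ids = tuple(SCRABBLE_TILE_COUNTS)
    counts = np.array([SCRABBLE_TILE_COUNTS[v] for v in ids], dtype=np.int64)
    return SourcePopulation(
        variant_ids=ids,
        true_proportions=Simplex(counts / counts.sum()),
        tile_counts=tuple(int(c) for c in counts),
    )


def sample_library(
    pop: SourcePopulation, library_size: int, seed: int | np.random.Generator
) -> CountVector:
    """Draw one library: counts ~ Multinomial(library_size, true proportions)."""
    if library_size < 1:
        raise ValueError("library_size must be >= 1")
    rng = np.random.default_rng(seed)
    x = rng.multinomial(library_size, pop.true_proportions.proportions)
    return CountVector(pop.variant_ids, x)


def sample_libraries(
    pop: SourcePopulation,
    library_size: int,
    n_replicates: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Replicate multinomial libraries as an (n_replicates x variants) matrix."""
    if library_size < 1 or n_replicates < 1:
        raise ValueError("library_size and n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.multinomial(
        library_size, pop.true_proportions.proportions, size=n_replicates
    )


def simulate_design(pop: SourcePopulation, design: SimulationDesign) -> ASVTable:
    """Simulate a full ASV table: one column per (library size x replicate).

    Columns are named ``N<library_size>_r<replicate>``; a fixed design seed
    gives bit-identical output across runs.
    """
    rng = np.random.default_rng(design.seed)
    cols = []
    names = []
    for n in design.library_sizes:
        draws = rng.multinomial(
            n, pop.true_proportions.proportions, size=design.n_replicates
        )
        for r in range(design.n_replicates):
            cols.append(draws[r])
            names.append(f"N{n}_r{r + 1}")
    return ASVTable(pop.variant_ids, tuple(names), np.column_stack(cols))
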