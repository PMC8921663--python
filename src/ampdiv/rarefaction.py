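"""Repeated rarefaction: sample-level diversity at a normalized library size.

Rarefying subsamples a library *without replacement* down to a common
depth m, describing what data might have been obtained had only m reads
been sequenced. A single rarefaction injects arbitrary subsampling noise;
rarefying repeatedly (default 1,000 times, each an independent re-subsample
of the original counts, never chained) characterizes that noise as a
distribution of plug-in Shannon values per sample. Samples from the same
source then show overlapping distributions at a common depth regardless of
their original library sizes, which is the model-free route to comparing
sample-level diversity. The recommended common depth is the smallest
library size among the samples compared.

Each rarefaction is an exact multivariate hypergeometric draw, so every
repetition sums to m, no variant exceeds its original count, and zero
variants stay zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .asv_io import ASVTable, CountVector, extract_sample
from .bayes_shannon import _tukey_summary
from .diversity_core import shannon_of_counts

__all__ = [
    "RarefactionResult",
    "rarefy_once",
    "rarefy_repeatedly",
    "normalize_table",
]


@dataclass(frozen=True)
class RarefactionResult:
    """Distribution of plug-in Shannon values from repeated rarefaction."""

    depth: int
    n_repetitions: int
    shannon_values: np.ndarray = field(repr=False)
    summary: dict[str, float]
    seed: int | None = None

    @property
    def mean(self) -> float:
        return self.summary["mean"]


def _check_depth(m: int, n: int) -> None:
    if m < 1:
        raise ValueError("depth m must be >= 1")
    if m > n:
        raise ValueError(f"cannot rarefy up: depth {m} exceeds library size {n}")


def rarefy_once(
    counts: CountVector, m: int, seed: int | np.random.Generator = 0
) -> CountVector:
    """One multivariate hypergeometric subsample of m reads from the N observed."""
    n = counts.library_size
    _check_depth(m, n)
    rng = np.random.default_rng(seed)
    sub = rng.multivariate_hypergeometric(counts.counts, m)
    return CountVector(counts.variant_ids, sub)


def rarefy_repeatedly(
    counts: CountVector,
    m: int,
    n_repetitions: int = 1_000,
    seed: int | np.random.Generator = 0,
) -> RarefactionResult:
    """Independent rarefactions of the original counts, Shannon per repetition."""
    n = counts.library_size
    _check_depth(m, n)
    if n_repetitions < 1:
        raise ValueError("n_repetitions must be >= 1")
    rng = np.random.default_rng(seed)
    subs = np.stack(
        [rng.multivariate_hypergeometric(counts.counts, m) for _ in range(n_repetitions)]
    )
    values = np.atleast_1d(shannon_of_counts(subs))
    return RarefactionResult(
        depth=m,
        n_repetitions=n_repetitions,
        shannon_values=values,
        summary=_tukey_summary(values, 0.95),
        seed=seed if isinstance(seed, int) else None,
    )


def normalize_table(
    table: ASVTable,
    m: int | None = None,
    n_repetitions: int = 1_000,
    seed: int | np.random.Generator = 0,
) -> dict[str, RarefactionResult]:
    """Rarefy every sample of a table repeatedly to a common depth m.

    ``m`` defaults to the minimum library size across samples. Samples with
    fewer than m reads are skipped with a warning; if none can be rarefied
    a ``ValueError`` is raised.
    """
    sizes = table.library_sizes
    if m is None:
        positive = sizes[sizes > 0]
        if positive.size == 0:
            raise ValueError("table has no reads; nothing to rarefy")
        m = int(positive.min())
    rng = np.random.default_rng(seed)
    results: dict[str, RarefactionResult] = {}
    for sid, n in zip(table.sample_ids, sizes):
        if n < m:
            warnings.warn(
                f"sample {sid!r} has library size {n} < depth {m}; skipped",
                stacklevel=2,
            )
            continue
        vec = extract_sample(table, sid)
        results[sid] = rarefy_repeatedly(vec, m, n_repetitions, rng)
    if not results:
        raise ValueError(f"no sample reaches depth {m}; nothing rarefied")
    return results
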