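"""Generative error models for amplicon sequencing counts, and a formal
compatibility test against the multinomial relative-abundance model.

The multinomial model (reads drawn independently with source proportions)
holds only under strong assumptions about how a sample becomes a library.
Each operator here simulates one step of that chain:

* independent Poisson or negative-binomial per-variant counts
  (random dispersion of organisms in the sampled water — clustering
  yields the overdispersed negative binomial);
* conditioning a replicate set on a fixed library size (the act of
  observing a library of a particular total);
* non-differential loss / analytical recovery (binomial thinning);
* gene-copy clustering (each organism contributing several copies);
* PCR amplification (a Polya-urn copy-at-a-time scheme, or per-cycle
  binomial doubling at a given efficiency).

The two-variant special case of the multinomial is a binomial, so
compatibility is assessed by a Pearson chi-square goodness-of-fit of
conditioned variant-1 counts against Binomial(N, p). Independent Poisson
counts conditioned on their total are *exactly* binomial (so the test
rejects at its nominal type-I rate), while overdispersed clustering and
amplification are provably incompatible — the test's power against them
approaches one as replicates accumulate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .asv_io import CountVector

__all__ = [
    "DispersionModel",
    "RecoveryProfile",
    "CompatTestResult",
    "simulate_counts",
    "condition_on_library",
    "amplify",
    "thin",
    "cluster_counts",
    "binomial_compat_test",
]


@dataclass(frozen=True)
class DispersionModel:
    """Per-variant count dispersion: independent Poisson or negative binomial.

    ``means`` are the per-variant expected counts (concentration x volume).
    The negative binomial uses the ecological (mu, k) parameterization with
    variance mu + mu^2 / k, so any finite ``dispersion`` k is overdispersed
    relative to Poisson.
    """

    kind: str  # "poisson" | "negative_binomial"
    means: np.ndarray
    dispersion: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("poisson", "negative_binomial"):
            raise ValueError(f"unknown dispersion kind {self.kind!r}")
        mu = np.asarray(self.means, dtype=float)
        if mu.ndim != 1 or mu.size == 0 or np.any(mu <= 0):
            raise ValueError("means must be a non-empty vector of positive reals")
        if self.kind == "negative_binomial":
            if self.dispersion is None or self.dispersion <= 0:
                raise ValueError("negative_binomial requires dispersion k > 0")
        object.__setattr__(self, "means", mu)


@dataclass(frozen=True)
class RecoveryProfile:
    """Per-variant analytical recovery probabilities r_i in [0, 1].

    A constant profile (all r_i equal) is the non-differential-loss case,
    which preserves composition in expectation; differential recovery
    biases diversity inference.
    """

    recovery: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.recovery, dtype=float)
        if r.ndim != 1 or np.any(r < 0) or np.any(r > 1):
            raise ValueError("recovery probabilities must lie in [0, 1]")
        object.__setattr__(self, "recovery", r)

    @property
    def is_constant(self) -> bool:
        return bool(np.all(self.recovery == self.recovery[0]))


@dataclass(frozen=True)
class CompatTestResult:
    """Chi-square goodness-of-fit outcome with its pooled cell table."""

    statistic: float
    p_value: float
    reject: bool
    alpha: float
    df: int
    observed: np.ndarray
    expected: np.ndarray
    cell_edges: list[tuple[int, int]]


def simulate_counts(
    model: DispersionModel, n_replicates: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Independent per-variant counts per replicate (replicates x variants)."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    mu = model.means
    if model.kind == "poisson":
        return rng.poisson(mu, size=(n_replicates, mu.size))
    k = float(model.dispersion)
    # numpy's negative_binomial(n, p): n = k, p = k / (k + mu)
    return rng.negative_binomial(k, k / (k + mu), size=(n_replicates, mu.size))


def condition_on_library(counts: np.ndarray, target_n: int) -> np.ndarray:
    """Keep exactly the replicates whose total equals ``target_n``.

    Rejection conditioning: mirrors observing a library of a particular
    size. Returns a possibly empty matrix; emits a warning (not an error)
    when nothing is retained.
    """
    counts = np.atleast_2d(np.asarray(counts))
    keep = counts.sum(axis=1) == target_n
    out = counts[keep]
    if out.shape[0] == 0:
        warnings.warn(
            f"no replicates with library size {target_n}; empty result",
            stacklevel=2,
        )
    return out


def amplify(
    counts: CountVector,
    target_size: int,
    mechanism: str = "polya_urn",
    efficiency: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> CountVector:
    """Amplify a library of molecules up to (at least) ``target_size`` copies.

    ``polya_urn``: add one copy at a time, each duplicating an existing
    molecule chosen with probability proportional to current counts, until
    the total equals ``target_size`` exactly. ``cycle_doubling``: whole PCR
    cycles in which every molecule duplicates independently with probability
    ``efficiency``; cycles repeat until the total reaches ``target_size``
    and the final (possibly overshooting) total is reported, not truncated.

    Both mechanisms preserve zeros: a variant absent before amplification
    stays absent — amplification inflates the library only at the level of
    diversity already present.
    """
    x = counts.counts.astype(np.int64).copy()
    n = int(x.sum())
    if n < 1:
        raise ValueError("cannot amplify an empty library")
    rng = np.random.default_rng(seed)
    if mechanism == "polya_urn":
        if target_size < n:
            raise ValueError(
                f"polya_urn target {target_size} below current total {n}"
            )
        while x.sum() < target_size:
            i = rng.choice(x.size, p=x / x.sum())
            x[i] += 1
    elif mechanism == "cycle_doubling":
        if not (0 < efficiency <= 1):
            raise ValueError("efficiency must be in (0, 1]")
        while x.sum() < target_size:
            x = x + rng.binomial(x, efficiency)
    else:
        raise ValueError(f"unknown amplification mechanism {mechanism!r}")
    return CountVector(counts.variant_ids, x)


def thin(
    counts: CountVector,
    recovery: RecoveryProfile,
    seed: int | np.random.Generator = 0,
) -> CountVector:
    """Random loss: each variant's count thinned as Binomial(x_i, r_i)."""
    r = recovery.recovery
    if r.size != len(counts):
        raise ValueError("recovery profile length does not match counts")
    rng = np.random.default_rng(seed)
    y = rng.binomial(counts.counts, r)
    return CountVector(counts.variant_ids, y)


def cluster_counts(
    counts: CountVector, copies_per_organism: int, seed: int | np.random.Generator = 0
) -> CountVector:
    """Each organism contributes a fixed number of gene copies.

    The simplest clustering mechanism: counts are multiplied by the copy
    number, so conditioned totals only take values in multiples of it —
    already incompatible with the support of a binomial library.
    """
    if copies_per_organism < 1:
        raise ValueError("copies_per_organism must be >= 1")
    return CountVector(counts.variant_ids, counts.counts * copies_per_organism)


def _pool_cells(expected: np.ndarray, min_expected: float) -> list[tuple[int, int]]:
    """Pool adjacent support cells so every pooled expectation reaches
    ``min_expected``; returns [start, stop) index ranges.

    Greedy left-to-right accumulation pools the thin left tail; an
    underweight final pool is merged backward, pooling the right tail.
    """
    k = expected.size
    edges: list[tuple[int, int]] = []
    i = 0
    while i < k:
        j = i + 1
        acc = expected[i]
        while acc < min_expected and j < k:
            acc += expected[j]
            j += 1
        edges.append((i, j))
        i = j
    while len(edges) > 1 and expected[slice(*edges[-1])].sum() < min_expected:
        a0, _ = edges[-2]
        edges[-2] = (a0, edges[-1][1])
        edges.pop()
    return edges


def binomial_compat_test(
    variant1_counts: np.ndarray,
    n: int,
    p: float,
    alpha: float = 0.05,
    min_expected: float = 5.0,
) -> CompatTestResult:
    """Pearson chi-square test of conditioned counts against Binomial(n, p).

    ``variant1_counts`` are variant-1 counts from replicates already
    conditioned on library size ``n``. Support cells {0..n} with expected
    frequency below ``min_expected`` are pooled from the tails inward;
    degrees of freedom = (#cells - 1). Raises if fewer than two cells
    survive pooling.
    """
    x = np.asarray(variant1_counts, dtype=np.int64).reshape(-1)
    if x.size == 0:
        raise ValueError("no replicates supplied")
    if np.any(x < 0) or np.any(x > n):
        raise ValueError(f"counts must lie in [0, {n}]")
    if not (0 < p < 1):
        raise ValueError("p must be in (0, 1)")
    m = x.size
    support = np.arange(n + 1)
    pmf = stats.binom.pmf(support, n, p)
    expected_full = m * pmf
    edges = _pool_cells(expected_full, min_expected)
    if len(edges) < 2:
        raise ValueError(
            "fewer than 2 cells after pooling; need more replicates for the test"
        )
    obs_full = np.bincount(x, minlength=n + 1).astype(float)
    observed = np.array([obs_full[a:b].sum() for a, b in edges])
    expected = np.array([expected_full[a:b].sum() for a, b in edges])
    statistic, p_value = stats.chisquare(observed, f_exp=expected * m / expected.sum())
    df = len(edges) - 1
    return CompatTestResult(
        statistic=float(statistic),
        p_value=float(p_value),
        reject=bool(p_value < alpha),
        alpha=float(alpha),
        df=df,
        observed=observed,
        expected=expected,
        cell_edges=edges,
    )
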