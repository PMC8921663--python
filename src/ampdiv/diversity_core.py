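"""Shannon diversity on proportions and count vectors.

The Shannon index ``S = -sum(p_i * ln(p_i))`` (natural log, nats) measures
alpha diversity as a joint function of richness and evenness. It is a
functional of the *proportions* of variants, not their raw counts, so any
count vector must first be normalized by its library size. The plug-in
estimate (evaluating S on sample proportions) is biased low for the source
index at small library sizes: rare variants are progressively revealed as
the library grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .asv_io import CountVector

__all__ = ["Simplex", "ShannonResult", "proportions", "shannon_index"]

_SIMPLEX_TOL = 1e-12


@dataclass(frozen=True)
class Simplex:
    """A vector of variant proportions summing to one.

    Zero entries are allowed (variants modeled but not observed). Validation
    happens on construction; downstream code may assume the invariants.
    """

    proportions: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if p.ndim != 1 or p.size == 0:
            raise ValueError("simplex must be a non-empty 1-D vector")
        if np.any(p < 0):
            raise ValueError("simplex entries must be non-negative")
        if abs(p.sum() - 1.0) > max(_SIMPLEX_TOL, 1e-9 * p.size):
            raise ValueError(f"proportions sum to {p.sum()!r}, not 1")
        object.__setattr__(self, "proportions", p)

    def __len__(self) -> int:
        return self.proportions.size


@dataclass(frozen=True)
class ShannonResult:
    """Shannon index value in nats; 0 <= value <= ln(n_variants)."""

    value: float


def proportions(counts: CountVector) -> Simplex:
    """Convert observed counts to a proportion simplex, p_i = x_i / N.

    Raises ``ValueError`` on an empty library (N = 0): no simplex exists for
    a sample with no reads.
    """
    n = counts.library_size
    if n < 1:
        raise ValueError("cannot form proportions from an empty library (N = 0)")
    return Simplex(counts.counts / n)


def shannon_index(p: Simplex | np.ndarray) -> ShannonResult:
    """Shannon index S = -sum(p_i ln p_i) with the convention 0*ln(0) = 0.

    Accepts a :class:`Simplex` or a raw proportion vector (validated on the
    fly). Returned value is in nats and clipped at zero to absorb roundoff
    on degenerate (single-variant) inputs.
    """
    if not isinstance(p, Simplex):
        p = Simplex(np.asarray(p, dtype=float))
    v = p.proportions
    nz = v[v > 0]
    s = float(-(nz * np.log(nz)).sum())
    return ShannonResult(max(s, 0.0))


def shannon_of_counts(x: np.ndarray) -> float:
    """Plug-in Shannon index of one or many count vectors.

    ``x`` is a 1-D count vector or a 2-D array (replicates x variants);
    returns a float or a per-replicate float array. Zero counts contribute
    nothing (0*ln 0 = 0). Rows must have positive totals.
    """
    x = np.asarray(x, dtype=float)
    one = x.ndim == 1
    x = np.atleast_2d(x)
    totals = x.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("every count vector needs a positive library size")
    p = x / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    s = -terms.sum(axis=1)
    s = np.maximum(s, 0.0)
    return float(s[0]) if one else s
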