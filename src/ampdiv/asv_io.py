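"""Reading, validating and writing ASV count tables.

An ASV (amplicon sequence variant) table records non-negative integer read
counts with variants as rows and samples as columns. The per-sample library
size is the column sum and is always derived, never stored. Plain TSV/CSV
only: first row holds sample IDs, first column holds variant IDs, body is
integers. IDs containing whitespace are rejected rather than quoted.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ASVTable",
    "CountVector",
    "read_asv_table",
    "write_asv_table",
    "extract_sample",
]

_DIALECTS = {"tab": "\t", "comma": ","}


def _check_ids(ids: list[str], kind: str) -> None:
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate {kind} IDs: {dupes}")
    bad = [i for i in ids if any(ch.isspace() for ch in i)]
    if bad:
        raise ValueError(f"{kind} IDs may not contain whitespace: {bad}")


@dataclass(frozen=True)
class ASVTable:
    """Variants x samples matrix of non-negative integer read counts."""

    variant_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        vids = tuple(str(v) for v in self.variant_ids)
        sids = tuple(str(s) for s in self.sample_ids)
        _check_ids(list(vids), "variant")
        _check_ids(list(sids), "sample")
        c = np.asarray(self.counts)
        if not np.issubdtype(c.dtype, np.integer):
            cf = np.asarray(self.counts, dtype=float)
            if not np.all(np.isfinite(cf)) or np.any(cf != np.floor(cf)):
                raise ValueError("counts must be finite integers")
            c = cf.astype(np.int64)
        c = c.astype(np.int64)
        if c.shape != (len(vids), len(sids)):
            raise ValueError(
                f"count matrix shape {c.shape} does not match "
                f"{len(vids)} variants x {len(sids)} samples"
            )
        if c.size and c.min() < 0:
            r, s = np.argwhere(c < 0)[0]
            raise ValueError(
                f"negative count at variant {vids[r]!r}, sample {sids[s]!r}"
            )
        c.setflags(write=False)
        object.__setattr__(self, "variant_ids", vids)
        object.__setattr__(self, "sample_ids", sids)
        object.__setattr__(self, "counts", c)

    @property
    def library_sizes(self) -> np.ndarray:
        """Per-sample library size (column sums), derived on demand."""
        return self.counts.sum(axis=0)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.variant_ids), columns=list(self.sample_ids)
        )


@dataclass(frozen=True)
class CountVector:
    """One sample's per-variant read counts x_i with library size N = sum x_i.

    Zeros are permitted and preserved — they carry information (a modeled
    variant that was not detected) and are never silently dropped.
    """

    variant_ids: tuple[str, ...]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        vids = tuple(str(v) for v in self.variant_ids)
        _check_ids(list(vids), "variant")
        c = np.asarray(self.counts)
        if not np.issubdtype(c.dtype, np.integer):
            cf = np.asarray(self.counts, dtype=float)
            if cf.size and (not np.all(np.isfinite(cf)) or np.any(cf != np.floor(cf))):
                raise ValueError("counts must be finite integers")
            c = cf.astype(np.int64)
        c = c.astype(np.int64).reshape(-1)
        if len(vids) != c.size:
            raise ValueError("variant_ids and counts lengths differ")
        if c.size and c.min() < 0:
            raise ValueError("counts must be non-negative")
        c.setflags(write=False)
        object.__setattr__(self, "variant_ids", vids)
        object.__setattr__(self, "counts", c)

    @property
    def library_size(self) -> int:
        return int(self.counts.sum())

    def __len__(self) -> int:
        return self.counts.size


def _sep(dialect: str) -> str:
    try:
        return _DIALECTS[dialect]
    except KeyError:
        raise ValueError(f"dialect must be one of {sorted(_DIALECTS)}, got {dialect!r}")


def read_asv_table(
    path: str | Path | io.TextIOBase,
    dialect: str = "tab",
    transpose: bool = False,
) -> ASVTable:
    """Read a TSV/CSV ASV table (variants as rows, samples as columns).

    ``transpose=True`` accepts files written the other way around
    (samples as rows); the returned table is always variants x samples.
    Row/column order is preserved as in the file. Non-integer or negative
    cells raise ``ValueError`` naming the offending row and column.
    """
    sep = _sep(dialect)
    df = pd.read_csv(path, sep=sep, index_col=0, header=0, dtype=str)
    df.index = df.index.astype(str)
    if transpose:
        df = df.T
    body = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df.iloc[:, j]):
            try:
                val = int(str(raw))
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-integer cell {raw!r} at variant {df.index[i]!r}, "
                    f"sample {col!r}"
                ) from None
            if val < 0:
                raise ValueError(
                    f"negative count {val} at variant {df.index[i]!r}, sample {col!r}"
                )
            body[i, j] = val
    return ASVTable(tuple(df.index), tuple(str(c) for c in df.columns), body)


def write_asv_table(
    table: ASVTable, path: str | Path | io.TextIOBase, dialect: str = "tab"
) -> None:
    """Write a table so that :func:`read_asv_table` round-trips it exactly."""
    sep = _sep(dialect)
    table.to_frame().to_csv(path, sep=sep, index_label="variant_id")


def extract_sample(
    table: ASVTable, sample_id: str, drop_zeros: bool = False
) -> CountVector:
    """Pull one sample's column as a :class:`CountVector`.

    With ``drop_zeros`` only variants detected in this sample are retained
    (the zeros-excluded analysis); the library size is unchanged either way
    since dropped entries are zeros.
    """
    try:
        j = table.sample_ids.index(str(sample_id))
    except ValueError:
        raise KeyError(
            f"sample {sample_id!r} not in table (has {list(table.sample_ids)})"
        ) from None
    col = table.counts[:, j]
    vids = table.variant_ids
    if drop_zeros:
        keep = col > 0
        col = col[keep]
        vids = tuple(v for v, k in zip(vids, keep) if k)
    return CountVector(vids, col.copy())
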