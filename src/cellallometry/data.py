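"""Paired (cell number, cell type number) observations and their CSV dialect.

The analysis operates in double log-space: every record carries the raw
counts ``N`` (total cells) and ``K`` (cell types) together with
``n = log10 N`` and ``k = log10 K``.  Logical constraints: 1 <= K <= N.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = ["AllometryDataset", "read_dataset", "write_dataset"]

DEFAULT_CELLS_COL = "cells"
DEFAULT_TYPES_COL = "cell_types"


@dataclass(frozen=True)
class AllometryDataset:
    """Immutable table of organisms with cell and cell-type counts."""

    N: np.ndarray
    K: np.ndarray
    labels: Optional[Sequence[str]] = None
    n: np.ndarray = field(init=False)
    k: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        N = np.asarray(self.N, dtype=float)
        K = np.asarray(self.K, dtype=float)
        object.__setattr__(self, "N", N)
        object.__setattr__(self, "K", K)
        if N.ndim != 1 or K.ndim != 1 or len(N) != len(K):
            raise ValueError("N and K must be one-dimensional and equal length")
        if not (np.all(np.isfinite(N)) and np.all(np.isfinite(K))):
            raise ValueError("N and K must be finite")
        bad = np.nonzero((N < 1) | (K < 1) | (K > N))[0]
        if bad.size:
            raise ValueError(
                f"records violate 1 <= K <= N at rows {bad.tolist()[:10]}"
            )
        if self.labels is not None and len(self.labels) != len(N):
            raise ValueError("labels length mismatch")
        object.__setattr__(self, "n", np.log10(N))
        object.__setattr__(self, "k", np.log10(K))

    def __len__(self) -> int:
        return len(self.N)

    @property
    def n_obs(self) -> int:
        return len(self.N)

    def fingerprint(self) -> str:
        """Stable hash of the (n, k) values, used to guard model comparison."""
        h = hashlib.sha256()
        h.update(np.round(self.n, 12).tobytes())
        h.update(np.round(self.k, 12).tobytes())
        return h.hexdigest()[:16]

    def to_frame(
        self,
        cells_col: str = DEFAULT_CELLS_COL,
        types_col: str = DEFAULT_TYPES_COL,
    ) -> pd.DataFrame:
        cols = {}
        if self.labels is not None:
            cols["organism"] = list(self.labels)
        cols[cells_col] = self.N
        cols[types_col] = self.K
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        cells_col: Optional[str] = None,
        types_col: Optional[str] = None,
    ) -> "AllometryDataset":
        cells_col, types_col = _resolve_columns(df, cells_col, types_col)
        labels = None
        for cand in ("organism", "label", "name", "species"):
            if cand in df.columns:
                labels = df[cand].astype(str).tolist()
                break
        return cls(
            N=df[cells_col].to_numpy(dtype=float),
            K=df[types_col].to_numpy(dtype=float),
            labels=labels,
        )


def _resolve_columns(
    df: pd.DataFrame,
    cells_col: Optional[str],
    types_col: Optional[str],
) -> tuple[str, str]:
    """Resolve column names, falling back to case-insensitive substring match.

    The type column is any column containing "type"; the cell column is any
    column containing "cell" that is not the type column.
    """
    if cells_col is not None and types_col is not None:
        missing = [c for c in (cells_col, types_col) if c not in df.columns]
        if missing:
            raise ValueError(f"columns not found in CSV: {missing}")
        return cells_col, types_col
    lower = {c: str(c).lower() for c in df.columns}
    if types_col is None:
        if DEFAULT_TYPES_COL in df.columns:
            types_col = DEFAULT_TYPES_COL
        else:
            matches = [c for c, lc in lower.items() if "type" in lc]
            if not matches:
                raise ValueError(
                    "could not auto-detect a cell-type column "
                    f"(no column name contains 'type'): {list(df.columns)}"
                )
            types_col = matches[0]
    if cells_col is None:
        if DEFAULT_CELLS_COL in df.columns:
            cells_col = DEFAULT_CELLS_COL
        else:
            matches = [
                c
                for c, lc in lower.items()
                if "cell" in lc and c != types_col
            ]
            if not matches:
                raise ValueError(
                    "could not auto-detect a cell-number column "
                    f"(no column name contains 'cell'): {list(df.columns)}"
                )
            cells_col = matches[0]
    return cells_col, types_col


def read_dataset(
    path: Union[str, Path],
    cells_col: Optional[str] = None,
    types_col: Optional[str] = None,
) -> AllometryDataset:
    """Read a dataset from CSV (header row, scientific notation allowed)."""
    df = pd.read_csv(path)
    try:
        return AllometryDataset.from_frame(df, cells_col, types_col)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_dataset(
    dataset: AllometryDataset,
    path: Union[str, Path],
    cells_col: str = DEFAULT_CELLS_COL,
    types_col: str = DEFAULT_TYPES_COL,
) -> None:
    """Write a dataset in the same CSV dialect the reader consumes."""
    df = dataset.to_frame(cells_col=cells_col, types_col=types_col)
    # 12 significant digits so datasets round-trip losslessly
    df.to_csv(path, index=False, float_format="%.12g")
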