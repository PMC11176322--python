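"""Shared in-memory containers: genomic bin grids, binned read counts and
copy-number matrices.

All analyses operate on a synthetic genome of ``n_chromosomes`` chromosomes
tiled by fixed-width, 0-based half-open bins (default 1 Mb).  A bin grid is
represented as a :class:`pandas.DataFrame` with columns ``chrom``, ``start``,
``end``; per-bin vectors (counts, ratios, copy numbers) are numpy arrays
aligned row-by-row with that grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "make_bin_grid",
    "check_same_grid",
    "BinCounts",
    "CellCNMatrix",
    "CohortCNMatrix",
]


def make_bin_grid(n_bins: int, n_chromosomes: int, bin_size: int = 1_000_000) -> pd.DataFrame:
    """Tile a synthetic genome with fixed-width bins.

    Bins are split as evenly as possible across chromosomes (earlier
    chromosomes receive the remainder), named ``chr1`` .. ``chrN``.
    """
    if n_chromosomes < 1 or n_bins < n_chromosomes:
        raise ValueError("need n_bins >= n_chromosomes >= 1")
    base, extra = divmod(n_bins, n_chromosomes)
    chroms, starts = [], []
    for c in range(n_chromosomes):
        n = base + (1 if c < extra else 0)
        chroms.extend([f"chr{c + 1}"] * n)
        starts.extend(range(n))
    starts = np.asarray(starts, dtype=np.int64) * bin_size
    return pd.DataFrame(
        {"chrom": chroms, "start": starts, "end": starts + bin_size}
    )


def check_same_grid(a: pd.DataFrame, b: pd.DataFrame) -> None:
    """Raise ``ValueError`` naming the first discrepancy between two grids."""
    if len(a) != len(b):
        raise ValueError(f"bin grids differ in length: {len(a)} vs {len(b)}")
    for col in ("chrom", "start", "end"):
        neq = a[col].to_numpy() != b[col].to_numpy()
        if neq.any():
            i = int(np.argmax(neq))
            raise ValueError(
                f"bin grids differ at row {i}: {col} "
                f"{a[col].iloc[i]!r} vs {b[col].iloc[i]!r}"
            )


@dataclass
class BinCounts:
    """Per-bin read counts for one sample on a fixed bin grid."""

    sample_id: str
    bins: pd.DataFrame
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.counts) != len(self.bins):
            raise ValueError("counts length does not match bin grid")
        if (self.counts < 0).any():
            raise ValueError("read counts must be non-negative")

    @property
    def total_reads(self) -> int:
        return int(self.counts.sum())


@dataclass
class CellCNMatrix:
    """Integer copy-number calls per bin for a set of single cells (or clones).

    ``cn`` is (n_bins, n_cells); ``meta`` is indexed by cell id and may carry
    ``tumor`` and ``ploidy_group`` columns used by the diversity metrics.
    """

    bins: pd.DataFrame
    cn: np.ndarray
    cell_ids: list[str]
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.cn = np.asarray(self.cn, dtype=np.int64)
        if self.cn.ndim != 2 or self.cn.shape != (len(self.bins), len(self.cell_ids)):
            raise ValueError("cn must be (n_bins, n_cells)")
        if (self.cn < 0).any():
            raise ValueError("copy numbers must be >= 0")
        if self.meta.empty:
            self.meta = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id"))

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def subset(self, keep: list[str]) -> "CellCNMatrix":
        idx = [self.cell_ids.index(c) for c in keep]
        return CellCNMatrix(
            bins=self.bins,
            cn=self.cn[:, idx],
            cell_ids=list(keep),
            meta=self.meta.loc[keep].copy(),
        )


@dataclass
class CohortCNMatrix:
    """Gain/neutral/loss states per bin for a cohort of tumors.

    ``states`` is (n_bins, n_tumors) with values +1 (gain), 0 (neutral),
    -1 (loss); masked bins are encoded as the sentinel ``MASKED``.
    """

    MASKED = -9

    bins: pd.DataFrame
    states: np.ndarray
    tumor_ids: list[str]

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.shape != (len(self.bins), len(self.tumor_ids)):
            raise ValueError("states must be (n_bins, n_tumors)")
        if len(self.tumor_ids) < 2:
            raise ValueError("a cohort requires at least 2 tumors")
        valid = np.isin(self.states, [-1, 0, 1, self.MASKED])
        if not valid.all():
            raise ValueError("states must be in {-1, 0, 1} or masked")

    @classmethod
    def from_integer_cn(
        cls,
        bins: pd.DataFrame,
        cn: np.ndarray,
        tumor_ids: list[str],
        ploidies: np.ndarray | None = None,
    ) -> "CohortCNMatrix":
        """Collapse integer copy numbers to states given per-tumor ploidy.

        CN above ``round(ploidy)`` is a gain, below a loss.  When ploidies
        are not given, each tumor's mean CN is used.
        """
        cn = np.asarray(cn, dtype=float)
        if ploidies is None:
            ploidies = cn.mean(axis=0)
        ref = np.round(np.asarray(ploidies, dtype=float))
        states = np.sign(cn - ref[None, :]).astype(np.int8)
        return cls(bins=bins, states=states, tumor_ids=tumor_ids)
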