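"""Plain-text readers and writers for the pipeline's tabular formats.

Formats are deliberately simple: BED-like bin counts (chrom, start, end,
count), SNP tables (chrom, pos, ref_count, alt_count), copy-number matrices
(bins as rows, samples as columns, preceded by chrom/start/end columns),
long lesion tables, and JSON truth/summary files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import BinCounts, CellCNMatrix, CohortCNMatrix

__all__ = [
    "write_bin_counts", "read_bin_counts",
    "write_snp_table", "read_snp_table",
    "write_cn_matrix", "read_cell_cn_matrix", "read_cohort_matrix",
    "write_lesion_table", "read_lesion_table",
    "write_call_track", "write_json",
]


def write_bin_counts(bc: BinCounts, path: str | Path) -> None:
    out = bc.bins.copy()
    out["count"] = bc.counts
    out.to_csv(path, sep="\t", index=False)


def read_bin_counts(path: str | Path, sample_id: str | None = None) -> BinCounts:
    df = pd.read_csv(path, sep="\t")
    return BinCounts(
        sample_id=sample_id or Path(path).stem,
        bins=df[["chrom", "start", "end"]].copy(),
        counts=df["count"].to_numpy(),
    )


def write_snp_table(snps: pd.DataFrame, path: str | Path) -> None:
    snps.to_csv(path, sep="\t", index=False)


def read_snp_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_cn_matrix(
    bins: pd.DataFrame, values: np.ndarray, sample_ids: list[str], path: str | Path
) -> None:
    out = bins.copy()
    for j, sid in enumerate(sample_ids):
        out[sid] = values[:, j]
    out.to_csv(path, sep="\t", index=False)


def _split_matrix(path: str | Path) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    bins = df[["chrom", "start", "end"]].copy()
    sample_cols = [c for c in df.columns if c not in ("chrom", "start", "end")]
    return bins, df[sample_cols].to_numpy(), sample_cols


def read_cell_cn_matrix(path: str | Path, meta_path: str | Path | None = None) -> CellCNMatrix:
    bins, cn, ids = _split_matrix(path)
    meta = pd.DataFrame()
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t").set_index("cell_id")
    return CellCNMatrix(bins=bins, cn=cn.astype(np.int64), cell_ids=ids, meta=meta)


def read_cohort_matrix(path: str | Path) -> CohortCNMatrix:
    bins, states, ids = _split_matrix(path)
    return CohortCNMatrix(bins=bins, states=states.astype(np.int8), tumor_ids=ids)


def write_lesion_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_lesion_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_call_track(track, path: str | Path) -> None:
    """Per-bin call track as BED-like TSV (chrom, start, end, call, z, p)."""
    track.to_frame().to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
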