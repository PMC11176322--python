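"""Single-cell copy-number QC filters and heterogeneity metrics.

Filtering happens in two passes, in order.  First, near-uniform cells are
removed: a cell with >= 95% of its genome at copy number 2 is a diploid
contaminant (normal epithelium or lymphocyte), and one with >= 95% at copy
number 4 is likely a G2-phase cell or doublet.  Second, noisy profiles are
removed: a cell that shares fewer than 33% of its copy-number breakpoints
and whole-chromosome aberrations with any other cancer cell of the same
tumor (breakpoint match tolerance +-1 bin) is discarded; cells with no
breakpoints at all are kept.

Metrics on the curated cells:

* pairwise diversity — for each cell pair, the fraction of co-covered bins
  with different copy numbers; a pseudometric used as a proxy for
  cell-to-cell (or clone-to-clone) diversity;
* Shannon evenness — cells are grouped into clones by identical profile
  after light median-filter smoothing, and the entropy of clone
  proportions is normalized by ln(number of clones) (0 for a single clone);
* wGII — mean over chromosomes of the fraction of each chromosome's bins
  deviating from the cell's rounded ploidy (equal chromosome weights);
* ploidy and WGD — mean copy number, flagged as genome-doubled at >= 3.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .containers import CellCNMatrix
from .stats import TestResult, mann_whitney_u

__all__ = [
    "filter_normal_cells",
    "filter_noisy_cells",
    "pairwise_diversity",
    "shannon_evenness",
    "wgii",
    "ploidy_and_wgd",
    "group_compare",
]


def filter_normal_cells(
    cells: CellCNMatrix, purity_threshold: float = 0.95
) -> tuple[CellCNMatrix, pd.DataFrame]:
    """Drop diploid-contaminant and G2/doublet cells.

    A cell is excluded when at least ``purity_threshold`` of its bins sit
    at CN 2 (reason "diploid") or at CN 4 (reason "g2").
    """
    frac2 = (cells.cn == 2).mean(axis=0)
    frac4 = (cells.cn == 4).mean(axis=0)
    reasons = []
    keep = []
    for j, cid in enumerate(cells.cell_ids):
        if frac2[j] >= purity_threshold:
            reasons.append((cid, "diploid"))
        elif frac4[j] >= purity_threshold:
            reasons.append((cid, "g2"))
        else:
            keep.append(cid)
    excluded = pd.DataFrame(reasons, columns=["cell_id", "reason"])
    return cells.subset(keep), excluded


def _cell_features(
    cn: np.ndarray, chroms: np.ndarray, ploidy_ref: int
) -> tuple[list[tuple[str, int, int]], list[tuple[str, int]]]:
    """Breakpoints and whole-chromosome aberrations of one cell.

    Breakpoints are (chrom, bin index, integer CN step) transitions inside
    a chromosome; a whole-chromosome aberration is a uniform chromosome
    whose CN differs from the cell's ploidy reference.
    """
    bkpts = []
    wcas = []
    for chrom in pd.unique(chroms):
        idx = np.nonzero(chroms == chrom)[0]
        vals = cn[idx]
        diffs = np.diff(vals)
        steps = np.nonzero(diffs != 0)[0]
        bkpts.extend(
            (str(chrom), int(idx[s + 1]), int(diffs[s])) for s in steps
        )
        if steps.size == 0 and vals[0] != ploidy_ref:
            wcas.append((str(chrom), int(np.sign(vals[0] - ploidy_ref))))
    return bkpts, wcas


def filter_noisy_cells(
    cells: CellCNMatrix, share_threshold: float = 0.33, tol: int = 1
) -> tuple[CellCNMatrix, pd.DataFrame]:
    """Drop cells whose aberrations are mostly private within their tumor.

    For each cell, the fraction of its breakpoints and whole-chromosome
    aberrations found in at least one other cell of the same tumor
    (breakpoints matched within +-``tol`` bins on the same chromosome with
    the same copy-number step) is computed; cells below ``share_threshold``
    are excluded.  Cells without
    any feature are retained, and single-cell tumors are passed through
    with a warning.
    """
    chroms = cells.bins["chrom"].to_numpy()
    tumors = (cells.meta["tumor"] if "tumor" in cells.meta
              else pd.Series("T", index=cells.meta.index))
    features = {}
    for j, cid in enumerate(cells.cell_ids):
        ref = int(np.round(cells.cn[:, j].mean()))
        features[cid] = _cell_features(cells.cn[:, j], chroms, ref)

    keep: list[str] = []
    reasons = []
    for tumor, members in tumors.groupby(tumors):
        ids = [c for c in cells.cell_ids if c in members.index]
        if len(ids) < 2:
            warnings.warn(f"tumor {tumor} has a single cell; noisy-cell filter "
                          "skipped", stacklevel=2)
            keep.extend(ids)
            continue
        for cid in ids:
            bkpts, wcas = features[cid]
            if not bkpts and not wcas:
                keep.append(cid)
                continue
            others = [features[o] for o in ids if o != cid]
            other_bkpts = set(itertools.chain.from_iterable(o[0] for o in others))
            other_wcas = set(itertools.chain.from_iterable(o[1] for o in others))
            shared = 0
            for chrom, pos, step in bkpts:
                if any((chrom, pos + d, step) in other_bkpts
                       for d in range(-tol, tol + 1)):
                    shared += 1
            shared += sum(1 for w in wcas if w in other_wcas)
            frac = shared / (len(bkpts) + len(wcas))
            if frac < share_threshold:
                reasons.append((cid, "noisy", frac))
            else:
                keep.append(cid)
    excluded = pd.DataFrame(reasons, columns=["cell_id", "reason", "shared_fraction"])
    keep = [c for c in cells.cell_ids if c in set(keep)]
    return cells.subset(keep), excluded


def pairwise_diversity(
    cells: CellCNMatrix, within_ploidy_group: bool = True
) -> tuple[pd.DataFrame, pd.Series]:
    """Fraction of the genome with different copy number, per cell pair.

    Returns the symmetric pairwise matrix (NaN for pairs not compared)
    and per-tumor mean diversity.  Pairs are formed within each tumor
    and, when ``within_ploidy_group`` and the metadata carries a
    ``ploidy_group`` column, within the same FACS ploidy group.
    """
    if cells.n_cells < 2:
        raise ValueError("pairwise diversity needs >= 2 cells")
    ids = cells.cell_ids
    mat = pd.DataFrame(np.nan, index=ids, columns=ids)
    np.fill_diagonal(mat.values, 0.0)
    tumors = (cells.meta["tumor"] if "tumor" in cells.meta
              else pd.Series("T", index=cells.meta.index))
    groups = (cells.meta["ploidy_group"]
              if within_ploidy_group and "ploidy_group" in cells.meta else None)

    per_tumor: dict[str, list[float]] = {}
    col = {c: j for j, c in enumerate(ids)}
    for a, b in itertools.combinations(ids, 2):
        if tumors[a] != tumors[b]:
            continue
        if groups is not None and groups[a] != groups[b]:
            continue
        frac = float((cells.cn[:, col[a]] != cells.cn[:, col[b]]).mean())
        mat.loc[a, b] = mat.loc[b, a] = frac
        per_tumor.setdefault(str(tumors[a]), []).append(frac)
    if not per_tumor:
        raise ValueError("no comparable cell pairs")
    means = pd.Series({t: float(np.mean(v)) for t, v in per_tumor.items()},
                      name="mean_diversity")
    return mat, means


def _smooth_profiles(cells: CellCNMatrix, window: int) -> np.ndarray:
    """Median-filter each cell's profile within chromosomes."""
    if window <= 1:
        return cells.cn
    out = cells.cn.copy()
    chroms = cells.bins["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        sel = chroms == chrom
        out[sel, :] = median_filter(
            cells.cn[sel, :], size=(window, 1), mode="nearest"
        )
    return out


def shannon_evenness(cells: CellCNMatrix, smooth_window: int = 3) -> pd.Series:
    """Per-tumor Shannon evenness of clone proportions.

    Cells collapse into clones by exact profile identity after median
    smoothing (window ``smooth_window`` bins within chromosomes).  With
    proportions p_i over k clones, H = -sum p_i ln p_i and evenness is
    H / ln k; a single clone scores 0.
    """
    smoothed = _smooth_profiles(cells, smooth_window)
    tumors = (cells.meta["tumor"] if "tumor" in cells.meta
              else pd.Series("T", index=cells.meta.index))
    result = {}
    for tumor, members in tumors.groupby(tumors):
        idx = [cells.cell_ids.index(c) for c in members.index]
        profiles = [smoothed[:, j].tobytes() for j in idx]
        _, counts = np.unique(profiles, return_counts=True)
        k = counts.size
        if k < 2:
            result[str(tumor)] = 0.0
            continue
        p = counts / counts.sum()
        h = float(-(p * np.log(p)).sum())
        result[str(tumor)] = h / np.log(k)
    return pd.Series(result, name="shannon_evenness")


def wgii(cn: np.ndarray, chroms: Sequence[str], ploidy: float) -> float:
    """Weighted genome instability index of one profile.

    Per chromosome, the fraction of bins whose CN differs from
    round(ploidy); the wGII is the unweighted mean over chromosomes, so
    each chromosome contributes equally regardless of length.  NaN bins
    are masked; fully masked chromosomes are excluded.
    """
    if ploidy <= 0:
        raise ValueError("ploidy must be > 0")
    cn = np.asarray(cn, dtype=float)
    chroms = np.asarray(chroms)
    ref = np.round(ploidy)
    fractions = []
    for chrom in pd.unique(chroms):
        vals = cn[chroms == chrom]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            continue
        fractions.append(float((vals != ref).mean()))
    if not fractions:
        raise ValueError("no unmasked chromosomes")
    return float(np.mean(fractions))


def ploidy_and_wgd(cn: np.ndarray, wgd_threshold: float = 3.0) -> tuple[float, bool]:
    """Mean copy number of a profile and whether it indicates genome doubling."""
    cn = np.asarray(cn, dtype=float)
    cn = cn[np.isfinite(cn)]
    if cn.size == 0:
        raise ValueError("no unmasked bins")
    ploidy = float(cn.mean())
    return ploidy, bool(ploidy >= wgd_threshold)


def group_compare(
    values_by_group: Mapping[str, Sequence[float]],
) -> dict[str, TestResult]:
    """Two-sided Mann-Whitney U comparisons between all group pairs."""
    labels = list(values_by_group)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    for lab in labels:
        if len(values_by_group[lab]) == 0:
            raise ValueError(f"group {lab!r} is empty")
    return {
        f"{a}|{b}": mann_whitney_u(values_by_group[a], values_by_group[b])
        for a, b in itertools.combinations(labels, 2)
    }
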