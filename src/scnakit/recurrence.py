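"""Recurrent-SCNA detection by sampling simulation, plus euploidy-deviation
tracks and cross-species synteny projection.

Given a cohort of gain/neutral/loss profiles, each tumor's genome-wide gain
and loss rates are estimated as the fraction of (unmasked) bins affected.
A background distribution of per-bin alteration counts is then simulated:
in each of ``n_sim`` replicates, every tumor contributes a gain with its
own probability Rg (and, independently, a loss with Rl), and the counts
are summed over tumors.  The upper bound of the central 95% interval of
that empirical null (the 97.5th percentile) defines a single genome-wide
count threshold; bins whose observed count strictly exceeds it are
recurrent, and adjacent flagged bins merge into regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import CohortCNMatrix

__all__ = [
    "RatePair",
    "NullThresholds",
    "RecurrenceResult",
    "estimate_rates",
    "simulate_null",
    "recurrent_regions",
    "deviation_from_euploidy",
    "project_synteny",
]


@dataclass(frozen=True)
class RatePair:
    """Fractions of a tumor's genome gained and lost."""

    tumor_id: str
    r_gain: float
    r_loss: float

    def __post_init__(self) -> None:
        if not (0 <= self.r_gain <= 1 and 0 <= self.r_loss <= 1):
            raise ValueError("rates must be in [0, 1]")
        if self.r_gain + self.r_loss > 1 + 1e-12:
            raise ValueError("r_gain + r_loss must be <= 1")


@dataclass
class NullThresholds:
    gain_threshold: float
    loss_threshold: float
    null_gain: np.ndarray
    null_loss: np.ndarray
    n_simulations: int
    percentile: float


@dataclass
class RecurrenceResult:
    observed_gain: np.ndarray
    observed_loss: np.ndarray
    thresholds: NullThresholds
    recurrent_gain: np.ndarray  # bool per bin
    recurrent_loss: np.ndarray
    gain_regions: list[tuple[str, int, int]] = field(default_factory=list)
    loss_regions: list[tuple[str, int, int]] = field(default_factory=list)


def estimate_rates(cohort: CohortCNMatrix) -> list[RatePair]:
    """Per-tumor gain/loss rates as fractions of the unmasked genome."""
    rates = []
    for j, tid in enumerate(cohort.tumor_ids):
        col = cohort.states[:, j]
        valid = col != CohortCNMatrix.MASKED
        if not valid.any():
            raise ValueError(f"tumor {tid} has all bins masked")
        n = int(valid.sum())
        rates.append(RatePair(
            tumor_id=tid,
            r_gain=float((col[valid] == 1).sum() / n),
            r_loss=float((col[valid] == -1).sum() / n),
        ))
    return rates


def simulate_null(
    rates: Sequence[RatePair],
    n_sim: int = 1000,
    seed: int | np.random.Generator | None = None,
    percentile: float = 97.5,
) -> NullThresholds:
    """Bernoulli sampling simulation of per-bin alteration counts.

    Each simulation draws, for every tumor, one Bernoulli(Rg) gain
    indicator and one Bernoulli(Rl) loss indicator, and sums over tumors.
    Thresholds are the ``percentile`` of the simulated totals (97.5 = the
    upper bound of the central 95% interval; pass 95 for a one-sided
    reading).
    """
    if len(rates) < 2:
        raise ValueError("need >= 2 tumors")
    if n_sim < 100:
        warnings.warn(f"n_sim={n_sim} < 100: unstable percentile estimate",
                      stacklevel=2)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    rg = np.array([r.r_gain for r in rates])
    rl = np.array([r.r_loss for r in rates])
    null_gain = (rng.random((n_sim, rg.size)) < rg[None, :]).sum(axis=1)
    null_loss = (rng.random((n_sim, rl.size)) < rl[None, :]).sum(axis=1)
    return NullThresholds(
        gain_threshold=float(np.percentile(null_gain, percentile)),
        loss_threshold=float(np.percentile(null_loss, percentile)),
        null_gain=null_gain,
        null_loss=null_loss,
        n_simulations=n_sim,
        percentile=percentile,
    )


def _merge_regions(flags: np.ndarray, chroms: np.ndarray) -> list[tuple[str, int, int]]:
    """Merge adjacent flagged bins on one chromosome into (chrom, lo, hi)."""
    regions = []
    start = None
    for i, f in enumerate(flags):
        boundary = i > 0 and chroms[i] != chroms[i - 1]
        if start is not None and (not f or boundary):
            regions.append((str(chroms[start]), start, i - 1))
            start = None
        if f and start is None:
            start = i
    if start is not None:
        regions.append((str(chroms[start]), start, len(flags) - 1))
    return regions


def recurrent_regions(
    cohort: CohortCNMatrix, thresholds: NullThresholds
) -> RecurrenceResult:
    """Flag bins whose observed alteration count exceeds the null threshold."""
    obs_gain = (cohort.states == 1).sum(axis=1)
    obs_loss = (cohort.states == -1).sum(axis=1)
    rec_gain = obs_gain > thresholds.gain_threshold
    rec_loss = obs_loss > thresholds.loss_threshold
    chroms = cohort.bins["chrom"].to_numpy()
    return RecurrenceResult(
        observed_gain=obs_gain,
        observed_loss=obs_loss,
        thresholds=thresholds,
        recurrent_gain=rec_gain,
        recurrent_loss=rec_loss,
        gain_regions=_merge_regions(rec_gain, chroms),
        loss_regions=_merge_regions(rec_loss, chroms),
    )


def deviation_from_euploidy(
    cn: np.ndarray,
    groups: Mapping[str, Sequence[int]],
) -> pd.DataFrame:
    """Signed per-bin mean deviation from copy-number 2 per group.

    ``cn`` is (n_bins, n_samples); ``groups`` maps a label to column
    indices.  Deviations are non-absolute, so balanced gains and losses
    cancel.  Empty groups are skipped with a warning.
    """
    cn = np.asarray(cn, dtype=float)
    out = {}
    for label, cols in groups.items():
        cols = list(cols)
        if not cols:
            warnings.warn(f"group {label!r} is empty; skipped", stacklevel=2)
            continue
        out[label] = (cn[:, cols] - 2.0).mean(axis=1)
    return pd.DataFrame(out)


def _interval_mean(
    values: np.ndarray, starts: np.ndarray, bin_size: int, lo: float, hi: float
) -> tuple[float, float]:
    """Length-weighted mean of per-bin values over [lo, hi) on one chromosome.

    Returns (mean, covered_length); bins with NaN values are skipped.
    """
    first = int(np.searchsorted(starts, lo, side="right") - 1)
    first = max(first, 0)
    total = 0.0
    weight = 0.0
    for b in range(first, len(starts)):
        b_lo, b_hi = starts[b], starts[b] + bin_size
        if b_lo >= hi:
            break
        ov = min(hi, b_hi) - max(lo, b_lo)
        if ov <= 0 or not np.isfinite(values[b]):
            continue
        total += values[b] * ov
        weight += ov
    if weight == 0:
        return np.nan, 0.0
    return total / weight, weight


def project_synteny(
    source_values: np.ndarray,
    source_bins: pd.DataFrame,
    blocks: pd.DataFrame,
    target_bins: pd.DataFrame,
) -> np.ndarray:
    """Project a per-bin frequency track through homology blocks.

    ``blocks`` needs columns source_chrom, source_start, source_end,
    target_chrom, target_start, target_end.  Each target bin's value is
    the length-weighted mean of the source-bin values mapped into it by
    overlapping blocks (coordinates mapped linearly within each block;
    orientation is ignored because frequencies are strandless).  Target
    bins with no block coverage are NaN.
    """
    source_values = np.asarray(source_values, dtype=float)
    src_by_chrom = {
        chrom: (grp.index.to_numpy(), grp["start"].to_numpy())
        for chrom, grp in source_bins.reset_index(drop=True).groupby("chrom", sort=False)
    }
    src_bin_size = int((source_bins["end"] - source_bins["start"]).iloc[0])

    tgt_chroms = target_bins["chrom"].to_numpy()
    tgt_starts = target_bins["start"].to_numpy()
    tgt_ends = target_bins["end"].to_numpy()
    acc = np.zeros(len(target_bins))
    wts = np.zeros(len(target_bins))

    for _, blk in blocks.iterrows():
        s_len = blk["source_end"] - blk["source_start"]
        t_len = blk["target_end"] - blk["target_start"]
        if s_len <= 0 or t_len <= 0:
            raise ValueError(f"malformed synteny block with non-positive length: "
                             f"{blk.to_dict()}")
        if blk["source_chrom"] not in src_by_chrom:
            continue
        rows, starts = src_by_chrom[blk["source_chrom"]]
        vals = source_values[rows]
        hit = np.nonzero(
            (tgt_chroms == blk["target_chrom"])
            & (tgt_starts < blk["target_end"])
            & (tgt_ends > blk["target_start"])
        )[0]
        for t in hit:
            t_lo = max(tgt_starts[t], blk["target_start"])
            t_hi = min(tgt_ends[t], blk["target_end"])
            # map the target overlap linearly into source coordinates
            s_lo = blk["source_start"] + (t_lo - blk["target_start"]) * s_len / t_len
            s_hi = blk["source_start"] + (t_hi - blk["target_start"]) * s_len / t_len
            mean, covered = _interval_mean(vals, starts, src_bin_size, s_lo, s_hi)
            if covered > 0:
                w = t_hi - t_lo
                acc[t] += mean * w
                wts[t] += w
    with np.errstate(invalid="ignore"):
        out = np.where(wts > 0, acc / np.maximum(wts, 1e-300), np.nan)
    return out
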