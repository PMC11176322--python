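"""Progenitor-referenced somatic copy-number calling.

Calls gains and losses acquired by a daughter clone relative to its
single-cell-derived progenitor, without a matched normal sample.  The
procedure has four steps:

1. **Depth ratios.**  Library-size-normalized per-bin read-depth ratios
   daughter/progenitor; bins with zero coverage in either sample are
   masked.  A bin whose copy number is unchanged has expected ratio 1.
2. **Balanced bins.**  Heterozygous SNPs (depth >= 40, alt reads >= 10)
   are tested for allelic balance against BAF 0.5 with an exact two-sided
   binomial test; a bin is allelically balanced when more than 20% of its
   retained SNPs are compatible with balance.  Balanced bins anchor the
   reference copy-number state.
3. **Segmentation.**  Per-chromosome recursive binary changepoint
   segmentation of the ratio track with a penalized stopping rule, so
   neighbouring bins affected by the same event share a segment mean.
4. **Reference model and calls.**  A Gaussian mixture (component count by
   BIC) is fitted to the log-ratios of balanced bins — on the log scale
   the Poisson ratio noise is symmetric and its spread does not depend on
   the copy-number state — and the largest-weight component is the
   reference.  Each bin is tested with a two-sided Z-test of its segment's
   mean log-ratio against the reference; rejected bins above the reference
   mean are gains, below are losses (default alpha 0.1%, no
   multiple-testing correction — the alpha is set with the per-genome
   false-positive count in mind).

By default the Z statistic uses the standard error of the segment mean,
reference sigma / sqrt(min(segment length, ``n_cap``)).  The cap bounds
how far averaging can shrink the denominator, so that the small residual
uncertainty in the fitted reference mean cannot turn long neutral
segments into false calls; ``use_segment_se=False`` tests against the raw
bin-level sigma, which is far more conservative and misses single-copy
events on higher-ploidy backgrounds at moderate depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.mixture import GaussianMixture

from .containers import BinCounts, check_same_grid

__all__ = [
    "DepthRatioTrack",
    "Segment",
    "ReferenceModel",
    "CNCallTrack",
    "compute_depth_ratio",
    "test_snp_balance",
    "assign_snps_to_bins",
    "identify_balanced_bins",
    "segment_ratios",
    "fit_reference_model",
    "call_gains_losses",
    "annotate_genes",
    "call_clone_pair",
]


@dataclass
class DepthRatioTrack:
    """Library-size-normalized daughter/progenitor ratios on a bin grid."""

    bins: pd.DataFrame
    ratio: np.ndarray          # NaN where masked
    masked: np.ndarray         # True = excluded (zero coverage)

    @property
    def n_bins(self) -> int:
        return len(self.bins)


@dataclass(frozen=True)
class Segment:
    """A run of bins sharing one ratio level (global indices, inclusive)."""

    chrom: str
    start_bin: int
    end_bin: int
    mean_ratio: float
    n_bins: int


@dataclass
class ReferenceModel:
    """Gaussian mixture over balanced-bin log-ratios; the largest-weight
    component is the reference copy-number state.  Means/sigmas are on
    the natural-log scale."""

    means: np.ndarray
    sigmas: np.ndarray
    weights: np.ndarray
    reference_index: int

    @property
    def reference_mu(self) -> float:
        return float(self.means[self.reference_index])

    @property
    def reference_sigma(self) -> float:
        return float(self.sigmas[self.reference_index])


@dataclass
class CNCallTrack:
    """Per-bin gain/neutral/loss/masked calls with Z scores and p-values."""

    bins: pd.DataFrame
    call: np.ndarray           # str array: gain/neutral/loss/masked
    z: np.ndarray
    p: np.ndarray
    segments: list[Segment] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        out = self.bins.copy()
        out["call"] = self.call
        out["z"] = self.z
        out["p"] = self.p
        return out


def compute_depth_ratio(progenitor: BinCounts, daughter: BinCounts) -> DepthRatioTrack:
    """Per-bin read-depth ratio daughter/progenitor, library-size normalized.

    The per-bin ratio is multiplied by progenitor_total/daughter_total so
    that a copy-number-unchanged bin has expected ratio 1.  Bins with zero
    coverage in either sample are masked.
    """
    check_same_grid(progenitor.bins, daughter.bins)
    p = progenitor.counts.astype(float)
    d = daughter.counts.astype(float)
    masked = (p == 0) | (d == 0)
    scale = progenitor.total_reads / daughter.total_reads
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(masked, np.nan, d / np.where(p == 0, np.nan, p) * scale)
    return DepthRatioTrack(bins=progenitor.bins, ratio=ratio, masked=masked)


def _binom_two_sided_half(k: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Exact two-sided binomial p at rate 0.5, vectorized.

    The Binomial(n, 0.5) pmf is symmetric, so the minimum-likelihood
    two-sided p equals twice the smaller tail (capped at 1).
    """
    k = np.asarray(k)
    n = np.asarray(n)
    lower = sps.binom.cdf(k, n, 0.5)
    upper = sps.binom.sf(k - 1, n, 0.5)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


def test_snp_balance(
    snps: pd.DataFrame,
    alpha: float = 0.05,
    min_depth: int = 40,
    min_alt: int = 10,
) -> pd.DataFrame:
    """Filter SNPs and test each for allelic balance against BAF 0.5.

    Returns a copy with depth, baf, balance_p, balanced and retained
    columns; records failing the depth/alt-count filters are marked
    retained=False with a drop reason.
    """
    out = snps.copy()
    out["depth"] = out["ref_count"] + out["alt_count"]
    with np.errstate(invalid="ignore", divide="ignore"):
        out["baf"] = np.where(out["depth"] > 0, out["alt_count"] / out["depth"], np.nan)
    reason = np.where(
        out["depth"] < min_depth, f"depth<{min_depth}",
        np.where(out["alt_count"] < min_alt, f"alt<{min_alt}", ""),
    )
    out["retained"] = reason == ""
    out["drop_reason"] = reason
    out["balance_p"] = _binom_two_sided_half(
        out["alt_count"].to_numpy(), out["depth"].to_numpy()
    )
    out["balanced"] = out["retained"] & (out["balance_p"] >= alpha)
    return out


def assign_snps_to_bins(snps: pd.DataFrame, bins: pd.DataFrame) -> np.ndarray:
    """Global bin index for each SNP (-1 when outside the grid)."""
    snps = snps.reset_index(drop=True)
    idx = np.full(len(snps), -1, dtype=np.int64)
    offsets = {}
    pos0 = 0
    for chrom, grp in bins.groupby("chrom", sort=False):
        offsets[chrom] = (pos0, grp["start"].to_numpy(), grp["end"].to_numpy())
        pos0 += len(grp)
    for chrom, grp in snps.groupby("chrom", sort=False):
        if chrom not in offsets:
            continue
        base, starts, ends = offsets[chrom]
        j = np.searchsorted(starts, grp["pos"].to_numpy(), side="right") - 1
        ok = (j >= 0) & (grp["pos"].to_numpy() < ends[np.clip(j, 0, len(ends) - 1)])
        idx[grp.index.to_numpy()[ok]] = base + j[ok]
    return idx


def identify_balanced_bins(
    snps: pd.DataFrame,
    bins: pd.DataFrame,
    min_fraction: float = 0.20,
    min_snps: int = 5,
) -> np.ndarray:
    """Flag bins where allelic balance cannot be excluded.

    A bin is balanced when strictly more than ``min_fraction`` of its
    retained SNPs are compatible with BAF 0.5 and it holds at least
    ``min_snps`` retained SNPs; bins with too few SNPs stay unflagged
    (vacuous evidence).
    """
    if "balanced" not in snps.columns:
        raise ValueError("run test_snp_balance first")
    snps = snps.reset_index(drop=True)
    bin_idx = assign_snps_to_bins(snps, bins)
    keep = snps["retained"].to_numpy() & (bin_idx >= 0)
    n_ret = np.bincount(bin_idx[keep], minlength=len(bins))
    n_bal = np.bincount(
        bin_idx[keep & snps["balanced"].to_numpy()], minlength=len(bins)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_ret > 0, n_bal / np.maximum(n_ret, 1), 0.0)
    return (n_ret >= min_snps) & (frac > min_fraction)


def _robust_sigma2(x: np.ndarray) -> float:
    """Noise variance from median absolute successive differences."""
    if len(x) < 3:
        return float(np.var(x)) if len(x) > 1 else 1e-8
    d = np.abs(np.diff(x))
    s = np.median(d) / (0.6744897501960817 * np.sqrt(2.0))
    return max(float(s * s), 1e-12)


def _best_split(x: np.ndarray, min_size: int) -> tuple[int, float]:
    """Best changepoint by within-segment SSE reduction (O(n))."""
    n = len(x)
    cs = np.cumsum(x)
    total = cs[-1]
    k = np.arange(min_size, n - min_size + 1)
    left = cs[k - 1]
    # SSE reduction of splitting at k equals the between-group sum of squares
    gain = left**2 / k + (total - left) ** 2 / (n - k) - total**2 / n
    i = int(np.argmax(gain))
    return int(k[i]), float(gain[i])


def _segment_1d(x: np.ndarray, threshold: float, min_size: int) -> list[int]:
    """Recursive binary segmentation; returns sorted changepoints."""
    n = len(x)
    if n < 2 * min_size:
        return []
    split, gain = _best_split(x, min_size)
    if gain <= threshold:
        return []
    left = _segment_1d(x[:split], threshold, min_size)
    right = _segment_1d(x[split:], threshold, min_size)
    return left + [split] + [split + c for c in right]


def segment_ratios(
    track: DepthRatioTrack,
    penalty: float = 3.0,
    min_size: int = 2,
) -> list[Segment]:
    """Per-chromosome changepoint segmentation of the ratio track.

    A candidate split is accepted when its SSE reduction exceeds
    ``penalty * sigma^2 * log(n)`` with sigma estimated robustly from
    successive differences and n the chromosome's unmasked bin count.
    Masked bins are skipped; a fully masked chromosome is skipped with a
    warning.
    """
    segments: list[Segment] = []
    chroms = track.bins["chrom"].to_numpy()
    for chrom in track.bins["chrom"].unique():
        sel = np.nonzero((chroms == chrom) & ~track.masked)[0]
        if sel.size == 0:
            warnings.warn(f"chromosome {chrom} fully masked; skipped", stacklevel=2)
            continue
        x = track.ratio[sel]
        if sel.size == 1:
            segments.append(Segment(chrom, int(sel[0]), int(sel[0]), float(x[0]), 1))
            continue
        sigma2 = _robust_sigma2(x)
        threshold = penalty * sigma2 * np.log(sel.size)
        cps = _segment_1d(x, threshold, min_size)
        bounds = [0] + cps + [sel.size]
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            segments.append(Segment(
                chrom=str(chrom),
                start_bin=int(sel[lo]),
                end_bin=int(sel[hi - 1]),
                mean_ratio=float(x[lo:hi].mean()),
                n_bins=hi - lo,
            ))
    return segments


def fit_reference_model(
    track: DepthRatioTrack,
    balanced_bins: np.ndarray,
    max_components: int = 5,
    n_init: int = 10,
    min_balanced: int = 50,
    sigma_floor: float = 1e-4,
    random_state: int = 0,
) -> ReferenceModel:
    """Fit a Gaussian mixture to balanced-bin log-ratios; pick K by BIC.

    The component with the largest weight is the reference copy-number
    state.  Its sigma is floored at ``sigma_floor`` to avoid a degenerate
    reference on (near-)constant input.
    """
    values = track.ratio[np.asarray(balanced_bins, bool) & ~track.masked]
    values = np.log(values[np.isfinite(values) & (values > 0)])
    if values.size < min_balanced:
        raise ValueError(
            f"only {values.size} balanced bins (< {min_balanced}); relax the "
            "balanced-bin thresholds or provide more SNPs"
        )
    X = values.reshape(-1, 1)
    best = None
    best_bic = np.inf
    for k in range(1, max_components + 1):
        gm = GaussianMixture(
            n_components=k, n_init=n_init, random_state=random_state,
            reg_covar=1e-8,
        ).fit(X)
        bic = gm.bic(X)
        if bic < best_bic:
            best, best_bic = gm, bic
    means = best.means_.ravel()
    sigmas = np.sqrt(best.covariances_.ravel())
    sigmas = np.maximum(sigmas, sigma_floor)
    weights = best.weights_.ravel()
    return ReferenceModel(
        means=means, sigmas=sigmas, weights=weights,
        reference_index=int(np.argmax(weights)),
    )


def call_gains_losses(
    segments: list[Segment],
    model: ReferenceModel,
    track: DepthRatioTrack,
    alpha: float = 0.001,
    use_segment_se: bool = True,
    n_cap: int = 16,
) -> CNCallTrack:
    """Two-sided Z-test of each segment's mean log-ratio vs the reference.

    Bins in segments rejected above the reference mean are gains, below
    are losses; everything else is neutral.  With ``use_segment_se`` the
    Z denominator is reference sigma / sqrt(min(segment length, n_cap));
    otherwise the raw bin-level sigma.
    """
    sigma = model.reference_sigma
    if sigma <= 0:
        raise ValueError("reference sigma is zero; cannot test")
    n = track.n_bins
    call = np.full(n, "masked", dtype=object)
    z = np.full(n, np.nan)
    p = np.full(n, np.nan)
    log_ratio = np.where(
        ~track.masked & (track.ratio > 0), np.log(np.where(track.ratio > 0,
                                                           track.ratio, 1.0)),
        np.nan,
    )
    for seg in segments:
        vals = log_ratio[seg.start_bin:seg.end_bin + 1]
        seg_mean = float(np.nanmean(vals))
        if use_segment_se:
            se = sigma / np.sqrt(min(seg.n_bins, n_cap))
        else:
            se = sigma
        zval = (seg_mean - model.reference_mu) / se
        pval = 2.0 * sps.norm.sf(abs(zval))
        if pval < alpha:
            label = "gain" if zval > 0 else "loss"
        else:
            label = "neutral"
        sl = slice(seg.start_bin, seg.end_bin + 1)
        inside = ~track.masked[sl]
        idx = np.arange(seg.start_bin, seg.end_bin + 1)[inside]
        call[idx] = label
        z[idx] = zval
        p[idx] = pval
    return CNCallTrack(bins=track.bins, call=np.asarray(call), z=z, p=p,
                       segments=list(segments))


def annotate_genes(calls: CNCallTrack, genes: pd.DataFrame) -> dict[str, list[str]]:
    """Gene lists overlapping gained / lost bins (any-overlap rule).

    ``genes`` needs columns gene, chrom, start, end (half-open, same
    genome layout as the bin grid).  Genes outside the grid are skipped
    with a warning.
    """
    gained: list[str] = []
    lost: list[str] = []
    bins = calls.bins
    for _, g in genes.iterrows():
        sel = (
            (bins["chrom"] == g["chrom"])
            & (bins["start"] < g["end"])
            & (bins["end"] > g["start"])
        ).to_numpy()
        if not sel.any():
            warnings.warn(f"gene {g['gene']} outside the bin grid; skipped",
                          stacklevel=2)
            continue
        hits = calls.call[sel]
        if (hits == "gain").any():
            gained.append(str(g["gene"]))
        if (hits == "loss").any():
            lost.append(str(g["gene"]))
    return {"gained": gained, "lost": lost}


def call_clone_pair(
    progenitor: BinCounts,
    daughter: BinCounts,
    snps: pd.DataFrame,
    alpha: float = 0.001,
    balance_alpha: float = 0.05,
    min_fraction: float = 0.20,
    min_snps: int = 5,
    penalty: float = 3.0,
    use_segment_se: bool = True,
    n_cap: int = 16,
    random_state: int = 0,
) -> CNCallTrack:
    """Run the full four-step caller on one progenitor/daughter pair."""
    track = compute_depth_ratio(progenitor, daughter)
    tested = test_snp_balance(snps, alpha=balance_alpha)
    balanced = identify_balanced_bins(
        tested, track.bins, min_fraction=min_fraction, min_snps=min_snps
    )
    segments = segment_ratios(track, penalty=penalty)
    model = fit_reference_model(track, balanced, random_state=random_state)
    return call_gains_losses(
        segments, model, track, alpha=alpha, use_segment_se=use_segment_se,
        n_cap=n_cap,
    )
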