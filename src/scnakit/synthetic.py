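"""Synthetic inputs for every stage of the pipeline.

The generators emulate the statistical structure the analyses assume:

* clone-pair binned whole-genome coverage with planted gains/losses on a
  known background ploidy, Poisson counts and a shared log-normal per-bin
  bias (so progenitor normalization is meaningful), plus heterozygous-SNP
  allele counts that are binomially balanced outside planted events and
  imbalanced inside them;
* single-cell copy-number matrices with planted subclonal divergence,
  whole-genome-doubled cells, diploid contaminants and noisy cells;
* cohorts of per-tumor gain/neutral/loss profiles with controllable rates
  and optionally boosted recurrent bins;
* patient lesion-diameter trajectories with planted homogeneous / mixed /
  new-lesion / non-responder structure.

Every generator is driven by a single integer seed through
``numpy.random.default_rng`` and is byte-identical across runs for a fixed
configuration.  Ground truth is returned alongside each dataset so that
downstream modules can be tested by recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import BinCounts, CellCNMatrix, CohortCNMatrix, make_bin_grid

__all__ = [
    "SimConfig",
    "PlantedEvent",
    "PlantedTruth",
    "generate_clone_pair",
    "generate_single_cell_tumor",
    "generate_cohort_profiles",
    "generate_lesion_cohort",
    "sample_events",
]

LESION_CATEGORIES = (
    "homogeneous", "mixed_existing", "mixed_new_lesion", "non_responder",
)


@dataclass(frozen=True)
class SimConfig:
    """Shared simulation parameters.

    bias_sd is the standard deviation (log scale) of the multiplicative
    per-bin coverage bias shared between progenitor and daughter samples;
    snps_per_bin is the mean density of putative heterozygous SNPs.
    """

    seed: int = 0
    n_bins: int = 3000
    bin_size: int = 1_000_000
    n_chromosomes: int = 20
    bias_sd: float = 0.1
    snps_per_bin: int = 20

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.n_bins < self.n_chromosomes:
            raise ValueError("need n_bins >= n_chromosomes >= 1")
        if self.bias_sd < 0:
            raise ValueError("bias_sd must be >= 0")

    def bin_grid(self) -> pd.DataFrame:
        return make_bin_grid(self.n_bins, self.n_chromosomes, self.bin_size)


@dataclass(frozen=True)
class PlantedEvent:
    """A planted copy-number event over global bin indices [start_bin, end_bin)."""

    start_bin: int
    end_bin: int
    delta: int  # integer copy delta; >0 gain, <0 loss

    def __post_init__(self) -> None:
        if self.delta == 0:
            raise ValueError("event magnitude must be nonzero")
        if not (0 <= self.start_bin < self.end_bin):
            raise ValueError("event interval must be non-empty and non-negative")

    @property
    def kind(self) -> str:
        return "gain" if self.delta > 0 else "loss"

    @property
    def bins(self) -> np.ndarray:
        return np.arange(self.start_bin, self.end_bin)


@dataclass
class PlantedTruth:
    """Ground truth emitted by the generators."""

    events: list[PlantedEvent] = field(default_factory=list)
    ploidy: float | None = None
    cell_labels: dict[str, str] = field(default_factory=dict)
    cell_ploidy: dict[str, float] = field(default_factory=dict)
    patient_categories: dict[str, str] = field(default_factory=dict)
    tumor_rates: dict[str, tuple[float, float]] = field(default_factory=dict)
    recurrent_bins: list[int] = field(default_factory=list)

    def event_bin_mask(self, n_bins: int) -> np.ndarray:
        """Signed per-bin truth: +1 in gains, -1 in losses, 0 elsewhere."""
        mask = np.zeros(n_bins, dtype=np.int8)
        for ev in self.events:
            mask[ev.start_bin:ev.end_bin] = 1 if ev.delta > 0 else -1
        return mask

    def to_json_dict(self) -> dict:
        d = asdict(self)
        d["events"] = [asdict(e) | {"kind": e.kind} for e in self.events]
        return d


def _check_events(events: Sequence[PlantedEvent], n_bins: int) -> None:
    taken = np.zeros(n_bins, dtype=bool)
    for ev in events:
        if ev.end_bin > n_bins:
            raise ValueError(f"event {ev} extends past the bin grid ({n_bins} bins)")
        if taken[ev.start_bin:ev.end_bin].any():
            raise ValueError(f"overlapping planted events: {list(events)}")
        taken[ev.start_bin:ev.end_bin] = True


def sample_events(
    rng: np.random.Generator,
    cfg: SimConfig,
    n_events: int,
    min_len: int = 5,
    max_len: int = 40,
    deltas: Sequence[int] = (-2, -1, 1, 2, 3),
) -> list[PlantedEvent]:
    """Draw non-overlapping events confined to single chromosomes."""
    grid = cfg.bin_grid()
    chrom_of = grid["chrom"].to_numpy()
    events: list[PlantedEvent] = []
    taken = np.zeros(cfg.n_bins, dtype=bool)
    attempts = 0
    while len(events) < n_events and attempts < 1000 * n_events:
        attempts += 1
        length = int(rng.integers(min_len, max_len + 1))
        start = int(rng.integers(0, cfg.n_bins - length + 1))
        end = start + length
        if chrom_of[start] != chrom_of[end - 1]:
            continue
        if taken[max(0, start - 1):min(cfg.n_bins, end + 1)].any():
            continue
        delta = int(rng.choice(np.asarray(deltas)))
        events.append(PlantedEvent(start, end, delta))
        taken[start:end] = True
    if len(events) < n_events:
        raise RuntimeError("could not place the requested number of events")
    return sorted(events, key=lambda e: e.start_bin)


def _planted_baf(ploidy: float, delta: int) -> float:
    """Expected B-allele frequency in an event bin.

    The event is modelled as altering a single parental allele: starting
    from a balanced ploidy/2 per allele, a gain of +d raises the alternate
    allele to ploidy/2 + d out of ploidy + d total copies (losses mirror).
    Clamped away from 0/1 to mimic residual sequencing error.
    """
    alt = ploidy / 2.0 + delta
    tot = ploidy + delta
    if tot <= 0:
        return 0.02
    return float(np.clip(alt / tot, 0.02, 0.98))


def generate_clone_pair(
    cfg: SimConfig,
    ploidy: int = 3,
    events: Sequence[PlantedEvent] = (),
    mean_depth: float = 200.0,
    n_snps: int | None = None,
    snp_depth: float = 80.0,
) -> tuple[BinCounts, BinCounts, pd.DataFrame, PlantedTruth]:
    """Simulate progenitor/daughter binned coverage and SNP allele counts.

    Progenitor bin counts are Poisson(mean_depth x bias); daughter counts
    are scaled by (ploidy + delta)/ploidy inside planted events, with the
    multiplicative bias shared between the two samples.  SNP alt counts are
    Binomial(depth, 0.5) in balanced (non-event) bins and Binomial(depth,
    planted BAF) inside events.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    if ploidy < 1:
        raise ValueError("ploidy must be >= 1")
    events = list(events)
    _check_events(events, cfg.n_bins)
    rng = np.random.default_rng(cfg.seed)
    grid = cfg.bin_grid()

    bias = rng.lognormal(mean=0.0, sigma=cfg.bias_sd, size=cfg.n_bins)
    progenitor = rng.poisson(mean_depth * bias)

    mult = np.ones(cfg.n_bins)
    baf = np.full(cfg.n_bins, 0.5)
    for ev in events:
        mult[ev.start_bin:ev.end_bin] = (ploidy + ev.delta) / ploidy
        baf[ev.start_bin:ev.end_bin] = _planted_baf(ploidy, ev.delta)
    daughter = rng.poisson(mean_depth * bias * mult)

    if n_snps is None:
        n_snps = cfg.snps_per_bin * cfg.n_bins
    snp_bins = np.sort(rng.integers(0, cfg.n_bins, size=n_snps))
    offsets = rng.integers(0, cfg.bin_size, size=n_snps)
    depths = rng.poisson(snp_depth, size=n_snps)
    alts = rng.binomial(depths, baf[snp_bins])
    snps = pd.DataFrame({
        "chrom": grid["chrom"].to_numpy()[snp_bins],
        "pos": grid["start"].to_numpy()[snp_bins] + offsets,
        "ref_count": depths - alts,
        "alt_count": alts,
    })

    truth = PlantedTruth(events=events, ploidy=float(ploidy))
    return (
        BinCounts("progenitor", grid, progenitor),
        BinCounts("daughter", grid, daughter),
        snps,
        truth,
    )


def _diverge(
    rng: np.random.Generator,
    profile: np.ndarray,
    grid: pd.DataFrame,
    divergence_rate: float,
    mean_event_bins: float = 10.0,
) -> np.ndarray:
    """Apply random +-1 segment events covering ~divergence_rate of the genome."""
    out = profile.copy()
    n_bins = len(out)
    if divergence_rate <= 0:
        return out
    chrom_of = grid["chrom"].to_numpy()
    n_events = rng.poisson(divergence_rate * n_bins / mean_event_bins)
    for _ in range(n_events):
        length = 1 + rng.geometric(1.0 / mean_event_bins)
        start = int(rng.integers(0, n_bins))
        end = min(start + length, n_bins)
        # confine to one chromosome
        same = np.nonzero(chrom_of[start:end] != chrom_of[start])[0]
        if same.size:
            end = start + int(same[0])
        delta = int(rng.choice([-1, 1]))
        out[start:end] = np.maximum(out[start:end] + delta, 0)
    return out


def generate_single_cell_tumor(
    cfg: SimConfig,
    n_cells: int,
    founder: np.ndarray | None = None,
    divergence_rate: float = 0.05,
    wgd_fraction: float = 0.0,
    contaminant_fraction: float = 0.0,
    noisy_fraction: float = 0.0,
    n_subclones: int = 4,
    noisy_breakpoint_rate: float = 0.01,
    tumor_id: str = "T1",
) -> tuple[CellCNMatrix, PlantedTruth]:
    """Simulate an integer CN matrix for cells of one tumor.

    Cancer cells belong to one of ``n_subclones`` subclones; each subclone
    beyond the founder carries its own segment events covering roughly
    ``divergence_rate`` of the genome, so breakpoints are shared within a
    subclone and cell-to-cell diversity grows with the divergence rate.
    Cell roles are drawn independently per cell: diploid contaminant
    (all-CN-2), noisy (random breakpoints independent of the clonal
    structure), whole-genome doubled (founder x 2 plus the subclone's
    events), or plain tumor cell.
    """
    if n_cells < 2:
        raise ValueError("pairwise metrics are undefined for < 2 cells")
    fracs = (contaminant_fraction, noisy_fraction, wgd_fraction)
    if any(f < 0 or f > 1 for f in fracs) or sum(fracs) > 1:
        raise ValueError("cell-role fractions must be in [0,1] and sum <= 1")
    # independent substreams so that the tumor's clonal layout (founder,
    # cell roles, subclone assignments) is identical across divergence
    # rates for a fixed seed
    rng_layout = np.random.default_rng([cfg.seed, 0])
    rng_events = np.random.default_rng([cfg.seed, 1])
    rng = np.random.default_rng([cfg.seed, 2])
    grid = cfg.bin_grid()
    if founder is None:
        founder = np.full(cfg.n_bins, 2, dtype=np.int64)
        founder = _diverge(rng_layout, founder, grid, 0.15, mean_event_bins=30.0)
    founder = np.asarray(founder, dtype=np.int64)
    if len(founder) != cfg.n_bins:
        raise ValueError("founder profile length must equal n_bins")

    # subclone event sets: deltas on top of the (possibly doubled) founder
    subclone_deltas = [np.zeros(cfg.n_bins, dtype=np.int64)]
    for _ in range(1, max(n_subclones, 1)):
        delta = _diverge(rng_events, np.zeros(cfg.n_bins, dtype=np.int64) + 10,
                         grid, divergence_rate) - 10
        subclone_deltas.append(delta)
    subclone_p = rng_layout.dirichlet(np.full(max(n_subclones, 1), 2.0))

    roles = rng_layout.choice(
        np.array(["contaminant", "noisy", "wgd", "tumor"]),
        size=n_cells,
        p=[fracs[0], fracs[1], fracs[2], 1.0 - sum(fracs)],
    )
    subclone_of = rng_layout.choice(len(subclone_deltas), size=n_cells,
                                    p=subclone_p)
    cn = np.empty((cfg.n_bins, n_cells), dtype=np.int64)
    labels: dict[str, str] = {}
    cell_ids = [f"{tumor_id}_cell{i:03d}" for i in range(n_cells)]
    for j, role in enumerate(roles):
        if role == "contaminant":
            cn[:, j] = 2
        elif role == "noisy":
            # random segmentation unrelated to the clonal structure;
            # replication-timing-like noise affects every chromosome
            bkpts = rng.random(cfg.n_bins) < noisy_breakpoint_rate
            bkpts[0] = True
            chrom_arr = grid["chrom"].to_numpy()
            for chrom in grid["chrom"].unique():
                idx = np.nonzero(chrom_arr == chrom)[0]
                if len(idx) > 2:
                    bkpts[idx[rng.integers(1, len(idx))]] = True
            seg_id = np.cumsum(bkpts)
            seg_cn = rng.integers(0, 7, size=seg_id[-1] + 1)
            cn[:, j] = seg_cn[seg_id]
        elif role == "wgd":
            cn[:, j] = np.maximum(founder * 2 + subclone_deltas[subclone_of[j]], 0)
        else:
            cn[:, j] = np.maximum(founder + subclone_deltas[subclone_of[j]], 0)
        labels[cell_ids[j]] = str(role)

    meta = pd.DataFrame(
        {
            "tumor": tumor_id,
            "ploidy_group": ["4N" if labels[c] == "wgd" else "2N" for c in cell_ids],
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    cells = CellCNMatrix(bins=grid, cn=cn, cell_ids=cell_ids, meta=meta)
    truth = PlantedTruth(
        cell_labels=labels,
        cell_ploidy={c: float(cn[:, j].mean()) for j, c in enumerate(cell_ids)},
    )
    return cells, truth


def generate_cohort_profiles(
    cfg: SimConfig,
    n_tumors: int,
    gain_rate: float | tuple[float, float] = 0.1,
    loss_rate: float | tuple[float, float] = 0.1,
    recurrent_bins: Sequence[int] = (),
    recurrent_rate: float = 0.9,
    recurrent_kind: str = "gain",
) -> tuple[CohortCNMatrix, PlantedTruth]:
    """Simulate per-tumor gain/neutral/loss profiles.

    Rates may be scalars or (low, high) ranges sampled uniformly per tumor.
    Each bin is altered independently: gain with probability Rg, loss with
    Rl (mutually exclusive within a bin of a tumor).  ``recurrent_bins``
    are instead altered with probability ``recurrent_rate``.
    """
    if n_tumors < 2:
        raise ValueError("a cohort requires at least 2 tumors")
    rng = np.random.default_rng(cfg.seed)
    grid = cfg.bin_grid()

    def per_tumor(rate) -> np.ndarray:
        if np.isscalar(rate):
            arr = np.full(n_tumors, float(rate))
        else:
            lo, hi = rate
            arr = rng.uniform(lo, hi, size=n_tumors)
        if (arr < 0).any() or (arr > 1).any():
            raise ValueError("rates must be in [0, 1]")
        return arr

    rg = per_tumor(gain_rate)
    rl = per_tumor(loss_rate)
    if ((rg + rl) > 1).any():
        raise ValueError("gain + loss rate exceeds 1 for some tumor")

    u = rng.random((cfg.n_bins, n_tumors))
    states = np.zeros((cfg.n_bins, n_tumors), dtype=np.int8)
    states[u < rg[None, :]] = 1
    states[(u >= rg[None, :]) & (u < (rg + rl)[None, :])] = -1

    recurrent_bins = list(int(b) for b in recurrent_bins)
    if recurrent_bins:
        if recurrent_kind not in ("gain", "loss"):
            raise ValueError("recurrent_kind must be 'gain' or 'loss'")
        hit = rng.random((len(recurrent_bins), n_tumors)) < recurrent_rate
        val = 1 if recurrent_kind == "gain" else -1
        for i, b in enumerate(recurrent_bins):
            states[b, :] = np.where(hit[i], val, 0)

    tumor_ids = [f"tumor{i:03d}" for i in range(n_tumors)]
    truth = PlantedTruth(
        tumor_rates={t: (float(g), float(l)) for t, g, l in zip(tumor_ids, rg, rl)},
        recurrent_bins=recurrent_bins,
    )
    return CohortCNMatrix(bins=grid, states=states, tumor_ids=tumor_ids), truth


def _draw_changes(rng: np.random.Generator, category: str, n: int) -> tuple[np.ndarray, int]:
    """Per-lesion percent changes plus number of new lesions for one patient.

    Changes are drawn clear of the -30/+10 boundaries so that the planted
    category survives small measurement noise.
    """
    response = lambda k: rng.uniform(-80, -35, size=k)
    stable = lambda k: rng.uniform(-25, 5, size=k)
    progression = lambda k: rng.uniform(15, 60, size=k)
    n_new = 0
    if category == "homogeneous":
        k_resp = int(rng.integers(1, n + 1))
        changes = np.concatenate([response(k_resp), stable(n - k_resp)])
    elif category == "mixed_existing":
        k_resp = int(rng.integers(1, n))
        k_prog = int(rng.integers(1, n - k_resp + 1))
        changes = np.concatenate([
            response(k_resp), progression(k_prog), stable(n - k_resp - k_prog),
        ])
    elif category == "mixed_new_lesion":
        k_resp = int(rng.integers(1, n + 1))
        changes = np.concatenate([response(k_resp), stable(n - k_resp)])
        n_new = int(rng.integers(1, 3))
    elif category == "non_responder":
        k_prog = int(rng.integers(0, n + 1))
        changes = np.concatenate([progression(k_prog), stable(n - k_prog)])
    else:
        raise ValueError(f"unknown category {category!r}")
    return rng.permutation(changes), n_new


def generate_lesion_cohort(
    cfg: SimConfig,
    n_patients: int,
    lesions_per_patient: tuple[int, int] = (2, 8),
    category_mix: Sequence[float] = (0.4, 0.3, 0.1, 0.2),
    noise_sd: float = 0.0,
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Simulate a longitudinal lesion-diameter table.

    ``category_mix`` gives proportions over (homogeneous, mixed_existing,
    mixed_new_lesion, non_responder).  Rows are long-format: patient_id,
    lesion_id, timepoint in {baseline, followup}, diameter_mm, is_new.
    ``noise_sd`` (percent) perturbs follow-up diameters multiplicatively.
    """
    lo, hi = lesions_per_patient
    if lo < 2:
        raise ValueError(
            "mixed response requires >= 2 measurable lesions per patient"
        )
    mix = np.asarray(category_mix, dtype=float)
    if mix.size != 4 or (mix < 0).any() or not np.isclose(mix.sum(), 1.0):
        raise ValueError("category_mix must be 4 non-negative proportions summing to 1")
    rng = np.random.default_rng(cfg.seed)

    rows = []
    planted: dict[str, str] = {}
    for p in range(n_patients):
        pid = f"P{p:04d}"
        category = str(rng.choice(np.array(LESION_CATEGORIES), p=mix))
        planted[pid] = category
        n = int(rng.integers(lo, hi + 1))
        changes, n_new = _draw_changes(rng, category, n)
        baselines = rng.uniform(8.0, 60.0, size=n)
        followups = baselines * (1.0 + changes / 100.0)
        if noise_sd > 0:
            followups = followups * (1.0 + rng.normal(0.0, noise_sd / 100.0, size=n))
            followups = np.maximum(followups, 0.0)
        for i in range(n):
            lid = f"L{i:02d}"
            rows.append((pid, lid, "baseline", round(float(baselines[i]), 2), False))
            rows.append((pid, lid, "followup", round(float(followups[i]), 2), False))
        for i in range(n_new):
            lid = f"N{i:02d}"
            diam = float(rng.uniform(5.0, 20.0))
            rows.append((pid, lid, "followup", round(diam, 2), True))
    table = pd.DataFrame(
        rows, columns=["patient_id", "lesion_id", "timepoint", "diameter_mm", "is_new"]
    )
    return table, PlantedTruth(patient_categories=planted)
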