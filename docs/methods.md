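# Methods

This note records the models behind each module, the defaults that
matter, and the choices made where more than one reasonable design
existed.  Nothing here asserts an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic data: what is emulated, and what is not

All generators share a synthetic genome of `n_chromosomes` equal-length
chromosomes tiled by fixed-width 0-based half-open bins (default 1 Mb);
no reference genome is needed.  A single integer seed drives
`numpy.random.default_rng`, and outputs are byte-identical across runs
for a fixed configuration.

**Clone pairs** (`generate_clone_pair`).  Progenitor bin counts are
Poisson(mean_depth × bias), with a log-normal multiplicative per-bin bias
(sd 0.1 on the log scale, configurable) shared between progenitor and
daughter.  The shared bias is what makes progenitor normalization
meaningful: it cancels in the depth ratio, emulating mappability/GC
structure without modelling either explicitly.  Daughter counts are
scaled by (ploidy + δ)/ploidy inside planted events.  SNP alt counts are
Binomial(depth, BAF) with BAF 0.5 outside events; inside an event of
copy delta δ on background ploidy p, the event is modelled as hitting a
single parental allele, giving BAF = (p/2 + δ)/(p + δ) clamped to
[0.02, 0.98] (residual sequencing error).  SNP depth is Poisson(80) by
default, clearing the depth ≥ 40 retention filter for almost all sites.
Default SNP density is 20 per bin so the >20%-balanced rule is
well exercised.  Not emulated: read-level artifacts, GC-dependent
dispersion beyond the single bias term, subclonal (non-integer) events.

**Single-cell tumors** (`generate_single_cell_tumor`).  Cancer cells
belong to subclones (default 4, Dirichlet-distributed proportions): each
subclone beyond the founder carries its own ±1 segment events covering
about `divergence_rate` of the genome, so breakpoints are shared within
a subclone — the property the noisy-cell filter relies on — and mean
pairwise diversity grows with the divergence rate.  Whole-genome-doubled
cells are the doubled founder plus the same subclone events; diploid
contaminants are flat CN 2; noisy cells get random segment boundaries
(about 1 per 100 bins plus at least one per chromosome, mimicking
genome-wide replication-timing noise) with levels drawn uniformly from
0–6.  Independent RNG substreams keep the tumor's clonal layout
(founder, roles, subclone assignment) fixed when only the divergence
rate changes, so rate comparisons are paired.  Not emulated:
replication-timing structure of S-phase cells, coverage-quality
covariates, doublet mixtures of two real profiles.

**Cohort profiles** (`generate_cohort_profiles`).  Each bin of each
tumor is independently gain (probability Rg), loss (Rl) or neutral,
with per-tumor rates either fixed or drawn uniformly from a range —
exactly the independence structure the recurrence null assumes, which is
what makes the calibration check meaningful.  Planted recurrent bins are
altered with a boosted probability (default 0.9) instead.  Real tumors
have segmental, correlated alterations; bin-level independence makes the
null calibration test exact but understates between-bin correlation.

**Lesion cohorts** (`generate_lesion_cohort`).  Per-patient categories
are drawn from a four-way mix (homogeneous / mixed-existing /
mixed-new-lesion / non-responder); per-lesion percent changes are drawn
clear of the −30/+10 boundaries (responders −80..−35, stable −25..+5,
progressors +15..+60) so planted categories survive small measurement
noise; baselines are 8–60 mm.  New lesions are encoded as
baseline-diameter 0 rows flagged `is_new` at follow-up, avoiding a
division by zero in percent change.  Noise is multiplicative Gaussian on
the follow-up diameter (sd in percent).

## Response classification

Boundaries belong to the extreme categories: response at ≤ −30%,
progression at ≥ +10%, stable the open interval between.  This resolves
the ambiguity of prose definitions in which +10% can be read as both
stable and progressing.  Mixed vs homogeneous is assessed only among
patients with at least one responding lesion; patients with fewer than
two measurable lesions are not evaluable; a new lesion makes a responder
mixed even if every existing lesion responds.  Lesions that disappear
entirely (−100%) count as responses.  New lesions have no percent change
and are excluded from the per-patient MAD (unscaled — no 1.4826
normal-consistency factor).  The module classifies one assessment at a
time; choosing the timepoint (first follow-up vs maximum response) is
the caller's job.

## Copy-number calling

*Normalization direction.*  Per-bin daughter/progenitor ratios are
multiplied by total-progenitor/total-daughter so an unchanged bin has
expected ratio 1.  (Reading the normalization the other way — dividing by
that factor — would move unchanged bins away from 1 whenever library
sizes differ; the implementation normalizes so the reference state sits
at 1.)

*Segmentation.*  Recursive binary splitting per chromosome; a candidate
changepoint is kept when its within-segment SSE reduction exceeds
`penalty · σ̂² · log n` (penalty 3.0, minimum segment 2 bins), with σ̂
estimated robustly from median absolute successive differences.  On pure
noise this yields one segment per chromosome in ≥ 95% of runs (checked in
the suite); planted steps of ≈ 0.8 at noise sd 0.05 are located within
±2 bins.  A permutation-based CBS variant was considered and not
implemented: acceptance rests on planted-event recovery, not algorithm
identity.

*Reference model.*  The Gaussian mixture is fitted to **log**-ratios of
balanced bins.  On the log scale the Poisson ratio noise is symmetric
and its spread is state-independent, so a unimodal reference is not
split by skew and the largest-weight component's mean is an unbiased
anchor.  K is chosen by BIC over 1–5 with 10 initializations at a fixed
random state; the reference sigma is floored at 1e-4.  Balanced bins are
pooled genome-wide: an event bin whose BAF shift is too small for the
SNP test to flag (e.g. +1 on a high-ploidy background at modest SNP
depth) enters the pool, and it is precisely the mixture's job to isolate
such bins in a minority component.  The balanced-bin rule needs ≥ 5
retained SNPs per bin and a strictly greater than 20% balanced fraction,
with the denominator taken over retained SNPs.

*Testing unit.*  Each segment's mean log-ratio is Z-tested against the
reference with standard error σ/√min(len, 16), two-sided, α = 0.001,
no multiple-testing correction (the α is chosen with the per-genome
expected false-positive count in mind, given ~3000 bins).  Two details
matter.  Using the segment mean's standard error rather than the raw
bin-level σ is what makes single-copy events on a triploid background
detectable at depth ~100 (effect ≈ log 4/3 ≈ 0.29 vs bin-level σ ≈ 0.14:
a bin-level test needs z ≥ 3.29 and cannot reach it); the raw-σ variant
remains available as `use_segment_se=False`.  Capping the √n shrinkage
at 16 bins bounds how small the denominator can get, so the residual
uncertainty of the fitted reference mean (order 0.005 on the log scale)
cannot turn long neutral segments into false calls; without the cap a
150-bin segment would be tested at SE ≈ 0.01 and calibration collapses.

*Gene annotation* uses the any-overlap rule: a gene is gained/lost if
any bin it intersects carries that call.

## Recurrence

The null produces a single genome-wide count threshold per direction
(not per-bin nulls): each of 1000 simulations draws one Bernoulli(Rg,t)
gain and, independently, one Bernoulli(Rl,t) loss indicator per tumor
and sums over tumors.  The threshold is the 97.5th percentile of
simulated totals — the upper bound of the central 95% interval — with the
one-sided 95th percentile available via the `percentile` argument.
Observed counts must *strictly* exceed the threshold.  Adjacent flagged
bins on a chromosome merge into regions; a single-bin gap is not
bridged.  For integer-CN cohorts, states are collapsed per tumor against
round(ploidy) before rate estimation.  Synteny projection maps target
intervals linearly through each block and takes length-weighted means;
orientation is ignored because frequencies are strandless, and the
result is invariant to block subdivision.

## Diversity metrics

The diploid-contaminant wording is applied as "at most 5% of the genome
deviates from CN 2" (likewise CN 4 for G2), the only reading that
excludes normal cells.  Filtering order is fixed: normal-cell exclusion,
then the noisy-cell filter; both are idempotent.  The noisy-cell filter
matches breakpoints between cells of the same tumor within ±1 bin,
requiring the same integer copy-number step — a breakpoint is a specific
transition, and clonally shared breakpoints agree in their step, while
random noise steps rarely collide; whole-chromosome aberrations match by
chromosome and direction.  Cells with no features at all are retained
(a flat profile is not evidence of noise).

Clones for Shannon evenness are groups of cells with exactly identical
profiles after a 3-bin median filter within chromosomes (absorbing
single-bin artifacts); evenness is H/ln k, defined as 0 for a single
clone (a deviation from the Pielou convention of leaving it undefined,
chosen so that fully clonal tumors score minimal heterogeneity rather
than dropping out).  wGII weights chromosomes equally regardless of
length, with the ploidy reference round(mean CN).  The per-cell WGD flag
uses mean CN ≥ 3.0.  Pairwise diversity is a pseudometric (symmetric,
zero on identical profiles, triangle inequality bin-wise) computed
within tumor and, by default, within FACS ploidy group; gain/neutral/loss
call tracks are accepted in place of integer CN for clone-to-clone
comparisons.

## Statistics conventions

Fisher's exact two-sided p sums point probabilities of margin-preserving
tables no more probable than the observed one (the convention that
reproduces the printed clinical comparisons; verified against brute-force
enumeration in the suite).  The chi-squared test defaults to no
continuity correction with Yates available by flag — the two printed
chi-squared values pin opposite conventions, so both are first-class.
Mann–Whitney U uses exact enumeration for ≤ 20 observations per group
without ties and the tie-corrected normal approximation otherwise;
continuity correction is exposed as an option.  MAD is raw (no 1.4826).

## Problem sizes and runtime

The acceptance checks use 20 clone pairs of 3000 bins at depth 100–300
on a triploid background (the progenitor ploidy of the in-vitro system
emulated), 20 cohorts of 40 tumors × 1000 bins with 1000 simulations
each, 200-patient lesion cohorts, and 60–100-cell tumors on a ~2600-bin
genome — sizes at which every planted-recovery property is measurable
with comfortable Monte-Carlo margins while the whole suite runs in a few
minutes on one CPU.

## Known limitations

* The caller reports gain/neutral/loss relative to the progenitor, not
  allele-specific integer copy numbers.
* Detection power for single-copy events falls with background ploidy;
  on a hexaploid background at depth 100, 5-bin single-copy events are
  below the α = 0.001 detection limit by design.
* The recurrence null assumes bin-wise independence given per-tumor
  rates; segmental correlation in real cohorts makes the genome-wide
  threshold conservative for broad events.
* The noisy-cell filter needs at least two genuinely clonal cells per
  tumor to anchor sharing; tumors sequenced to one usable cell pass
  through unfiltered.
* No surrogate is attempted for visual-QC exclusions of cells whose raw
  coverage poorly fits the called profile.
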