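# scnakit

Analysis toolkit for studying **mixed radiological responses** to targeted
therapy and the **somatic copy-number evolution** behind them, built for
the setting of *EGFR*-driven lung adenocarcinoma treated with EGFR
tyrosine-kinase inhibitors, with or without p53 pathway disruption.

It is aimed at computational cancer biologists who need to:

* classify longitudinal lesion-diameter measurements into per-lesion
  (response / stable / progression / new lesion) and per-patient
  (homogeneous / mixed / non-responder) categories, beyond RECIST sums;
* call somatic copy-number alterations (SCNAs) acquired by a daughter
  clone **relative to its progenitor clone**, without a matched normal
  sample;
* find recurrently gained/lost genomic regions across a tumor cohort with
  a Bernoulli sampling-simulation null;
* quantify single-cell copy-number heterogeneity (pairwise diversity,
  Shannon evenness, wGII, ploidy/WGD) after contaminant and noisy-cell
  filtering;
* project SCNA frequency tracks between genomes through synteny blocks.

Every analysis runs on synthetic data produced by the built-in generators
(`scnakit.synthetic`), which plant known ground truth so the whole
pipeline is testable without any sequencing download.

## The core methods

**Per-lesion response.** For a lesion with baseline diameter $d_0$ and
follow-up diameter $d_1$, the percent change is
$\Delta = 100\,(d_1 - d_0)/d_0$.  A lesion *responds* if
$\Delta \le -30$, *progresses* if $\Delta \ge +10$, and is *stable* in
between.  A patient with $\ge 2$ measurable lesions and at least one
responding lesion has a **mixed response** when any lesion progresses or
any new lesion appears, and a homogeneous response otherwise.  Spread of
response within a patient is summarized by the unscaled median absolute
deviation (MAD) of per-lesion percent changes.

**Progenitor-referenced CN calling.**  With per-bin read counts $c^D_b$
(daughter) and $c^P_b$ (progenitor), the normalized depth ratio is

$$r_b = \frac{c^D_b}{c^P_b}\cdot\frac{\sum_b c^P_b}{\sum_b c^D_b},$$

so an unchanged bin has $\mathbb{E}[r_b] = 1$.  Heterozygous SNPs
(depth ≥ 40, alt ≥ 10) are tested for allelic balance (exact binomial
vs BAF 0.5); bins where > 20% of retained SNPs are compatible with
balance anchor the reference.  The ratio track is segmented per
chromosome (recursive binary changepoints with a penalized stopping
rule), a Gaussian mixture (K by BIC) is fitted to balanced-bin
log-ratios, the largest-weight component is the reference state, and
each segment is Z-tested against it at $\alpha = 0.001$ — gains above,
losses below.

**Recurrence null.**  Per-tumor genome-wide gain/loss rates
$R_{g,t}, R_{l,t}$ feed 1000 Bernoulli simulations of per-bin alteration
counts summed over tumors; the 97.5th percentile of the simulated totals
is the count threshold, and observed per-bin counts strictly above it
mark recurrent regions.

**Single-cell heterogeneity.**  After excluding cells ≥ 95% CN 2
(diploid contaminants) or ≥ 95% CN 4 (G2/doublets) and cells sharing
< 33% of their breakpoints with any other cell of the same tumor, the
toolkit computes pairwise fraction-of-genome-different, per-tumor Shannon
evenness $H/\ln k$ over clone proportions, per-cell
wGII (mean over chromosomes of the fraction of bins off the rounded
ploidy) and mean-CN ploidy with a WGD flag at ≥ 3.

## Worked example

```python
import numpy as np
from scnakit.synthetic import SimConfig, sample_events, generate_clone_pair
from scnakit.cn_calling import call_clone_pair

cfg = SimConfig(seed=1, n_bins=3000, n_chromosomes=20)
events = sample_events(np.random.default_rng(99), cfg, n_events=12)
prog, daughter, snps, truth = generate_clone_pair(
    cfg, ploidy=3, events=events, mean_depth=150,
)
calls = call_clone_pair(prog, daughter, snps)
print("gained bins:", (calls.call == "gain").sum(),
      "lost bins:", (calls.call == "loss").sum())

truth_mask = truth.event_bin_mask(cfg.n_bins)
pred = np.where(calls.call == "gain", 1,
                np.where(calls.call == "loss", -1, 0))
tp = ((pred != 0) & (pred == truth_mask)).sum()
print("precision %.3f" % (tp / max((pred != 0).sum(), 1)),
      "recall %.3f" % (tp / (truth_mask != 0).sum()))
```

Output:

```
gained bins: 139 lost bins: 140
precision 0.989 recall 0.945
```

The 12 planted events on the triploid background cover 292 bins; at mean
depth 150 the caller recovers 276 of them, with 3 neutral bins called —
the misses sit at event edges where the segmentation places a breakpoint
a bin or two off.

The same workflows are scriptable from the shell:

```bash
scnakit simulate clone-pair --seed 1 --out sim/
scnakit call-cn --progenitor sim/progenitor.bed --daughter sim/daughter.bed \
    --snps sim/snps.tsv --out calls/
scnakit simulate lesions --seed 2 --out lesions/
scnakit classify-response --lesions lesions/lesions.tsv --out response/
```

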