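# retime

Differential replication-timing (RT) analysis for two-fraction
Repli-chip/Repli-seq-style profiles, with the downstream genomic
statistics that usually accompany it: region characterization,
shuffle-based interval enrichment, RT-similarity clustering,
mother-to-daughter transmission, and regional chromatin-accessibility
comparisons. A seeded synthetic-cohort generator makes the whole
pipeline testable without any external data.

## Who this is for

Groups studying how replication stress (e.g. low-dose aphidicolin)
reshapes the replication-timing program. The input is the standard
two-fraction readout: per-probe `log2(early-S / late-S)` signal on a
fixed genomic grid, one bedGraph per biological replicate per condition,
where higher values replicate earlier.

## The statistics at the core

**Differential calling (aRTIL).** All replicates of both conditions are
jointly quantile-normalized and rescaled so the pooled 1st/99th
percentiles sit at −2/+2, then Loess-smoothed (tricube local linear
regression, 500 kb span). For non-overlapping windows of 10 probes the
per-probe deltas `Δ = mean(treated) − mean(control)` are tested with a
one-sample t-test against zero; windows with `p < 0.05` **and**
`|mean Δ| ≥ 0.3` are kept, same-sign windows within one window's gap are
merged, and regions shorter than 100 kb are dropped. Regions with
`Δ > 0` are **ADV** (advanced: later→earlier), `Δ < 0` are **DEL**
(delayed). The summary reports the percent of the probe-covered genome
impacted and the ADV/DEL split.

**Segmentation.** The smoothed profile is partitioned into Early / Mid /
Late constant-timing regions (value thresholds ±0.25) and temporal
transition regions (TTR, |slope| > 1 unit/Mb), with runs under 100 kb
absorbed into their longer neighbor.

**Interval enrichment.** For a query set vs a fixed target set the
bp-level Jaccard index `|A∩B| / |A∪B|` is compared with 1000
randomizations of the query placed uniformly on the mappable genome
(lengths preserved, placements disjoint):

    z = (J_observed − mean(J_null)) / sd(J_null)

An empirical p-value (rank of the observed value in the null) is
reported alongside, since the null need not be normal.

**Transmission.** A mother-generation region is transmitted when a
same-direction daughter-generation region covers ≥ 50% of its bp; the
daughter/mother amplitude ratio is recorded per transmitted region.

**Clustering.** Cohorts are compared by 1 − Pearson correlation of their
replicate-mean smoothed profiles with average linkage; edge support is
an ordinary probe-resampling bootstrap.

**ATAC regional comparison.** Peak values are depth-normalized (counts
per million), averaged over replicates, paired across conditions by
nearest peak centers, assigned to region classes by the control peak's
midpoint, and tested per class with the Wilcoxon matched-pairs
signed-rank test (exact null for n ≤ 25).

## Worked example

```python
from retime import (SyntheticSpec, make_rt_profiles, normalize_replicates,
                    call_differential)

spec = SyntheticSpec()          # 2 chr x 20 Mb, probes every 10 kb, seed 42
profiles, truth = make_rt_profiles(spec)
control = [profiles[("control", "t0", f"r{i+1}")] for i in range(2)]
treated = [profiles[("treated", "t0", f"r{i+1}")] for i in range(2)]
normed  = normalize_replicates(control + treated)
artil   = call_differential(normed[:2], normed[2:])
print(len(artil), artil.n_adv, artil.n_del)
```

On the default cohort (twelve implanted 1 Mb shifts of amplitude |1.2|,
probe noise 0.25) this prints `21 8 13`: all 8 implanted advances and
all 4 implanted delays are recovered (the extra delayed calls are the
documented quantile-normalization artifact — see `docs/methods.md`),
impacting 42% of the probe-covered genome. Testing the calls against
the cohort's fragile-site track (built to overlap 80% of the advances):

```text
ADV vs CFS: observed J=0.3101 null=0.1418+-0.0546 z=+3.08 empirical p=0.005
DEL vs CFS: observed J=0.1529 null=0.1748+-0.0532 z=-0.41 empirical p=0.653
```

so only the advances overlap fragile sites beyond chance. A
mother/daughter cohort built with 57% inheritance at 0.6× amplitude
yields `4 of 7 transmitted (57%)` with a measured amplitude ratio of
0.69. The scripts in `examples/` walk through each capability and print
these numbers with a line on what they mean; `retime --help` exposes the
same steps as shell commands (`simulate`, `call`, `enrich`, `cluster`,
`atac`, `characterize`, `run`).

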