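# Methods

This note documents the models and numerical choices behind `retime`:
what each stage computes, the parameters that matter, what the
synthetic-cohort generator does and does not emulate, and the known
limitations. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Signal model and conventions

Replication timing is represented as a per-probe `log2(early/late)`
ratio on a fixed grid; higher = earlier replication. All coordinates are
0-based half-open (BED native) throughout; 1-based dialects must be
converted at the I/O boundary, and a leading `chr` prefix is stripped by
default so hg18/hg19-style files can be mixed. Strand is ignored
everywhere: every interval set handled here is unstranded. No liftover
is performed — all inputs must share one assembly, which is validated
against the chromosome-sizes table.

## Normalization

All replicates of both conditions and generations in a comparison are
quantile-normalized **jointly** (reference = mean of column-sorted
values; rank ties broken by genomic order for determinism), then
linearly rescaled so the pooled 1st/99th percentiles map to −2/+2. Joint
normalization prevents distribution-shape differences between
conditions from masquerading as regional timing changes.

*Known artifact.* Forcing identical marginals is only neutral when the
treatment leaves the value distribution unchanged. When a large genome
fraction genuinely shifts (the default cohort implants +1.2 over ~20% of
the genome), the displaced probe mass warps the empirical reference and
unchanged probes acquire a compensatory shift of opposite sign — on the
default cohort this produces spurious delayed calls of amplitude ≈ −0.35
in late plateaus near the implanted advances. The amplitude floor bounds
but does not eliminate them. Users comparing heavily-shifted conditions
should read DEL calls adjacent to strong ADV territory with this in
mind. A related consequence: classic quantile normalization is *not*
invariant under a monotone distortion of a single replicate (the
reference itself moves); what is guaranteed is equalized marginals,
exact absorption of additive shifts by the percentile rescale, and rank
preservation — the test suite asserts exactly these.

## Smoothing

Loess in the strict sense: tricube-weighted local **linear** regression
over a ±span/2 genomic window (default span 500 kb ≈ 50 probes at 10 kb
spacing), truncated at chromosome ends. On a uniform grid the interior
prediction reduces to a fixed-kernel convolution because the slope term
vanishes by symmetry; edge probes use the explicit truncated-window fit.
Constant profiles and linear ramps are reproduced exactly (local-linear
exactness). Chromosomes with fewer than five probes pass through with a
warning.

## Segmentation

Probes whose smoothed slope magnitude exceeds 1 normalized unit/Mb are
temporal transition regions (TTR); remaining probes are Early
(value ≥ +0.25), Late (≤ −0.25) or Mid. Same-label runs merge, and runs
shorter than `min_domain` (100 kb) are iteratively absorbed into the
longer neighbor, shortest run first. The labels partition the
probe-covered span of each chromosome.

## Differential calling ("mean method")

The "mean method" is named in the replication-timing literature without
an accompanying formula; the concrete test here is fixed as:

1. smooth every replicate, form per-probe deltas
   `Δ = mean(treated) − mean(control)`;
2. tile each chromosome with non-overlapping 10-probe windows (partial
   trailing windows kept if ≥ 2 probes) and apply a one-sample t-test of
   the window's probe deltas against zero;
3. keep windows with `p < 0.05` **and** `|mean Δ| ≥ 0.3`;
4. merge same-sign kept windows separated by at most one window;
5. drop regions shorter than 100 kb.

The amplitude floor, not the p-value, is what controls genome-wide false
calls: smoothed deltas are strongly autocorrelated inside a window, so
the t-test alone is anti-conservative, and no multiple-testing
correction is applied by default (Benjamini–Hochberg across windows is
available via `CallParams(fdr=True)`). With the floor, no-implant
cohorts yield essentially zero percent impacted (the acceptance suite
measures the mean over 100 cohorts).

Degenerate windows (zero variance, as in noise-free simulations) take
the t-test's limit: p = 0 for a non-zero mean, p = 1 otherwise. This
keeps the caller defined on noise-free cohorts, where it is used to
verify exact transmission recovery.

A region's amplitude is the mean smoothed delta over its probes; its
p-value is the smallest window p inside it (exported as −log10 p in the
BED score column). `percent_genome_impacted` is the union bp of calls
over the probe-covered bp.

## Transmission

A mother region is transmitted when a single same-direction daughter
region overlaps ≥ `min_recip` (default 0.5) of the mother's bp; no
standard overlap rule exists for such counts, so this threshold is the
package's own choice. Because delayed calls can be normalization
artifacts (above), transmission of advances should be assessed on the
ADV subset, as the examples do; the transmitted fraction is a ratio of
counts, so with 7 advances and inheritance 0.57 the noise-free recovery
is exactly 4/7 = 0.571.

## Interval enrichment

`z = (J_obs − mean J_null)/sd J_null` with the null built by placing
each query interval uniformly at random wholly inside the mappable set
(capacity-weighted segment choice, so placement is uniform over all
valid positions), lengths preserved, placements pairwise disjoint by
rejection sampling with a retry cap (default 1000 per interval),
cross-chromosome placement allowed (both switchable). The target is
never shuffled, so the pairwise matrix is asymmetric by design and both
orientations are reported rather than symmetrized. The full null vector
is retained; the z-score is recomputable from it and an empirical
p-value is exported because the null need not be normal. Pre-merging of
inputs before the Jaccard follows bedtools semantics.

On default cohorts the fragile-site check behaves as intended — ADV
calls enriched (z ≥ 3), DEL calls compatible with random — but the DEL
z-score varies with the landscape seed and can reach ≈ −2.5 on cohorts
where the spurious DEL calls sit in peak-poor late territory; the
acceptance suite asserts the property at the fixed default conditions.

## Clustering

Distance 1 − Pearson correlation between cohorts' replicate-mean
smoothed profiles restricted to the common probe set; average linkage
(no height inversions). Support values are the fraction of
probe-resampling bootstrap trees (default B = 100, seeded) containing
the same leaf set — an ordinary bootstrap, deliberately not the
multiscale/AU variant used by pvclust-style protocols.

## ATAC regional comparison

Replicate peak values are scaled by `1e6 / total`; the denominator is
the replicate's recorded library size when available, else the sum of
its peak values. The distinction matters: dividing by the within-peak
sum pins every replicate's peak total exactly, and that single linear
constraint lies along the direction a location test measures, making the
class that holds most of the peak mass arbitrarily conservative. Depth
denominators avoid this, which is why the generator records them.
Normalized replicates are averaged per condition, peaks paired by greedy
nearest-center matching (cap 500 bp; the pairing rule is this package's
own, since "matched pairs" requires one), assigned to the first class
containing the control peak's midpoint, and tested with the two-sided
Wilcoxon signed-rank test — exact for n ≤ 25 non-zero differences,
normal approximation with continuity correction beyond, zeros discarded,
all-zero classes reported as p = 1. Classes with fewer than six pairs
are flagged underpowered. A two-way class × condition ANOVA on log
values is available as a coarse parametric cross-check.

## Synthetic cohorts

The generator is the package's test bed: the simplest seeded model that
exhibits every phenomenon the pipeline must detect.

* **Landscape.** Per chromosome, white noise smoothed to a correlation
  length (default 2 Mb), passed through a saturating tanh (≈ 0.7 of the
  field's sd), percentile-rescaled to [−2, 2]. The saturation matters:
  it produces the wide early/late plateaus joined by short transitions
  that real RT profiles show, and those plateaus are what makes room for
  the default implant load. Truth early/late domains are the flat
  (|slope| ≤ 1 unit/Mb) stretches beyond ±0.25.
* **Implants.** Flat-top bumps with 100 kb cosine shoulders; advances
  placed inside truth-late plateaus, delays inside truth-early ones,
  pairwise separated by ≥ 300 kb. Defaults: 8 ADV and 4 DEL of 1 Mb at
  amplitude 1.2 on 2 × 20 Mb with probe noise 0.25 and duplicate
  replicates. This load deliberately stresses capacity: roughly half of
  arbitrary seeds cannot host it and raise an explicit placement error
  (the default seed 42 holds 10 + 9 slots).
* **Generations.** Daughter profiles reuse the same landscape with
  fresh noise; a seeded subset (`round(inherit_fraction × n_ADV)`) of
  the advances persists at `inherit_amplitude_factor` (defaults 0.57 and
  0.6); delays do not persist.
* **Covariate tracks.** GC probability per probe 0.42 + 0.02 × base;
  origins Poisson at 3:2:1 early:mid:late density; gene lengths
  log-normal (median ≈ 36 kb, heavy tail past 400 kb) with an
  early-biased placement; fragile sites cover 80% of the advances plus
  decoys placed away from implants; four histone-mark-like tracks
  thresholded from noisy copies of the landscape (two early-, one mid-,
  one late-associated); ATAC peaks at early-biased density with
  log-normal values, per-replicate log-normal noise (sd 0.1), a random
  library depth (log-normal sd 0.2, recorded), and a 1.2× value
  multiplier inside advances in the treated condition.
* **Determinism.** Every draw comes from a named child stream of the one
  spec seed (numpy PCG64 via `SeedSequence((seed, purpose, ...))`), so
  all outputs are byte-identical across runs and platforms for a fixed
  seed.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: dye/array artifacts and wave effects,
S/G2 contamination of the late fraction, under-replication (so delayed
fragile sites that never finish replicating are invisible here as in the
assay), copy-number variation, probe dropout, read-competition
compositional effects in ATAC libraries, and any cell-to-cell
heterogeneity. Effect sizes are large by design (amplitude ≈ 5× probe
noise) so that detection failures indicate implementation errors rather
than borderline power.

## Problem sizes

Defaults were chosen to mirror CGH-array-like density while keeping
every check fast: 4,000 probes per cohort, 1000 shuffles per enrichment,
100 no-implant cohorts for null calibration, 200 repetitions for z-score
calibration, 100 cohorts for the ATAC type-I rate, B = 100 bootstrap
trees. The full test suite runs in a few minutes on one CPU; the
acceptance script in about a minute.
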