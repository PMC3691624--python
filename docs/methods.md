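# Methods

## The problem and the model

Array-CGH measures, per probe, the log ratio of a patient's DNA copy number
against a reference. In constitutional disorders the pathogenic signal is a
*rare* CNV — an interval where one patient (or ≤ 1% of the cohort) deviates
while everyone else is diploid. Two artifacts dominate single-sample
analysis at high resolution: "waves" (genome-position-correlated
oscillations whose pattern is shared across samples, hypothesised to track
GC content / replication timing) and experimenter/batch bias concentrated on
disrupted probes. Both are *column* effects: at any fixed probe they distort
all samples in the same direction. The screen therefore works on per-probe
ranks across the cohort, which are exactly invariant to any monotone
per-column distortion.

### Pseudo-ranks

For probe `q`, `R_qs = rank(L_qs among observed samples) / (m_q + 1)`, with
midranks for ties and `m_q` the observed count, so the observed marginal is
uniform on `{1/(m+1), …, m/(m+1)}` regardless of missingness. Midranks make
the transform deterministic and conserve the column rank sum (`m/2`);
random tie-breaking was rejected for reproducibility. Columns with fewer
than two observations carry no information and are flagged missing.

### The windowed outlier statistic

Within a window `Q` of `k` consecutive probes (windows never span
chromosome boundaries; default stride 1), sample `s` has

    μ_d(s) = (1/|S|) Σ_{j∈S} ( Σ_{l∈Q} |R_ls − R_lj|^d )^{1/d}

with `d = 1` (Manhattan) by default; the zero self-term stays inside the
mean, reading the definition literally. For `d = 1` the double sum
separates per probe, so fully observed windows are computed from per-column
pairwise-distance sums with sliding-window totals in `O(n p log n)`;
windows touching missing cells fall back to a direct computation in which a
sample missing any cell is excluded from that window entirely (it neither
receives a μ nor contributes to others' means — no imputation).

For `k = 1` the statistic has the explicit limit
`μ(z) → ∫₀¹ |t−z| dt = (z² + (1−z)²)/2` for a sample at pseudo-rank `z`:
half the summed squared Euclidean distance to the two extreme corners of
the unit interval, minimised at `z = ½` (¼) and maximal at the edges (½).
Under column independence the `k > 1` null is a sum of `k` independent such
terms (mean `k/3`); `simulate_independence_null` draws from it by Monte
Carlo and serves as the calibration oracle for the tests.

### The Beta null and marker calling

Real windows are not independence-null — consecutive probes are correlated,
more so inside rearranged regions — so the null is fitted per window: the
cohort's μ values are rescaled to their observed `[min, max]` and a
Beta(α, β) is fitted by the method of moments, with boundary values nudged
inward by `ε = 1/(2n)` (the rescaled extremes sit exactly on the Beta
support boundary). Moments were preferred to maximum likelihood: closed
form, deterministic, no optimizer, and robust on 100–400 points.
Degenerate windows (zero spread, moments outside the Beta-feasible region)
yield no fit and no markers.

Markers are (sample, window) pairs with **upper-tail** p-value strictly
below 0.01 — the suggested population frequency of pathogenic CNVs; only
the upper tail makes sense since outliers *maximise* mean distance. No
multiple-testing correction is applied across windows: the 1% tail is the
operational definition of "outstanding", not a hypothesis test to be
FDR-controlled. Two consequences worth knowing: the window maximum always
gets p = 0 (the empirical rate has a floor of `1/n` per window), and the
Beta tail is lighter than the independence null's, so the realised null
marker rate sits somewhat *above* nominal (≈ 1.9% at n = 200 in the checks)
— the method is deliberately anti-conservative at this stage because the
downstream density-score and polymorphism filters carry the specificity.

### Polymorphic profile

Rank outliers also appear in genuinely polymorphic regions, where the
cohort background itself diverges. The in-cohort profile marks probe `q`
polymorphic when strictly more than `floor(0.01·n)` samples (3 of 366 —
"more than 1%") have a probe-mapped segment mean with absolute value
strictly above 0.07 log10 (the conservative 0.24 log2 aberration cutoff;
0.24·log10 2 ≈ 0.07). Probes outside every segment carry signal 0. Markers
whose window is a fully polymorphic `k`-mer are removed (`intersect` mode,
the literal reading); an `overlap` mode also removes markers sharing ≥ 1
probe with a polymorphic window, since the source text supports both
readings. The filter only ever shrinks the marker set and is idempotent.

### Scoring, candidates, annotation

A segment's **density score** is `100 × (probes covered by that sample's
marker-window union) / n_probes`; coverage is counted per probe, the
simplest reading consistent with "percent of the segment covered" (windows
straddling a segment boundary contribute their inside probes). Segments
with no marker are sieved out. Candidates need score strictly above 50 and
`|seg_mean|` strictly above 0.1, sorted by descending score (stable).
Candidates are intersected with interval tracks registered under the
`isca` / `gad` / `dgv` roles; ≥ 3 overlapping DGV records (count overlap by
default, optional reciprocal-overlap fraction — the source does not define
"significant intersection", so it is a parameter) label `common_dgv`,
otherwise any ISCA/GAD hit labels `rare_candidate`, else `unsupported`.
The enrichment curve walks down the score ranking and plots the cumulative
fraction of known positives recovered.

## Segmentation

Segmentation is a pluggable input: any SEG-dialect file (1-based inclusive
bp) is mapped to genome-order probe ranges (a probe belongs to a segment
when its start bp falls inside it). The built-in `simple_segment` is
deliberately minimal plumbing: per sample and chromosome it recursively
extracts the interior segment `[i, j)` maximising the pooled t statistic
between inside and outside means — the circular-split form, because a
single left/right breakpoint cannot detect a short CNV diluted inside a
long region — and splits while the Bonferroni-adjusted p-value over
candidate pairs is below `alpha = 0.01` with every part ≥ `min_probes = 10`.
Bonferroni over the ~m²/2 correlated candidate pairs is conservative, which
is the right failure mode here: spurious splits feed wave bumps into the
polymorphic profile and mask true rare CNVs. The segmentation-free mode
instead clusters marker windows directly (union of window intervals, gaps
≤ `max_gap_probes` merged, means recomputed from the logratios).

## The synthetic cohort generator

`synth.simulate_cohort` emulates the structure the screen assumes in an
exon-targeted patient cohort, with ground truth:

| component | default | rationale |
|---|---|---|
| cohort | 100 samples × 1200 probes (2 chromosomes) | large enough for 1%-frequency logic, small enough for seconds-per-cohort |
| probe noise | Gaussian, sd 0.1 log10 | order of magnitude of per-probe scatter on high-resolution arrays |
| wave | sinusoid, amplitude 0.03, period 150 probes, shared phase + per-sample jitter (shared_fraction 0.5) | visible against noise yet below the 0.07 segment threshold after half-period averaging (2A/π ≈ 0.02) — 0.07 is meant as a cutoff waves do not reach |
| batch bias | 2 batches, offsets sd 0.2 on 1% "disrupted" probes | reproduces technician-discrimination on a few probes |
| inflated-variance probes | 1% of probes at 3× sd | disrupted-probe scatter |
| rare CNV | 1 carrier, 30 probes, amplitude −0.3 | one-copy loss on the log10 scale with signal compression; 1 of 100 = the 1% limit |
| polymorphic CNV | 5% carriers, 30 probes, −0.3 | clearly above the 1% polymorphism line |

The random stream is consumed in a fixed order so configs differing only in
one amplitude differ only in that component's contribution (this is what
makes the shared-wave invariance check *exact*). Rare CNVs with more than
1% carriers are a config error. The generator does **not** model probe GC
content, dye effects, spatial array artifacts, or length/frequency spectra
of real CNV polymorphism — passing tests show the statistical machinery
behaves as designed under its own assumptions, not that real-cohort
sensitivity/specificity figures transfer.

## Problem sizes used in the checks

The bundled checks run the screen at 200 × 1400 (null marker rate, wave
robustness at 100 × 1400), n = 5000 for the k = 1 limit, 20 000 Monte-Carlo
draws for the independence null, and 50 seeded replicates of the
100 × 1200 planted-CNV condition (artifact amplitudes zero there, so that
detection and polymorphism-exclusion rates measure the CNV logic in
isolation; wave behaviour is checked separately and exactly).

## Known limitations

- A rare CNV that coincides with a region the profile marks polymorphic —
  including wave-peak regions that many samples' segments track when the
  wave approaches the 0.07 threshold — is filtered with everything else;
  rank invariance protects the *markers* from waves but the profile is
  built from raw segment means.
- The per-window min/max rescaling makes the Beta fit sensitive to the two
  extreme samples; with a true generating interval the moments estimator
  recovers (α, β) accurately, but with empirical extremes the shape is
  biased (this is inherent to the "shift to the observed interval" rule).
- The copula-based nulls alluded to for correlated windows are out of
  scope; the Beta fit is the implemented and validated approach.
- `simple_segment` holds an O(m²) candidate-pair grid per (sample,
  chromosome) region; for chromosomes beyond a few thousand probes supply
  an external segmentation instead.
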