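# Methods

## Model and procedure

The analysis treats each plasma sample as a collection of aligned,
deduplicated cfDNA fragment intervals on a single copy-number-informative
target region (chromosome 18q in the colorectal-cancer setting; any
`GenomicRegion` works). Coordinates are 0-based half-open (BED
convention) throughout, strand is ignored, and "length" always means the
aligned insert length `end − start`. The adapter-ligated library
molecule measured by capillary electrophoresis is longer; the size-gate
scheme carries an `adapter_offset` (default 0 for sequencing-derived
fragments, 130 bp preset for emulating electropherogram gates) that maps
the insert length onto the library-size axis before gate lookup.

Stages:

1. **Size gating.** Four half-open gates (lower bound inclusive) on the
   library-size axis: [100, 400), [400, 585), [585, 825), [825, 5500) bp,
   corresponding to DNA wrapped around 1, 2, 3, or more nucleosomes.
   Percentages are relative to all fragments considered, so the four
   gates may sum below 100% — matching how electrophoresis software
   reports out-of-gate material. Matched chemistry arms are compared per
   gate with a two-sided paired Wilcoxon signed-rank test on the
   percentage differences; the test is an implementation choice, made
   because the paired design and non-Gaussian percentages rule out a
   paired t-test as a default.
2. **Features.** The region is tiled left-to-right into uniform windows
   (default 5 kb; the last window may be shorter). A fragment contributes
   to the window containing its midpoint `⌊(start+end)/2⌋` — unambiguous
   and unbiased for boundary-spanning fragments — and to the size class
   containing its length. Short is 100–150 bp and medium 151–220 bp
   (inclusive insert sizes), the fragmentomics convention splitting the
   mono-nucleosomal population into a tumor-enriched shortened tail and
   the nucleosome-core mode; both bounds are configurable, and layouts
   with separate short/medium columns or their ratio are available. The
   default feature is the combined short+medium count per window,
   normalized to counts per million in-region class-qualifying fragments
   (CPM) so samples of unequal depth are comparable. No GC or
   mappability correction is applied before modeling.
3. **Selection.** Features are partitioned in genomic order into
   consecutive batches of 1000. Within a batch, the Pearson correlation
   matrix across training samples is computed, and each feature's mean
   absolute correlation with the other batch members is recorded.
   Features with mean |r| > 0.7 are removed in a single simultaneous
   pass (the criterion is evaluated for all features before any removal,
   so the result is invariant to feature order within a batch; an
   iterative greedy variant exists but is off by default). Absolute
   correlation is used because strong negative dependence is redundancy
   too. Constant features have undefined correlation; they are assigned
   mean |r| = 0 and kept. Selection sees only the training split. An
   optional per-feature two-sided Wilcoxon rank-sum test (cancer vs
   control) can be applied after the filter; a rank-sum rather than a
   signed-rank test because the two groups are independent, not paired.
4. **Classification.** Gaussian LDA with a pooled within-class
   covariance shrunk toward its own diagonal,
   `Σ̂ = (1−α)·S + α·diag(S)`. Diagonal-target shrinkage keeps
   per-feature variances intact while damping noisy off-diagonal
   entries; it is mandatory in the p ≫ n regime of thousands of windows
   and a few dozen samples. The default intensity is the analytic
   Schäfer–Strimmer estimate (ratio of summed sampling variances of the
   off-diagonal covariance entries to their summed squares, clipped to
   [0, 1]); any fixed α may be supplied, and α = 0 with p ≥ n raises an
   error that names the remedy. The pooled covariance uses the biased
   (/n) normalization: the scale cancels in the decision rule and exact
   invariance under duplicating the training set holds. Priors default
   to (0.5, 0.5) — a diagnostic operating point independent of cohort
   composition — and a sample is called cancer at posterior ≥ 0.5.
   Reported metrics: confusion counts; sensitivity and specificity as
   percentages with one decimal (integer-rounded in summaries);
   per-stage, per-location and location-group (proximal/distal, split at
   the splenic flexure, configurable map) sensitivities; combined
   early-stage (0/I/IIA) sensitivity; and AUC by the rank statistic with
   ties counted 0.5.
5. **GC bias.** 150 bp windows tile the region; the GC fraction is
   (G+C)/(unambiguous bases) with ambiguous bases excluded from both
   numerator and denominator and all-ambiguous windows dropped. 3000
   windows are drawn without replacement, allocated equally across the
   ten 5%-wide GC gates spanning [0.15, 0.65) with any remainder going
   to the lowest gates (a per-gate mode that draws a fixed count from
   every gate is available). Per-window coverage is the count of
   fragment midpoints — the same assignment rule as the feature matrix —
   and ordinary least squares of coverage on GC yields slope, intercept
   and Pearson r. Both slope and r are reported: they answer different
   questions (steepness vs tightness of the GC dependence), and only r
   is comparable across libraries of different depth.

## Synthetic cohort generator

No patient data ships with the package; the generator produces cohorts
with the statistical structure the analysis assumes.

* **Genome.** A single-chromosome region (default 10 Mb at 5 kb bins)
  with a smooth sinusoidal GC track (period 1 Mb, amplitude 0.26 around
  0.40, small Gaussian roughness) spanning all ten GC gates, and
  log-linear baseline emission weights positively coupled to GC
  (coupling 2.0 with lognormal roughness sd 0.2), emulating the
  empirically GC-increasing coverage of untreated cfDNA libraries.
* **Fragments.** Candidate fragments draw a bin (∝ weight × copy
  number), a length from a four-component Gaussian mixture at
  167/334/501/668 bp (sd 25 bp, geometric weights with ratio 1/4 — the
  canonical nucleosome ladder), and a uniform position within the bin,
  clamped into the region. The tumor-derived component (probability =
  tumor fraction) is shifted −20 bp, the literature-standard ctDNA
  shortening. In CNV bins the expected emission is scaled by
  `(1 − tf) + tf × copy_ratio`. Each candidate survives conversion with
  probability `exp(−(λ_len · max(0, length − 250) + λ_gc · gc))`;
  candidates are drawn until the requested number are retained, so
  sequencing depth is held fixed across chemistries (libraries are
  typically sequenced to a target depth regardless of conversion loss).
* **Chemistries.** WGS: survival ≡ 1. WGES (enzymatic): λ_len 0.0005,
  λ_gc 0.3, near-lossless. WGBS (bisulfite): λ_len 0.01, λ_gc 1.5 —
  strips multi-nucleosome fragments and depletes GC-rich bins. Bisulfite
  additionally carries two variability terms: per-sample lognormal
  jitter (sd 0.5) on both rates, modelling batch-to-batch conversion
  harshness, and per-(sample, bin) lognormal overdispersion (sd 0.5;
  0.05 for WGES) on the emission weights, modelling locus-level
  degradation variability — WGBS coverage is well known to be
  overdispersed. The jitter alone is a low-rank disturbance a linear
  classifier can project out; the overdispersion is the component that
  genuinely degrades bisulfite classification at matched depth.
* **Cohorts.** Defaults mirror the reference study design: 24+24
  training and 12+12 test samples, 50,000 fragments per sample, a
  contiguous CNV block covering 5% of the bins at copy ratio 3, and a
  stage-graded tumor fraction: the reference tumor fraction (0.2) scaled
  by stage multipliers {0: 0.2, I: 0.45, IIA: 0.75, III/IIIA: 1.25,
  IIIB: 1.5, IV: 2.0}, reflecting the steep rise of ctDNA burden with
  stage and producing the expected pattern of lower early-stage
  sensitivity. Stages and colon locations are assigned by deterministic
  round-robin over configurable composition lists (the training
  composition follows the reference study's stage table), so per-stage
  reporting is exercisable and output is byte-identical per seed.

With these conditions, enzymatic-chemistry cohorts are recovered at
sensitivity and specificity ≥ 10/12 in at least 8 of 10 seeded
replicates, bisulfite cohorts show strictly lower mean sensitivity, the
coverage-vs-GC Pearson r orders WGS > WGES > WGBS, and null cohorts
(tumor fraction 0) give chance-level AUC — the acceptance suite asserts
exactly these properties, and `scripts/acceptance.py` recomputes them.

**What the simulator does not model:** reads, base qualities,
methylation states, alignment and mappability artifacts, multi-
chromosome genomes, germline copy-number variation, and clonal
heterogeneity. Passing tests therefore demonstrate that the pipeline
recovers the signal structure it is designed for — regional count
inflation against nucleosome-periodic background under
chemistry-dependent degradation — not clinical performance on patient
plasma.

## Numerical choices and degenerate inputs

* Half-open gate and bin intervals everywhere; boundary lengths go to
  the upper gate.
* Fragment-length draws are rounded to integers and floored at 50 bp.
* A chemistry whose survival vanishes over the whole genome raises
  "degenerate chemistry" instead of looping.
* Rank tests: identical values in both groups give p = 1; the exact
  null is used by scipy where sample sizes permit and ties are absent.
* Correlation filtering requires ≥ 3 samples, ≥ 2 features, and finite
  values; feature batches are consecutive in genomic order and the last
  batch is smaller.
* AUC ties count 0.5; posteriors are clipped away from {0, 1} by one
  machine epsilon.
* Problem sizes in tests and the acceptance script (10 Mb region, 2000
  windows, 50,000 fragments/sample, 10 replicates per chemistry) were
  chosen so the complete property suite runs in minutes on one CPU
  while keeping per-window counts in the regime where the CNV effect is
  comparable to Poisson noise — small enough that the classifier is
  genuinely challenged, as the stage-graded sensitivities show.

## Known limitations

* The correlation filter's batching makes the kept set depend on
  feature order across batch boundaries (two highly correlated features
  in different batches are never compared) — inherent to the batched
  design.
* The single-pass filter can retain pairs whose mutual correlation
  exceeds the threshold when their batch means stay below it; the
  iterative variant addresses this at the cost of removing more.
* The location-group map and early-stage definition are configurable
  conventions, not biology derived from data.
* BAM ingestion is out of scope; fragments enter as BED3 intervals
  produced upstream.
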