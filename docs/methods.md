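# Methods

This note documents the models, the estimator and parameter choices,
the synthetic-data generator, and what the shipped benchmarks do and do
not demonstrate.

## Coverage signals

**RC** counts filtered reads by leftmost mapping position: primary,
mapped, non-duplicate alignments with mapping quality strictly greater
than the threshold (default 10, i.e. MQ ≤ 10 discarded). The leftmost
coordinate is used regardless of strand — deterministic and
strand-symmetric in expectation. **DOC** averages per-base aligned depth
over the window; aligned bases are the gapless M/=/X stretches of the
CIGAR, so deleted reference bases contribute nothing, and a read
spanning several windows is apportioned per base. DOC is preferred when
read length exceeds the window, where start-position counting would
leave most windows empty.

Windows are 0-based half-open. The trailing window of a chromosome may
be short; it is excluded from normalization when it covers less than
half a window, because its count is systematically low.

## Median normalization

For covariate X ∈ {GC percent, mappability bin}: corrected value =
value · m / m_X with m_X the bin median and m the global median. The
two passes run GC first, then mappability, each as a 1-D correction
(the correction formula is defined per single covariate; a joint 2-D
binning would leave many near-empty cells). After correction every
populated bin has median exactly m.

Parameters and conventions:

* **GC bins** are integer percent, computed with ambiguous bases (N)
  excluded from numerator and denominator; an all-N window is flagged
  unusable. Rounding is half away from zero.
* **Mappability bins** are multiples of 0.1; the per-window value is
  the mean over bases with positions missing from the track counted as
  0 (an unreported position is treated as unmappable — conservative).
* **min_bin_count = 30**: a bin with fewer windows borrows the median
  of the nearest populated bin, because medians of a handful of windows
  are too unstable to divide by. If no bin is populated every bin keeps
  its own median.
* Zero-median bins are masked rather than divided.
* The median is the standard sample median (mean of the two central
  order statistics for even n).

Two-copy rescaling maps the genome-wide median of usable windows to 2;
this assumes the majority of the genome is diploid, which holds for
germline genomes and is the reason the `nocontrol` design targets
population studies. log2(norm/2) is then 0 at two copies. Windows with
non-positive corrected values are masked; segmentation runs on the
usable subset with original coordinates preserved, so segments may span
masked gaps.

In `paired`/`pooling` designs each sample is bias-corrected
independently and the log2 ratio test/control is analysed; the pooled
control is the window-wise sum of the control pool's raw counts.

## Shifting level model

The signal is x_i = m_i + ε_i with ε_i ~ N(0, σ²_ε); the level m_i
stays put with probability 1−η and with probability η jumps to a fresh
draw from N(μ, σ²_μ). Discretising the level onto K candidate values
makes this an HMM with transition matrix
A_ij = (1−η)·1[i=j] + η·w_j, where w_j is the normalised N(μ, σ²_μ)
density at level j (also the initial distribution), and Gaussian
emissions N(x; level_j, σ²_ε). Viterbi decoding gives the exact MAP
level sequence; ties break toward staying in the current state,
favouring longer segments. Each chromosome is segmented independently.

Estimator choices (all exposed in `RunConfig`):

* **Candidate levels**: K = min(40, #distinct values) equally spaced
  points spanning the range of a 5-window running-median smoothing of
  the signal. Smoothing keeps single-window outliers from stretching
  the grid while preserving shifts of a few windows or more.
* **Noise variance σ²_ε**: from the median absolute successive
  difference, scaled for Gaussian noise (median|Δ| = 0.9539 σ for
  differences of white noise). A level shift contaminates a single
  difference, so this estimate is robust to exactly the structure being
  segmented, unlike the raw signal variance, which mixes noise and
  event variance.
* **Level-process variance σ²_μ**: max(ω·var(signal), (span/2)²) with
  ω = 0.1 and span the width of the candidate grid. The floor matters:
  were σ²_μ a small fraction of the signal variance alone, the jump
  prior would put essentially zero mass on levels one log2 unit away
  and the decoder could never reach a heterozygous-deletion level at
  low coverage, whatever the evidence. With the floor, every candidate
  level keeps non-negligible prior mass and the data decide.
* **Jump probability η = 5·10⁻³**: the prior expectation of a few
  breakpoints per thousand windows, the regime of CNV-bearing genomic
  profiles. Larger η trades specificity for sensitivity; the number of
  decoded breakpoints is monotone non-decreasing in η (tested). On
  pure-noise chromosomes the default produces no calls (0 non-neutral
  calls on 30 simulated noise-only 1000-window chromosomes).
* Degenerate inputs (constant signal, fewer than 10 windows) return a
  single segment rather than an error.
* Optional Baum–Welch refinement (off by default) re-estimates η and
  σ²_ε only, holding levels and μ fixed; treating the per-step jump
  indicator as an extra latent variable keeps both updates exact
  M-steps, so the log-likelihood is monotone non-decreasing (tested).
  Re-estimating the tied landing distribution w is not log-linear and
  is deliberately out of scope.

All decoding is in log space.

## Five-state calling

Segment means (each weighted by its window count — long segments carry
more evidence) are fitted with a five-component Gaussian mixture whose
means are pinned at the cellularity-adjusted expectations

μ_k(c) = log2(max(c·CN_k + 2(1−c), 0.1)/2), CN_k = 0..4,

with a floor of 0.1 copies keeping the CN 0 anchor finite (residual
mismapping produces nonzero coverage in real homozygous deletions). EM
estimates the mixing weights and a shared standard deviation; when the
cellularity is not supplied it is chosen by likelihood over the grid
0.1, 0.2, …, 1.0. In `nocontrol` mode the signal is on the absolute
two-copy scale, so c = 1 by construction and the grid search is
skipped.

Classification uses cut points at the **copy-number midpoints**,
log2((c·(CN_k + ½) + 2(1−c))/2): at c = 1 the neutral bracket on the
raw two-copy scale is exactly (1.5, 2.5), so a region whose median
coverage is 1.5 copies or lower can never be called neutral, and
symmetrically at 2.5 for gains. Values exactly on a cut point go to the
lower state. Each component of the reported model is the Gaussian
renormalised to its bracket; because the brackets partition the line,
the truncated-mixture posterior is degenerate (0 or 1), so the reported
`prob` is the posterior of the assigned state under the corresponding
untruncated mixture, which is informative and still row-normalised.
The EM likewise uses untruncated responsibilities for numerical
stability; with anchored means and a shared sd the fits agree.

With fewer than five segments the mixture is unidentifiable and fixed
cut points (−1.5, −0.42, +0.32, +1.0 on the log2 scale) are used
instead.

Copy numbers: state-implied CN for states 0–3; multiple gain is
genotyped from the signal as max(4, round(2·2^mean_log2)), supporting
genotypes of 5, 6 and beyond. `genotype_absolute` additionally
estimates CN = round(region median of the two-copy-scaled signal) and
records (without overriding the state call) whether the two agree.

## Synthetic data generator

Window counts are negative binomial with mean
base_mean · (cn/2) · gc_bias(gc) · map_bias(map) and variance φ·mean.

* **φ = 3** by default: real window counts show an index of dispersion
  clearly above 1 but moderate; φ is configurable and φ ≤ 1 falls back
  to Poisson.
* **base_mean** = coverage · window_size / read_length (read length
  100 bp), e.g. 30 per 100 bp window at 30x.
* **CN 0** windows use a floor of 0.1 copies, mirroring the calling
  model's assumption about residual mismapping.
* **Default GC bias**: unimodal factor 1 − 0.4·((gc−45)/55)², peaking
  at 45% GC and falling 40% at the extremes — coverage is empirically
  maximal in the 35–60% GC band. **Default mappability bias**:
  0.4 + 0.6·map. Synthetic annotations draw GC uniformly over 20–80%
  and make 70% of windows uniquely mappable.
* The flagship protocol builds 1000-window chromosomes with one
  deletion or duplication of N consecutive windows (N ≤ 500) at a
  uniform random position; everything is reproducible from a seed.

What the generator does **not** emulate: correlated noise along the
genome (wave artefacts, replication timing), breakpoint microhomology
or imprecision at the base-pair level, segmental-duplication
mismapping structure, multi-event chromosomes, or subclonal mixtures of
more than one aberrant population. Passing the synthetic benchmarks
therefore demonstrates the correctness and calibration of the
algorithmic chain under the stated noise model, not performance on any
particular real cohort.

## Benchmarks shipped with the package

Problem sizes were chosen to keep every benchmark comfortably within a
developer's patience on one CPU core:

* Full-pipeline detection: 200 single-event chromosomes per condition
  (5 kb events at 30x/100 bp; 10 kb events at 10x/1000 bp), scored by
  ≥ 50% reciprocal overlap with direction matching; TPR ≥ 0.9 expected
  in both regimes.
* Deletion/duplication asymmetry: deletions are detected at least as
  well as duplications at matched size (100 chromosomes per size in
  {5, 10, 20} windows) — the deletion shift (−1) is nearly twice the
  duplication shift (+0.585) on the log2 scale.
* Distribution fit: on 10⁵ NB(φ=3) counts the moment-fitted negative
  binomial has a smaller KS distance than the moment-fitted Poisson.
* Bias removal: at base mean 2000 (e.g. 20x with 10 kb windows) the
  default 40% GC bias induces |Pearson r| > 0.3 between raw counts and
  GC, erased to |r| < 0.05 by normalization; likewise for mappability.
  (At 30x/100 bp the NB noise dominates the marginal correlation, so
  the check runs where the bias is resolvable.) GC and mappability are
  injected in separate runs so each marginal correlation is
  attributable.
* Viterbi exactness: 200 random instances with n ≤ 12 windows and
  K ≤ 3 levels against vectorised exhaustive enumeration of all K^n
  paths; also cross-checked against an external HMM decoder on one
  larger instance.
* Genotyping: 210 regions of 50 windows at CN 0–6, 30x: regression
  slope of predicted vs true CN within [0.95, 1.05] and ≥ 95% exact.
* Null specificity: a sample paired against itself yields a constant
  zero log2 ratio and no non-neutral calls on 10⁵ windows.

## Known limitations

* The five-state model assumes a single aberrant population; complex
  subclonal architectures need downstream deconvolution.
* The 1-D cellularity grid is a convenience, not a purity/ploidy joint
  search; highly aneuploid genomes can defeat the two-copy median
  anchor.
* Sequential 1-D bias correction cannot remove interactions between GC
  and mappability bias.
* Breakpoints are resolved to window boundaries; sub-window precision
  requires split-read evidence outside the read-depth paradigm.
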