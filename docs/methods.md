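# Methods

## Steady-state kinetic model

The core assumption is a birth–death balance for a constitutively
transcribed gene: mRNA is produced at a constant whole-cell rate
β_tot = φ·c·β (φ the fraction of scorable alleles actively transcribing, c
the allele count, β the per-allele rate) and each molecule decays
independently at rate δ. At stationarity the mature count M is
Poisson(β_tot/δ), so a measured M and an independent estimate of β give
δ = φ·β·c/M and t½ = (ln 2/δ)·60 minutes.

β comes from the transcription focus. A polymerase resides on the gene for
L/v hours (L gene length in nt, v elongation rate in nt/h), so by Little's
law the mean polymerase load is β·L/v. A nascent transcript only
hybridises the probes 5′ of its polymerase; for a probe library with
centres x_i the expected hybridisable fraction under a uniform polymerase
position is the weighting factor K = (1/n)·Σ(L−x_i)/L. The focus intensity
in single-transcript units, N, therefore estimates K × (polymerase load),
and β = (N/K)·v/L.

Assumptions worth keeping in view:

- **Steady state.** A growing, dividing cell never quite reaches it. The
  package surfaces the caveat as metadata on every result table; it does
  not attempt a correction.
- **Constant elongation, no pausing or bursting.** v defaults to 90,000
  nt/h (1.5 kb/min); published estimates in comparable tissues span
  1.1–1.5 kb/min and the parameter accepts that range. Time-resolved or
  bursting models are out of scope.
- **Probe-site convention.** A probe counts as hybridisable once the
  polymerase passes its *centre*, as a step function. The symmetric centre
  convention changes K by less than probe_length/L relative to a 3′-end
  convention; for a 20 nt probe on a 9 kb transcript that is < 0.3%.

## Per-cell estimation and the focus-calling floor

Estimates are made per cell and then averaged within groups (mean ±
s.e.m.), matching how per-cell measurements are normally reported. The
per-cell half-life is proportional to M/N, and 1/N is heavy-tailed when the
nascent signal is weak, which would bias a naive mean upwards. The
focus-calling rule regularises this: a nuclear spot must exceed
`min_focus_multiple` (default 2.0) single-transcript equivalents to be
called a focus, and cells without a called focus are flagged and excluded
from half-life averages. Under the default study-like conditions (mean
polymerase load ≈ 22, E[N] ≈ 3.4, E[M] ≈ 100) this leaves the mean
per-cell half-life within a few percent of truth — the recovery tests
measure it directly. φ defaults to 1.0 under this reading ("analyse cells
with a visible focus"); the alternative reading, φ = population fraction of
focus-positive cells, is available via `phi_from_focus_fraction=True`.

## What the simulator emulates — and what it does not

`simulate_counts` draws M directly from the Poisson stationary law and the
polymerase load from Poisson(β·L/v) with i.i.d. uniform positions; the
focus signal is the summed hybridisable fraction over polymerases. Tests
verify this shortcut against an explicit Gillespie birth–death simulation
(stationarity χ²) and an event-level elongation simulation (Little's law),
which exist only in the test suite. Covariate pairs come from a bivariate
normal at a specified population correlation, optionally mapped
monotonically onto per-cell half-life. `render_image` draws each transcript
as an anisotropic 3D Gaussian (PSF σ 110 nm lateral / 350 nm axial, voxels
200×74×74 nm), the focus as one brighter nuclear spot, with Poisson shot
noise, Gaussian read noise and a flat background inside ellipsoidal
cell/nuclear masks.

The default transcript is a *synthetic* myc-long-like model: 9 kb with 48
probes evenly tiling a 2.75 kb 3′ window, constructed so the layout's
weighting factor equals the study constant K = 0.15264. It reproduces the
3′ bias of a UTR-directed library but is not the published probe set; the
sequence-level tests build a synthetic transcript around it. Transcription
rate is held fixed across simulated conditions (β ≈ 223.6 mRNA/h, giving
100 expected mature transcripts at the 18.6 min condition) and only δ
varies — consistent with the observation that nascent counts are stable
across genotypes while mature counts move with stability. Because of that,
passing recovery tests show the estimator is calibrated for 3′-biased
libraries at moderate nascent signal; they do not exercise mitotic cells,
segmentation error, chromatic offsets, optical aberrations or transcription
bursting, none of which are simulated.

## Spot quantification choices

Detection is Laplacian-of-Gaussian at the PSF scale with per-axis sigmas,
3D local maxima, and a threshold of `threshold_sd` (default 5) robust
background s.d. (1.4826·MAD) of the filtered response. Because a smoothed
noise field occasionally pushes a local maximum past that threshold, a
detected peak must also clear an integrated-intensity floor of
`threshold_sd` times the photon-noise s.d. of a background box sum.
Integrated intensity is the pixel sum over a ±3σ box minus the median of
the box's border shell (a pixel-sum convention; Gaussian-fit photometry is
not implemented). Sub-voxel positions are intensity-weighted centroids.

Unit (single-transcript) intensity is the *median* of non-focus spot
intensities pooled over the whole batch — robust to unresolved doublets —
with the mean available via `unit_stat="mean"`. Focus candidates (brightest
nuclear spot per cell) are excluded from the pool before calibration, so
the unit is independent of cell order. Mask membership is evaluated at the
spot's centroid voxel; boundary voxels count as inside. Mitotic-cell
exclusion is an input flag on the cells manifest, not an image classifier.

## Statistics

Defaults mirror common GUI-package conventions: pooled-variance two-sided
t-tests (Welch and paired via flags), one-way fixed-effects ANOVA, Dunnett
two-sided comparisons to a single control via the equicoordinate
multivariate-t distribution (seeded quadrature, error well below 10⁻³),
pairwise-complete Pearson correlations with p from t = r√((n−2)/(1−r²)),
and Benjamini–Hochberg step-up FDR at q = 0.05 (the specific FDR variant
used upstream is unnamed; BH is the standard choice and is flagged as such).

## RIP-seq ranking

Size factors are median-of-ratios against a geometric-mean reference over
genes nonzero in every library, falling back (with a log message) to
total-count scaling below 50 such genes. Genes with summed raw input counts
< 10 are dropped *after* the calibration is computed, so the per-gene ratio
does not depend on which other genes survive. Enrichment is
(mean normalised IP + 0.5)/(mean normalised input + 0.5), ranked
descending, ties broken by gene id; the 0.5 pseudo-count is a zero-handling
choice. Overlapping ncRNA flags remove genes from top-N views only.
External differential-test columns (padj, log2FC) are applied as a filter
(padj < 0.01, log2FC > 2) and never recomputed. The planted-enrichment
generator draws NB counts (var = μ + 0.1μ²); rank-recovery tests plant a
*graded* enrichment spectrum up to 8-fold, since a binary enriched/not
design leaves the true ranking mostly tied and caps any rank correlation
near 0.5 regardless of estimator quality.

## Problem sizes and numerical details

Recovery runs use 200 cells per population and 10,000 covariate pairs;
Monte-Carlo equivalence checks use 10⁴–2×10⁵ draws; the Dunnett
family-wise-error simulation uses 10⁴ replicate null datasets. All
randomness flows through `numpy.random.default_rng` seeds recorded in
outputs; CLI runs additionally write a manifest with the resolved config
and its hash. Degenerate inputs (M = 0, N = 0, uncalled focus, constant
features, all-zero count matrices) produce flagged records or explicit
errors, never silent drops.

## Known limitations

- The weighting-factor reproduction uses the synthetic probe layout; with a
  real probe table (CSV of positions or FASTA of sequences) the same code
  paths apply, but the shipped K = 0.15264 equality is by construction.
- Intensity photometry is pixel-sum, not PSF fitting; dense spot fields
  (separations below ~3σ) will merge.
- No segmentation: cell and nuclear masks are inputs.
- The steady-state estimator is undefined for cells with no mature
  transcripts and excludes focus-negative cells; strongly bursty genes
  violate its assumptions.
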