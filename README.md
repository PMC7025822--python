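# fishkin

Single-cell smFISH transcription kinetics: from per-cell transcript counts
and transcription-focus intensities to transcription rates, mRNA decay rates
and half-lives — plus the surrounding per-cell statistics and RIP-seq
enrichment ranking.

## Who this is for

Groups quantifying gene expression in individual cells with single-molecule
FISH (for example *Drosophila* neuroblasts, where RNA-binding proteins such
as Imp and Syp tune *myc* mRNA stability cell by cell). Mature mRNAs appear
as diffraction-limited spots; the nuclear transcription focus carries all
nascent transcripts at the locus. From just two numbers per cell — the
mature count *M* and the focus intensity in units of one mature transcript,
*N* — steady-state kinetics lets you split a change in transcript number
into a transcription-rate effect and a stability effect.

## The model

A probe library tiles the transcript; a nascent transcript only carries the
probe sites 5′ of its polymerase. For probe centres *x<sub>i</sub>* on a
transcript of length *L*, the **weighting factor**

> K = (1/n) Σ<sub>i</sub> (L − x<sub>i</sub>)/L

is the expected hybridisable fraction of the library for a polymerase
uniform on [0, L], so *N*/K estimates the number of engaged polymerases.
With elongation rate *v* (default 1.5 kb/min), chromosome fraction φ and
copy number *c*:

> β (mRNA/h) = ((N / K) · v) / L
> δ (1/h)  = (φ · β · c) / M      (steady state: production = degradation)
> t<sub>½</sub> (min) = (ln 2 / δ) · 60

Each cell gets its own estimate; groups are summarised as mean ± s.e.m. of
per-cell values. A transcription focus is only *called* when it exceeds
2× the single-transcript unit intensity; cells without a called focus are
flagged and excluded from half-life averages rather than silently dropped.

The package also provides:

- **`simulate`** — a generative simulator matching the model (Poisson mature
  counts, Poisson polymerase loads at uniform positions, optional rendered
  3D image stacks with realistic voxel anisotropy), with ground truth for
  closed-loop validation;
- **`spotquant`** — LoG spot detection in 3D stacks, focus identification,
  batch unit-intensity calibration and nascent counting (or a bypass mode
  for precomputed spot/count tables);
- **`cellstats`** — pairwise-complete Pearson correlation matrices, one-way
  ANOVA with Dunnett comparisons to control, pooled/Welch/paired t-tests,
  Benjamini–Hochberg FDR;
- **`ripseq`** — RIP-seq IP/input enrichment ranking with median-of-ratios
  library-size correction, low-abundance filtering, overlapping-ncRNA
  flagging and seven keyword-defined GO categories.

## Worked example

```python
import fishkin as fk

transcript = fk.myc_like_transcript()          # 9 kb, 48 probes in the 3' UTR region
print("K =", round(fk.weighting_factor(transcript), 5))

cfg = fk.wild_type_like_config(n_cells=200, half_life_min=18.6, seed=1)
counts = fk.simulate_counts(cfg)               # cell_id, M, focus_signal, ...
quants = fk.cellquants_from_counts(counts)     # bypass mode: counts -> CellQuant
results = fk.SteadyStateKinetics(quants, transcript).fit()
print(results.summary())
```

```
K = 0.15264
Steady-state transcription kinetics
============================================================
gene: myc-like   L = 9000 nt   probes = 48
K = 0.15264   v = 90000 nt/h   phi = 1.000   c = 1
------------------------------------------------------------
beta_mRNA_per_hr   all          mean    247.335 mRNA/h  sem    6.365  n 166
delta_per_hr       all          mean      2.508 1/h     sem    0.070  n 166
half_life_min      all          mean     18.752 min     sem    0.512  n 166
------------------------------------------------------------
flagged cells: 34 / 200
Estimates assume steady state (production = degradation) and a constant
elongation rate without pauses or pulsing; ...
```

The population was simulated with a true half-life of 18.6 min and an
expected 100 mature transcripts per cell; the pipeline's mean per-cell
estimate lands at 18.75 min (within one s.e.m.). 166 of 200 cells had a
callable transcription focus (≥ 2 mature-transcript equivalents); the other
34 are flagged, not dropped silently.

The same flow is available from a shell:

```sh
fishkin simulate --n-cells 200 --half-life-min 18.6 --seed 1 --out run/
fishkin quantify --counts run/counts.csv --out run/estimates/
fishkin stats --table features.csv --correlate --out run/stats/
fishkin riprank --counts counts.tsv --go-map go.tsv --out run/rip/
```

Every command writes a `manifest.json` with the resolved configuration,
seed and config hash.

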