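# Methods

`zctexture` quantifies how a membrane-receptor immunostain is organised on
the cell surface.  Collagen-activated receptor tyrosine kinases such as DDR1
redistribute after ligand binding: a fine punctate stain gives way within
minutes to connected linear clusters, and over ~an hour to coarse, dense
aggregates that carry the phosphorylated receptor.  The package implements
the image statistics that make this progression measurable — a
zero-crossing texture score, morphological per-cell masking and intensity
quantification, and multi-channel ridge-profile analysis — together with a
synthetic scene generator that provides ground truth for every stage.

## The zero-crossing (ZC) linear-density score

**Model.**  Within a texture patch, the image is decomposed as
`I = background + texture`, where the background varies on scales much
larger than the texture (uneven staining, illumination).  The background is
estimated as a running local mean over a square window (default **10 μm**)
and subtracted; at patch edges the mean is renormalised over in-patch
pixels only, and a final constant offset enforces an exactly zero in-patch
mean.  The result (the *reference image*) carries only textural variation.

**Statistic.**  Random lines are drawn across the patch — a uniformly
random in-patch anchor pixel and a uniformly random angle in [0, π) — and
the reference image is sampled along each line at 1-px steps with bilinear
interpolation.  Each line contributes `crossings / length` (crossings of
the zero level per μm); the ZC score is the mean over lines (default
**2000**; the pooled alternative, total crossings over total length, is
available via `aggregation="pooled"`).  Zero-valued samples carry the
previous non-zero sign, so a tangency of the zero level is not a crossing.
A dead band of 10⁻⁹ × the in-patch RMS of the input image treats
numerically-zero residues as exact zeros; this makes the score's amplitude
invariance — `zc(c·I) == zc(I)` for any c > 0 under a shared seed — exact
in floating point for any realistic image.

**Theoretical anchors.**  For a sinusoidal grating of period P px, the
expected density over uniform angles is `(2/P)·E|cos θ| = 4/(πP)` crossings
per px.  For an isotropic Gaussian random field with Gaussian
autocorrelation `ρ(d) = exp(−d²/2ℓ²)`, Rice's formula gives `1/(πℓ)`.
Both are verified by the test suite (3 % and 10 % tolerances respectively;
the Rice check averages four field realisations because a single 256² field
with ℓ = 12 px has only ~450 independent patches and its realised crossing
rate fluctuates by ~5 %).  The averaging window must be much larger than
the texture scale: the Rice tests use 0.05 μm/px so the 10 μm window spans
200 px ≥ 16 ℓ; with smaller ratios the high-pass effect of mean subtraction
inflates the rate by several per cent.

**Units.**  Scores are reported per μm (pixel size is an explicit input);
a per-px conversion is provided on the result object.

## Cell masking and texture patches

The cell mask is built from the receptor channel: pixels strictly above a
pre-determined background level are selected, then two rounds of
[3×3 dilate → fill holes → 3×3 erode] close the stain into a solid region,
and the largest 8-connected component is taken as the cell (ties broken by
lowest centroid row, then column).  Pixels outside the frame count as
background; holes fill through 4-connected background.  When no background
level is supplied, a fallback of histogram mode + 3·(1.4826·MAD) is used.
An empty result raises a "no cell detected" error rather than returning an
empty mask silently.

Texture patches subdivide the cell into 1–4 regions of clean, representative
texture using Gaussian gradient signatures at two scales:

- *texture presence*: the fine-scale (σ = 0.15 μm) gradient magnitude,
  spread over 1 μm so the gaps between individual structures stay
  connected, must exceed 5 % of its in-cell 90th percentile;
- *confound exclusion*: the coarse-scale (σ = 0.6 μm) smoothed intensity
  flags bright membrane ruffles (above median + 4 robust SD) and
  out-of-focus/void areas (below 2 % of the median); the exclusion zone is
  dilated by 0.5 μm.

Surviving 8-connected components of at least 64 px are kept, largest first,
at most four.  All thresholds are keyword arguments; the defaults were
chosen on generator scenes so that a confound-free cell yields one patch
covering ≥ 70 % of the mask while a ruffle leaks < 5 % of its area into any
patch.  The two-scale construction is an interpretation — the underlying
idea (fine scale finds texture, coarse scale finds confounds) is standard,
but no published formula exists for it.

## Per-cell quantification and normalizations

- `mean_intensity` — arithmetic mean strictly within the mask.
- `restrict_to_colocalized` — intersects the receptor mask with a manual
  crop before quantifying the ligand channel, so extracellular ligand
  aggregates are excluded.
- `anchor_normalize` — affine rescaling `x ↦ 100·(x − mean(low)) /
  (mean(high) − mean(low))`; the two anchor-condition means map exactly to
  0 and 100 A.U., values outside the anchor range map outside [0, 100].
- `fraction_positive` — percentage of cells above a threshold with its
  binomial standard error; the default threshold is mean + 2 SD of the
  unstimulated condition (the original judgement was manual, so the
  threshold is configurable).
- `densitometry_fractions` — per-lane phospho/total band ratios expressed
  as percentages of the blot-wide ratio sum; conserves 100 exactly.
- `normalize_by_expression` — signal median ÷ expression median.  The
  ratio is the simplest reading of expression weighting; a regression-based
  alternative was considered and rejected for lack of a defined formula.
- `group_compare` — one-way ANOVA (scipy) with Bonferroni, Tukey HSD or
  Dunnett post-hoc, α = 0.05, returned as a tidy table.  Identical groups
  (zero between-group variance) report p = 1 rather than NaN.

## Line profiles, FWHM and double-wall detection

`extract_profile` samples every channel with identical geometry along a
user-placed segment at 1-px steps, averaging bilinear samples across a
perpendicular line width (default **0.2 μm**, the convention for
super-resolution ridge profiles).  `minmax_normalize` maps each channel's
extrema to exactly 0/100 A.U.  `fwhm` measures a structure's width between
the two half-maximum crossings nearest the peak with linear interpolation;
the baseline defaults to the profile minimum (a zero baseline is available
via `baseline="zero"` — whether background was subtracted before the
half-max in the original analyses is not documented, so both conventions
exist and the default is stated here).

`detect_double_wall` classifies a wall/filler profile pair: true iff the
wall channel shows two local maxima flanking a trough of depth ≥ 30 % of
the wall's range and the filler channel's global maximum falls strictly
between the peaks.  Peak *finding* runs on a lightly smoothed copy
(Gaussian, σ = 1 sample, prominence ≥ 10 on the 0–100 scale) to suppress
noise peaks, but peak positions and the trough depth are measured on the
raw normalised profile — at gaps of only 4–5 samples the smoothing itself
would fill the trough.  Failures return reason codes (`single_peak`,
`shallow_trough`, `filler_offset`) instead of raising.

## The synthetic scene generator

Scenes emulate the study conditions, not arbitrary images:

| class        | geometry                                   | char. length (default) | density |
|--------------|--------------------------------------------|------------------------|---------|
| `punctate`   | Gaussian spots, Poisson-sampled centres    | 0.2 μm (FWHM)          | 8 /μm²  |
| `linear_cidc`| persistent random-walk ridges              | 0.3 μm (FWHM)          | 0.5 /μm²|
| `aggregate`  | fewer, larger blobs (count = expectation)  | 0.8 μm (FWHM)          | 0.5 /μm²|
| `double_wall`| paired ridges ± g/2 off a centreline; a single centred ridge in the ligand and phospho channels | g = 0.2 μm (gap) | 0.2 /μm² |

Design points, in order of consequence:

- **Constant coverage across classes.**  Densities are set so every class
  fills the cell at roughly half coverage; the characteristic length then
  drives the crossing rate (≈ 4:2:1 for 0.2/0.3/0.8 μm).  With sparse
  textures the ZC score would instead measure structure spacing and
  camera-noise crossings in empty regions, which is not what the
  experimental images look like (the stain covers the cell).
- **Diffuse baseline.**  A uniform in-cell level of 15 % of the structure
  amplitude models unclustered receptor; without it, intensity
  thresholding cannot recover the cell outline from a punctate stain.  It
  is expressed as a fraction of amplitude so rendering stays exactly
  linear in amplitude.
- **Confounds.**  Multiplicative low-order-polynomial illumination
  (peak-to-trough set by `illumination_amplitude`, default 0.2), bright
  Gaussian ruffle blobs (3–5× amplitude, σ 0.4 μm) centred within 1 μm of
  the mask boundary, Poisson shot noise (intensities as expected photon
  counts × gain) and additive Gaussian read noise (sd 2 a.u. against a
  100 a.u. amplitude).
- **Timecourse mapping.**  0 min → punctate, 5–30 min → linear, ≥ 45 min →
  aggregate, with strictly increasing characteristic length; the
  phospho-channel amplitude is 0 / 15 / 100 % of the receptor amplitude
  along the same ordering, mirroring the slow activation kinetics.
- **Double-wall scenes** use 0.04 μm/px (super-resolution-like sampling —
  a 0.2 μm gap is not resolvable at the 0.1 μm default) and confine the
  wall centrelines to a mask eroded by g/2 + 2σ so walls are never clipped
  by the cell edge; the offset wall polylines are re-densified so wall
  brightness stays uniform along curves.
- **Determinism.**  One scene seed drives independent child streams for
  shape, texture and per-channel corruption (channel streams keyed by a
  CRC of the channel name, so determinism holds across processes).

What the generator does **not** emulate: optical PSF/SIM reconstruction
artefacts, 3-D structure, photobleaching, per-cell expression variability,
or multi-cell fields (cropping to single cells is an input, as in the
original workflow).  Consequently the positive-cell-fraction readout is
qualitative on synthetic cohorts (it rises with time but its absolute
percentages are not calibrated to real cell-to-cell heterogeneity), and
passing tests demonstrate correctness of the *computations*, not
performance on real microscope data.

## Numerical choices and degenerate inputs

- Bilinear interpolation (`order=1`, nearest-edge padding) everywhere a
  sub-pixel sample is needed; 1-px steps never miss crossings of
  band-limited signals.
- Line sampling keeps only the contiguous in-patch run through the anchor
  (membership tested at the nearest pixel); lines shorter than 3 samples
  are redrawn, with a retry cap of 50 before a degenerate-patch error.
- Largest-component ties broken deterministically (centroid row, column).
- `anchor_normalize` with equal anchor means, constant profile channels in
  `minmax_normalize`, empty masks, zero-length segments, and zero lane
  totals all raise errors naming the offending quantity.
- All randomness flows through `numpy.random.Generator` objects seeded from
  explicit arguments; every output table records its seed.

## Problem sizes in tests

The default test suite and the acceptance script use 128² scenes (12.8 μm
cells at 0.1 μm/px), 100–400 lines per patch for cohort-level scores, 20 000
lines for the single-grating density, 50 timecourse replicates, and
100 + 100 labelled scenes for double-wall classification; these sizes put
the Monte-Carlo error comfortably below each check's tolerance while
keeping the whole suite fast.

## Known limitations

- Whether the original score counted crossings per μm or per pixel is not
  documented; per-μm is the default here, with an explicit conversion.
- Whether the per-line or pooled aggregation was used originally is not
  documented; per-line mean is the default and the option is exposed.
- The two-scale patch segmentation is an interpretation (see above); its
  thresholds are calibrated on the generator, not on real images.
- `normalize_by_expression` implements one defensible reading of
  expression weighting; results carry that convention.
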