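# Methods

## Measurement model

Feulgen densitometry assumes the dye bound in a nucleus is proportional
to its DNA mass (1:1 stoichiometry), and that the preparation is a
spread monolayer so whole nuclei are measured individually without
overlap in the optical path. Under Beer–Lambert, a pixel's absorbance is
`OD = log10(1/T)` with `T = I/I0`, and a nucleus's integrated optical
density `IOD = Σ log10(1/Tᵢ)` over its segmented pixels is proportional
to its DNA mass. The per-pixel OD is summed directly (not mean OD ×
area), and no background subtraction is applied inside the mask beyond
the white-reference normalisation: IOD is defined purely as the summed
log-ratio.

Quantification uses a one-point internal standard: chicken erythrocyte
nuclei (2C = 2.5 pg) processed in the same staining batch. The
calibration stores a standard curve — the origin plus (2.5 pg, mean
standard IOD) — so multi-standard curves remain representable, but the
conversion itself is the single ratio `pg = 2.5 / mean IOD(standard) ×
IOD(sample)`. The implied assumptions: stain uptake per pg is the same
for standard and sample (same batch, same reagents), and the chromatic
response is linear over the measured OD range. Per-slide spiked
standards are not modelled; standards come from dedicated smear images
in the same batch.

## Image processing

* **White reference.** `I0` is estimated as the median of the bright
  class after an Otsu split of the intensity histogram; if the two
  classes are not separated beyond twice the overall spread the whole
  image is treated as blank background. This is unbiased under
  symmetric noise whenever a reasonable fraction of the field is
  background.
* **OD transform.** `T` is clamped to `[t_floor, 1]` with `t_floor =
  1e-3` (OD cap 3.0), avoiding log-of-zero on dark pixels and mapping
  glare to OD 0.
* **Segmentation.** Default threshold is Otsu's value on the OD
  histogram, floored at `min_od = 0.05` so blank fields produce no
  labels. Because Otsu sits high when foreground is sparse, the binary
  mask is produced by hysteresis: seeds above the Otsu level are grown
  down to the floor, so weakly stained rims are captured rather than
  fragmented. Masks are hole-filled. Components are 8-connected;
  coordinates are row/column, 0-based; areas are whole-pixel counts.
* **QC flags.** Components touching the border, outside
  [`min_area_um2` = 8, `max_area_um2` = 400] (plausible nuclei span
  roughly 25–75 μm² mean areas), or with solidity < 0.75
  (`merged_suspect`) are flagged and excluded from measurement by
  default. The solidity heuristic also trips on genuinely non-convex
  nuclei (bell/cup shapes, chains); `include_flagged=True` measures them
  anyway. Watershed splitting of touching nuclei is opt-in
  (`split_touching`), since spreads are monolayers by design.
* **Densitometric SD** uses the n−1 denominator; single-pixel labels
  report 0 with a `tiny` flag.

## Synthetic slides

The generator renders `I = i0 · L(x,y) · 10^(−A) + ε`, where `A` is the
summed absorbance field, `L` an optional linear illumination field and
`ε` additive Gaussian noise clipped to `[0, i0]` (shot noise is not
modelled). Each nucleus deposits exactly `stain_factor × pg` total
absorbance over its footprint, distributed by a centre-weighted profile
(weight 1 at the rim, 1 + `texture_strength` at the deepest interior
point, adapting to any footprint shape) with optional multiplicative
texture noise — so the densitometric SD is nonzero, as in real
chromatin. Footprint shapes: ellipse (eccentricity ≤ 0.6), cigar
(≥ 0.9), bell (open annulus), syncytium (wandering chain of 4–10
nuclei with ≥2 px gaps), multinucleated (cluster of 2–20 in a disc).
Shape classes exist to stress segmentation, not as biological models.
Placement is rejection sampling with a 2 px margin and a 200-retry
budget; unplaceable nuclei are skipped with a warning and excluded from
ground truth.

Defaults, chosen once as a realistic operating point:

| parameter | default | rationale |
|---|---|---|
| `i0` | 30 000 (16-bit) | mid-range white level; quantisation error on IOD ≪ 0.1% |
| `stain_factor` | 300 OD·px/pg | mean intra-nuclear OD ≈ 0.3 for diploid nuclei — well inside the linear densitometry range |
| `area_per_pg` | 10.36 μm²/pg | puts cRBC (2.5 pg) at 25.9 μm² and diploid human nuclei near 62 μm², typical spread-preparation values |
| diploid spread | 6.0 ± 0.6 pg (CV 10%) | biological + staining spread of a clean 2C population |
| sub-diploid populations | 3.0 ± 0.5, 1.7 ± 0.3 pg | osteoclast- and syncytium-like low-DNA nuclei |
| cRBC staining spread | CV 23% (on absorbance, not pg) | a well-run cRBC standard shows ~23% IOD CV; `true_pg` stays exactly 2.5 |
| `area_noise_cv` | 0.10 | area tracks DNA only loosely |
| `noise_sd` | 50 | background OD noise ≈ 7×10⁻⁴, i.e. nuclear contrast ≈ 400× noise |

What the generator does **not** emulate: optical blur/PSF, shot noise,
focus gradients, stain precipitate and debris, truly overlapping
nuclei, and section-thickness effects. Passing tests therefore
demonstrate correctness of the measurement chain under the stated image
formation model, not segmentation robustness on difficult real
material.

## Statistics

Conventions (the printed tables this layer mirrors do not state them):
SDs use n−1; skewness is the adjusted Fisher–Pearson estimator;
kurtosis is excess (Fisher) with bias correction; CI95 uses the normal
multiplier 1.96 (which reproduces the reference Total-row CI, unlike a
t quantile); the CV column is computed on nuclear areas, and the same
ratio on pg is reported separately as DCV (DNA content variation) —
the two are distinct columns because published tables conflate them.
Pooling combines within- and between-sample sums of squares,
`s² = [Σ(nᵢ−1)sᵢ² + Σnᵢ(x̄ᵢ−x̄)²]/(N−1)`, which is exact: pooling
per-sample rows equals describing the concatenated raw data.

Group comparison is the tie-corrected Kruskal–Wallis test (chi-square
p) with Dunn's rank-based pairwise z tests; the pairwise adjustment
defaults to none, with Bonferroni and Holm available. All-tied input
returns H = 0, p = 1 rather than an error. Fold-C histograms report
modes as prominence-filtered local maxima and a near-Gaussian flag when
|skewness| ≤ 2 and |excess kurtosis| ≤ 3 (configurable working limits).
The qPCR helpers compute triplicate mean ± SD (2 decimals) and
ΔCT = CT(target) − CT(reference).

## Problem sizes

The test suite and the reproduction script run entirely on synthetic
renders: smears of 50–300 cRBC nuclei and slides of 60–200 sample
nuclei (canvases around 2000–3200 px square), 1000 null simulations for
the Kruskal–Wallis type-I check, and 10⁵ draws for estimator
sanity checks. At these sizes the end-to-end mean recovered DNA mass
carries a ~1.8% standard error (sampling spread of 200 nuclei plus the
standard-mean uncertainty), comfortably inside the ±3% recovery check.

## Known limitations

* One standard species: the standard curve has a single non-origin
  point, so nonlinearity of stain response cannot be detected from a
  run.
* The `merged_suspect` solidity flag cannot distinguish merged nuclei
  from genuinely non-convex (bell/chained) morphologies.
* Skewness/kurtosis of pooled rows are not recoverable from second
  moments and are reported as NaN in Total rows.
* The estimator conventions above are this package's documented
  choices; published tables using other conventions will differ in the
  shape statistics.
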