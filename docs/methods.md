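# Methods

This note documents the models, parameters and numerical choices of
the package, and what the synthetic study does and does not establish.

## The measurement model

One acquisition is four RGB images (filter cubes U1, U2, BL, GR) of a
grain cross-section, 14-bit counts (16,384 gray levels). Merging the
R/G/B planes in canonical order gives a 12-channel cube
`U1b U1g U1r U2b U2g U2r BLb BLg BLr GRb GRg GRr`; U1r is removed
(excitation-band reflection), leaving 11 working channels. Channels
below their excitation wavelength (BLb, GRb, GRg) carry no
fluorescence and are kept as a baseline in every pseudo-spectrum.
Because the visible filters are acquired dimmer than the UV ones, a
multiplicative gain is applied to the BL/GR planes at assembly; its
value is not documented for the reference instrument, so the synthetic
generator exposes the inverse gain as a configuration value
(`visible_gain`, default 1 so that round trips are self-consistent).

Background is channel-dependent and additive. It is estimated as the
per-channel mean over a few signal-free rectangles read on a handful
of images (default: three corner rectangles × one image per stage =
12 regions) and subtracted everywhere, clamping at zero — counts are
nonnegative and the downstream sum images and Otsu thresholds assume
it.

## Synthetic phantoms

The generator replaces the unavailable raw data and defines the study
conditions: 4 stages × 10 sections from 5 grains (1–3 sections each).
Geometry is an ellipse (aspect 0.72) with a tapering ventral crease
notch; concentric layers are assigned by Euclidean distance to the
boundary: outer pericarp (6 px at the 512-wide default grid), endocarp
(9 px), testa line (2 px), aleurone (4 px, present from 450 °DAF), and
starchy endosperm inside; a crease-complex band surrounds the notch.
Per-stage target section areas are 4.64, 6.56, 7.11 and 6.11 mm² with
between-section jitter matching the reported standard deviations
(0.22/0.57/0.37/0.46 mm²). The default 512 × 384 grid covers the same
physical field as a full-scale 3500-px mosaic, so the pixel size is
1.44 µm × 3500/512 ≈ 9.84 µm; all morphological sizes scale with grid
width accordingly, and full-scale grids remain reachable through the
geometry configuration.

Three endmember pseudo-spectra span the contrasts of interest:

* **chlorophyll-like** — red emission under visible excitation
  (GRr 1.0, BLr 0.9, U2r 0.25);
* **hydroxycinnamate-like** — blue emission under UV
  (U1b 1.0, U2b 0.9, plus green shoulders);
* **lignin-like** — green emission under Blue excitation (BLg 1.0)
  with a broad blue/UV shoulder and only a weak red tail (BLr 0.06,
  GRr 0.03): a stronger tail would make the homogeneous late-stage
  deposit rival residual chlorophyll in red emission, contradicting
  the monotone decay of red fluorescence across development.

Stage trajectories (abundances in counts at unit weight):

| stage (°DAF) | chlorophyll (endocarp + crease) | hydroxycinnamate (outer layers) | lignin |
|---|---|---|---|
| 250 | 9000, homogeneous | 1500 | absent |
| 450 | 5500, homogeneous | 3000 (+ endocarp at 50%) | dots (40) |
| 650 | 6000 on 35% patches, ~2% residual | 4500 (+ endocarp at 50%) | dots (120) |
| 850 | 4000 on 2% dots | 2800 (+ endocarp at 50%) | 5000, homogeneous over all outer layers |

The chlorophyll trajectory is modelled as *coverage collapse* — the
per-pixel level stays high where the pigment remains while its
spatial coverage shrinks — rather than uniform fading: the developing
tissue shows high homogeneous red fluorescence early, irregular
patches at 650 °DAF and sparse dots at desiccation, and the decreasing
*proportion* of strongly red-fluorescent pixels is exactly what the
percentile-binned score distributions measure. Mean chlorophyll
abundance over the endocarp remains strictly non-increasing in stage.
The endosperm carries a weak diffuse phenolic signal (250–500 counts)
so the section interior is segmentable. The endocarp gains a moderate
phenolic signal from 450 °DAF on, consistent with the reported
UV-excited blue emission of that tissue during filling; it also keeps
the tissue detectable where chlorophyll has receded.

The forward model is linear mixing plus background, additive Gaussian
noise (default sd 10 counts), rounding and clipping to [0, 16383].
Gaussian noise is the minimal choice that supports CLT-based
verification of the background estimator; the renderer does not model
PSF blur, vignetting, spectral bleed-through or stitching seams (an
optional multiplicative seam band exists, off by default, as the
reference workflow ignored such artefacts). The U1r plane is rendered
as a bright reflection over the section rather than fluorescence.

**What passing tests show** — that the analysis chain recovers known
geometry (Jaccard against label maps), known mixing directions
(subspace angles to endmember differences), and known developmental
orderings from data with realistic dynamic range, noise and
quantization. **What they do not show** — robustness to optical
artefacts, stitching seams, focus variation, or tissue spectra that
drift continuously between stages; real acquisitions spread variance
over more than three components.

## Segmentation

*Whole section*: threshold 2 on the 8-bit sum-of-intensity image
(rescaled per image by its own maximum — the fixed threshold needs a
fixed 0–255 scale), then opening and closing with square elements of
sizes 51 and 150 at full mosaic resolution, scaled by grid width and
floored at 1. The largest 8-connected component is kept, making the
single-region invariant explicit. Per-image threshold overrides mirror
the manual adjustments of the reference workflow.

*Outer tissues*: Otsu thresholds on 8-bit rescalings (over section
pixels) of the 11-channel sum (T1) and of the U1b+U1g+U2b+U2g+BLg sum
avoiding red emission (T2); pixels at or above either threshold are
merged (union — the merge rule is not specified upstream), then disk
opening (1), dilation (8) and opening (12), scaled, and the largest
component kept. Thresholds are applied inclusively (≥) so an explicit
zero override selects every section pixel. A constant image over the
section raises a degenerate-input error rather than guessing a
threshold.

"Size" means side length for squares and radius for disks; the
upstream description does not define it, so it is fixed here and
recorded in every mask's `params_used`.

Section area = pixel count × pixel_size² × 10⁻⁶ mm².

## Streaming series PCA

Per image: `n_i`, `Σ x`, `X_i'X_i` over the whole-section ROI, in
double precision; per-image contributions are combined by pairwise
(tree) reduction to limit floating-point drift on long series.
Covariance uses the N−1 divisor (explained-variance percentages are
divisor-invariant) and is centered via the global mean — the score
step subtracts that same mean. Channels are not standardized: the
analysis runs on raw fluorescence counts, so component 1 is an
intensity contrast. Eigendecomposition uses `numpy.linalg.eigh` on the
symmetrized covariance; eigenvalues are sorted descending and each
loading is sign-flipped so its largest-magnitude entry is negative,
which renders bright tissue dark in score images and makes the
intensity loading all-negative. Tests compare loadings up to sign.

8-bit score rendering uses the common window ±3√λ_k (covering ≈99.7%
of a Gaussian score spread); the window derives from the eigenvalues
only, so all images of the series share it. Zero maps to mid-gray 128
(rounding half up). The spread factor is configurable.

Components are indexed 0-based in code and CSV tables and 1-based in
rendered file names (`*_c1.png` is loading-1's score image), matching
the field convention for naming loadings.

## Score distributions and similarity maps

The global pass histograms pooled scores on 10,000 linear bins in two
streaming passes (min/max, then counts); percentile edges (steps of
1%, i.e. ≤100 bins) are interpolated linearly *within* fine bins
rather than re-streaming raw scores — this matches the two-step
construction and keeps memory bounded at the fine-histogram size.
Duplicate edges from massive ties are merged (frequencies of merged
bins add); a fully degenerate pooled distribution (all scores equal)
yields a single bin. Observed per-image distributions are *relative*
frequencies — images with different ROI sizes stay comparable; the
normalization is a package choice, as is averaging stages without
re-weighting by grain (grains contribute 1–3 sections each).

Both the global percentile pass and the per-image pass run on the
outer-tissue ROI. The upstream description computes the global
histogram over "all the pixels" and the observed distributions over
the outer tissues; using one pixel population for both makes the
percentile construction self-consistent — the pooled pixel-weighted
distribution is uniform at 1% per bin by construction, which is the
conservation property the test suite checks.

The similarity map is an ordinary column-centered, unscaled PCA
(scikit-learn, full SVD) of the images × bins frequency matrix; with
n images at most n−1 components are meaningful.

## Pipeline

`run_pipeline(config)` chains simulate → assemble → segment → pca →
distributions → similarity, each stage reading from and writing to the
run directory; stage completion markers make `resume=True` skip
finished stages with byte-identical final outputs. The default renders
the first 5 components (all 11 are available). A single-section run
skips the similarity stage with a logged notice. Failures during
assembly name the offending section, supporting the per-section
override workflow.

Default problem size: the 512 × 384 grid with 4 × 10 sections keeps a
complete run, including acceptance recomputation, around a minute on
one CPU while preserving the physical field of view and scaled
morphology of the full-resolution design.

## Known limitations

* Three endmembers give the phantom series exactly three
  variance-carrying components; explained-variance *values* are not
  comparable to a real 40-image series, only their conservation
  properties and orderings are.
* No flat-field or per-filter exposure normalization beyond the single
  visible gain.
* Percentile edges inherit a quantization of ~1/10,000 of the pooled
  mass from the fine histogram; with heavy ties bins can be fewer
  than 100.
* The crease is one composite tissue label; sub-tissue anatomy
  (nucellar projection, pigment strand, vascular bundle) is out of
  scope, as are embryo-plane sections and optical realism.
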