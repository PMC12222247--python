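# grainfluor

Macroscopic multispectral autofluorescence analysis of developing
cereal grain cross-sections.

Developing wheat grains change the chemistry of their outer tissue
layers — chlorophyll in the endocarp is degraded, cell-wall phenolics
(hydroxycinnamic acids, lignin) accumulate — and these compounds
autofluoresce with distinct excitation/emission signatures. Imaging
whole transverse sections under a fluorescence macroscope with four
excitation filter cubes (two UV: U1, U2; two visible: Blue, Green)
yields, per section, four 14-bit RGB images whose merged color planes
form an 11-channel multispectral cube (the U1 red plane is dropped
because it carries the excitation Rayleigh reflection). The per-pixel
vector over the 11 channels is the pixel's *pseudo-spectrum*.

This package implements the complete analysis chain for a series of
such acquisitions, targeted at a study design of 4 developmental
stages (250, 450, 650, 850 cumulative degree-days after flowering,
°DAF) × 10 sections:

1. **Cube assembly** — merge the four RGB acquisitions (visible-filter
   planes rescaled by a gain), drop U1r, subtract a per-channel
   additive background estimated from signal-free rectangles.
2. **ROI segmentation** — whole grain section (fixed threshold on the
   8-bit sum-of-intensity image + square-element opening/closing,
   sizes 51/150 at full mosaic resolution, scaled to the grid) and
   grain outer tissues (union of two Otsu thresholds — full 11-channel
   sum and a UV-dominated sum avoiding red emission — cleaned with
   disk elements, largest region kept). Section areas in mm² come from
   the whole-section mask.
3. **Series-wide streaming PCA ("large PCA")** — every image is
   unfolded to a pixel × channel table X_i restricted to its ROI, and
   only `(n_i, Σx, X_i'X_i)` are accumulated. With N pixels overall and
   global mean m, the covariance is `C = (Σ X_i'X_i − N·m·m') / (N−1)`
   and its eigendecomposition gives eigenvalues λ_k and loadings L
   common to the whole series. Scores `(x − m)·L[:,k]` are refolded to
   score images and rendered to 8 bits on the shared window
   `±3√λ_k`, so score images are comparable across the series.
4. **Score distributions** — per component, the pooled scores of all
   outer-tissue pixels are histogrammed on 10,000 a-priori linear
   bins; percentiles (1% steps) of that distribution define shared
   variable-width bins; per-image relative frequencies on those bins
   quantify which images hold the contrasted pixels.
5. **Similarity maps** — an ordinary PCA of the stacked 40 × ~100
   distribution matrix places every image on a plane where
   developmental stages separate and order.

Because no public dataset accompanies the study design, the package
includes a first-class **synthetic phantom generator**: elliptical
sections with a ventral crease, concentric outer layers (outer
pericarp, endocarp, testa line, aleurone from 450 °DAF), three
fluorophore endmembers (chlorophyll-like, hydroxycinnamate-like,
lignin-like) with stage-dependent abundance trajectories, linear
mixing, channel-dependent background, Gaussian noise, 14-bit
quantization — plus ground-truth label maps for exact scoring of any
downstream mask.

## Worked example

The analysis is organised as numbered drivers over the library; each
stage can also be called directly (`grainfluor.run_pipeline` runs all
of them from one `RunConfig`).

```bash
python analysis/01_simulate_series.py --seed 1
python analysis/02_assemble_cubes.py  --seed 1
python analysis/03_segment_rois.py    --seed 1
python analysis/04_fit_series_pca.py  --seed 1
python analysis/05_score_distributions.py --seed 1
python analysis/06_similarity_maps.py --seed 1
```

Output (seed 1, default 512 × 384 grid):

```
simulated 40 sections (10 at 250 °DAF, 10 at 450 °DAF, 10 at 650 °DAF, 10 at 850 °DAF)
assembled 40 cubes (12 channels merged, U1r dropped -> 11 kept)
section areas (mm^2) per stage:
  250 °DAF: 4.63 ± 0.29  (n=10)
  450 °DAF: 6.37 ± 0.50  (n=10)
  650 °DAF: 7.05 ± 0.45  (n=10)
  850 °DAF: 6.15 ± 0.52  (n=10)
fitted on 2,498,145 ROI pixels of 40 images
leading components (% variance): 54.53, 37.51, 7.95, 0.00, 0.00 | top-5 cumulative 100.00%
observed distributions computed for 40 images x 5 components
component 1: axis-1 stage ordering 250 > 450 > 650 > 850 (axis 1 explains 42.3%)
```

Reading the numbers: the grain grows from 250 to 650 °DAF and shrinks
slightly at desiccation (the area trajectory). Component 1 of the
series PCA is the red-emission (chlorophyll) intensity contrast; its
similarity map orders the four stages monotonically along axis 1 —
the chlorophyll decay signal. With three synthetic fluorophores the
phantom series has exactly three variance-carrying components; real
tissue spectra spread variance over more components, with the five
leading ones carrying essentially all of it in the reference analysis
(82.26 + 13.78 + 2.02 + 1.30 + 0.51 = 99.87%).

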