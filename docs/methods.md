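# Methods

`senometrix` quantifies three complementary readouts of mitochondrial
state in therapy-induced senescent cancer cells: label-free two-photon
excited fluorescence (TPEF) of the metabolic cofactors NAD(P)H and FAD,
JC-1 membrane-potential ratiometry, and MALDI-TOF lipid profiling. Real
acquisitions come from proprietary instruments, so every pipeline is
paired with a synthetic-data generator that produces inputs with known
ground truth; all quantitative claims in the tests and in
`scripts/acceptance.py` are recovery statements about those synthetic
conditions.

## TPEF preprocessing and the Aggregation Index

**Model.** A field of view contains cells whose cofactor fluorescence is
either concentrated in punctate mitochondrial structures or dispersed
through the cytosol. Two acquisition artifacts corrupt the raw frame:
single-pixel cosmic-ray extrema (dark and bright) and a serpentine
distortion in which alternate raster rows are circularly shifted by an
integer number of columns by the motorized stage.

**Procedure.** Processing order is fixed: outlier removal, deskew,
thresholding, metrics.

1. *Cosmic-ray filter.* A pixel is replaced by its 3×3 window median
   when it is the strict unique extremum of the window **and**
   |value − window median| > k·MAD of the window (default k = 5,
   unscaled MAD). The uniqueness requirement restricts the filter to
   genuine single-pixel events: edge and plateau pixels share their
   value with a neighbor and are never modified, which is what makes
   sensitivity 1.0 with zero structure pixels altered achievable on
   noiseless fields.
2. *Serpentine deskew.* The integer shift s ∈ [−max_shift, max_shift]
   maximizing the mean Pearson correlation between odd rows shifted by
   s and their even-row neighbors is applied to the odd rows. Ties are
   broken toward smaller |s|, then negative s. A constant image returns
   shift 0 with a degenerate flag. Circular shifts are exactly
   invertible, so re-injecting the estimated shift reproduces the input
   bit-for-bit.
3. *Thresholding.* A universal absolute threshold of 0.25 a.u.
   separates endogenous signal from diffuse background. The threshold
   is absolute by design — images must already be on that a.u. scale,
   or an explicit calibration divisor must be supplied; there is no
   silent auto-normalization, and the metric is deliberately **not**
   invariant under intensity rescaling.
4. *Metrics, per cell* (masks are required inputs; the bundled Otsu
   segmenter is a convenience, not part of the metric definition):
   `max_tpef` = mean of the top ⌈10%⌉ pixel values in the cell (cells
   under 10 pixels are rejected); area fraction = 100 · (above-threshold
   pixels in cell) / (cell pixels); Aggregation Index
   AI = max_tpef / area fraction [%]. Cells with no above-threshold
   pixel are reported as missing (flagged), never as AI = 0.

Per-cell computation is used throughout because the group comparisons
are over distributions of cells; group pairs are compared with two-sided
Mann–Whitney U tests on AI and on area fraction.

## JC-1 ratiometry

Per-cell ratio = mean(red)/mean(green) inside the label mask; optional
background subtraction uses the per-channel median of unlabeled pixels
(off by default). Cells with non-positive denominators are flagged and
excluded rather than propagated as infinities. Groups are compared with
a two-sample t-test — pooled-variance Student by default, Welch by flag.
The ratio is invariant under common rescaling of both channels (when
background subtraction is off), which is the point of ratiometric dyes.

## MALDI lipid spectra

TIC normalization scales each spectrum to unit total ion count
(idempotent, scale-invariant). Replicate averaging interpolates
linearly onto a common grid over the overlap of all inputs and takes the
pointwise mean. Three half-open m/z regions structure the differential
analysis: Region 1 [600, 825) mixed phosphatides, Region 2 [825, 950)
phosphatidylinositols, Region 3 [1300, 1500) cardiolipins; region
intensity is the trapezoidal integral over the in-region samples
(boundary 825 belongs to Region 2). Peak extraction returns the
windowed maximum within ±0.2 Da by default — the tolerance follows from
a TOF resolving power of ≈5000 at m/z 885.56 (FWHM ≈ 0.18 Da); an
integral mode exists by flag. The annotation table ships the four
diagnostic species — CerP (d16:1/18:0) at 616.47, PG (18:1/18:1) at
773, SM (d18:1/24:1) at 797.67, PG (18:1/22:6) at 819 — and calls
unmatched Region-3 masses cardiolipin at the class level. Per-peak
group differences vs control use two-sided Mann–Whitney U tests on the
TIC-normalized per-spectrum peak intensities; both per-spectrum values
and replicate averages are emitted, since box plots are conventionally
drawn over the hundreds of individual spectra while statistics can be
run on replicate averages.

A note on ranges: acquisition hardware ranges and analysis ranges for
such data can disagree (e.g. an 800–1600 acquisition window vs a
region scheme starting at 600); the module is deliberately
range-agnostic and integrates whatever grid the spectrum carries.

## pLSA

Spectra are TIC-normalized and summed into 1-Da bins (default) to form a
document–term matrix; continuous nonnegative weights enter EM directly —
the pLSA updates never require integer counts. The aspect model
P(d,w) = P(d) Σ_z P(z|d) P(w|z) is fitted by plain EM (no tempering):
E-step posterior P(z|d,w) ∝ P(z|d)P(w|z); M-step re-normalizes the
responsibility-weighted sums. Initialization draws both distributions
from symmetric Dirichlet(1) with the stated seed; 5 restarts (default)
keep the best final log-likelihood; convergence at relative
log-likelihood change < 1e-6 or 500 iterations. The trace is
non-decreasing (EM guarantee, asserted to 1e-10 slack). K = 1 has the
analytic fixed point: P(w|z) equals the corpus term marginal.

Discrimination is read off the document-topic simplex: per-class
centroids of P(z|d), nearest-centroid assignment, accuracy, and a
silhouette score. The factorization itself never sees the labels. Topic
permutation ambiguity is handled in tests by matching dominant topics to
blocks rather than fixing an order.

## Statistical kernels

*Mann–Whitney U*: exact two-sided p by the classical counting recurrence
for the U null distribution (lower tail of min(U, n_x·n_y − U), doubled,
capped at 1), used automatically for tie-free samples with
n_x + n_y ≤ 20; otherwise a normal approximation with midrank tie
correction and 0.5 continuity correction. When U equals its null mean
the two-sided p is exactly 1, so duplicated samples compare as
indistinguishable. *t-tests* delegate to `scipy.stats.ttest_ind`.
*DEG arithmetic*: totals plus half-up-rounded integer percentages (their
sum may be 99–101 by rounding). No multiple-testing correction is
applied by default — per-comparison raw p-values are reported; a
Benjamini–Hochberg helper exists but is opt-in.

## Synthetic generators: what they emulate, and what they do not

*TPEF fields.* Cells are non-overlapping random ellipses (matching the
enlarged, flat senescent morphology and keeping masks unambiguous). The
`aggregation` parameter in [0,1] linearly mixes a punctate component
(Gaussian spots of σ = 2 px, centers ≥ 3σ inside the cell) with a
uniform component over the cell, at a fixed per-cell photon total
(amplitude · 2πσ² · spots), so aggregated and dispersed cells differ in
distribution, not brightness — this forces area fraction to be
non-increasing and AI increasing in `aggregation` on noiseless fields.
Defaults (amplitude 3 a.u., 5 spots, background σ 0.05 a.u., 10 cosmic
rays, serpentine shift 2) put the dispersed in-cell level ≈0.5 a.u.,
comfortably above the 0.25 a.u. threshold, which is where the real
assay operates. Artifact order matters: the stage distortion is applied
before cosmic rays are injected, so the preprocessing order (rays
first, deskew second) is actually exercised. Injected outlier pixels
are accepted only where they register as isolated single-pixel extrema
— a "dark ray" inside a dim or steeply varying neighborhood is not an
observable outlier and would make sensitivity claims meaningless. Not
modeled: two-photon PSF, photobleaching, shot noise, cell-shape
irregularity.

*JC-1 pairs.* Per-cell true ratios are Gaussian draws (polarized mean
2.0, depolarized mean 0.8, σ 0.3, 50 cells/group — effect sizes chosen
to mirror a clear depolarization contrast at the sample sizes the assay
used); channels are piecewise-constant, so measured ratios equal drawn
ratios exactly. Not modeled: spectral crosstalk, dye loading, pixel
noise.

*Spectra.* Sums of Gaussian peaks (FWHM 0.18 Da on a 0.05 Da grid from
600 to 1500) at the annotated diagnostic positions plus supporting PE /
PG / PI / CL species; per-group multiplicative effects by region or by
specific peak (defaults mirror the reported directions: cardiolipins up
in both senescence models, PG 773/819 up everywhere, SM 797.67 down
under doxorubicin); log-normal mean-1 amplitude noise (CV 0.1) and
uniform per-spectrum TIC jitter in [1/1.2, 1.2]; 20 spectra per group.
Not modeled: isotope patterns, baseline drift, mass-calibration error,
detector saturation.

Because the generators are parametric idealizations, a passing recovery
test demonstrates the correctness and calibration of the computation,
not the biological effect sizes of any real experiment.

## Problem sizes and numerical choices

The recovery experiments run at desk scale as the package's own choice
of study conditions: 20 seeds × 20 cells/group on 420×420 px images for
the AI experiment; 20 seeds × 60 spectra for pLSA (K = 3, 3 restarts in
the batch experiment); 1000 Monte-Carlo replicates for MWU calibration;
100 random cells for the top-decile oracle. Degenerate inputs are
handled explicitly: all-zero spectra, constant images, zero-coverage
cells, K exceeding matrix rank, and empty samples all raise or flag
rather than returning silent zeros.

## Known limitations

- The exact a.u. calibration of the 0.25 threshold depends on the
  acquisition setup; it is exposed as a config value and the metric is
  meaningless on uncalibrated intensities.
- The serpentine model assumes one global integer shift for all odd
  rows; sub-pixel or row-varying distortions are out of scope.
- The pLSA variant in commercial MSI software (initialization,
  tempering, K selection) is unpublished; group separation is
  reproduced qualitatively, never numerically.
- Whether per-cell or per-field maxima were used in the original TPEF
  analysis is ambiguous; per-cell is implemented because the reported
  comparisons are over distributions of cells.
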