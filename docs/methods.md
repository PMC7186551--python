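# Methods

`smfishq` quantifies single-molecule RNA FISH combined with
immunofluorescence (smFISH-IF) in budding yeast: it detects individual
mRNAs as diffraction-limited spots in 3D widefield stacks, converts
transcription-site (TS) brightness into nascent-transcript counts, assigns
molecules to outlined cells, scores each cell's cycle phase from its
anti-tubulin IF signal and morphology, and aggregates per-cell statistics.
A synthetic scene generator renders ground-truth stacks with the same
acquisition geometry so that every stage is verifiable quantitatively.

## Image and spot model

Stacks are 41 focal planes at 200 nm z-pitch with 64.5 nm lateral pixels
(100x objective over a 6.45 um camera pixel). A single mRNA hybridized by a
set of short singly-labelled probes appears as one spot; the package models
it as a tri-axial Gaussian with sigma_x = sigma_y (widefield PSF symmetry),
*integrated over each voxel* via error-function differences. The fitted
model per spot is

    I(v) = B + Q * gx(v) * gy(v) * gz(v)

with local background B and integrated intensity Q (ADU*voxel); the peak
amplitude A = Q dx dy dz / ((2 pi)^{3/2} sigma_xy^2 sigma_z) is derived.
Because the renderer and the fitter share the voxel-integrated forward
model, noiseless fits recover generator parameters to machine precision and
rendered mass is conserved exactly up to window truncation — the oracle
tests rely on this.

## Detection pipeline

1. **Bandpass (difference of Gaussians).** sigma_small = 1 px / 0.5 plane,
   sigma_large = 5 px / 2.5 planes; negatives clipped. Single precision is
   used for this stage (candidate finding only).
2. **Pre-detection.** 3D local maxima (26-connectivity) above a threshold;
   the default threshold is data-driven — median + 8 robust SD of the
   unclipped bandpass response — standing in for the interactive tuning on
   a reference cell; thresholds in settings files take precedence. Maxima
   closer than `min_separation` (3 voxels) merge, brighter wins, with a
   deterministic (value, z, y, x) order.
3. **Fitting with neighbour subtraction.** Candidates are fitted
   brightest-first by bounded least squares (scipy `least_squares`, trf;
   sigma_xy in [50, 400] nm, sigma_z in [150, 1000] nm; cost tolerance
   1e-8) on a working copy from which every previously fitted spot is
   subtracted; a second pass refits each candidate with all *other* spots
   removed. The fitted center is constrained within `min_separation` of its
   candidate voxel so a fit cannot drift onto a neighbouring molecule. In
   crowded cells this removes the background inflation and intensity bias
   that single-pass fitting suffers (in our benchmarks, per-spot intensity
   errors drop from a -10%/+150% spread to a few percent).
4. **Acceptance filtering.** A fit is accepted iff converged and every
   parameter is inside its [min, max] bound; rejected fits are kept with a
   per-bound reason; sub-resolution duplicates deduplicate by residual.
   The batch convention then tightens the intensity window to
   [0.5, 1.5] x median accepted Q (`refine_q_bounds`), the programmatic
   equivalent of refining the histogram cursors: residual doublets land
   above the window, dim spurious fits below.

## Single-molecule reference and nascent counting

The single-mRNA reference intensity Q_ref is by default the **median of
accepted per-spot Q** (robust to doublet contamination); the refit of the
averaged, background-subtracted, re-centered spot image is also computed
(visualization parity with the classic averaged-molecule view). Re-centering
uses linear interpolation, which preserves positivity but softens the
averaged image slightly; the refit estimator therefore reads ~1% low, one
reason "robust" is the default.

A transcription site is an intra-nuclear spot (accepted, or rejected only
as over-bright) with Q >= ts_factor * Q_ref (default 1.5: a TS must outshine
a single mRNA by 50%); at most one TS per cell by default (haploid). The
nascent count is max(1, round(Q_ts / Q_ref)); the fractional ratio is kept
for audit. Note the inherent selection: a TS carrying a single transcript is
indistinguishable from a single mRNA and is not called, so the detected-TS
mean nascent count sits slightly above the unconditional mean of the
underlying law (~+0.3 at the default conditions) — as in the real assay.

Cytoplasmic counting uses the same ratio logic for optically merged
molecules: converged cytoplasmic fits are grouped into proximity clusters
(within 2 x min_separation); a cluster containing an over-bright fit counts
as round(total Q / Q_ref), so a split pair is neither dropped nor counted
one-and-a-half times. Accepted singles count one each.

## Cell assignment and cell-cycle scoring

Spots are assigned to cell outlines by lateral point-in-polygon (on-edge
counts inside; overlapping outlines resolve to the smaller polygon). IF
integrated intensity is the sum, inside the cell polygon, of the maximal
projection over planes above the lowest `exclude_bottom = 3` planes (so
slide-bottom debris never enters), minus the whole-image median background.

Phase scoring encodes the standard yeast cues as an ordered decision list:

    M   if spindle_span > 2000 nm          (anaphase spindle)
    G2  elif bud_ratio > 0.35              (large bud)
    S   elif bud_ratio > 0.05              (bud emergence)
    G1  elif IF intensity < cohort 40th percentile  (single SPB, low tubulin)
    unscored otherwise

`bud_ratio` is measured from the outline alone: the rasterized cell mask is
eroded with growing discs until the bud neck pinches it into two fragments,
every pixel is assigned to its nearest fragment, and the smaller/larger
area ratio is returned (0 for round cells). `spindle_span` is the maximal
pairwise distance among IF pixels brighter than background + 30% of the
within-cell peak. A manual scoring CSV, when given, overrides the automatic
decision per cell. On synthetic cohorts at default noise the confusion
accuracy is ~99%.

## Z-drift QC and DIC registration

Stage drift during z-acquisition (~1 px/plane, e.g. from a bubble in the
immersion oil) turns each spot into a slanted streak. The QC detects it by
**spot tracklets**: bright spots are found on the bandpassed stack, each
spot's lateral intensity centroid is followed across +-2 neighbouring
planes, and the median per-spot centroid slope is the drift estimate; the
tracking windows are re-centered on the running estimate over three passes
so large drifts are not attenuated by window truncation. Whole-plane
correlation methods (tried first) fail at smFISH spot densities because
chance alignments between different molecules — especially bright TS —
rival the true correlation peak. The tracklet estimator recovers injected
linear drifts in [0, 2] px/plane to within 0.085 px/plane on all tested
seeds; stacks are flagged above 0.5 px/plane. Featureless stacks are
"not estimable" and never flagged.

DIC-to-fluorescence registration follows the translate workflow: integer
shifts by exhaustive normalized cross-correlation over a +-10 px window,
with a 0.1 correlation confidence floor below which the image is left
unshifted with a warning.

## Synthetic scenes: what they emulate and what they do not

Defaults describe a non-synchronized exponential BY4741 culture probed for
a G1-restricted cyclin transcript with a 48-probe set:

| parameter | default | rationale |
|---|---|---|
| phase fractions G1/S/G2/M | 0.35/0.25/0.25/0.15 | unbudded fraction of an exponential haploid culture |
| expressing fraction (G1 only) | 0.8 | transcript restricted to late G1 |
| mature mRNAs per expressing cell | NB(mean 10.1, size 3.0) | reported cohort mean; NB for the overdispersed per-cell distribution |
| nascent RNAs per active TS | zero-truncated Poisson, mean 3.6 | reported TS mean; at least one transcript at an active site |
| active-TS fraction of expressing cells | 0.22 | reported TS-to-expressing-cell ratio (154/688) |
| per-mRNA brightness | q_probe * Binomial(48, 0.8) | probe-occupancy model; narrow single-molecule histogram (CV 7.2%) |
| PSF sigma_xy / sigma_z | 130 / 350 nm | typical NA-1.35 widefield |
| camera | offset 100 ADU, gain 2 ADU/photon, read SD 2 ADU, autofluorescence 20 ADU | peak-SNR ~10 for a fully-labelled mRNA |
| cell / nucleus radius | 2.0 / 0.9 um, ~3 um axial extent | BY4741 dimensions |

Cells are placed on a jittered grid with collision-checked retries; G1
cells are rounded blobs, later phases two-lobe (mother + bud) unions with
phase-appropriate bud ratios; the tubulin/spindle IF structure is a focus
(G1), twin foci (S), a short bar (G2) or an extended bar (M) whose
integrated photons rise after G1. Artifact injectors reproduce per-plane
z-drift, slide-bottom IF debris, and a DIC proxy (edge map) with a
systematic offset correctable by `register_dic`.

Not emulated: true DIC physics, chromatic aberration, photobleaching,
cell-to-cell autofluorescence variation, segmentation errors in outlines
(outlines are ground truth). Passing tests therefore validate the
quantification machinery under known optics and noise, not the upstream
segmentation or staining quality of real data.

## Problem sizes and numerical choices

The cohort-level verification runs 87 positions x 12 cells = 1044 cells
(~3100 molecules), enough for the bootstrap CI of the expressing-cell mean
to be decisive at the +-0.7 scale of interest; detection benchmarks use ten
100-spot sparse fields; TS recovery uses ladders of 2..8 transcripts; the
bootstrap calibration uses 1000 cohorts of 688 expressing cells — the
study's cohort size, where the percentile bootstrap is near-nominal — with
2000 resamples each (the public default is 10,000 resamples; 2000 keeps the
calibration loop cheap without changing coverage at the 1% level). At small
cohorts (n≈100) the percentile bootstrap of a skewed NB mean under-covers
by 1-2%, which the reporting unit tests document. Random draws are
`numpy.random.default_rng` seeded per scene; channel renders derive
independent streams from (seed, channel) so channels are independent but
reproducible. Degenerate inputs (flat windows, empty scenes, featureless
stacks, cells without nuclei) return flagged results or warnings rather
than raising, except where the contract demands an error (empty probe list,
zero-plane TIFF, missing settings keys).

## Known limitations

- Molecule pairs closer than the diffraction limit are counted by intensity
  ratio, not resolved; per-cell counts are 93-97% exact at default SNR with
  the residual errors concentrated in cells from the NB tail (>20 copies).
- TS with one nascent transcript are not detectable by brightness.
- The phase scorer's IF cut is a cohort percentile; it assumes the cohort
  contains a reasonable G1 fraction.
- Outline-derived bud ratios assume the bud neck is the thinnest part of
  the two-lobe silhouette.
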