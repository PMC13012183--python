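# Methods

This note documents the models behind each analysis stage, the parameter
choices that matter, what the synthetic generators do and do not emulate,
and the numerical conventions fixed for determinism.

## Speckle contrast and flow index

Spatial speckle contrast is `K(x, y) = s / m`, where `s` and `m` are the
sample standard deviation (n−1 denominator, n = 49) and mean of intensity
in a 7x7 window centered on the pixel.  Computation is valid-region only:
the 3-pixel border, and any pixel whose window mean is zero, are flagged
invalid rather than padded or zeroed — padding fabricates contrast at
edges.  The flow index is `ICT = 1/K^2`, undefined (flagged) where K = 0.

Two reduction orders are offered because the field is genuinely split on
it.  `mode="literal"` averages the 15 raw frames of a set first and
computes K on the average; `mode="per_frame"` computes K per raw frame and
averages the K maps.  They are *not* equivalent on dynamic speckle:
averaging decorrelated frames before K suppresses contrast by roughly
1/sqrt(n_frames).  "literal" is the default; users wanting the
conventional per-exposure contrast should use "per_frame".

Relative blood flow is the ROI-mean flow index normalized by its mean over
a baseline frame range, so rBF averages 1 over the baseline and is
invariant to global intensity rescaling.

Occlusion quantification offers the manual route (percent of the window
inside user-drawn polygons) and an automatic surrogate: pixels darker than
a fixed fraction (default 0.02) of the robust (p1–p99) within-window
intensity range, kept only in connected components of at least 50 px to
suppress isolated noise.  A fraction of the intensity *range* — not a
quantile of the pixel distribution — is used because near-black drying
artifacts have essentially zero reflectance while their total area is the
unknown being estimated; a quantile threshold would always flag a fixed
fraction of pixels regardless of the true occluded area.

## Window transparency

The transparency statistic is the percent of brain-masked pixels assigned
to the dark class by Otsu thresholding.  At 530 nm hemoglobin absorbs, so
vessels are dark; the dark class is fixed as the vessel class
(`polarity="dark_vessels"`).  The histogram uses 256 bins spanning the
masked min–max regardless of bit depth, which makes the statistic
deterministic across 8/16-bit inputs and invariant (up to bin
quantization) to affine intensity rescaling.  Ties in the between-class
variance are broken toward the lowest threshold.  Artifact or
inflammation regions are excluded by subtracting user polygons from the
mask before thresholding.

Note one behavior worth knowing: the statistic is *not* monotone under
Gaussian blurring of the image, because Otsu re-adapts and blurred vessel
halos join the dark class.  It is monotone under opacification (vessels
hidden beneath a bright haze), which is the failure mode it is meant to
track.

## Homotopic connectivity

Preprocessing is a fixed-order chain — spatial block-mean downsampling
(512→128, i.e. 4x4 averaging), per-pixel linear detrending, zero-phase
bandpass, global signal regression — followed by mirror-pixel correlation.
Stages can be disabled but never reordered.

* **Detrending** removes a per-pixel least-squares line; the order
  (linear) is a deliberate, minimal choice.
* **Bandpass** is an order-4 Butterworth at 0.035–0.08 Hz applied
  forward–backward (`sosfiltfilt`), so band-interior components keep their
  phase.  The family/order are fixed here for determinism.
* **Global signal regression** removes, per pixel, the OLS projection onto
  the mask-mean time course; residuals are orthogonal to the regressor to
  machine precision.

Homotopic pairs are obtained by reflecting each pixel across the line
through bregma and lambda — the anatomical midline — so that left pairs
with right (medio-lateral mirroring).  Partner lookup is nearest-pixel
(no interpolation, no resampling of time series); pixels on the midline,
pixels whose mirror leaves the image or mask, and zero-variance pixels are
dropped from the paired set.  Pearson r is clipped to |r| ≤ 1−1e-7 before
`z = atanh(r)`; the connectivity index is the plain mean of z over paired
pixels.

For CSD recordings the first 500 frames after induction (~2.8 min at
3 fps, wave still propagating) are discarded and the remainder analyzed as
three 10-min (1800-frame) blocks against a separate baseline recording.
A 32.7-min recording has 5886 frames, leaving 5386 — two full blocks and a
1786-frame third block, which is analyzed and flagged `short` rather than
rejected; a final block under half length raises instead.  When the chain
downsamples, landmark coordinates are rescaled into the downsampled pixel
grid (block-mean by factor f maps pixel x to x/f − (f−1)/(2f)).

## Microglia counting and Sholl analysis

The binarization chain runs, in order: Gaussian blur σ = 0.5 px;
rolling-ball background subtraction with radius 50 px
(`skimage.restoration.rolling_ball`, the classic ball algorithm); Otsu
binarization (bright class = cells, as appropriate for fluorescence);
outlier removal — a pixel is replaced by the median of its radius-2 disk
neighborhood when it deviates from that median by more than 50 on the
0–255 scale, which on a binary image removes isolated flipped pixels;
removal of 8-connected components smaller than 10 px; and a radius-5
median filter.  The provenance (ordered steps with parameters) is attached
to the output.

Sholl profiles sample each concentric circle (5-µm steps) at ≤1-px arc
spacing with nearest-pixel lookup and count maximal contiguous foreground
runs, merging runs that wrap the 0/2π seam.  The maximum radius defaults
to the distance from the center to the nearest image border.  Cell counts
take the post-chain 8-connected components at least as large as a disk of
radius 3 µm — a physiological lower bound on soma size that rejects
detached process fragments — and average over the three maximum-projection
fields.  `fov_from_zoom` records the field-of-view bookkeeping
(443 µm base field; 177.2 µm at 2.5x zoom).

A caution on scale: the radius-5 median filter is an 81-pixel majority
vote, so structures thinner than roughly the filter radius are erased.  At
the intended acquisition scale (2048 px over ~177 µm, 0.0865 µm/px) a 1-µm
process is ~12 px wide and survives; heavily downsampled images should
reduce `median_radius` accordingly.

## Synthetic generators

All generators are seed-deterministic (identical params + seed give
bit-identical output) and return a ground-truth dictionary alongside the
data; recovery tests read truth only from it.

* **Dynamic speckle.**  The complex field is white circular Gaussian noise
  filtered by a circular frequency-domain aperture (grain size, default
  4 px), evolving between exposure substeps as AR(1) with coefficient
  `exp(−dt/tau_c)` — a Lorentzian-type decorrelation.  A frame integrates
  the exposure as the mean of 16+ substep intensities; partial coherence
  β is modeled as incoherent averaging of `round(1/β)` independent
  patterns.  The expected contrast for given τc/T is *not* taken from a
  closed form but from `expected_contrast_bruteforce`, a many-realization
  single-pixel simulation of the same process, avoiding any
  model-vs-formula mismatch.  Intensities are quantized to 8 bits at mean
  ~40 counts; recovery tolerances absorb the quantization.  Note the
  oracle describes per-exposure ensemble contrast: a windowed estimate is
  biased slightly low by the finite window and grain correlation, and
  "literal"-mode averaging of decorrelated frames lowers K further by
  design.
* **Bilateral hemodynamics.**  For each homotopic pixel pair,
  `left = sqrt(ρ)·s + sqrt(1−ρ)·e_L` and mirrored for the right, with s,
  e_L, e_R independent unit-variance Gaussian processes band-limited to
  0.035–0.08 Hz (white noise filtered by the same order-4 zero-phase
  Butterworth and standardized), so the mirror-pixel correlation is ρ by
  construction.  Pair assignment is exactly mirror-symmetric about the
  bregma–lambda line; midline and unpaired pixels get independent signals.
  Optional nuisance terms: linear drift (counts/frame), a common in-band
  global component, and white noise.  Signals map to 8-bit intensity at
  128 ± 18 counts/SD.  Defaults (1800 frames at 3 fps — one 10-min block)
  match the block length the connectivity analysis uses.
* **CSD movies.**  On top of a bilateral movie, the ipsilateral
  hemisphere receives (a) a radially propagating intensity gain — brief
  hyperemia (x1.4 for ~10 s) then oligemia (x0.75) recovering linearly —
  and (b) a variance-preserving attenuation of the shared component
  (`att·s + sqrt(1−att²)·e2`), dropping to 0.15 at onset and recovering
  over `recovery_frames` (default 3600 frames = 20 min, so block 1 is
  suppressed and block 3 is back at baseline).  The contralateral
  hemisphere is bit-identical to the no-CSD movie at the same seed; CSD
  randomness comes from an independent stream.
* **Vessels / occlusion.**  Vessels are smoothed random walks dilated to
  the target width, accumulated until the foreground fraction is within
  0.01 of target (exact mask recorded); occlusions are near-black disks
  placed entirely inside the window until their union reaches the target
  fraction.
* **Microglia.**  A cell is a disk soma plus k straight radial branches at
  roughly even angles (optional bifurcation doubling the distal count),
  rasterized at the requested width, over a background gradient plus
  noise.  Default geometry (4-µm soma, 20-µm branches, 0.5 µm/px) keeps
  rings at 5/10/15 µm strictly between soma edge and branch tips.

What the generators do **not** emulate: photon transport or skull
scattering, realistic vascular topology, hemodynamic response shapes
beyond band-limited Gaussians, spatially correlated noise, motion, or
non-radial microglial arbors.  Passing recovery tests therefore
demonstrates that the analysis chain measures what it claims under its own
statistical assumptions — not that those assumptions hold in any given
recording.

## Problem sizes used in the test and acceptance runs

The verification suite favors many small problems over few large ones:
bilateral movies are 24x24 x 1800 frames (the statistic is averaged over
~260 independent pixel pairs, giving sub-0.01 standard error on the mean
Fisher z), CSD movies 24x24 x 5900 frames, speckle fields 128x128, vessel
and occlusion images 256x256, and morphology fields 256x256 at 0.5 µm/px.
These sizes leave recovery tolerances dominated by the estimators
themselves rather than simulation noise.

## Known limitations

* The occlusion "auto" method assumes artifacts are the darkest structures
  in the window; dark vessels in raw (non-LSCI-averaged) images could
  confound it.  The polygon route exists for exactly that case.
* Otsu-based transparency assumes a bimodal masked histogram; a fully
  opaque window (unimodal) yields a threshold splitting noise, and a
  constant region raises a degenerate-input error by design.
* Mirror pairing is nearest-pixel; sub-pixel midline placement can drop a
  one-pixel seam of pairs near the line.
* The connectivity index is reported without any group-level statistics;
  per-block CSV output is the intended hand-off to statistical software.
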