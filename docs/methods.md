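# Methods

## Scope and model

The package reconstructs 2D dynamic PET frames from Poisson sinogram data by
kernelized expectation-maximization (KEM), where the kernel encodes
similarity of per-pixel feature vectors extracted from composite-frame prior
reconstructions — prior intensity plus two texture descriptors (GGCM inverse
difference moment, GLRLM long-run low gray-level emphasis). It also contains
everything needed to validate the method end to end: a digital phantom with
regional kinetics, a forward model, and image-quality metrics.

## Forward model

The system operator P is a 2D parallel-beam projector: 210 angles uniform
over [0°, 180°), 249 radial bins spanning the grid diagonal (both scale
proportionally for smaller grids). Discretization is pixel-driven with linear
splatting: each pixel center's radial coordinate `r = x·cosθ + y·sinθ` is
split linearly between its two bracketing bins, scaled by the bin width so
sinogram values approximate line integrals in pixel units. This choice has
two properties EM depends on: the backprojector is the *exact transpose* of
the forward projector (one sparse matrix serves both directions), and total
mass per view is preserved exactly, bin widths notwithstanding. A ray-driven
(Joseph) discretization was considered and rejected because with 249 bins
over the 217-pixel diagonal the ray spacing exceeds one pixel and per-view
mass acquires interpolation ripple.

Attenuation is bin-wise multiplicative: survival factors
`exp(−∫μ dl)` computed by projecting a μ-map with the same geometric
operator, baked into P (and its adjoint). The default μ is water-like
(0.0096 per pixel ≈ per mm) over the head support. Pixels outside the
inscribed circle are never projected and are frozen at zero.

## Phantom and acquisition

The phantom emulates an axial brain slice with nested elliptical regions:
head support, gray-matter shell, white-matter core, and a tumor disc of
radius 5 pixels (81 pixels when rasterized by center containment) embedded in
white matter, on a 217×217 grid. It is a programmatic emulation — it
reproduces region topology, contrast and scale, not the convoluted cortical
geometry of a real anatomical slice; conclusions about texture descriptors on
real anatomy (where neighborhood structure varies much more) should be drawn
cautiously from it.

Regional kinetics are piecewise-linear time–activity curves in arbitrary
units, chosen once to emulate typical FDG brain kinetics: gray matter peaks
early (≈1.0 at 4 min) and washes out slightly; white matter rises slowly to a
low plateau (≈0.35); the tumor rises fast and keeps accumulating (1.1 at
5 min → 1.9 at 60 min), exceeding gray matter; extra-cerebral background
stays low. The 24-frame schedule is 4×20 s, 4×40 s, 4×60 s, 4×180 s, 8×300 s
(60 min). Frames store *expected emissions* (frame-mean rate × duration), so
projection followed by Poisson sampling needs no extra time weighting; the
frame mean of each piecewise-linear curve is computed exactly (trapezoid on
segment knots).

Counts are calibrated globally: expected prompts (trues + background) over
the whole study total 3.0×10⁷, of which 20% is background, modelled as a
spatially uniform sinogram per frame. The global fraction is apportioned
across frames proportionally to each frame's trues (the study states only
the global fraction; proportional apportionment keeps the per-frame
background-to-trues ratio constant). Each of the (default 10) noise
realizations draws independent Poisson counts from its own seeded
sub-stream (`SeedSequence(seed).spawn`), so realizations are reproducible
individually and jointly.

Composite frames for priors: the study duration is split into three equal
wall-clock intervals (20 min each → frames 1–16, 17–20, 21–24 of the default
schedule) and member sinograms are summed. Interval edges must coincide with
frame boundaries — a Poisson frame cannot be split — and the rebinning
conserves counts exactly.

## Texture descriptors

Quantization maps a patch to integer levels `INT(f·N/f_M)+1` clamped to
[1, N] with N = 8 levels; a zero maximum maps everything to level 1. The
clamp resolves the boundary case where the raw formula yields N+1 at the
patch maximum; the degenerate rule avoids division by zero deterministically.
Gradients use the standard 3×3 Sobel kernels (magnitude `√(gx²+gy²)`),
with replicate padding.

* GGCM: joint histogram H(i,j) of (gray level, gradient level), P = H/ΣH;
  IDM = Σ P(i,j)/(1+(i−j)²) ∈ (0, 1], equal to 1 only when all mass is
  diagonal.
* GLRLM: counts of *maximal* runs (Galloway semantics — a run of length j
  contributes one count at column j) of equal quantized level along
  0°/45°/90°/135° at unit step; N_L equals the window's longest possible run.
  LRLGE = (1/n_r)·Σ p(i,j)·j²/i², averaged over the four directions.
* GLCM correlation (comparator feature): Haralick correlation of the
  symmetric unit-offset cooccurrence matrix, four directions averaged;
  defined as 0 for zero-variance windows.

Feature maps slide a window over the image (5×5 for GGCM and GLCM, 3×3 for
GLRLM) with replicate padding at borders. The quantization maxima can be
taken per window (`normalization="window"`: descriptors measure pure local
contrast) or from the whole image (`"global"`: one quantization shared by
all windows, so maps discriminate absolute regional structure). The map
default is global — the standard construction in sliding-window texture
analysis, and markedly less noise-sensitive on reconstructed priors — while
the single-patch functions are window-local by definition. All windowed maps
are numba-compiled and call the same jitted cores as the single-patch API,
so there is exactly one implementation of each definition; the test suite
checks them against independently written brute-force code.

## Kernel

Feature channels (three prior intensities, then each texture map across the
priors) are z-scored per channel over the field of view; channels with
near-zero variance are set to zero rather than divided by it. Per-channel
scaling follows the cited KEM convention and makes σ = 1 scale-free; it also
means every channel gets equal distance weight (see Limitations). Each
in-mask pixel's k = 50 nearest neighbors (Euclidean distance in feature
space) are found within a 9×9 spatial search window — k must be below the
window's candidate count; pixels near the mask boundary may have fewer —
with ties broken by ascending flat pixel index (candidates are enumerated in
row-major order and sorted stably). K holds `exp(−d²/2σ²)` on neighbor
pairs and 1 on the diagonal; rows are normalized to unit sum by default so K
maps constants to themselves, which keeps reconstructed activity
quantitative. The un-normalized form is available by flag.

## Reconstruction

MLEM and KEM share one implementation (MLEM is the K = None path, and an
explicit identity kernel reproduces MLEM bitwise):

```
α ← α / (Kᵀ Pᵀ 1) · Kᵀ Pᵀ ( y / (P K α + r) ),    x̂ = K α̂
```

Numerical conventions: α starts at 1 inside the field of view; pixels with
zero sensitivity are frozen at 0; EM-ratio denominators are floored at 1e-12
of their positive mean; the expected background r enters the denominator
only and is never backprojected as data. Nonnegativity holds by
construction; the Poisson log-likelihood is non-decreasing per iteration
(verified to 1e-9 relative tolerance in tests). Priors use 100 MLEM
iterations per composite; dynamic reconstruction applies one shared kernel
to every frame independently. Default 100 iterations.

## Metrics

SNR = 10·log10(ΣT²/Σ(T−R)²) dB with T the reconstruction and R the truth
(numerator uses the reconstructed image as printed in the defining formula;
a reference-energy variant is available by flag). NMSE = Σ(T−R)²/ΣT².
SSIM is the global single-window form with c1 = (0.01·L)², c2 = (0.03·L)²
and L the dynamic range; it is exactly 1 for identical images. The regional
SD is (1/R̄)·√(Σ(T−R)²/(n−1)) over a mask — a truth-referenced normalized
RMS deviation, implemented as printed in its defining formula; an
across-realizations ensemble SD is also provided since "background SD"
often means that in the literature. CRC divides the reconstructed ROI
contrast (T̄_ROI/T̄_BGD − 1) by the true contrast. Phantom ROI conventions:
tumor mask as ROI; white matter excluding a 2-pixel dilation of the tumor as
both the CRC background and the noise region.

## Problem sizes used in validation

The test suite exercises the full 217×217 study for the EM guarantees
(likelihood monotonicity over 100 iterations on frame 24, identity-kernel
reduction) and a scaled study — 128×128 grid, 3 realizations, 50
iterations, frames 12 and 24 — for the method comparison; simulator
calibration uses a 64×64 phantom with 200 realizations. These sizes are the
package's validation conditions; all parameters other than grid size,
realization count and iteration count keep their defaults.

## Limitations

* The phantom is piecewise-constant with smooth elliptical boundaries. On
  such an object the composite-prior *intensities* are already a sufficient
  statistic for region identity, and with equal-weight (z-scored) channels
  the texture descriptors contribute the same regional signal at lower
  signal-to-noise. Consequently the dual-texture kernel robustly beats MLEM
  (NMSE typically 5–8× lower) but does not outperform the intensity-only
  kernel on this phantom — its tumor CRC trails the intensity-only method
  by ~0.01–0.03 at matched iterations, across feature normalizations,
  bandwidths and channel weightings that were examined. Texture features
  can only add information when neighborhood structure varies in ways
  point intensity does not capture (convoluted anatomy, textured uptake);
  this phantom does not emulate that regime.
* No scatter model beyond the uniform background; no detector blurring,
  dead time or normalization effects; 2D only; no OSEM subsets.
* The printed SD formula mixes truth-deviation and noise; both readings are
  computed but only the printed one enters the default reports.
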