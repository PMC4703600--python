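# Methods

## The pipeline

`endocolor` implements a two-stage scheme for enhancing endoscopic frames
and restoring (or re-toning) their color from a *theme image* — a color
frame from a nearby anatomical location.

### Stage 1 — grayscale enhancement

A color input P is reduced to luminance with the hardware-friendly weights

    Y = R/4 + G/2 + B/4

evaluated exactly as (R + 2G + B)/4 with a single round-to-nearest step
(white maps to 255 and every achromatic pixel is a fixed point; three
truncating divisions would map white to 253). A grayscale input passes
through unchanged.

Endoscopic captures are over-lit and low-contrast: their histograms sit in
the low intensities with support starting well above zero. The histogram is
therefore shifted left by the global minimum, Yh = Y − Ymin (the exact
minimum, not a percentile), after which a modified unsharp mask sharpens the
mucosal structure:

    ΔY  = Yh − g(Yh),        Yeh = Yh + λ·ΔY

where g is a Gaussian blur and λ the sharpening factor. λ in 2–8 works
well; the default is 4 (the midpoint), values above 8 log a warning because
the residual's noise is magnified and ringing appears, and values above 16
are rejected. The blur uses σ = 2.0 px with support truncated at
ceil(3σ) per side (>99% of kernel mass) and reflective borders. All
intermediate arithmetic is float; the result is clipped to [0, 255] and
rounded once at the end, since λ up to 8 necessarily overshoots the 8-bit
range at edges.

### Stage 2 — dictionary-based colorization

A 256-row lookup table Z maps each luminance value to an (R, G, B) triplet:

1. **Binning.** Every theme pixel lands in the bin of its luminance.
2. **Collision averaging.** Colliding triplets are averaged channel-wise at
   float precision (e.g. a bin holding (32, 16, 8) and (0, 28, 0) stores
   (16, 22, 4)).
3. **Pinning and gap filling.** Rows 0 and 255 are pinned to full black and
   full white *before* filling, so every run of empty rows is bounded; a run
   M..M+d between observed rows M−1 and M+d+1 is filled channel-wise by

       X[M+i] = X[M−1] + (X[M+d+1] − X[M−1])·(i+1)/(d+2),  i = 0..d.

   A variant of this formula with the slope term's sign flipped circulates
   in some descriptions of the scheme; it extrapolates *away* from the next
   observed entry and is unbounded, which contradicts both the stated intent
   ("linear interpolation between the two nearest neighboring entries") and
   the bounded map plots it is meant to produce. The sign-corrected form
   above is the default; the flipped form is kept behind
   `printed_form=True` / `--printed-interpolation` for auditing, with its
   output clipped.
4. **Smoothing.** The raw interpolated table ripples, which shows up as
   color artifacts; each channel is smoothed independently as a 1-D series
   over Y. Six families are supported — moving average, linear/quadratic
   local regression, Savitzky–Golay (order 2), and robust variants of the
   local regressions — over spans {5, 9, 15, 19} (other odd spans are
   accepted with a logged note). The default is linear local regression
   with span 19, the best-scoring combination under the luminance
   round-trip PSNR protocol. Local regression is tricube-weighted least
   squares over the nearest-span window (the LOWESS/LOESS convention;
   verified against statsmodels to 1e-8); robust variants add five bisquare
   re-weighting passes; the moving average shrinks its window symmetrically
   at the ends so straight lines are reproduced exactly. After smoothing
   the endpoints are re-pinned and values clipped to [0, 255]. Whether
   pinning happens before or after smoothing is a genuinely open choice; we
   pin both before gap filling (needed for boundedness) and after smoothing
   (so the finalized invariant always holds).

Colorization is then a pure per-pixel table lookup, and a tone curve (a
256-entry per-channel transfer table, the generic hook for virtual
chromoendoscopy tone models) can be composed onto a fitted map, with
endpoints re-pinned. Bin means stay at float precision until the map is
quantized once at application time.

Because every bin entry is a mean of pixels whose luminance *is* that bin
index, the finalized map is approximately luminance-preserving, and
linear gap-filling between luminance-consistent anchors preserves that
property; this is why regenerating the luminance of a colorized image is
nearly lossless (>40 dB PSNR in the acceptance suite; exact on many
synthetic themes).

## Metric suite

* **PSNR** — 10·log10(255²/MSE); identical images report the sentinel
  `inf`.
* **SVR** — the cited statistics-of-visual-representation formulas are not
  printed in the sources that name them; we use the documented
  reconstruction contrast = (σp − σo)/σo, intensity = (μp − μo)/μo, which
  is dimensionless and carries the expected sign semantics (enhancement
  gives higher contrast, darker tone). Undefined cases (σo = 0 or μo = 0)
  return NaN.
* **UIQ** — Wang–Bovik index on 8×8 sliding windows with unit weights,
  including the original implementation's degenerate-window conventions.
* **CIE94 ΔE** — evaluated from the definition on skimage's sRGB→Lab
  (D65/2°) conversion, with the ΔH² term floored at zero so identical
  pixels give an exact 0.
* **SSIM / MSSIM / SHSIM** — computed on the Cb/Cr planes of *full-range*
  BT.601 YCbCr (the common studio-range conversion would compress chroma).
  SSIM is the global single-window form; MSSIM averages the 11×11
  Gaussian-window (σ = 1.5) local map with the standard stabilizing
  constants at dynamic range 255, matching skimage's SSIM map on interior
  windows to 1e-7; SHSIM is a documented variant — the local structural
  term multiplied by hue agreement 1 − |Δh|/π, where h is the angle of the
  window-averaged chroma vector (Cr−128, Cb−128).
* **CM / CEF** — the opponent-channel colorfulness metric
  sqrt(σ²rg + σ²yb) + 0.3·sqrt(μ²rg + μ²yb) and the processed/original
  ratio. CM of an exactly achromatic image is 0, so CEF against a grayscale
  original is +inf when the processed image carries chroma (unbounded
  enhancement) and NaN when both are achromatic.

## Synthetic scenes

The generator emulates what the pipeline needs from real endoscopy frames
and nothing more: a low-frequency mucosa-toned random field (correlation
length ≈ min(H, W)/8), darker curvilinear vessel strokes (smooth random
walks stamped at the requested width), a randomly off-center radial
vignette for inhomogeneous lighting, a slight smooth chroma modulation,
additive Gaussian channel noise, and a histogram concentrated in the low
intensities. Three palettes: `red-mucosa` (R > G > B pixel-wise, WLI-like),
`pink-mucosa`, and `nbi-dark` (green/blue cast of raw narrow-band
captures).

Defaults: 256×256, 8 vessels of width 2–5 px, noise σ = 3, low-intensity
bias 0.7 (at least 70% of luminance mass below 128). Two calibrations are
part of the generator's contract rather than free dials: the luminance
field is standardized to mean 0.42 / sd 0.13 per scene, so scenes drawn
from one parameter set share brightness statistics and a theme/target pair
differs in geometry, not palette (their colorfulness agrees within 25%);
and values are floored at 0.12 (channel clip at 6), giving every scene the
clearly nonzero black level characteristic of the over-lit captures the
histogram-shift stage exists for. One integer seed drives fixed sub-streams
(background, vessels, noise, pair geometry), so generation is deterministic
component-wise.

What passing on these scenes does **not** show: robustness to specular
highlights, lesions, fine mucosal texture, compression artifacts, or
anatomical mismatch between theme and target — real deployments should
validate on real frames.

## Numerical choices and edge cases

* Rounding: luminance and map application round half away from zero on
  exact quotients; blur/sharpen round once after clipping.
* Problem sizes in the test and acceptance suites (96–128 px scenes,
  10–20 seeds) were chosen as the smallest sizes at which the field
  statistics stabilize; every check runs in seconds on one core.
* Degenerate inputs: empty themes are rejected; a theme with a single
  luminance value still yields a complete map (two linear ramps through the
  pinned endpoints); constant images are fixed points of blurring and
  sharpening and map to all-zero after shifting.
* `ThemeColorizer.fit_transform` is deliberately disabled: `fit` consumes a
  theme image and `transform` a grayscale image, so the fused call would be
  a type error.

## Known limitations

* Theme selection is manual, as intended — no automatic anatomical
  matching.
* The map is global in luminance: two structures with equal luminance get
  equal color (collision averaging can blur hue boundaries); this is
  inherent to the dictionary design, not an implementation limit.
* SVR and SHSIM are reconstructions (flagged above); absolute values are
  comparable within this package, not necessarily with other codebases.
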