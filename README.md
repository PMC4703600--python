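# endocolor

Enhancement and theme-based color reproduction for endoscopic images.

Endoscopy frames — white-light, raw narrow-band (NBI) and capsule captures —
are often over-lit, low-contrast, and sometimes transmitted or stored as
grayscale to save power and bandwidth. `endocolor` implements a lightweight
two-stage pipeline for such frames:

1. **Grayscale enhancement.** The luminance channel Y = R/4 + G/2 + B/4 is
   histogram-shifted left by its minimum (Yʰ = Y − Y_min) and sharpened with
   a modified unsharp mask Yᴱᴴ = Yʰ + λ(Yʰ − g(Yʰ)), where g is a Gaussian
   blur and λ the sharpening factor (recommended 2–8, default 4).
2. **Colorization.** A dynamic 256-entry dictionary Z : Y → (R, G, B) is
   learned from a *theme image* (a color frame from a nearby anatomical
   location): theme pixels are binned by luminance, collisions averaged
   channel-wise, gaps filled by linear interpolation between the nearest
   observed entries with rows 0/255 pinned to black/white, and the table
   smoothed per channel (default: linear local regression, span 19).
   Colorizing is then a pure per-pixel lookup; a 256-entry tone curve can be
   composed onto the map for virtual-chromoendoscopy style re-toning.

The package also ships the full-reference metric suite used to evaluate
such pipelines (PSNR, SVR contrast/intensity, UIQ, CIE94 ΔE, SSIM/MSSIM/
SHSIM on YCbCr chroma, colorfulness CM and the enhancement factor CEF) and
a deterministic generator of endoscopy-like synthetic scenes, so everything
is testable without clinical data.

## Worked example

```sh
endocolor synth theme.png  --seed 1 --size 128x128   # synthetic WLI scene
endocolor synth target.png --seed 2 --size 128x128
python -c "from endocolor.io import *; \
           write_image(rgb_to_luminance(read_image('target.png')), 'gray.png')"
endocolor colorize gray.png theme.png colorized.png \
          --save-map map.csv --report report.csv
cat report.csv
```

```
psnr_db,77.9705
```

The report line is the luminance round-trip fidelity: converting the
colorized output back to luminance and comparing it with the enhanced
grayscale input gives 77.97 dB PSNR, i.e. the learned dictionary is almost
exactly luminance-preserving — color is added without disturbing the
structure the clinician reads. `map.csv` holds the fitted 256-row table
(`Y,R,G,B,provenance`), with each row flagged `observed`, `interpolated`,
or `pinned`.

Comparing the colorized result with the original color scene:

```sh
endocolor evaluate target.png colorized.png
```

```
stem,psnr_db,svr_contrast,svr_intensity,uiq,cie94_delta_e,ssim,mssim,shsim,cef
target,22.566253,0.241867,-0.204415,0.462879,8.026570,0.885169,0.808351,0.802780,1.002572
```

Read: the enhancement stage raised global contrast by 24% (`svr_contrast`
> 0) and darkened the mean by 20% (`svr_intensity` < 0) — the intended
direction for over-lit frames — while the chroma planes of the colorized
image stay structurally close to the true colors (`ssim`/`mssim`/`shsim`
≈ 0.8–0.89) with colorfulness fully restored (`cef` ≈ 1.0 against the
color original).

The same pipeline from Python, sklearn-style:

```python
from endocolor import GrayscaleEnhancer, ThemeColorizer

enhanced  = GrayscaleEnhancer(sharpening_factor=4.0).fit_transform(frame)
colorized = ThemeColorizer(span=19).fit(theme).transform(enhanced)
```

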